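# icptrack

Detection and tracking of the three characteristic peaks of the
intracranial-pressure (ICP) pulse waveform.

Continuous ICP monitoring in the neuro-ICU produces a quasi-periodic
signal whose single-cardiac-cycle beats are *triphasic*: each carries a
percussion (P1), tidal (P2) and dicrotic (P3) sub-peak.  The latencies and
elevations of these peaks track cerebrovascular state, so locating them
automatically — per beat, and continuously across beats despite noise and
signal dropouts — is a core primitive of ICP morphological analysis.  This
package is for researchers benchmarking such peak detectors and trackers:
it provides a generative simulator with exact groundtruth, the standard
preprocessing chain, six single-pulse detectors, four sequential trackers,
and a cross-validated evaluation harness.

## What is inside

**Simulator** (`icptrack.simulate`) — a beat is a 3-component Gaussian
mixture over beat time plus a diastolic baseline,

    w(t) = Σ_k π_k e_k exp(−(t − l_k)² / 2σ_k²) + b·S(t),

with two independent sine processes drifting each component's latency and
elevation across beats, uniform noise at a fraction of signal range, and
randomly placed missing segments of 2–4 consecutive beats.  Every beat
carries exact peak annotations.  `fit_pulse_gmm` refits the mixture to a
set of beats by weighted EM.

**Preprocessing** (`icptrack.preprocess`) — resample each beat to 400
samples, circularly shift its minimum to the first element, normalize the
area under the curve to 1; peak annotations map through every transform
and back.

**Detectors** (`icptrack.detectors`) — regression from the preprocessed
beat to the three peak latencies (ms): spectral regression (SR) and its
RBF-kernelized form (KSR), support vector regression, a feed-forward
neural network, extremely randomized trees with Gaussian-sampled split
thresholds, and an LSTM.  Elevations are read off the waveform at the
predicted latencies.

**Trackers** (`icptrack.trackers`) — refine per-beat peak observations
across a sequence: a constant-velocity Kalman filter, nonparametric belief
propagation (particle messages on the p1–p2–p3 chain with temporal edges),
MOCAIP-style designation (representative pulse by hierarchical clustering,
curvature candidates, Gaussian-prior designation), and an LSTM sequence
filter.  The LSTM and MOCAIP also infer peaks for missing beats; Kalman
and NBP require input every beat and refuse the missing-data protocol.

**Evaluation** (`icptrack.evaluation`) — patient-level nested
cross-validation with noise sweeps for the detectors, and
tracking/missing-data protocols for the trackers, reporting per-peak MAE
and RMSE in ms.

## Worked example

```python
import numpy as np
import icptrack as it
from icptrack.evaluation import run_experiment2

df, traces = run_experiment2(trackers=["kalman", "nbp"],
                             noise_levels=[0.05], n_beats=300, seed=1)
print(df[df["peak"] == "avg"][["tracker", "mae_ms", "rmse_ms"]].round(3))
```

prints

```
        tracker  mae_ms  rmse_ms
3        kalman   1.790    2.101
7           nbp   1.576    1.914
8   observation   1.857    2.131
```

A 300-beat sequence is simulated with slow sinusoidal drift of each peak;
its groundtruth latency/elevation streams are perturbed by uniform noise
at 5% of each stream's range (the `observation` row: raw noisy
observations err by ~1.9 ms on average).  Both trackers filter the streams
to below the observation error — about 1.6–1.8 ms mean absolute latency
error averaged over P1–P3, comfortably inside the ±3 ms band that makes
peak-trend monitoring usable.

The same from the command line:

```bash
icptrack simulate --n-pulses 300 --seed 1 --out seq.h5
icptrack detect --method ksr --train seq.h5 --in seq.h5 --out preds.csv
icptrack track --tracker kalman --in seq.h5 --obs preds.csv --out tracked.csv
icptrack benchmark --out-dir bench/   # reduced detection+tracking tables
```

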