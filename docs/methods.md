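# Methods

`icptrack` benchmarks algorithms that locate the three sub-peaks of the
intracranial-pressure (ICP) pulse — P1 (percussion), P2 (tidal) and P3
(dicrotic) — within segmented beats and across beat sequences.  A peak is
the pair (latency `l`, elevation `e`): time from beat onset in ms and
pressure height.  Because annotated clinical ICP recordings are scarce, the
package ships a generative simulator with exact groundtruth; everything
below is evaluated against that simulator.

## The pulse simulator

**Shape model.**  A beat is a 3-component Gaussian mixture over beat time.
Component k has weight π_k, latency l_k (fraction of the beat), temporal
width σ_k, and elevation e_k; the rendered waveform on an n-sample grid is

    w(t) = Σ_k π_k (e_k + Δe_k) exp(−(t − (l_k + Δl_k))² / 2σ_k²) + b·S(t)

The term b·S(t), with S(t) = (1 − e^{−t/0.02}) e^{−t/1.2} and b = 0.15, is
a diastolic baseline: a real ICP beat starts at a sharp end-diastolic
minimum, rises steeply with the systolic upstroke, and decays slowly until
the next beat truncates it.  Without this floor the rendered tail is flat
near zero and the minimum-based alignment point (below) becomes unstable
under noise, which is not how real beats behave.

Default components (chosen once to reproduce a normal triphasic beat with
P1 sharpest and tallest): π = (0.35, 0.35, 0.30), l = (0.13, 0.33, 0.55),
σ = (0.045, 0.060, 0.075), e = (1.00, 0.85, 0.70); beat duration 1000 ms at
400 Hz → 400 samples.  Latency units are fs-aware so other rates work.

**Groundtruth.**  The annotated latency of peak k is the local maximum of
the rendered waveform nearest the component centre, refined to sub-sample
precision by a parabolic fit; if bump overlap suppresses the maximum, the
component centre is used and flagged.  The annotated elevation is the
linear interpolation of the sampled waveform at that latency, so the
annotation/waveform consistency invariant holds exactly by construction.

**Temporal dynamics.**  Two independent sine processes act on every
component, one on latency and one on elevation, with beat index as time:
amplitudes 0.03 of the beat (latency) and 10% of the component elevation,
periods 60 and 97 beats, phase 0.  The incommensurate periods keep latency
and elevation from moving in lockstep.  Small iid Gaussian jitter (sd
0.003 beat / 2% elevation, clipped at 3 sd) adds beat-to-beat variability.
A validation step guarantees the excursions can never reorder the peaks.

**Noise.**  Uniform additive noise at a level λ ∈ {0, 5, 10, 15}% of signal
range: each value gets + U(−a, a) with a = λ·range.  For waveforms the
range is the pulse's own range; for peak-observation streams each latency
and elevation stream is scaled by its own range and perturbed
independently.  Perturbations are strictly bounded by a.

**Missing data.**  The sequence is split into groups of 30 beats; each
group receives 2–3 non-overlapping missing segments of 2–4 consecutive
beats, separated by at least one observed beat so runs never merge beyond
4.  Masked beats carry no waveform or annotation; the availability mask
records them.

**Patients.**  A synthetic "patient" is an independent draw of the shape
model: latencies jittered ±0.02, elevations and widths ±10%, weights ±15%
(renormalized), rejected if any pair of components comes closer than 0.08.
This makes patient-level cross-validation meaningful on simulated data.

**Model refitting.**  `fit_pulse_gmm` treats the (mean) pulse as a
pressure-weighted density over beat time and runs a weighted 1-D EM with
one extra fixed-shape background component (the diastolic envelope, free
weight) that absorbs the floor mass; it is hand-written because sklearn's
GaussianMixture has no sample weights.  A 1-D curve determines only the
products π_k e_k and σ_k, so π and e are not separately identifiable; the
package adopts the convention that weights are the temporal mass fractions
of the bump components and elevations follow from bump heights.  Under the
default parameters, generate-then-refit recovers latencies within 0.02 of
the beat and weights within 0.05 — the identifiability convention and the
generating weights happen to agree that closely; for very different
width/elevation profiles the recovered weights would be the mass fractions,
not π.

## Preprocessing

Each beat is (1) linearly resampled to 400 samples spanning the beat, (2)
circularly shifted so the (first) minimum is element 0 — a heart-rate-free
alignment point, (3) scaled to unit AUC (sample sum 1), removing the
unreliable absolute pressure magnitude.  Annotations map through the same
transforms (index = latency mapped through the resampling grid, minus the
shift, modulo 400; elevation divided by the AUC scale) and back; forward
then inverse is the identity to 1e-9.  Latency targets and errors are
always expressed in original beat time (ms), so MAE is well-defined across
heart rates.

## Single-pulse detectors

All six regress the preprocessed 400-vector onto the three peak latencies
(ms).  Elevations are never regressed: they are read off the waveform at
the predicted latencies.  Training beats with a missing peak are excluded
only for that peak's target (per-target sub-models when the target matrix
has NaNs).  Independent per-peak regressors do not guarantee l1 < l2 < l3,
so predictions pass through an ordering projection (sort), with a flag when
it changed anything.

- **SR / KSR** (spectral regression): a symmetrized k-NN affinity graph
  (heat-kernel weights, self-scaled by the median neighbour distance) over
  the training pulses defines a smoothness objective Σ (ŷ_i − ŷ_j)² W_ij.
  The model takes the m smoothest non-trivial generalized eigenvectors of
  the graph Laplacian as an embedding, learns an out-of-sample map from
  features to the embedding (ridge for SR; RBF kernel ridge for KSR,
  kernel exp(−β‖x_i − x‖²)), and ridge-regresses the latencies on the
  embedding.  On a full graph with the full embedding the composite is
  exactly kernel ridge regression, which the tests verify against the
  closed form.
- **SVR**: one RBF ε-insensitive support vector machine per peak;
  prediction is recomputed from the stored support vectors, dual
  coefficients and bias alone, and is checked against a brute-force dual
  QP on a tiny problem.
- **NN**: a small multilayer perceptron minimizing sum-of-squared errors;
  the optimizer contract is the objective, and the default solver is the
  quasi-Newton lbfgs.
- **Extra-Trees (Gaussian splits)**: an ensemble of randomized regression
  trees in which each candidate threshold is drawn from a Gaussian fitted
  to the feature's values at the node, the best candidate by variance
  reduction wins, and leaves close on (near-)constant targets or fewer
  than 2·min_samples_leaf samples (a stopping floor that pure "constant
  output" never reaches with continuous targets).  A uniform-threshold
  variant (sklearn ExtraTreesRegressor) sits behind a config switch.
- **LSTM**: a compact numpy LSTM (standard forget/input/output gate
  equations, BPTT, Adam) consumes the pulse sequentially in 16-sample
  chunks (25 steps; every sample enters the network, only the step
  granularity is coarser than 1) and regresses the final hidden state onto
  the three latencies.

Default hyperparameter grids are small and centred on the observed feature
scale (median squared distance between preprocessed pulses ≈ 6e−4, hence
RBF widths around 1.7e3); the nested cross-validation's inner folds pick
within them.

## Trackers

Observations are the per-beat (latency, elevation) triples — in the
default protocol the simulator's groundtruth perturbed by uniform noise,
optionally the KSR detector's outputs.

- **Kalman**: per peak, an independent linear filter on the 4-D state
  (latency, elevation and their beat-to-beat velocities), constant-velocity
  transition, no control input.  The gain is the standard
  K = P⁻Hᵀ(HP⁻Hᵀ+R)⁻¹.  The measurement covariance R should be the known
  or estimated observation-noise variance (the harness passes a²/3 for
  uniform noise of half-width a); the process variance is estimated from
  the observation second differences after removing the 6R noise
  contribution.
- **NBP** (nonparametric belief propagation): per beat, three nodes with
  hidden variable (l, e), chain edges p1–p2–p3 carrying Gaussian
  inter-peak-offset potentials, a temporal edge per peak to its previous
  belief (widened by the increment variance), and Gaussian observation
  potentials.  Messages are mixtures of D Gaussian kernels (default 75)
  built by importance sampling from the observation×temporal product,
  reweighting by incoming messages, condensation back to D kernels, and
  propagation through the pairwise potential; two synchronous sweeps are
  exact on the 3-chain.  Potential parameters are estimated from training
  annotations.  In the single-component limit the belief means match a
  closed-form Gaussian BP filter to within Monte-Carlo tolerance.
- **MOCAIP**: windows of 60 consecutive beats (standing in for the 1-min
  clinical segment at ~1 Hz beat rate) are reduced to a representative
  pulse by hierarchical clustering (correlation distance, average linkage,
  cut at 0.3; mean of the largest cluster), candidates are extracted from
  the representative's second derivative (local maxima plus inflections of
  the convex/concave regions on the ascending and descending edges), and
  the ordered candidate triple maximizing the summed log-likelihood under
  per-peak Gaussian priors over (latency, elevation) — fitted on training
  annotations only — is designated.  Designation is verified against
  exhaustive triple enumeration.
- **LSTM filter**: a sequence-to-sequence numpy LSTM over the 6-vector of
  observations, trained to output the true positions (a learned temporal
  denoiser).  On masked beats it free-runs on its own previous output,
  which is how it bridges missing-data gaps.

Kalman and NBP update only on observed input; they are refused on the
missing-data protocol, which is restricted to the LSTM filter and MOCAIP.

## Evaluation protocols

**Detection (nested CV).**  Patient-level outer folds (default 10, reduced
3 for the benchmark presets) split synthetic patients into train/test;
inner folds (default 3, reduced 2) on the outer-training patients pick
hyperparameters by latency MAE; the winner is refit on the full outer
training set.  No patient id ever appears on both sides, which the harness
asserts.  Metrics: MAE and RMSE per peak and averaged, with RMSE reported
both in ms and in normalized latency (fraction of beat) — the two scales
answer different questions and only the ms numbers are comparable to MAE.
Beats with a missing groundtruth peak stay in the experiment; that peak is
simply skipped in the error. Noise replicates the whole dataset
at each level before preprocessing, matching a monitoring setup in which
train and test beats share the noise source.  One consequence, visible in
the harness and worth knowing: training on noisy beats acts as data
augmentation, so between high noise levels the error of the stochastic
methods is not strictly monotone.  The robustness invariant in the test
suite therefore trains on clean beats and raises only the test noise,
under which every detector degrades monotonically.

**Tracking.**  A training and an evaluation sequence (the training one
twice as long) come from the same model and dynamics; whatever needs
fitting (LSTM filter, MOCAIP prior, NBP potentials) sees only the training
sequence.  Observation noise is applied per stream; trackers are scored
against groundtruth on observed beats (or only on masked beats in the
missing-data protocol).  The raw observation MAE is reported alongside as
the baseline a tracker must beat.  MOCAIP's output is a window-level step
function; with the default sine dynamics (period 60 beats, amplitude 30
ms) its within-window error is necessarily larger than the observation MAE
at 5% noise (~1.5 ms), so "filtering beats observations" is asserted for
Kalman/NBP/LSTM and only logged for MOCAIP — consistent with its coarser
granularity and with its role as the training-free option.

## Numerical choices and edge cases

- Alignment ties break to the first index; interpolation is linear
  everywhere; AUC normalization refuses zero-sum beats.
- EM: deterministic quantile initialisation with a seeded 1e-4
  perturbation; convergence on relative log-likelihood change < 1e-10;
  variance floor 1e-8.
- Kalman rejects non-PSD Q/R; an R of exactly 0 is floored at 1e-12, which
  leaves a ~1e-6 ms residual between filtered output and observations in
  the zero-noise limit.
- NBP kernel bandwidths follow Silverman's rule on the belief particles;
  degenerate (all-zero) importance weights fall back to uniform with a
  resample.
- MOCAIP's second-derivative sign analysis uses a curvature floor of
  1e-6·max|d2| (with an absolute guard) so float noise on flat or linear
  stretches creates no candidates.
- LSTM training keeps the best-loss epoch; gradients are norm-clipped at 5;
  the forget-gate bias starts at +1.

## What the simulator does and does not show

Passing these benchmarks shows the methods recover peaks whose shape
family, slow drift, noise and missingness match the generative model:
smooth triphasic beats, sinusoidal drift, bounded uniform noise,
well-separated bumps.  Real ICP adds pathological morphologies (rounded
P2-dominant beats), respiration/ABP coupling, segmentation errors, sensor
drift and heavy-tailed artifacts, none of which are modelled; absolute
errors here say nothing about clinical recordings, only the relative
behaviour of the methods under controlled variability does.  Benchmark
problem sizes (300-beat sequences; 10 patients × 150 beats with 3×2 folds)
are the package's reference conditions and are deliberately modest; all
presets scale up through configuration.

## Known limitations

- The LSTM detector is the weakest and most seed-sensitive of the six
  (cross-patient generalization from a few synthetic patients is hard for
  a sequence model reading raw chunks).
- NBP's particle condensation introduces a small bias relative to exact
  inference (visible only against the closed-form oracle).
- The mixture-weight identifiability convention above means `fit_pulse_gmm`
  weights are comparable across fits of similar waveforms, not physical π.
- Model persistence for fitted detectors uses joblib, the sklearn-ecosystem
  standard; HDF5 is reserved for sequence data.
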