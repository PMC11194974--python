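"""Compact numpy LSTM with backpropagation through time.

One LSTM layer with the standard gate equations

    F_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        forget gate
    I_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        input gate
    O_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        output gate
    Ct~ = tanh   (W_c [h_{t-1}, x_t] + b_c)        candidate cell
    C_t = F_t * C_{t-1} + I_t * Ct~
    h_t = O_t * tanh(C_t)

followed by a linear readout.  Trained with full-batch Adam on mean squared
error; small fixed-size problems only (a few hundred sequences of at most a
few hundred steps), which is exactly the regime of single-beat latency
regression and beat-to-beat peak filtering.

The four gate blocks are stored in the order [f, i, o, c] inside one weight
matrix of shape (n_in + n_hidden, 4 * n_hidden).
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMCore", "lstm_step"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def lstm_step(x_t, h_prev, c_prev, W, b):
    """One LSTM step; returns (h, c, cache).  Gate order [f, i, o, c]."""
    H = h_prev.shape[-1]
    concat = np.concatenate([h_prev, x_t], axis=-1)
    z = concat @ W + b
    f = _sigmoid(z[..., :H])
    i = _sigmoid(z[..., H : 2 * H])
    o = _sigmoid(z[..., 2 * H : 3 * H])
    g = np.tanh(z[..., 3 * H :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c, (concat, f, i, o, g, c_prev, c)


class LSTMCore:
    """LSTM layer + linear readout, trained by BPTT with Adam."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        d = n_in + n_hidden
        scale = 1.0 / np.sqrt(d)
        self.W = rng.uniform(-scale, scale, size=(d, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[:n_hidden] = 1.0  # forget-gate bias: remember by default
        self.Wout = rng.uniform(-scale, scale, size=(n_hidden, n_out))
        self.bout = np.zeros(n_out)
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self._adam = None

    # -- forward ---------------------------------------------------------

    def forward(self, X: np.ndarray, h0=None, c0=None):
        """X (B, T, n_in) -> hidden states (B, T, H) and per-step caches."""
        B, T, _ = X.shape
        H = self.n_hidden
        h = np.zeros((B, H)) if h0 is None else h0
        c = np.zeros((B, H)) if c0 is None else c0
        hs = np.empty((B, T, H))
        caches = []
        for t in range(T):
            h, c, cache = lstm_step(X[:, t], h, c, self.W, self.b)
            hs[:, t] = h
            caches.append(cache)
        return hs, caches

    def readout(self, hs: np.ndarray) -> np.ndarray:
        return hs @ self.Wout + self.bout

    # -- backward --------------------------------------------------------

    def _backward(self, X, hs, caches, d_hs):
        """Gradient of a loss with upstream d_hs (B, T, H) w.r.t. W, b."""
        B, T, _ = X.shape
        H = self.n_hidden
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            concat, f, i, o, g, c_prev, c = caches[t]
            dh = d_hs[:, t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [df * f * (1 - f), di * i * (1 - i), do * o * (1 - o), dg * (1 - g**2)],
                axis=-1,
            )
            dW += concat.T @ dz
            db += dz.sum(axis=0)
            dh_next = (dz @ self.W.T)[:, :H]
        return dW, db

    # -- training --------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        mode: str = "last",
        epochs: int = 120,
        lr: float = 1e-2,
        clip: float = 5.0,
        verbose: bool = False,
    ) -> list[float]:
        """Train on X (B, T, n_in).

        mode='last': Y (B, n_out), loss on the final hidden state only
        (sequence-to-one).  mode='seq': Y (B, T, n_out), loss at every step
        (sequence-to-sequence).  Returns the per-epoch loss history; the
        parameters of the best epoch are kept.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        params = [self.W, self.b, self.Wout, self.bout]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss, best = np.inf, None
        history = []
        B = X.shape[0]
        for epoch in range(1, epochs + 1):
            hs, caches = self.forward(X)
            if mode == "last":
                pred = self.readout(hs[:, -1])
                err = pred - Y
                loss = float(np.mean(err**2))
                dpred = 2 * err / err.size
                dWout = hs[:, -1].T @ dpred
                dbout = dpred.sum(axis=0)
                d_hs = np.zeros_like(hs)
                d_hs[:, -1] = dpred @ self.Wout.T
            else:
                pred = self.readout(hs)
                err = pred - Y
                loss = float(np.mean(err**2))
                dpred = 2 * err / err.size
                dWout = np.einsum("bth,bto->ho", hs, dpred)
                dbout = dpred.sum(axis=(0, 1))
                d_hs = dpred @ self.Wout.T
            history.append(loss)
            if loss < best_loss:
                best_loss = loss
                best = [p.copy() for p in params]
            dW, db = self._backward(X, hs, caches, d_hs)
            grads = [dW, db, dWout, dbout]
            gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
            if gnorm > clip:
                grads = [g * (clip / gnorm) for g in grads]
            for k, (p, g) in enumerate(zip(params, grads)):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g**2
                mhat = m[k] / (1 - beta1**epoch)
                vhat = v[k] / (1 - beta2**epoch)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
            if verbose and epoch % 20 == 0:
                print(f"epoch {epoch}: loss {loss:.6g}")
        if best is not None:
            self.W, self.b, self.Wout, self.bout = best
        return history
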