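"""Independent brute-force / closed-form oracles used by the test-suite.

Each oracle re-derives the expected answer by a route independent of the
implementation it checks: dense linear algebra for the spectral regressors,
an exact-KKT quadratic program for the support vector machine, scalar
Gaussian message algebra for belief propagation, and exhaustive enumeration
for peak designation.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg
from scipy.optimize import minimize
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# spectral regression: dense reimplementation of the three-stage pipeline
# ---------------------------------------------------------------------------


def dense_spectral_regression(W, X, Y, Xt, alpha, target_alpha, beta=None):
    """Plain-numpy spectral regression (graph embedding -> feature map ->
    target map); ``beta`` switches the feature map to an RBF kernel ridge."""
    n = W.shape[0]
    d = np.maximum(W.sum(axis=1), 1e-12)
    dis = 1.0 / np.sqrt(d)
    L = np.eye(n) - dis[:, None] * W * dis[None, :]
    L = 0.5 * (L + L.T)
    vals, vecs = scipy.linalg.eigh(L)
    m = min(n - 1, vecs.shape[1] - 1)
    E = dis[:, None] * vecs[:, 1 : m + 1]
    E = E / np.maximum(np.linalg.norm(E, axis=0), 1e-12)

    if beta is None:
        # ridge with intercept: centre, solve normal equations
        Xc = X - X.mean(axis=0)
        A = Xc.T @ Xc + alpha * np.eye(X.shape[1])
        coef = np.linalg.solve(A, Xc.T @ (E - E.mean(axis=0)))
        E_hat = (Xt - X.mean(axis=0)) @ coef + E.mean(axis=0)
    else:
        K = np.exp(-beta * cdist(X, X, "sqeuclidean"))
        dual = np.linalg.solve(K + alpha * np.eye(n), E)
        E_hat = np.exp(-beta * cdist(Xt, X, "sqeuclidean")) @ dual

    Ec = E - E.mean(axis=0)
    w = np.linalg.solve(Ec.T @ Ec + target_alpha * np.eye(E.shape[1]), Ec.T @ (Y - Y.mean(axis=0)))
    return (E_hat - E.mean(axis=0)) @ w + Y.mean(axis=0)


def kernel_ridge_closed_form(X, y, Xt, beta, alpha):
    """k(x)' (K + aI)^-1 (y - mean) + mean."""
    K = np.exp(-beta * cdist(X, X, "sqeuclidean"))
    c = np.linalg.solve(K + alpha * np.eye(len(X)), y - y.mean(axis=0))
    return np.exp(-beta * cdist(Xt, X, "sqeuclidean")) @ c + y.mean(axis=0)


# ---------------------------------------------------------------------------
# support vector regression: brute-force dual QP + exact KKT refinement
# ---------------------------------------------------------------------------


def svr_dual_qp(X, y, Xt, beta, C, epsilon):
    """Solve the epsilon-SVR dual numerically, refine the active set by an
    exact linear solve, and predict at Xt."""
    n = len(y)
    K = np.exp(-beta * cdist(X, X, "sqeuclidean"))

    def neg_dual(a):
        d = a[:n] - a[n:]
        return 0.5 * d @ K @ d + epsilon * np.sum(a) - y @ d

    best = None
    for t in range(3):
        x0 = np.random.default_rng(t).uniform(0, C / 4, 2 * n)
        r = minimize(
            neg_dual, x0, bounds=[(0, C)] * 2 * n,
            constraints=[{"type": "eq", "fun": lambda a: np.sum(a[:n] - a[n:])}],
            method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or r.fun < best.fun:
            best = r
    d = best.x[:n] - best.x[n:]

    tolb = 1e-5 * C
    free = [i for i in range(n) if tolb < abs(d[i]) < C - tolb]
    dfix = np.where(np.abs(d) >= C - tolb, C * np.sign(d), 0.0)
    dfix[free] = 0.0
    A = np.zeros((len(free) + 1, len(free) + 1))
    rhs = np.zeros(len(free) + 1)
    A[: len(free), : len(free)] = K[np.ix_(free, free)]
    A[: len(free), -1] = 1.0
    A[-1, : len(free)] = 1.0
    rhs[: len(free)] = y[free] - epsilon * np.sign(d[free]) - K[np.ix_(free, range(n))] @ dfix
    rhs[-1] = -dfix.sum()
    sol = np.linalg.solve(A, rhs)
    d_exact = dfix.copy()
    d_exact[free] = sol[: len(free)]
    b = sol[-1]
    return np.exp(-beta * cdist(Xt, X, "sqeuclidean")) @ d_exact + b


# ---------------------------------------------------------------------------
# exact Gaussian belief propagation on the per-beat 3-chain (filtering)
# ---------------------------------------------------------------------------


def gaussian_bp_filter(obs, d12, d23, tau, q, r):
    """Closed-form counterpart of the particle tracker in the
    single-component Gaussian limit: per beat, exact tree BP on p1-p2-p3
    with Gaussian messages; the temporal prior is the previous belief
    marginal widened by the increment variance q.  1-D (per coordinate)."""
    obs = np.asarray(obs, float)
    n, K = obs.shape
    means = np.zeros((n, K))
    shift = {(0, 1): d12, (1, 2): d23, (1, 0): -d12, (2, 1): -d23}
    prior = None

    def product(m1, v1, m2, v2):
        v = 1.0 / (1.0 / v1 + 1.0 / v2)
        return v * (m1 / v1 + m2 / v2), v

    for t in range(n):
        if prior is None:
            bm, bv = obs[t].copy(), np.full(K, r)
        else:
            prm, prv = prior[0], prior[1] + q
            bv = 1.0 / (1.0 / r + 1.0 / prv)
            bm = bv * (obs[t] / r + prm / prv)
        msgs = {}
        msgs[(0, 1)] = (bm[0] + shift[(0, 1)], bv[0] + tau)
        m12 = product(bm[1], bv[1], *msgs[(0, 1)])
        msgs[(1, 2)] = (m12[0] + shift[(1, 2)], m12[1] + tau)
        msgs[(2, 1)] = (bm[2] + shift[(2, 1)], bv[2] + tau)
        m10 = product(bm[1], bv[1], *msgs[(2, 1)])
        msgs[(1, 0)] = (m10[0] + shift[(1, 0)], m10[1] + tau)

        out_m = np.empty(K)
        out_v = np.empty(K)
        out_m[0], out_v[0] = product(bm[0], bv[0], *msgs[(1, 0)])
        mm, vv = product(bm[1], bv[1], *msgs[(0, 1)])
        out_m[1], out_v[1] = product(mm, vv, *msgs[(2, 1)])
        out_m[2], out_v[2] = product(bm[2], bv[2], *msgs[(1, 2)])
        means[t] = out_m
        prior = (out_m, out_v)
    return means


# ---------------------------------------------------------------------------
# exhaustive peak designation
# ---------------------------------------------------------------------------


def exhaustive_designation(latencies, elevations, prior):
    """Best ordered triple by brute-force enumeration over all index
    combinations, scored with the prior's own log-likelihood."""
    m = len(latencies)
    best, best_t = -np.inf, None
    for i, j, k in itertools.product(range(m), repeat=3):
        if not (i < j < k):
            continue
        s = (
            prior.log_likelihood(0, latencies[i], elevations[i])
            + prior.log_likelihood(1, latencies[j], elevations[j])
            + prior.log_likelihood(2, latencies[k], elevations[k])
        )
        if s > best:
            best, best_t = s, (i, j, k)
    return best_t
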