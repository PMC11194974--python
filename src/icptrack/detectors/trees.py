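"""Extremely randomized regression trees with Gaussian-sampled splits.

Each tree is grown top-down; at every node a random subset of features is
considered and, for each, one candidate threshold is drawn from a Gaussian
fitted to that feature's values at the node (mean, sd of the training
samples reaching it).  The best candidate by variance reduction wins.
Growth stops when a node's targets are (near-)constant or too few samples
remain; leaves predict the node's target mean, and the forest averages over
its trees.

A conventional variant with thresholds drawn uniformly in the feature range
(sklearn's ExtraTreesRegressor) is available behind ``split_rule='uniform'``
for comparison.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import ExtraTreesRegressor

from .base import PeakDetector

__all__ = ["GaussianSplitForest"]

_LEAF = -1


class _Tree:
    """Flat-array binary tree: feature/threshold per node, leaf values."""

    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[np.ndarray] = []

    def _new_node(self) -> int:
        self.feature.append(_LEAF)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(None)  # type: ignore[arg-type]
        return len(self.feature) - 1

    def build(self, X, Y, idx, rng, max_features, min_samples_leaf, n_retries) -> int:
        node = self._new_node()
        y = Y[idx]
        if idx.size < 2 * min_samples_leaf or np.all(np.ptp(y, axis=0) < 1e-12):
            self.value[node] = y.mean(axis=0)
            return node
        d = X.shape[1]
        feat_pool = rng.permutation(d)[:max_features]
        best = None
        for _ in range(n_retries):
            for f in feat_pool:
                col = X[idx, f]
                mu, sd = col.mean(), col.std()
                if sd < 1e-12:
                    continue
                thr = rng.normal(mu, sd)
                mask = col <= thr
                nl = int(mask.sum())
                if nl < min_samples_leaf or idx.size - nl < min_samples_leaf:
                    continue
                yl, yr = y[mask], y[~mask]
                score = nl * np.sum(yl.mean(axis=0) ** 2) + (idx.size - nl) * np.sum(
                    yr.mean(axis=0) ** 2
                )  # maximizing between-group sum of squares == variance reduction
                if best is None or score > best[0]:
                    best = (score, int(f), float(thr), mask)
            if best is not None:
                break
        if best is None:
            self.value[node] = y.mean(axis=0)
            return node
        _, f, thr, mask = best
        self.feature[node] = f
        self.threshold[node] = thr
        self.left[node] = self.build(X, Y, idx[mask], rng, max_features, min_samples_leaf, n_retries)
        self.right[node] = self.build(X, Y, idx[~mask], rng, max_features, min_samples_leaf, n_retries)
        return node

    def predict(self, X: np.ndarray, n_out: int) -> np.ndarray:
        out = np.empty((X.shape[0], n_out))
        for r in range(X.shape[0]):
            node = 0
            while self.feature[node] != _LEAF:
                node = self.left[node] if X[r, self.feature[node]] <= self.threshold[node] else self.right[node]
            out[r] = self.value[node]
        return out


class GaussianSplitForest(PeakDetector):
    def __init__(
        self,
        n_estimators: int = 30,
        max_features: str | int = "sqrt",
        min_samples_leaf: int = 5,
        n_retries: int = 5,
        split_rule: str = "gaussian",
        seed: int = 0,
    ) -> None:
        super().__init__()
        if n_estimators < 1:
            raise ValueError("tree count must be >= 1")
        if split_rule not in ("gaussian", "uniform"):
            raise ValueError(f"unknown split rule {split_rule!r}")
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.n_retries = n_retries
        self.split_rule = split_rule
        self.seed = seed

    def _resolved_max_features(self, d: int) -> int:
        if self.max_features == "sqrt":
            return max(1, int(np.sqrt(d)))
        return min(int(self.max_features), d)

    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        self._n_out = Y.shape[1]
        if self.split_rule == "uniform":
            self._forest = ExtraTreesRegressor(
                n_estimators=self.n_estimators,
                max_features=self._resolved_max_features(X.shape[1]) / X.shape[1],
                min_samples_leaf=self.min_samples_leaf,
                random_state=self.seed,
            )
            self._forest.fit(X, np.squeeze(Y))
            self._trees = None
            return
        self._forest = None
        mf = self._resolved_max_features(X.shape[1])
        idx = np.arange(X.shape[0])
        self._trees = []
        root = np.random.default_rng(self.seed)
        for _ in range(self.n_estimators):
            t = _Tree()
            t.build(X, Y, idx, np.random.default_rng(root.integers(2**31)),
                    mf, self.min_samples_leaf, self.n_retries)
            self._trees.append(t)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        if self._trees is None:
            P = self._forest.predict(X)
            return P[:, None] if P.ndim == 1 else P
        acc = np.zeros((X.shape[0], self._n_out))
        for t in self._trees:
            acc += t.predict(X, self._n_out)
        return acc / len(self._trees)
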