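"""Deterministic CART regression tree for parameter fusion.

Binary recursive partitioning minimizing within-leaf sum of squared errors
(variance reduction). The implementation is intentionally deterministic:
candidate thresholds are midpoints between consecutive distinct feature
values, features are scanned in ascending index order, and exact ties in
split quality keep the earlier (lower feature index, then lower threshold)
candidate. Descent convention: a sample goes left when ``value < threshold``
and right when ``value >= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError


@dataclass
class TreeNode:
    value: float
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    """CART regression tree with fixed depth/leaf-size hyperparameters."""

    max_depth: int = 4
    min_leaf: int = 3
    root: TreeNode | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be [n x p] and y length n")
        if y.size == 0:
            raise InsufficientDataError("empty training set")
        if y.size < 2 * self.min_leaf:
            raise InsufficientDataError(
                f"need at least 2*min_leaf = {2 * self.min_leaf} samples, got {y.size}"
            )
        self.root = self._grow(X, y, depth=0)
        return self

    def _best_split(self, X: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
        n, p = X.shape
        best: tuple[float, int, float] | None = None  # (sse, feature, threshold)
        for j in range(p):
            order = np.argsort(X[:, j], kind="stable")
            xs = X[order, j]
            ys = y[order]
            # cumulative sums give left/right SSE at every cut in O(n)
            csum = np.cumsum(ys)
            csum2 = np.cumsum(ys**2)
            total, total2 = csum[-1], csum2[-1]
            for i in range(self.min_leaf, n - self.min_leaf + 1):
                if xs[i - 1] == xs[i]:
                    continue  # not a boundary between distinct values
                thr = 0.5 * (xs[i - 1] + xs[i])
                sse_left = csum2[i - 1] - csum[i - 1] ** 2 / i
                nr = n - i
                sse_right = (total2 - csum2[i - 1]) - (total - csum[i - 1]) ** 2 / nr
                sse = sse_left + sse_right
                if best is None or sse < best[0] - 1e-12 * max(1.0, abs(best[0])):
                    best = (sse, j, thr)
        if best is None:
            return None
        return best[1], best[2]

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(value=float(y.mean()))
        if (
            depth >= self.max_depth
            or y.size < 2 * self.min_leaf
            or np.ptp(y) == 0
        ):
            return node
        split = self._best_split(X, y)
        if split is None:
            return node
        j, thr = split
        mask = X[:, j] < thr
        node.feature = j
        node.threshold = float(thr)
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def predict_one(self, x: np.ndarray) -> float:
        if self.root is None:
            raise RuntimeError("tree is not fitted")
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] < node.threshold else node.right
        return node.value

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array([self.predict_one(row) for row in X])

    @property
    def depth(self) -> int:
        def _d(node: TreeNode | None) -> int:
            if node is None or node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    @property
    def n_leaves(self) -> int:
        def _n(node: TreeNode | None) -> int:
            if node is None:
                return 0
            if node.is_leaf:
                return 1
            return _n(node.left) + _n(node.right)

        return _n(self.root)
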