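"""Least-squares CART regression tree used as the boosting base learner.

Greedy recursive binary partitioning: each split is chosen to minimize the
summed squared error of the two children over all (feature, threshold)
candidates, where candidates are midpoints between consecutive distinct
sorted feature values.  Splitting stops at the depth limit, when a child
would fall below ``min_samples_leaf`` subjects, or when no split strictly
reduces the SSE.  Ties among equal-SSE splits are broken deterministically:
lowest feature index first, then lowest threshold.

A row is routed left iff ``x[feature] <= threshold``.  Leaf values are the
means of their training targets; the boosting loop may overwrite them
(terminal-node refits) through :meth:`RegressionTree.set_leaf_values`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["RegressionTree"]


def _find_best_split(x_sorted, y_sorted, min_leaf):
    """Best threshold for one pre-sorted feature column.

    Returns (sse, threshold) or None if no admissible split exists.
    SSE is computed from prefix sums; candidate positions are restricted to
    boundaries between distinct feature values with both children holding at
    least ``min_leaf`` rows.
    """
    n = x_sorted.shape[0]
    cs = np.cumsum(y_sorted)
    cs2 = np.cumsum(y_sorted * y_sorted)
    total, total2 = cs[-1], cs2[-1]
    k = np.arange(1, n)  # left-child sizes
    valid = (x_sorted[:-1] < x_sorted[1:]) & (k >= min_leaf) & (n - k >= min_leaf)
    if not np.any(valid):
        return None
    k = k[valid]
    left_sum, left_sum2 = cs[k - 1], cs2[k - 1]
    sse = (left_sum2 - left_sum**2 / k) + (
        (total2 - left_sum2) - (total - left_sum) ** 2 / (n - k)
    )
    best = int(np.argmin(sse))  # first minimum => lowest threshold on ties
    thr = 0.5 * (x_sorted[k[best] - 1] + x_sorted[k[best]])
    return float(sse[best]), float(thr)


class RegressionTree(BaseEstimator):
    """Depth-limited least-squares regression tree.

    Parameters
    ----------
    max_depth : int, default 6
        Maximum number of split levels below the root (0 = a single leaf).
    min_samples_leaf : int, default 10
        Minimum training subjects in any leaf.

    Attributes
    ----------
    tree_ : dict
        Nested node records.  Internal: ``{"feature", "threshold", "left",
        "right"}``; leaf: ``{"value", "n", "leaf_id"}``.
    n_features_in_ : int
    n_leaves_ : int
    """

    def __init__(self, max_depth: int = 6, min_samples_leaf: int = 10):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] == 0:
            raise ValueError("cannot fit a tree on empty input")
        if X.shape[0] != y.shape[0]:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
        if not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        if self.max_depth < 0 or self.min_samples_leaf < 1:
            raise ValueError("max_depth must be >= 0 and min_samples_leaf >= 1")
        self.n_features_in_ = X.shape[1]
        self._leaf_counter = 0
        self.tree_ = self._grow(X, y, np.arange(X.shape[0]), depth=0)
        self.n_leaves_ = self._leaf_counter
        del self._leaf_counter
        return self

    def _grow(self, X, y, idx, depth):
        y_node = y[idx]
        n = idx.shape[0]
        if depth >= self.max_depth or n < 2 * self.min_samples_leaf:
            return self._leaf(y_node)
        node_sse = float(np.sum((y_node - y_node.mean()) ** 2))
        best = None  # (sse, feature, threshold)
        for f in range(X.shape[1]):
            col = X[idx, f]
            order = np.argsort(col, kind="stable")
            found = _find_best_split(col[order], y_node[order], self.min_samples_leaf)
            if found is None:
                continue
            sse, thr = found
            if best is None or sse < best[0]:  # strict < keeps lowest feature on ties
                best = (sse, f, thr)
        if best is None or best[0] >= node_sse - 1e-12 * max(1.0, node_sse):
            return self._leaf(y_node)
        _, f, thr = best
        go_left = X[idx, f] <= thr
        return {
            "feature": int(f),
            "threshold": float(thr),
            "left": self._grow(X, y, idx[go_left], depth + 1),
            "right": self._grow(X, y, idx[~go_left], depth + 1),
        }

    def _leaf(self, y_node):
        leaf = {
            "value": float(np.mean(y_node)),
            "n": int(y_node.shape[0]),
            "leaf_id": self._leaf_counter,
        }
        self._leaf_counter += 1
        return leaf

    # -- prediction ----------------------------------------------------------
    def _check_X(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; tree was fitted with {self.n_features_in_}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        X = self._check_X(X)
        out = np.empty(X.shape[0], dtype=float)
        self._route(self.tree_, X, np.arange(X.shape[0]), out, key="value")
        return out

    def apply(self, X) -> np.ndarray:
        """Leaf id reached by each row."""
        X = self._check_X(X)
        out = np.empty(X.shape[0], dtype=float)
        self._route(self.tree_, X, np.arange(X.shape[0]), out, key="leaf_id")
        return out.astype(int)

    def _route(self, node, X, idx, out, key):
        if "value" in node:
            out[idx] = node[key]
            return
        go_left = X[idx, node["feature"]] <= node["threshold"]
        self._route(node["left"], X, idx[go_left], out, key)
        self._route(node["right"], X, idx[~go_left], out, key)

    def set_leaf_values(self, values: dict):
        """Overwrite leaf predictions, e.g. after a terminal-node refit.

        ``values`` maps leaf_id -> new value; leaves absent from the mapping
        keep their fitted mean.
        """

        def walk(node):
            if "value" in node:
                if node["leaf_id"] in values:
                    node["value"] = float(values[node["leaf_id"]])
                return
            walk(node["left"])
            walk(node["right"])

        walk(self.tree_)
        return self

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "n_features": self.n_features_in_,
            "root": self.tree_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        tree = cls(max_depth=d["max_depth"], min_samples_leaf=d["min_samples_leaf"])
        tree.n_features_in_ = int(d["n_features"])
        tree.tree_ = d["root"]
        tree.n_leaves_ = sum(1 for _ in _iter_leaves(d["root"]))
        return tree


def _iter_leaves(node):
    if "value" in node:
        yield node
    else:
        yield from _iter_leaves(node["left"])
        yield from _iter_leaves(node["right"])
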