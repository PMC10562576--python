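"""Gradient-boosted decision trees for binary classification.

Second-order boosting with the logistic objective: each tree is fit to the
gradient/hessian statistics of the current margin, leaf weights are
``-G / (H + lambda)``, and split gain is

    0.5 * (GL^2/(HL+lambda) + GR^2/(HR+lambda) - G^2/(H+lambda)) - gamma

so the regularisation hyperparameters keep their usual meaning: ``gamma``
is the minimum loss reduction required to split, ``min_child_weight`` the
minimum hessian sum in a child, ``subsample`` the row fraction drawn
(without replacement) per tree, ``colsample_bytree`` the feature fraction
per tree.  The implementation is self-contained so that exact
path-dependent SHAP attributions can be computed from the stored trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Tree", "BoostedTreesClassifier"]

_LEAF = -1


@dataclass
class Tree:
    """Flat-array binary tree; ``children_* == -1`` marks a leaf.

    ``value`` holds the leaf weight (learning rate included); ``cover`` the
    number of training rows routed through each node.
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    value: np.ndarray
    cover: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        for i, x in enumerate(X):
            node = 0
            while self.children_left[node] != _LEAF:
                if x[self.feature[node]] < self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            out[i] = self.value[node]
        return out

    def expected_value(self) -> float:
        """Cover-weighted mean leaf value (the tree's contribution for an
        unknown input under the path-dependent expectation)."""

        def rec(node: int) -> float:
            left = self.children_left[node]
            if left == _LEAF:
                return float(self.value[node])
            right = self.children_right[node]
            cl, cr = self.cover[left], self.cover[right]
            return (cl * rec(left) + cr * rec(right)) / (cl + cr)

        return rec(0)


class _TreeBuilder:
    def __init__(self, max_depth, reg_lambda, gamma, min_child_weight, learning_rate):
        self.max_depth = max_depth
        self.lam = reg_lambda
        self.gamma = gamma
        self.mcw = min_child_weight
        self.lr = learning_rate
        self.feature, self.threshold = [], []
        self.left, self.right = [], []
        self.value, self.cover = [], []

    def _new_node(self, n_rows: int) -> int:
        idx = len(self.feature)
        self.feature.append(_LEAF)
        self.threshold.append(0.0)
        self.left.append(_LEAF)
        self.right.append(_LEAF)
        self.value.append(0.0)
        self.cover.append(float(n_rows))
        return idx

    def _best_split(self, X, g, h, rows, cols):
        Xs = X[np.ix_(rows, cols)]
        order = np.argsort(Xs, axis=0, kind="stable")
        xs = np.take_along_axis(Xs, order, axis=0)
        gs = np.cumsum(g[rows][order], axis=0)
        hs = np.cumsum(h[rows][order], axis=0)
        G, H = gs[-1, 0], hs[-1, 0]
        GL, HL = gs[:-1], hs[:-1]
        GR, HR = G - GL, H - HL
        valid = (xs[:-1] < xs[1:]) & (HL >= self.mcw) & (HR >= self.mcw)
        if not valid.any():
            return None
        parent_score = G * G / (H + self.lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = 0.5 * (GL**2 / (HL + self.lam) + GR**2 / (HR + self.lam) - parent_score)
        gain = np.where(valid, gain - self.gamma, -np.inf)
        flat = int(np.argmax(gain))
        if gain.flat[flat] <= 0.0:
            return None
        pos, cidx = divmod(flat, gain.shape[1])
        thr = 0.5 * (xs[pos, cidx] + xs[pos + 1, cidx])
        if not xs[pos, cidx] < thr:  # adjacent floats: keep the split exact
            thr = xs[pos + 1, cidx]
        return int(cols[cidx]), float(thr)

    def build(self, X, g, h, rows, cols) -> Tree:
        def grow(rows: np.ndarray, depth: int) -> int:
            node = self._new_node(len(rows))
            split = None
            if depth < self.max_depth:
                split = self._best_split(X, g, h, rows, cols)
            if split is None:
                G, H = g[rows].sum(), h[rows].sum()
                self.value[node] = -self.lr * G / (H + self.lam)
                return node
            feat, thr = split
            go_left = X[rows, feat] < thr
            self.feature[node] = feat
            self.threshold[node] = thr
            left_id = grow(rows[go_left], depth + 1)
            right_id = grow(rows[~go_left], depth + 1)
            self.left[node] = left_id
            self.right[node] = right_id
            return node

        grow(np.asarray(rows), 0)
        return Tree(
            feature=np.asarray(self.feature, dtype=np.intp),
            threshold=np.asarray(self.threshold, dtype=float),
            children_left=np.asarray(self.left, dtype=np.intp),
            children_right=np.asarray(self.right, dtype=np.intp),
            value=np.asarray(self.value, dtype=float),
            cover=np.asarray(self.cover, dtype=float),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BoostedTreesClassifier:
    """Gradient-boosted trees with a binary logistic objective.

    Parameters mirror the usual extreme-gradient-boosting names.  The
    initial margin is 0 (prior probability 0.5), matching the convention
    under which SHAP base values are reported.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int = 3,
        learning_rate: float = 0.3,
        gamma: float = 0.0,
        min_child_weight: float = 1.0,
        subsample: float = 1.0,
        colsample_bytree: float = 1.0,
        reg_lambda: float = 1.0,
        random_state=None,
    ):
        if not 0 < subsample <= 1 or not 0 < colsample_bytree <= 1:
            raise ValueError("subsample and colsample_bytree must be in (0, 1]")
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.gamma = gamma
        self.min_child_weight = min_child_weight
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.reg_lambda = reg_lambda
        self.random_state = random_state

    def get_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "gamma": self.gamma,
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "reg_lambda": self.reg_lambda,
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoostedTreesClassifier":
        X = np.ascontiguousarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        n_rows = max(1, int(round(self.subsample * n)))
        n_cols = max(1, int(round(self.colsample_bytree * p)))
        margin = np.zeros(n)
        self.trees_: list[Tree] = []
        self.n_features_in_ = p
        for _ in range(self.n_estimators):
            prob = _sigmoid(margin)
            g = prob - y
            h = prob * (1.0 - prob)
            rows = rng.permutation(n)[:n_rows] if n_rows < n else np.arange(n)
            cols = np.sort(rng.permutation(p)[:n_cols]) if n_cols < p else np.arange(p)
            builder = _TreeBuilder(
                self.max_depth, self.reg_lambda, self.gamma,
                self.min_child_weight, self.learning_rate,
            )
            tree = builder.build(X, g, h, np.sort(rows), cols)
            self.trees_.append(tree)
            margin += tree.predict(X)
        return self

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        """Raw additive margin (log-odds) for each row."""
        X = np.ascontiguousarray(X, dtype=float)
        margin = np.zeros(len(X))
        for tree in self.trees_:
            margin += tree.predict(X)
        return margin

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, 2); column 1 is the positive class."""
        p1 = _sigmoid(self.predict_margin(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_margin(X) >= 0.0).astype(int)
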