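"""Exact path-dependent SHAP attributions for flat-array binary trees.

Implements the polynomial-time recursive algorithm for tree ensembles in
which the conditional expectation of an unknown feature follows both
children weighted by their training cover.  Attributions are additive in
the trees, so the ensemble value for one sample is the sum of per-tree
attributions plus the cover-weighted expected value of each tree.
"""

from __future__ import annotations

import numpy as np

from ._boost import _LEAF, Tree

__all__ = ["tree_shap", "model_shap"]


class _Path:
    """Unique-feature path with Shapley subset-permutation weights."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self):
        self.d: list[int] = []  # feature of each path element (-1 for the root)
        self.z: list[float] = []  # fraction of zero (cold) paths flowing through
        self.o: list[float] = []  # fraction of one (hot) paths flowing through
        self.w: list[float] = []  # permutation weights

    def copy(self) -> "_Path":
        p = _Path()
        p.d = self.d.copy()
        p.z = self.z.copy()
        p.o = self.o.copy()
        p.w = self.w.copy()
        return p


def _extend(m: _Path, pz: float, po: float, pi: int) -> _Path:
    m = m.copy()
    l = len(m.d)
    m.d.append(pi)
    m.z.append(pz)
    m.o.append(po)
    m.w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        m.w[i + 1] += po * m.w[i] * (i + 1) / (l + 1)
        m.w[i] = pz * m.w[i] * (l - i) / (l + 1)
    return m


def _unwind(m: _Path, i: int) -> _Path:
    l = len(m.d) - 1
    o, z = m.o[i], m.z[i]
    out = m.copy()
    n = out.w[l]
    if o != 0.0:
        for j in range(l - 1, -1, -1):
            t = out.w[j]
            out.w[j] = n * (l + 1) / ((j + 1) * o)
            n = t - out.w[j] * z * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            out.w[j] = out.w[j] * (l + 1) / (z * (l - j))
    for j in range(i, l):
        out.d[j] = out.d[j + 1]
        out.z[j] = out.z[j + 1]
        out.o[j] = out.o[j + 1]
    del out.d[l], out.z[l], out.o[l], out.w[l]
    return out


def _unwound_sum(m: _Path, i: int) -> float:
    return sum(_unwind(m, i).w)


def tree_shap(tree: Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Per-feature attributions of ``tree`` for one sample ``x``.

    Satisfies local accuracy: ``sum(phi) == tree.predict(x) - tree.expected_value()``.
    """
    phi = np.zeros(n_features)

    def recurse(node: int, m: _Path, pz: float, po: float, pi: int) -> None:
        m = _extend(m, pz, po, pi)
        left = tree.children_left[node]
        if left == _LEAF:
            v = tree.value[node]
            for i in range(1, len(m.d)):
                w = _unwound_sum(m, i)
                phi[m.d[i]] += w * (m.o[i] - m.z[i]) * v
            return
        right = tree.children_right[node]
        feat = int(tree.feature[node])
        if x[feat] < tree.threshold[node]:
            hot, cold = left, right
        else:
            hot, cold = right, left
        iz = io = 1.0
        k = None
        for idx in range(1, len(m.d)):
            if m.d[idx] == feat:
                k = idx
                break
        if k is not None:
            iz, io = m.z[k], m.o[k]
            m = _unwind(m, k)
        cover = tree.cover[node]
        recurse(hot, m, iz * tree.cover[hot] / cover, io, feat)
        recurse(cold, m, iz * tree.cover[cold] / cover, 0.0, feat)

    recurse(0, _Path(), 1.0, 1.0, -1)
    return phi


def model_shap(trees: list[Tree], X: np.ndarray, n_features: int,
               base_margin: float = 0.0) -> tuple[np.ndarray, float]:
    """Attributions for an additive tree ensemble, summed over trees.

    Returns ``(phi, base)`` with ``phi`` of shape ``(n_samples, n_features)``
    and ``base`` the expected ensemble margin, such that for every row
    ``base + phi[i].sum()`` equals the ensemble margin of that row.
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros((len(X), n_features))
    base = base_margin + sum(t.expected_value() for t in trees)
    for tree in trees:
        for i, x in enumerate(X):
            phi[i] += tree_shap(tree, x, n_features)
    return phi, base
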