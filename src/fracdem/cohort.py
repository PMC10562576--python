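"""Synthetic case-control cohort generator for the baseline feature table.

The default specification reproduces the per-group summary statistics
(mean, SD, range, group sizes 46/18) of the 21 baseline features in four
categories: demographic, neuropsychological, visually assessed MRI and
quantitative MRI.  Features are drawn independently within each group —
no covariance structure is published, so real-data correlations are not
emulated.  Continuous features follow truncated Gaussians; ordinal scores
are rounded, clipped truncated Gaussians; sex is Bernoulli with the
per-group female proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupParams",
    "FeatureSpec",
    "FeatureTable",
    "CATEGORIES",
    "N_NEG_DEFAULT",
    "N_POS_DEFAULT",
    "default_cohort_spec",
    "simulate_cohort",
    "inject_missingness",
    "make_separable_cohort",
]

CATEGORIES = ("demographic", "neuropsychological", "visual_mri", "quantitative_mri")

#: default group sizes: 46 without and 18 with transition to dementia
N_NEG_DEFAULT = 46
N_POS_DEFAULT = 18


@dataclass(frozen=True)
class GroupParams:
    """Per-group summary: mean (SD) [min, max]."""

    mean: float
    sd: float
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.vmin <= self.mean <= self.vmax:
            raise ValueError(
                f"mean {self.mean} outside range [{self.vmin}, {self.vmax}]"
            )


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: name, category, type, and per-group distribution params.

    For binary features ``mean`` holds the probability of value 1 and the
    other fields are ignored.
    """

    name: str
    category: str
    ftype: str  # 'continuous' | 'binary' | 'ordinal'
    neg: GroupParams
    pos: GroupParams

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.ftype not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown feature type {self.ftype!r}")

    def group(self, label: int) -> GroupParams:
        return self.pos if label == 1 else self.neg


@dataclass
class FeatureTable:
    """Subjects x features with a binary outcome and a feature->category map."""

    data: pd.DataFrame  # index: subject ids; columns: features
    labels: pd.Series  # 1 = transition to dementia, 0 = no transition
    categories: dict[str, str]  # feature -> category

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels must share the same subject index")
        if not set(self.labels.unique()) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if self.labels.nunique() < 2:
            raise ValueError("both outcome classes must be present")
        missing = set(self.data.columns) - set(self.categories)
        if missing:
            raise ValueError(f"features without a category: {sorted(missing)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def to_csv(self, path: str) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "subject_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str, categories: Mapping[str, str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        if "label" not in df.columns:
            raise ValueError("cohort CSV is missing the 'label' column")
        labels = df.pop("label").astype(int)
        if categories is None:
            default = {s.name: s.category for s in default_cohort_spec()}
            unknown = set(df.columns) - set(default)
            if unknown:
                raise ValueError(
                    f"unknown feature columns {sorted(unknown)}; "
                    "pass an explicit feature->category map"
                )
            categories = {name: default[name] for name in df.columns}
        return cls(data=df, labels=labels, categories=dict(categories))

    def category_map_json(self) -> str:
        return json.dumps(self.categories, indent=2, sort_keys=True)


def _spec(name, category, ftype, neg, pos) -> FeatureSpec:
    return FeatureSpec(name, category, ftype, GroupParams(*neg), GroupParams(*pos))


def default_cohort_spec() -> list[FeatureSpec]:
    """The 21-feature specification of the study cohort.

    Values are per-group mean (SD) [min, max]; sex is binary with female
    proportions 22/46 (no transition) and 8/18 (transition).
    """
    return [
        # demographic (3)
        _spec("age", "demographic", "continuous",
              (73.96, 6.67, 61.12, 89.03), (76.34, 6.693, 59.80, 84.09)),
        _spec("sex", "demographic", "binary",
              (22 / 46, 0.0, 0.0, 1.0), (8 / 18, 0.0, 0.0, 1.0)),
        _spec("education", "demographic", "continuous",
              (8.17, 4.25, 3.0, 18.0), (7.44, 4.30, 2.0, 18.0)),
        # neuropsychological (6)
        _spec("MoCA", "neuropsychological", "continuous",
              (21.23, 4.62, 11.95, 29.29), (18.93, 3.95, 13.10, 25.24)),
        _spec("ROCF_immediate_copy", "neuropsychological", "continuous",
              (23.68, 7.21, 5.59, 35.58), (21.27, 10.61, 4.0, 36.0)),
        _spec("SDMT", "neuropsychological", "continuous",
              (39.18, 10.03, 22.02, 59.94), (31.18, 5.38, 24.67, 43.49)),
        _spec("Stroop", "neuropsychological", "continuous",
              (33.44, 23.81, -3.45, 114.57), (51.59, 36.02, 8.83, 155.09)),
        _spec("TMT_A", "neuropsychological", "continuous",
              (61.47, 47.97, 3.77, 202.2), (64.47, 43.15, 8.42, 152.92)),
        _spec("VS", "neuropsychological", "continuous",
              (32.84, 8.61, 14.3, 50.17), (29.08, 7.78, 15.41, 41.27)),
        # visually assessed MRI (4)
        _spec("lacunar_infarcts", "visual_mri", "ordinal",
              (2.02, 0.80, 1, 3), (2.28, 0.83, 1, 3)),
        _spec("cerebral_microbleeds", "visual_mri", "ordinal",
              (0.91, 2.57, 0, 15), (2.24, 5.77, 0, 18)),
        _spec("EPVS_basal_ganglia", "visual_mri", "ordinal",
              (1.67, 0.82, 0, 4), (1.83, 0.62, 1, 3)),
        _spec("EPVS_centrum_semiovale", "visual_mri", "ordinal",
              (1.89, 0.77, 1, 3), (1.44, 0.70, 1, 3)),
        # quantitative MRI (8)
        _spec("WM_lesion_load", "quantitative_mri", "continuous",
              (0.07, 0.04, 0.01, 0.20), (0.09, 0.05, 0.02, 0.20)),
        _spec("WM_volume", "quantitative_mri", "continuous",
              (0.15, 0.01, 0.12, 0.17), (0.14, 0.01, 0.13, 0.16)),
        _spec("GM_volume", "quantitative_mri", "continuous",
              (0.12, 0.01, 0.10, 0.14), (0.11, 0.01, 0.10, 0.12)),
        _spec("hippocampal_volume", "quantitative_mri", "continuous",
              (0.0023, 0.0005, 0.0010, 0.0031), (0.0020, 0.0002, 0.0020, 0.0024)),
        _spec("WM_FD", "quantitative_mri", "continuous",
              (2.45, 0.04, 2.35, 2.51), (2.43, 0.04, 2.36, 2.49)),
        _spec("GM_FD", "quantitative_mri", "continuous",
              (2.34, 0.02, 2.30, 2.38), (2.33, 0.02, 2.27, 2.36)),
        _spec("median_FA", "quantitative_mri", "continuous",
              (0.37, 0.02, 0.33, 0.41), (0.36, 0.02, 0.32, 0.40)),
        _spec("median_MD", "quantitative_mri", "continuous",
              (0.82, 0.05, 0.7, 0.9), (0.82, 0.04, 0.8, 0.9)),
    ]


def truncated_mean(p: GroupParams) -> float:
    """Analytic mean of the truncated Gaussian actually sampled for ``p``.

    Differs from ``p.mean`` when the printed range is asymmetric around the
    printed mean (e.g. a mean sitting on the range boundary).
    """
    if p.sd == 0:
        return p.mean
    a, b = (p.vmin - p.mean) / p.sd, (p.vmax - p.mean) / p.sd
    return float(stats.truncnorm.mean(a, b, loc=p.mean, scale=p.sd))


def _draw(spec: FeatureSpec, params: GroupParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.ftype == "binary":
        return (rng.random(n) < params.mean).astype(float)
    if params.sd == 0:
        return np.full(n, params.mean, dtype=float)
    a = (params.vmin - params.mean) / params.sd
    b = (params.vmax - params.mean) / params.sd
    vals = stats.truncnorm.rvs(a, b, loc=params.mean, scale=params.sd, size=n, random_state=rng)
    if spec.ftype == "ordinal":
        vals = np.clip(np.rint(vals), params.vmin, params.vmax)
    return np.asarray(vals, dtype=float)


def simulate_cohort(
    spec: Sequence[FeatureSpec] | None = None,
    n_neg: int = N_NEG_DEFAULT,
    n_pos: int = N_POS_DEFAULT,
    seed: int | None = None,
) -> FeatureTable:
    """Draw a synthetic cohort of ``n_neg`` + ``n_pos`` subjects.

    Continuous features come from per-group truncated Gaussians, ordinal
    features are rounded and clipped, binary features are Bernoulli; all
    features are drawn independently.  Reproducible for a fixed ``seed``.
    """
    if spec is None:
        spec = default_cohort_spec()
    if n_neg < 5 or n_pos < 5:
        raise ValueError("need at least 5 subjects per group")
    rng = np.random.default_rng(seed)
    n = n_neg + n_pos
    labels = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    ids = [f"S{i:04d}" for i in range(n)]
    cols = {}
    for fs in spec:
        col = np.empty(n, dtype=float)
        col[:n_neg] = _draw(fs, fs.neg, n_neg, rng)
        col[n_neg:] = _draw(fs, fs.pos, n_pos, rng)
        cols[fs.name] = col
    data = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))
    return FeatureTable(
        data=data,
        labels=pd.Series(labels, index=data.index, name="label"),
        categories={fs.name: fs.category for fs in spec},
    )


def inject_missingness(table: FeatureTable, rate: float, seed: int | None = None) -> FeatureTable:
    """Independently blank each feature cell with probability ``rate`` (MCAR).

    Labels are never blanked.  Returns a new table.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missingness rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    if rate > 0.0:
        mask = rng.random(data.shape) < rate
        data = data.mask(mask)
    return FeatureTable(data=data, labels=table.labels.copy(), categories=dict(table.categories))


def make_separable_cohort(
    n_neg: int = N_NEG_DEFAULT,
    n_pos: int = N_POS_DEFAULT,
    signal_feature: str = "GM_FD",
    effect_sd: float = 6.0,
    seed: int | None = None,
) -> FeatureTable:
    """Cohort where only ``signal_feature`` separates the groups.

    Every feature uses the no-transition group distribution for both groups,
    except ``signal_feature`` whose group means differ by ``effect_sd``
    pooled standard deviations.  Truncation bounds are widened so the shift
    is not clipped; with ``effect_sd = 0`` the groups are exchangeable.
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    base = default_cohort_spec()
    names = [fs.name for fs in base]
    if signal_feature not in names:
        raise ValueError(f"unknown feature {signal_feature!r}")
    spec = []
    for fs in base:
        if fs.ftype == "binary":
            neg = pos = GroupParams(fs.neg.mean, 0.0, 0.0, 1.0)
        elif fs.name == signal_feature:
            sd = fs.neg.sd if fs.neg.sd > 0 else 1.0
            lo = fs.neg.mean - 8 * sd
            hi = fs.neg.mean + (effect_sd + 8) * sd
            neg = GroupParams(fs.neg.mean, sd, lo, hi)
            pos = GroupParams(fs.neg.mean + effect_sd * sd, sd, lo, hi)
        else:
            neg = pos = fs.neg
        spec.append(FeatureSpec(fs.name, fs.category, fs.ftype, neg, pos))
    return simulate_cohort(spec, n_neg=n_neg, n_pos=n_pos, seed=seed)
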