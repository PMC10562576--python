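"""SHAP-based feature-importance aggregation across validation repetitions.

Per repetition, a feature's global importance is the mean absolute SHAP
value over the out-of-bag subjects; the final importance is the median of
the per-repetition values.  Category importances average the member
features' per-repetition values.  The top two features (by final
importance) are compared with a one-tailed Wilcoxon signed-rank test on
their paired per-repetition values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._boost import BoostedTreesClassifier
from ._treeshap import model_shap
from .evaluation import wilcoxon_signed_rank

__all__ = [
    "ShapMatrix",
    "ImportanceSummary",
    "shap_on_test",
    "global_importance",
    "category_importance",
    "compare_top_two",
]


@dataclass(frozen=True)
class ShapMatrix:
    """Per-subject per-feature attributions in log-odds margin units."""

    values: np.ndarray  # (n_subjects, n_features)
    base_value: float  # expected model margin
    feature_names: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.feature_names):
            raise ValueError("values must be (n_subjects, n_features)")
        object.__setattr__(self, "values", v)

    def local_accuracy_error(self, margins: np.ndarray) -> float:
        """Max |base + sum(phi) - margin| over subjects."""
        recon = self.base_value + self.values.sum(axis=1)
        return float(np.max(np.abs(recon - np.asarray(margins, dtype=float))))


def shap_on_test(model: BoostedTreesClassifier, X_test: np.ndarray,
                 feature_names: Sequence[str] | None = None) -> ShapMatrix:
    """Exact path-dependent SHAP attributions of ``model`` on test rows.

    Satisfies local accuracy: ``base + phi.sum(axis=1)`` equals the model
    margin for every row.
    """
    if not hasattr(model, "trees_"):
        raise TypeError("model must be a fitted tree ensemble")
    X_test = np.asarray(X_test, dtype=float)
    if len(X_test) < 1:
        raise ValueError("need at least one test row")
    p = model.n_features_in_
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"feature_{j}" for j in range(p)
    )
    phi, base = model_shap(model.trees_, X_test, p)
    return ShapMatrix(values=phi, base_value=base, feature_names=names)


@dataclass
class ImportanceSummary:
    """Per-feature global importances across repetitions.

    ``per_repetition`` has one row per repetition, one column per feature,
    holding the mean absolute SHAP value over that repetition's test
    subjects.
    """

    per_repetition: pd.DataFrame

    @property
    def median(self) -> pd.Series:
        """Final global feature importance (median over repetitions)."""
        return self.per_repetition.median(axis=0)

    @property
    def ranking(self) -> list[str]:
        """Feature names, most important first; name order breaks exact ties."""
        med = self.median
        order = sorted(med.index, key=lambda f: (-med[f], f))
        return list(order)

    def table(self) -> pd.DataFrame:
        """Summary table: median with 25th/75th percentiles, ranked."""
        q25 = self.per_repetition.quantile(0.25)
        q75 = self.per_repetition.quantile(0.75)
        out = pd.DataFrame({"median": self.median, "q25": q25, "q75": q75})
        return out.loc[self.ranking]


def global_importance(shap_matrices: Sequence[ShapMatrix]) -> ImportanceSummary:
    """Mean |SHAP| per feature within each repetition, stacked over repetitions."""
    if len(shap_matrices) == 0:
        raise ValueError("need at least one repetition")
    names = shap_matrices[0].feature_names
    rows = []
    for sm in shap_matrices:
        if sm.feature_names != names:
            raise ValueError("all repetitions must share the same features")
        rows.append(np.abs(sm.values).mean(axis=0))
    return ImportanceSummary(
        per_repetition=pd.DataFrame(rows, columns=list(names))
    )


def category_importance(summary: ImportanceSummary,
                        categories: Mapping[str, str]) -> pd.DataFrame:
    """Per-repetition category importances.

    A category's value is the sum of its member features' global values
    divided by the member count (their mean), repetition by repetition.
    """
    unmapped = set(summary.per_repetition.columns) - set(categories)
    if unmapped:
        raise ValueError(f"features without a category: {sorted(unmapped)}")
    cats = sorted(set(categories[f] for f in summary.per_repetition.columns))
    out = {}
    for cat in cats:
        members = [f for f in summary.per_repetition.columns if categories[f] == cat]
        out[cat] = summary.per_repetition[members].mean(axis=1)
    return pd.DataFrame(out)


def compare_top_two(summary: ImportanceSummary) -> float:
    """One-tailed Wilcoxon signed-rank p-value: top feature vs runner-up.

    Features are ranked by the median over repetitions; the test pairs the
    per-repetition global values of the first- and second-ranked features.
    """
    if summary.per_repetition.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if summary.per_repetition.shape[0] < 5:
        raise ValueError("need at least 5 repetitions")
    first, second = summary.ranking[:2]
    diffs = (summary.per_repetition[first] - summary.per_repetition[second]).to_numpy()
    return wilcoxon_signed_rank(diffs, alternative="greater")


def beeswarm_export(shap_matrices: Sequence[ShapMatrix],
                    feature_values: Sequence[np.ndarray]) -> pd.DataFrame:
    """Long-format export (subject, feature, shap_value, feature_value)
    suitable for beeswarm-style plots."""
    records = []
    for rep, (sm, fv) in enumerate(zip(shap_matrices, feature_values)):
        fv = np.asarray(fv, dtype=float)
        for i in range(sm.values.shape[0]):
            for j, name in enumerate(sm.feature_names):
                records.append(
                    (rep, i, name, sm.values[i, j], fv[i, j])
                )
    return pd.DataFrame(
        records,
        columns=["repetition", "subject", "feature", "shap_value", "feature_value"],
    )
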