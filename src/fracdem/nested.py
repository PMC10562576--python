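"""Repeated stratified bootstrap nested validation for the boosted-tree model.

Each repetition draws a stratified bootstrap of the cohort (resampling with
replacement within each outcome class, preserving the class counts
exactly); the out-of-bag subjects form the outer test set.  Imputation and
standardization statistics are learned on the outer training multiset only.
Hyperparameters are chosen by random search over the printed grid with a
subject-level 5-fold inner cross-validation, in which every bootstrap copy
of a subject follows that subject's fold, preventing leakage.  The selected
model is refit on the outer training multiset and evaluated on the
out-of-bag subjects (probabilities, AUC, ROC coordinates, SHAP values).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._boost import BoostedTreesClassifier
from ._treeshap import model_shap
from .cohort import FeatureTable
from .evaluation import RocCurve, roc_and_auc

__all__ = [
    "PreprocessModel",
    "HYPERPARAM_GRID",
    "grid_points",
    "OuterSplit",
    "RepetitionResult",
    "fit_preprocessor",
    "stratified_bootstrap_split",
    "subject_level_folds",
    "random_search",
    "run_nested_validation",
]

logger = logging.getLogger(__name__)

#: hyperparameter search space (Cartesian grid of 3*4*3*3*4*3 = 1296 points)
HYPERPARAM_GRID: dict[str, tuple] = {
    "gamma": (0.6, 0.7, 0.8),
    "colsample_bytree": (0.25, 0.5, 0.75, 1.0),
    "max_depth": (2, 3, 4),
    "min_child_weight": (2, 3, 5),
    "n_estimators": (5, 10, 20, 100),
    "subsample": (0.1, 0.2, 0.4),
}


def grid_points(grid: Mapping[str, Sequence] | None = None) -> list[dict]:
    """All hyperparameter combinations of ``grid`` in deterministic order."""
    grid = dict(HYPERPARAM_GRID if grid is None else grid)
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


@dataclass
class PreprocessModel:
    """Training-derived mean imputation followed by z-standardization.

    Columns with zero training variance transform to zero.
    """

    impute_means: np.ndarray
    std_means: np.ndarray
    std_sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        nan_rows, nan_cols = np.nonzero(np.isnan(X))
        X[nan_rows, nan_cols] = self.impute_means[nan_cols]
        out = (X - self.std_means) / np.where(self.std_sds > 0, self.std_sds, 1.0)
        out[:, self.std_sds == 0] = 0.0
        return out


def fit_preprocessor(X_train: np.ndarray) -> PreprocessModel:
    """Learn imputation and standardization statistics from training rows only."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D array with at least 2 training rows")
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"features entirely missing in training: columns {np.nonzero(all_missing)[0].tolist()}"
        )
    impute_means = np.nanmean(X, axis=0)
    X_filled = np.where(np.isnan(X), impute_means, X)
    return PreprocessModel(
        impute_means=impute_means,
        std_means=X_filled.mean(axis=0),
        std_sds=X_filled.std(axis=0, ddof=0),
    )


@dataclass(frozen=True)
class OuterSplit:
    """One bootstrap repetition: training multiset and out-of-bag test set."""

    train_ids: tuple  # multiset, with repetitions; size == cohort size
    test_ids: tuple  # unique out-of-bag subject ids
    seed: int  # requested seed
    effective_seed: int  # seed actually used (> seed after degenerate redraws)

    @property
    def n_redraws(self) -> int:
        return self.effective_seed - self.seed


def stratified_bootstrap_split(table: FeatureTable, seed: int) -> OuterSplit:
    """Stratified bootstrap: resample each class with replacement to its own
    count; out-of-bag subjects of either class form the test set.

    If the out-of-bag set lacks a class, the draw is repeated with an
    incremented seed (the event is logged).
    """
    labels = table.labels
    class_counts = labels.value_counts()
    if class_counts.min() < 5:
        raise ValueError("need at least 5 subjects in each class")
    ids_by_class = {c: labels.index[labels == c].to_numpy() for c in (0, 1)}
    all_ids = set(labels.index)
    eff_seed = seed
    while True:
        rng = np.random.default_rng(eff_seed)
        train: list = []
        for c in (0, 1):
            ids = ids_by_class[c]
            train.extend(rng.choice(ids, size=len(ids), replace=True))
        oob = sorted(all_ids - set(train))
        oob_classes = {int(labels[i]) for i in oob}
        if oob_classes == {0, 1}:
            return OuterSplit(
                train_ids=tuple(train), test_ids=tuple(oob),
                seed=seed, effective_seed=eff_seed,
            )
        logger.info("degenerate out-of-bag draw at seed %d; redrawing", eff_seed)
        eff_seed += 1


def subject_level_folds(
    train_ids: Sequence, labels: Mapping, k: int = 5, seed: int | None = None
) -> dict:
    """Stratified partition of the *unique* subjects into ``k`` folds.

    Every bootstrap copy of a subject follows its subject's fold.  Within
    each class, subjects are shuffled and dealt round-robin, so fold class
    proportions are within one subject of the overall proportions.
    """
    unique_ids = sorted(set(train_ids))
    if len(unique_ids) < k:
        raise ValueError(f"need at least {k} unique subjects, got {len(unique_ids)}")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    next_fold = rng.integers(k)  # random starting fold, then deal round-robin
    for c in (0, 1):
        class_ids = [i for i in unique_ids if labels[i] == c]
        for sid in rng.permutation(class_ids):
            assignment[sid] = int(next_fold)
            next_fold = (next_fold + 1) % k
    return assignment


def _make_model(params: Mapping, random_state) -> BoostedTreesClassifier:
    return BoostedTreesClassifier(random_state=random_state, **params)


def random_search(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Sequence,
    labels: Mapping,
    n_candidates: int = 50,
    seed: int | None = None,
    k: int = 5,
    grid: Mapping[str, Sequence] | None = None,
) -> dict:
    """Random search over the hyperparameter grid with subject-level inner CV.

    Samples ``n_candidates`` distinct grid points and scores each by mean
    validation AUC over ``k`` subject-level folds, refitting the
    preprocessor per fold.  Folds whose validation set contains one class
    contribute no AUC; a candidate with no valid fold is discarded.  Ties
    are broken by fewer trees, then shallower trees, then sampling order.

    ``X`` holds the *raw* (untransformed) outer-training rows, one per
    bootstrap copy, aligned with ``subject_ids``.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    points = grid_points(grid)
    rng = np.random.default_rng(seed)
    n_candidates = min(n_candidates, len(points))
    chosen_idx = rng.choice(len(points), size=n_candidates, replace=False)
    candidates = [points[i] for i in chosen_idx]
    folds = subject_level_folds(subject_ids, labels, k=k, seed=rng.integers(2**32))
    fold_of_row = np.asarray([folds[s] for s in subject_ids])
    y = np.asarray(y)
    fit_seeds = rng.integers(2**32, size=(n_candidates, k))

    best = None
    for ci, params in enumerate(candidates):
        fold_aucs = []
        for f in range(k):
            val = fold_of_row == f
            if len(np.unique(y[val])) != 2 or val.all() or not val.any():
                continue
            prep = fit_preprocessor(X[~val])
            model = _make_model(params, random_state=int(fit_seeds[ci, f]))
            model.fit(prep.transform(X[~val]), y[~val])
            scores = model.predict_proba(prep.transform(X[val]))[:, 1]
            _, auc = roc_and_auc(y[val], scores)
            fold_aucs.append(auc)
        if not fold_aucs:
            continue
        key = (-float(np.mean(fold_aucs)), params["n_estimators"], params["max_depth"], ci)
        if best is None or key < best[0]:
            best = (key, params)
    if best is None:
        raise RuntimeError("no hyperparameter candidate had a valid inner-CV score")
    return dict(best[1])


@dataclass
class RepetitionResult:
    """Outcome of one nested-validation repetition."""

    split: OuterSplit
    params: dict
    test_ids: tuple
    y_test: np.ndarray
    scores: np.ndarray  # predicted P(transition) per out-of-bag subject
    auc: float
    roc: RocCurve
    shap_values: np.ndarray  # (n_test, n_features), log-odds margin units
    shap_base: float
    test_margins: np.ndarray


def run_nested_validation(
    table: FeatureTable,
    n_repetitions: int = 100,
    n_candidates: int = 50,
    base_seed: int = 0,
    k_folds: int = 5,
    grid: Mapping[str, Sequence] | None = None,
) -> list[RepetitionResult]:
    """Run the full repeated stratified bootstrap nested validation.

    Repetition ``r`` uses seed ``base_seed + r`` for its bootstrap split;
    all other randomness is derived deterministically from the same seed.
    """
    results = []
    labels = table.labels
    X_all = table.data
    n_features = len(table.feature_names)
    for r in range(n_repetitions):
        seed_r = base_seed + r
        split = stratified_bootstrap_split(table, seed_r)
        X_train = X_all.loc[list(split.train_ids)].to_numpy(dtype=float)
        y_train = labels.loc[list(split.train_ids)].to_numpy(dtype=int)
        X_test = X_all.loc[list(split.test_ids)].to_numpy(dtype=float)
        y_test = labels.loc[list(split.test_ids)].to_numpy(dtype=int)

        params = random_search(
            X_train, y_train, split.train_ids, labels,
            n_candidates=n_candidates, seed=[seed_r, 1], k=k_folds, grid=grid,
        )
        prep = fit_preprocessor(X_train)
        model = _make_model(params, random_state=[seed_r, 2])
        model.fit(prep.transform(X_train), y_train)

        X_test_t = prep.transform(X_test)
        scores = model.predict_proba(X_test_t)[:, 1]
        roc, auc = roc_and_auc(y_test, scores)
        phi, base = model_shap(model.trees_, X_test_t, n_features)
        results.append(
            RepetitionResult(
                split=split, params=params, test_ids=split.test_ids,
                y_test=y_test, scores=scores, auc=auc, roc=roc,
                shap_values=phi, shap_base=base,
                test_margins=model.predict_margin(X_test_t),
            )
        )
        logger.debug("repetition %d: AUC %.3f with %s", r, auc, params)
    return results
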