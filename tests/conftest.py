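"""Shared fixtures.

The two expensive nested-validation workloads (null calibration over
permuted labels and the strong-signal recovery run) are session-scoped so
the acceptance tests and the importance/leakage property tests can share
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fracdem import make_separable_cohort, run_nested_validation, simulate_cohort
from fracdem.cohort import FeatureTable

N_NULL_RUNS = 20
N_REPS = 20


def permute_labels(table: FeatureTable, seed: int) -> FeatureTable:
    rng = np.random.default_rng(seed)
    permuted = pd.Series(
        rng.permutation(table.labels.to_numpy()),
        index=table.labels.index, name="label",
    )
    return FeatureTable(data=table.data.copy(), labels=permuted,
                        categories=dict(table.categories))


@pytest.fixture(scope="session")
def null_runs():
    """20 independent nested-validation runs on permuted-label cohorts.

    Each run permutes the labels of the default simulated cohort with its
    own seed and executes 20 repetitions at the reduced search budget
    (n_candidates=10).
    """
    base_table = simulate_cohort(seed=0)
    runs = []
    for k in range(N_NULL_RUNS):
        table = permute_labels(base_table, seed=1000 + k)
        results = run_nested_validation(
            table, n_repetitions=N_REPS, n_candidates=10, base_seed=100 * k
        )
        runs.append((table, results))
    return runs


@pytest.fixture(scope="session")
def signal_run():
    """Strong-signal recovery run: only GM_FD separates the groups (d = 6)."""
    table = make_separable_cohort(effect_sd=6.0, signal_feature="GM_FD", seed=1)
    results = run_nested_validation(
        table, n_repetitions=N_REPS, n_candidates=50, base_seed=0
    )
    return table, results
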