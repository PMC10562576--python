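# fracdem

Tools for studying the transition to dementia in mild cognitive impairment
with small-vessel disease, in two parts:

1. **3-D box-counting fractal dimension** (FD) of binary brain-structure
   masks (NIfTI) with grid-offset exploration and automated selection of the
   fractal scaling window (best adjusted R² over contiguous log-log
   sub-intervals), plus analytic phantoms (cube, slab, line, Menger sponge)
   for validation.
2. **An explainable prediction pipeline**: a gradient-boosted tree
   classifier over 21 baseline features (demographic, neuropsychological,
   visually assessed MRI, quantitative MRI), evaluated by 100× repeated
   stratified bootstrap nested validation with leakage-free preprocessing,
   hyperparameter random search in a subject-level 5-fold inner CV, median
   ROC / Youden operating-point evaluation, a one-tailed Wilcoxon test
   against chance, and exact path-dependent SHAP feature attributions
   aggregated into per-feature and per-category importances.

Because the patient data are not public, a cohort simulator reproduces the
published per-group summary statistics (means, SDs, ranges; group sizes
46/18) so the pipeline is fully testable on synthetic data.

The boosted-tree learner and the tree-SHAP attributions are implemented
in-package (second-order boosting with the usual `gamma`,
`min_child_weight`, `subsample`, `colsample_bytree` semantics; attributions
validated against brute-force Shapley enumeration), so no external boosting
library is required.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis), independent
brute-force oracles for box counting, scaling-window selection, AUC,
Wilcoxon and Shapley values, and an acceptance suite
(`tests/test_acceptance.py`) covering phantom FD recovery, null
calibration, signal recovery, leakage/stratification audits and SHAP local
accuracy. The full run takes a few minutes on one CPU.

## Command line

```bash
# fractal dimension of a mask
fracdem fd mask.nii.gz --offsets 20 --seed 1 --out fd.json

# validation phantoms
fracdem simulate-phantom --kind menger --iterations 4 --out sponge.nii.gz

# synthetic cohort (46 non-converters / 18 converters, 21 features)
fracdem simulate-cohort --seed 0 --missing-rate 0.05 --out cohort.csv

# full nested validation + report bundle
fracdem run-nested cohort.csv --repetitions 100 --candidates 50 --seed 0 --out results/
fracdem report results/ --plot roc.png
```

`run-nested` writes `summary.json` (mean AUC with 90% CI, Wilcoxon p,
Youden operating point, feature/category importances, provenance block),
`repetitions.json`, `median_roc.csv`, `importance.tsv`,
`category_importance.tsv` and per-repetition SHAP matrices under `shap/`.
Runs are exactly reproducible from the configured seed.

## Python API sketch

```python
from fracdem import (
    compute_fd, make_phantom, PhantomSpec,
    simulate_cohort, run_nested_validation,
    median_roc, youden_optimal, summarize_auc, wilcoxon_vs_chance,
    global_importance, category_importance, compare_top_two,
)

fd = compute_fd(make_phantom(PhantomSpec("menger", iterations=4)), seed=0)
table = simulate_cohort(seed=0)
results = run_nested_validation(table, n_repetitions=100, n_candidates=50)
mean_auc, ci90 = summarize_auc([r.auc for r in results])
```

## Design notes

- Box counts use the minimal covering over grid offsets (the aligned grid
  is always one of them); averaging over offsets is available
  (`agg="mean"`) but biases the log-log slope shallow for compact
  structures. Default scales are the divisors of the largest bounding-box
  edge (≤ half the edge), falling back to powers of two, so grids tile the
  structure exactly. Grids are anchored at the foreground bounding box,
  making the FD exactly translation invariant.
- The stratified bootstrap resamples within outcome classes, so every outer
  training multiset has exactly the cohort's class counts; inner CV folds
  are assigned per unique subject and every bootstrap copy follows its
  subject's fold.
- The 90% CI of the AUC is the empirical 5th–95th percentile interval of
  the repetition AUCs; the Wilcoxon signed-rank test uses the exact
  sign-flip null distribution (midranks) up to n = 25.
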