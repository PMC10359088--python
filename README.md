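# oncoassign

Interpretable per-patient drug assignment from ex vivo drug-sensitivity
screens.

Precision-oncology cohorts such as AML ex vivo screens measure, for every
patient, the sensitivity (log-IC50) of the patient's tumor cells to a
panel of drugs, alongside genomic biomarkers (binary mutation calls,
continuous expression).  The *patient-centered* question is: **which drug
should each patient get?**  Black-box learners can answer it but cannot be
read by a clinician; `oncoassign` implements two methods whose output *is*
the decision criterion:

* **Optimal Decision Trees (ODT).**  Unlike a classification tree, each
  split jointly selects a biomarker `m` (with a threshold `th` for
  continuous markers) *and one drug per branch*, maximizing the summed
  benefit

  ```
  max over (m, th, d1, d2) of  A + B
  A = Σ_p  f(b_{p,d1}) · [x_{pm} ≥ th]      (carriers get d1)
  B = Σ_p  f(b_{p,d2}) · [x_{pm} < th]      (non-carriers get d2)
  ```

  where `b = −IC50*` is the benefit scale and `f` is the identity or a
  signed square root that damps outliers.  Branches recurse until a group
  is smaller than `min_group_size` or the optimum puts the same drug on
  both sides.  The fitted tree is a few lines a physician can follow.

* **Vote-split multinomial lasso.**  Hard multiclass labels penalize
  assigning a patient's second-best drug as harshly as the worst.  Instead
  each patient casts one vote shared across drugs,

  ```
  z_pd = exp(−K · y_pd / min_d' y_pd') / Σ_i exp(−K · y_pi / min_d' y_pd')
  ```

  (temperature `K`: uniform votes at `K = 0`, one-hot at the most
  effective drug as `K → ∞`), and a soft-label multinomial regression
  `Xβ ~ Z` is fitted with a lasso or grouped-lasso penalty — the grouped
  form selects one compact marker set shared by all drugs.

Both methods work on **IC50\***: per-drug mean-centered log-IC50.
Centering removes overall potency, so uniformly potent (often uniformly
toxic) compounds stop dominating and drugs with *differential* effects —
the ones a companion biomarker can exploit — rise to the top.

Evaluation follows the protocol of the field: the **Oracle** gives every
patient the observed-minimum-IC50* drug (the floor of achievable
response); a method's quality is its per-patient excess
**ΔIC50\* = achieved − oracle ≥ 0**, summarized under seeded k-fold
cross-validation, plus intragroup validation (two-sided rank-sum test of a
drug's ΔIC50* in patients it was recommended to versus everyone else) and
a variable-count interpretability metric.

## Worked example

Everything runs on seeded synthetic cohorts with known ground truth; no
downloads are needed.  Fit an ODT on a cohort whose response follows a
hidden depth-2 biomarker tree:

```python
from oncoassign import (PlantedTreeSpec, generate_planted_tree_cohort,
                        compute_ic50_star, ODTModel)

Y_log, X, truth = generate_planted_tree_cohort(PlantedTreeSpec(seed=3))
Y = compute_ic50_star(Y_log)            # per-drug centering
res = ODTModel(Y, X, min_group_size=10).fit()
print(res.summary())
```

```
Optimal Decision Tree Results
==============================================
No. patients:        200
No. drugs:           4
Response scale:      ic50_star
Transform:           identity
Min group size:      10
Tree depth:          2
Splits / leaves:     3 / 4
Markers used:        g26, g20, g18
Training median excess over Oracle: 0.0000
Training mean excess over Oracle:   0.0019
----------------------------------------------
g26 == 1? (n=200)
  yes: g20 == 1? (n=86)
    yes: <drug_B>
    no:  <drug_C>
  no:  g18 == 1? (n=114)
    yes: <drug_A>
    no:  <drug_D>
```

The fitted tree is exactly the generator's planted tree: three markers
route every patient to the drug planted as best, and the training median
ΔIC50* is 0 — every patient reaches their Oracle drug.  Cross-validated
comparison against the best-single-drug baseline:

```python
from oncoassign import make_folds, cross_validate, compare_methods, constant_best_drug_spec

plan = make_folds(Y.patient_ids, 5, seed=7)
reports = [cross_validate(Y, X, res.method_spec(), plan),
           cross_validate(Y, X, constant_best_drug_spec(), plan)]
print(compare_methods(reports).round(3))
```

```
                    n  n_excluded  median_achieved  iqr_achieved  mean_delta  median_delta  variable_count
method
ODT (identity)    200           0           -0.734         0.374       0.002         0.000             3.0
best single drug  200           0            0.189         0.651       0.803         0.874             0.0
```

Held out from training, the tree still assigns near-Oracle drugs (median
achieved IC50* −0.734, median Δ = 0) using 3 variables, while always
giving the overall-best drug costs ~0.87 median Δ — the per-drug
log-units of sensitivity lost by ignoring biomarkers.  The same flows are
available from the shell:

```bash
oncoassign simulate planted-tree --seed 3 --out-prefix sim/
oncoassign fit-odt --sensitivity sim/Y.tsv --biomarkers sim/X.tsv --out tree.json --dot tree.dot
oncoassign predict --tree tree.json --biomarkers sim/X.tsv --out assignments.tsv
oncoassign evaluate --sensitivity sim/Y.tsv --biomarkers sim/X.tsv \
    --method odt --method baseline --cv 5 --seed 7 --out report.json
```

The vote-split lasso mirrors the same API
(`VoteSplitLassoModel(Y, X, K=1.0).fit(lam="cv", seed=7)`), returning the
M × D coefficient matrix, the CV path and the selected-variable count.

## Layout

| Module | Contents |
| --- | --- |
| `oncoassign.data` | `SensitivityMatrix`, `BiomarkerMatrix`, `Assignment`, TSV/CSV I/O |
| `oncoassign.tree` | `DecisionTree`/`DecisionNode`, JSON round-trip, DOT and text export |
| `oncoassign.normalization` | IC50* centering, signed-sqrt transform, benefit convention |
| `oncoassign.odt` | split scoring, exhaustive split search, recursive tree fitting, routing |
| `oncoassign.multinomial` | vote matrix, FISTA solver for the penalized soft-label fit, CV path |
| `oncoassign.evaluation` | Oracle, ΔIC50*, fold plans, CV harness, rank-sum tests, comparison tables |
| `oncoassign.synthetic` | planted-tree and sparse-linear cohort generators with ground truth |
| `oncoassign.model` | statsmodels-style `ODTModel` / `VoteSplitLassoModel` + Results |
| `oncoassign.cli` | `oncoassign` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
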