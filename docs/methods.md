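# Methods

This note records the models, conventions, parameter choices and
numerical decisions behind `oncoassign`, and what the synthetic
experiments do and do not demonstrate.

## Data model and scales

The inputs are a patients × drugs response matrix `Y` (log-IC50 or
derived scales; lower = more sensitive) and a patients × markers matrix
`X` whose columns are binary (0/1 mutation calls) or continuous
(expression-like).  Missing entries are allowed only in `Y`: sensitivity
screens are the sparse object in practice, and a missing biomarker row is
an upstream QC problem we refuse rather than impute.  Column kind is
auto-detected (binary iff all observed values are 0/1) and can be
overridden.

**IC50\*.**  For each drug the mean of its observed log-IC50 values is
subtracted, making every column mean zero.  The centering removes overall
potency: a compound that is potent (or toxic) in everyone carries no
information about *who* should receive it, while the residual,
patient-differential signal is exactly what a companion biomarker can
target.  IC50* is idempotent under re-centering and invariant to adding a
per-drug constant, and both properties are tested.

**Benefit convention.**  The tree objective is written as a maximization
of summed responses, while IC50-type inputs are better when smaller.  We
resolve the sense once, at the matrix level: `to_benefit` negates values
and flags the scale, every fitter maximizes benefit, and the Oracle is
equivalently the row minimum of IC50*.  The flag travels with the matrix
so no call site guesses the optimization direction.

**Signed square root.**  The optional outlier-damping transform is
`sign(y)·sqrt(|y|)`.  Since IC50* is centered, sensitive patient–drug
pairs are negative and a plain square root would be undefined; the signed
form is the minimal odd extension, strictly increasing, hence
order-preserving and commuting with the benefit negation.

## Optimal decision trees

At each node the fitter enumerates every admissible split and, for each,
the best drug per side:

* binary marker → the single partition `x == 1` vs `x == 0`;
* continuous marker → thresholds at midpoints between consecutive
  distinct values in the node's subset (exhausts all distinct partitions
  and is scan-order independent; `observed_values` is available as an
  alternative policy);
* the inner drug choice decomposes per branch (the optimal pair is the
  pair of per-branch optima), so the search is O(M · thresholds · D).

The recursion turns a branch into a leaf (labeled with the branch's best
single drug) when the group is smaller than `min_group_size`, when the
optimal split recommends the same drug on both sides, when no marker
yields two non-empty sides, or at `max_depth`.  A marker is never reused
along a root-to-leaf path (a binary re-split is vacuous, and continuous
re-splits would trade readability for marginal gain); reuse across
sibling subtrees is allowed.

Ties are broken deterministically: scanning markers in column order and
thresholds ascending, keeping the first strict improvement, with
first-maximum drug argmax — i.e. the lexicographically smallest
(marker index, threshold, drug_true index, drug_false index) among
objective-maximal decisions.  This makes the search exactly reproducible
and lets tests compare it bitwise against brute-force enumeration.

Defaults: `min_group_size = 10` (keeps leaves large enough to be
clinically meaningful at a few-hundred-patient cohort scale; always
user-settable), identity transform, unlimited depth (stopping is driven
by group size).  Missing responses: the default policy demands a complete
matrix and errors otherwise; the opt-in `mean` policy scores branches by
per-drug means over observed entries, since sums over unequal observation
counts would bias the drug choice toward well-measured drugs.

## Vote matrix and the soft-label multinomial lasso

The vote matrix divides each patient's unit vote across drugs by
effectiveness,

    z_pd ∝ exp(−K · y_pd / min_i y_pi),

with the minimum taken within the patient's own row (`min_mode =
"per_patient"`, the default).  This scaling yields the two advertised
limits exactly — uniform votes 1/D at `K = 0` and, as `K` grows, the
whole vote at the patient's minimum-y drug — and the maximum row entry is
non-decreasing in `K`.  A `per_drug` mode (scaling each response by the
drug's column minimum) is provided for completeness; its K→∞ vote does
not in general concentrate on the patient's best drug, which is why it is
not the default.  The exponent presumes strictly positive responses; the
default policy rejects non-positive values, and the opt-in `shift` policy
translates the matrix by `−min + 1e-6·range` first (needed for centered
IC50*).  `K` is a required, logged hyperparameter with default 1.

The fit minimizes the soft-label multinomial negative log-likelihood

    −(1/P) Σ_p Σ_d z_pd log softmax_d(b_d + x_p·β_·d)
        + λ Σ_m |β_m·|₁          (lasso)
        + λ Σ_m ‖β_m·‖₂          (grouped lasso)

with unpenalized intercepts, internally standardized features, and
coefficients reported on the original scale.  The grouped penalty zeroes
a marker's coefficients jointly across drugs, so the selected variable
set is shared by the whole panel.  The solver accepts the probabilistic
targets directly (no pseudo-observation expansion).

**Solver.**  Monotone FISTA: accelerated proximal gradient with the step
`1/L`, `L = σ_max(X₁)²/(2P)` (the softmax cross-entropy Hessian in the
logits is bounded by I/2), an ISTA fallback whenever the accelerated
candidate would increase the objective, and momentum restart after a
fallback.  The objective history is non-increasing by construction and is
checked; convergence is declared on a relative objective change below
`tol` (1e-9 final fits, 1e-8 path fits).  Independent verification:
tests re-minimize the identical objective with L-BFGS-B on the exact
smooth split-variable reformulation of the lasso and agree to ~1e-12
relative.

**Regularization path and CV.**  100 log-spaced λ from λ_max (the
smallest λ with an all-zero coefficient matrix, computed from the
gradient at β = 0) down to `1e-4·λ_max`, warm-started.  `lam = "cv"`
(seed mandatory) evaluates held-out soft-label deviance over seeded
k-folds (default 5).  The default selection is the one-standard-error
rule — the largest λ whose mean CV deviance is within one SE of the
minimum.  We prefer it to the raw deviance minimizer because near λ_max
the CV curve is flat to within fold noise on signal-free data, so the
argmin frequently lands on small spurious supports; the 1-SE rule keeps
the support empty when there is nothing to find while, at the effect
sizes of interest, still retaining every truly predictive marker
(`cv_rule = "min"`, ties to the largest λ, remains available).  The
selected-variable count is the number of coefficient rows with any entry
above 1e-8 after unstandardization.

## Evaluation protocol

* **Oracle** — each patient's observed-best drug (row minimum of IC50*,
  ties to the lowest drug index): the floor of achievable response.
* **ΔIC50\*** — achieved minus Oracle value, per patient, always ≥ 0 and
  0 iff the assignment is Oracle-optimal.  Methods output a drug, not a
  predicted value, so "achieved" is always the patient's own measured
  response to the assigned drug; held-out patients whose assigned drug is
  unmeasured are excluded from summaries and counted, never imputed.
* **Cross-validation** — seeded, unstratified, balanced folds.  The fold
  map depends only on (patient-id set, seed, k), so reordering the cohort
  cannot silently change the partition.  Per-fold method failures are
  recorded and flag the report partial rather than aborting the run.
* **Intragroup validation** — the two-tailed comparison of a drug's
  ΔIC50* between recommended and non-recommended patients is the
  two-sample rank-sum (Mann–Whitney) test: the groups are independent, so
  the paired signed-rank variant does not apply.  ΔIC50* is the default
  metric (it is the quantity a recommendation should shrink); raw
  responses are a flag away.  p-values: exact null distribution when both
  groups have ≤ 12 tie-free observations; exhaustive permutation
  enumeration for small tied samples; otherwise the normal approximation
  with tie and continuity corrections.
* **Comparison table** — one row per method: median/IQR of achieved
  IC50*, mean and median Δ, selected-variable count.

## Synthetic cohorts

Both generators are fully seeded (spec + seed ⇒ bit-identical cohort).

**Planted-tree cohort** (tree recovery): a hidden depth-1..3 tree over a
few markers routes each patient to an intended drug;
`y_pd = baseline_d − effect·[d == intended_p] + N(0, noise_sd)` with
per-drug baselines drawn N(0,1) once, so the IC50* correction is
exercised non-trivially — raw row minima are baseline-dominated (the
uniform-potency artifact), and the intended drug is the row argmin only
after centering.  Masking at `missing_rate` never hits a patient's
intended drug, keeping Oracle and Δ defined.  Default conditions:
n = 200 patients, 30 markers, 4 drugs, depth 2, effect 1.0 (log-IC50
units), noise sd 0.25.

Marker prevalences default to a structured layout: the root lesion at
0.5, the refining lesions below it at 0.3, decoys at 0.5.  This is the
identifiability condition for exact recovery, not a convenience: with
every prevalence at 0.5 and a flat per-leaf effect, the expected
root-split objective is *identical* for the planted root and both planted
child markers (each isolates two half-pure drug groups), so the greedy
root choice is decided by noise for any correct fitter.  With root
prevalence q₀ and child prevalences q₁, q₂, the root objective is
`e·q₀(1−q₀)·P·[max(q₁,1−q₁) + max(q₂,1−q₂)]` against a child's
`2e·q₀·q₁(1−q₁)·P`; an evenly-splitting root with rarer refinements (the
classic major-subtype / subclonal-event pattern) makes the planted tree
the strict optimum.  A user-supplied scalar or per-marker vector
overrides the layout.

**Sparse-linear cohort** (support recovery): drug logits are
`α_d + x_p·β` with β nonzero on `n_active_markers` rows (entries of
magnitude `coefficient_scale = 2` with random signs, resampled if a row
is constant across drugs — a constant row shifts all logits equally,
leaves the softmax unchanged, and is therefore unrecoverable in
principle); responses are the negated logits plus noise, shifted so the
global minimum is exactly 1 (strictly positive, ratio-informative votes).
Defaults: n = 300, 100 markers, 4 drugs, 5 active markers, noise sd 0.25,
intercept sd 0.5, vote temperature 1.

**What passing these experiments shows — and does not.**  The generators
emulate subgroup structure, per-drug location shifts, additive Gaussian
noise and missingness.  They do not emulate correlated markers (LD-like
co-mutation patterns), heavy-tailed or heteroscedastic assay noise, batch
effects, dose-response censoring, or panel composition drift between
cohorts.  Recovery and calibration results on these cohorts validate the
implementation and the identifiability logic, not clinical performance on
real screens.

## Numerical choices and degenerate inputs

* Split-search equality against brute force is asserted *exactly*; both
  paths compute branch sums with the same column-sum reduction so the
  comparison is bitwise, and the documented lexicographic tie-break makes
  decisions unique.
* Tree JSON round-trips losslessly (floats via `repr`); node objectives
  are serialized diagnostics but excluded from structural equality, so
  patient-permutation invariance holds despite summation-order float
  differences.
* All-missing drug columns, all-missing patient rows, constant markers,
  zero-variance features, empty CV groups, and non-simplex vote rows are
  rejected or skipped with named errors rather than propagating NaNs.
* Seeds: every stochastic step (generators, folds, CV) takes an explicit
  seed; CLI reruns with identical config + seed are byte-identical.

## Problem sizes used in the verification battery

The acceptance script and test suite run at desk scale, chosen to make
each property measurable in seconds-to-minutes on one CPU: 200 random
instances per split-oracle check (P = 15, D = 4), 100 random matrices for
vote limits, 50 seeded cohorts per tree-recovery rate, 25 + 25 seeded
cohorts for grouped-lasso support recovery, all ~2000 tie-free rank
configurations with n ≤ 10 for rank-sum exactness plus 500 null
replicates for calibration.

## Known limitations

* The tree is greedy; each split optimizes its own objective, not the
  final tree.  With continuous markers, a midpoint threshold can route a
  boundary patient across the generator's cut and repair it one level
  deeper, so exact-topology recovery is only guaranteed for binary
  splits.
* Grouped-lasso coefficients are shrunk, not debiased; the package
  reports selection and assignment quality, not coefficient confidence
  intervals.
* The multinomial solver is dense; cohorts beyond ~10⁴ markers would
  want a sparse design path.
* Cross-cohort transfer (training on one screen, validating on another)
  is supported mechanically by fitting and predicting on separate
  matrices, but no harmonization of assay scales between cohorts is
  attempted — that is upstream responsibility.
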