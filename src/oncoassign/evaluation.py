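"""Validation protocol: Oracle assignment, delta-IC50*, seeded k-fold
cross-validation, intragroup rank-sum validation and method comparison.

The Oracle gives every patient the drug with the minimum observed IC50*
(the lower bound of achievable response); any method's quality is the
per-patient excess ``delta = achieved - oracle >= 0``.  Cross-validation
records, for each held-out patient, the *measured* response of the drug
the model assigned — methods output a drug, not a predicted value, so
their achieved response is read off the patient's own screen.

The "two-tailed Wilcoxon" intragroup comparison is the two-sample
rank-sum (Mann-Whitney) test: the recommended group is compared against
all other patients — independent groups, not paired measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Any, Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    Assignment,
    BiomarkerMatrix,
    SensitivityMatrix,
    attach_achieved,
    check_aligned,
)
from .exceptions import AlignmentError, ConfigError, EvaluationError

__all__ = [
    "FoldPlan",
    "MethodSpec",
    "EvaluationReport",
    "RankSumResult",
    "oracle_assign",
    "delta_ic50",
    "make_folds",
    "cross_validate",
    "rank_sum_test",
    "intragroup_test",
    "compare_methods",
]


def _row_best(values: np.ndarray, higher_is_better: bool) -> np.ndarray:
    """Per-patient best observed value (NaN-aware)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmax(values, axis=1) if higher_is_better else np.nanmin(values, axis=1)


def oracle_assign(y: SensitivityMatrix) -> Assignment:
    """Assign each patient its observed-best drug (ties -> lowest index)."""
    obs = y.observed()
    if not obs.any(axis=1).all():
        bad = [y.patient_ids[i] for i in np.flatnonzero(~obs.any(axis=1))]
        raise EvaluationError(f"patient(s) with no observed drug value: {bad}")
    vals = y.values.copy()
    if y.higher_is_better:
        vals = np.where(np.isnan(vals), -np.inf, vals)
        idx = np.argmax(vals, axis=1)
    else:
        vals = np.where(np.isnan(vals), np.inf, vals)
        idx = np.argmin(vals, axis=1)
    drugs = [y.drug_names[j] for j in idx]
    achieved = y.values[np.arange(y.n_patients), idx]
    return Assignment(list(y.patient_ids), drugs, achieved)


def delta_ic50(assignment: Assignment, y: SensitivityMatrix) -> np.ndarray:
    """Per-patient excess over the Oracle: ``y[assigned] - min_d y`` (>= 0).

    Patients whose assigned drug is unmeasured get NaN (reported missing,
    never zero).  On the benefit scale the excess is ``max_d y - y[assigned]``.
    """
    pos = {p: i for i, p in enumerate(y.patient_ids)}
    missing = [p for p in assignment.patient_ids if p not in pos]
    if missing:
        raise AlignmentError(f"patients absent from the response matrix: {missing[:5]}")
    rows = np.array([pos[p] for p in assignment.patient_ids])
    cols = np.array([y.drug_index(d) for d in assignment.assigned_drug])
    achieved = y.values[rows, cols]
    best = _row_best(y.values, y.higher_is_better)[rows]
    return (best - achieved) if y.higher_is_better else (achieved - best)


@dataclass(frozen=True)
class FoldPlan:
    """Seeded balanced partition into k folds, labels 1..k.

    The patient -> fold map depends only on (patient_ids as a set, seed,
    k): folds are drawn on the sorted identifiers, so permuting the
    cohort's row order permutes the labels identically.
    """

    k: int
    fold_labels: np.ndarray  # aligned with patient_ids, values 1..k
    patient_ids: tuple[str, ...]
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_labels == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_labels != fold)


def make_folds(patient_ids: Sequence[str], k: int, seed: int) -> FoldPlan:
    """Balanced uniform random fold assignment (sizes differ by <= 1)."""
    ids = [str(p) for p in patient_ids]
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > len(ids):
        raise ConfigError(f"k={k} exceeds the number of patients ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    labels_sorted = np.empty(len(ids), dtype=int)
    labels_sorted[order] = np.arange(len(ids)) % k + 1
    # map labels assigned on sorted ids back to the input order
    sorted_pos = {p: i for i, p in enumerate(sorted(ids))}
    labels = np.array([labels_sorted[sorted_pos[p]] for p in ids])
    return FoldPlan(k=k, fold_labels=labels, patient_ids=tuple(ids), seed=seed)


@dataclass
class MethodSpec:
    """A fit/predict pair the CV harness can drive.

    ``fit(Y_train, X_train) -> state``; ``predict(state, X_test) ->``
    :class:`Assignment`.  ``variable_count`` optionally reports how many
    input variables the fitted state uses (interpretability metric).
    """

    name: str
    fit: Callable[[SensitivityMatrix, BiomarkerMatrix], Any]
    predict: Callable[[Any, BiomarkerMatrix], Assignment]
    variable_count: Callable[[Any], int] | None = None


@dataclass
class EvaluationReport:
    """Concatenated held-out results for one method on one cohort."""

    method: str
    patient_ids: list[str]
    assigned_drug: list[str | None]
    achieved: np.ndarray  # measured response of the assigned drug (NaN if unmeasured)
    oracle: np.ndarray  # per-patient best observed response
    delta: np.ndarray  # achieved - oracle (NaN when achieved is NaN)
    fold_labels: np.ndarray | None = None
    seed: int | None = None
    variable_counts: list[int] = field(default_factory=list)
    fold_errors: dict[int, str] = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return bool(self.fold_errors)

    @property
    def n_excluded(self) -> int:
        return int(np.isnan(self.achieved).sum())

    def summary(self) -> dict[str, float]:
        ok = ~np.isnan(self.achieved)
        ach = self.achieved[ok]
        dl = self.delta[ok]
        return {
            "n": int(ok.sum()),
            "n_excluded": self.n_excluded,
            "median_achieved": float(np.median(ach)) if ach.size else float("nan"),
            "q1_achieved": float(np.percentile(ach, 25)) if ach.size else float("nan"),
            "q3_achieved": float(np.percentile(ach, 75)) if ach.size else float("nan"),
            "mean_delta": float(np.mean(dl)) if dl.size else float("nan"),
            "median_delta": float(np.median(dl)) if dl.size else float("nan"),
            "variable_count": float(max(self.variable_counts)) if self.variable_counts else float("nan"),
        }

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "patients": self.patient_ids,
            "assigned_drug": self.assigned_drug,
            "achieved": [None if np.isnan(v) else v for v in self.achieved],
            "oracle": list(map(float, self.oracle)),
            "delta": [None if np.isnan(v) else v for v in self.delta],
            "fold_labels": None if self.fold_labels is None else self.fold_labels.tolist(),
            "variable_counts": self.variable_counts,
            "fold_errors": {str(k): v for k, v in self.fold_errors.items()},
            "summary": self.summary(),
        }

    def plot(self, ax=None):
        """Boxplot of achieved responses next to the Oracle reference."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ok = ~np.isnan(self.achieved)
        ax.boxplot([self.oracle[ok], self.achieved[ok]], tick_labels=["Oracle", self.method])
        ax.set_ylabel("achieved response")
        return ax


def cross_validate(
    y: SensitivityMatrix,
    x: BiomarkerMatrix,
    method: MethodSpec,
    plan: FoldPlan,
) -> EvaluationReport:
    """k-fold CV: fit on each fold's complement, assign drugs to the
    held-out patients, and record their measured responses."""
    check_aligned(y, x)
    if tuple(y.patient_ids) != plan.patient_ids:
        raise AlignmentError("fold plan does not match the cohort's patients")
    oracle_vals = _row_best(y.values, y.higher_is_better)
    assigned: list[str | None] = [None] * y.n_patients
    achieved = np.full(y.n_patients, np.nan)
    var_counts: list[int] = []
    errors: dict[int, str] = {}
    for fold in range(1, plan.k + 1):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        try:
            state = method.fit(y.take_patients(tr), x.take_patients(tr))
            pred = method.predict(state, x.take_patients(te))
        except Exception as e:  # recorded, report flagged partial
            errors[fold] = f"{type(e).__name__}: {e}"
            continue
        if list(pred.patient_ids) != [y.patient_ids[i] for i in te]:
            errors[fold] = "prediction is not aligned with the held-out patients"
            continue
        for local, i in enumerate(te):
            drug = pred.assigned_drug[local]
            assigned[i] = drug
            achieved[i] = y.values[i, y.drug_index(drug)]
        if method.variable_count is not None:
            var_counts.append(int(method.variable_count(state)))
    delta = np.where(
        np.isnan(achieved),
        np.nan,
        (oracle_vals - achieved) if y.higher_is_better else (achieved - oracle_vals),
    )
    return EvaluationReport(
        method=method.name,
        patient_ids=list(y.patient_ids),
        assigned_drug=assigned,
        achieved=achieved,
        oracle=oracle_vals,
        delta=delta,
        fold_labels=plan.fold_labels.copy(),
        seed=plan.seed,
        variable_counts=var_counts,
        fold_errors=errors,
    )


# ---------------------------------------------------------------------------
# rank-sum (Mann-Whitney) test


@dataclass(frozen=True)
class RankSumResult:
    n_recommended: int
    n_other: int
    statistic: float  # U of the first (recommended) group
    p_value: float
    method: str  # exact | permutation | asymptotic
    skipped: str | None = None


_EXACT_MAX_GROUP = 12  # exact null distribution up to this per-group size
_PERM_MAX_COMB = 50_000  # enumeration cap for tied small samples


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x via midranks (tie-aware)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive two-sided permutation p-value: P(|U - mu| >= |u_obs - mu|)."""
    n1, n = x.size, x.size + y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * y.size / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        hits += abs(u - mu) >= dev_obs - 1e-12
        total += 1
    return hits / total


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided two-sample rank-sum test.

    Tie-free samples with both groups <= 12 use the exact null
    distribution; small tied samples fall back to exhaustive permutation
    enumeration; everything else uses the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return RankSumResult(x.size, y.size, float("nan"), float("nan"), "none", "empty group")
    tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
    if tie_free and max(x.size, y.size) <= _EXACT_MAX_GROUP:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(x.size, y.size, float(res.statistic), float(res.pvalue), "exact")
    if not tie_free and comb(x.size + y.size, x.size) <= _PERM_MAX_COMB:
        return RankSumResult(
            x.size, y.size, _u_statistic(x, y), _permutation_p(x, y), "permutation"
        )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(x.size, y.size, float(res.statistic), float(res.pvalue), "asymptotic")


def intragroup_test(
    assignment: Assignment,
    y: SensitivityMatrix,
    drug: str,
    *,
    metric: Literal["delta", "raw"] = "delta",
) -> RankSumResult:
    """Compare a drug's response between the patients it was recommended
    to and everyone else.

    ``metric='delta'`` (default) compares each patient's excess of that
    drug over their own best (the quantity the recommendation should
    shrink); ``'raw'`` compares the drug's response values directly.
    """
    j = y.drug_index(drug)
    pos = {p: i for i, p in enumerate(y.patient_ids)}
    rows = np.array([pos[p] for p in assignment.patient_ids])
    vals = y.values[rows, j]
    if metric == "delta":
        best = _row_best(y.values, y.higher_is_better)[rows]
        vals = (best - vals) if y.higher_is_better else (vals - best)
    rec = np.array([d == drug for d in assignment.assigned_drug])
    ok = ~np.isnan(vals)
    grp_rec, grp_other = vals[rec & ok], vals[~rec & ok]
    if grp_rec.size == 0 or grp_other.size == 0:
        return RankSumResult(
            grp_rec.size, grp_other.size, float("nan"), float("nan"), "none",
            "degenerate group: no observed values on one side",
        )
    return rank_sum_test(grp_rec, grp_other)


def compare_methods(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Aligned one-row-per-method table of achieved-response medians,
    IQRs, mean excess over Oracle and variable counts."""
    if not reports:
        raise ConfigError("no reports to compare")
    cohort = reports[0].patient_ids
    for r in reports[1:]:
        if r.patient_ids != cohort:
            raise AlignmentError(f"report {r.method!r} covers a different cohort")
    rows = []
    for r in reports:
        s = r.summary()
        rows.append(
            {
                "method": r.method,
                "n": s["n"],
                "n_excluded": s["n_excluded"],
                "median_achieved": s["median_achieved"],
                "iqr_achieved": s["q3_achieved"] - s["q1_achieved"],
                "mean_delta": s["mean_delta"],
                "median_delta": s["median_delta"],
                "variable_count": s["variable_count"],
            }
        )
    return pd.DataFrame(rows).set_index("method")
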