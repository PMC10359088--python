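"""Optimal Decision Trees for per-patient drug assignment.

Unlike a classification tree, each split here jointly selects a biomarker
(and a threshold for continuous markers) *and* one drug per branch: among
all candidate partitions of the current patient group, the fitter picks
the one maximizing

    A + B,   A = sum of f(benefit of drug_true)  over the true branch,
             B = sum of f(benefit of drug_false) over the false branch,

where benefit = -IC50* and f is the configured response transform.  The
inner drug choice decomposes per branch (the best pair is the pair of
per-branch best drugs), so the search is O(M * candidates * D) rather
than O(M * candidates * D^2).  Branches recurse until a group is smaller
than ``min_group_size``, the optimal split recommends the same drug on
both sides, or no marker yields two non-empty sides.

Tie-breaking is deterministic: among objective-maximal decisions the
lexicographically smallest (marker index, threshold, drug_true index,
drug_false index) wins, implemented by scanning markers in column order,
thresholds in ascending order, and taking the first-maximal drug per
branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import Assignment, BiomarkerMatrix, SensitivityMatrix, check_aligned
from .exceptions import (
    ConfigError,
    FeatureError,
    FitError,
    MissingDataError,
)
from .normalization import TransformSpec, apply_transform, to_benefit
from .tree import DecisionNode, DecisionTree

__all__ = [
    "ODTConfig",
    "SplitDecision",
    "score_split",
    "find_best_split",
    "fit_tree",
    "predict_tree",
]


@dataclass(frozen=True)
class ODTConfig:
    """Tunable fitting parameters.

    min_group_size : groups smaller than this become leaves (>= 2).
    transform      : response transform applied to benefit values.
    threshold_policy : candidate thresholds for continuous markers —
        ``midpoints`` between consecutive distinct sorted values (default,
        exhausts all distinct partitions) or the ``observed_values``
        themselves.
    max_depth      : optional hard depth cap (None = unlimited; stopping
        is normally driven by min_group_size).
    missing_policy : ``error`` requires a complete response matrix;
        ``mean`` scores branches by the mean over observed entries
        instead of the sum (robust to unequal observation counts).
    """

    min_group_size: int = 10
    transform: TransformSpec = field(default_factory=TransformSpec)
    threshold_policy: str = "midpoints"
    max_depth: int | None = None
    missing_policy: str = "error"

    def __post_init__(self) -> None:
        if self.min_group_size < 2:
            raise ConfigError("min_group_size must be >= 2")
        if self.threshold_policy not in ("midpoints", "observed_values"):
            raise ConfigError(f"unknown threshold_policy {self.threshold_policy!r}")
        if self.missing_policy not in ("error", "mean"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1 or None")


@dataclass
class SplitDecision:
    marker: str
    threshold: float | None
    drug_true: str
    drug_false: str
    objective: float
    n_true: int
    n_false: int


def _transformed_benefit(y: SensitivityMatrix, config: ODTConfig) -> np.ndarray:
    """Benefit-scale, transformed response values (NaN policy checked)."""
    if y.scale != "benefit":
        y = to_benefit(y)
    y = apply_transform(y, config.transform)
    vals = y.values
    if config.missing_policy == "error" and np.isnan(vals).any():
        raise MissingDataError(
            "response matrix has missing entries; use missing_policy='mean' "
            "or impute/filter upstream"
        )
    return vals


def _branch_scores(f_sub: np.ndarray, policy: str) -> np.ndarray:
    """Per-drug branch score: column sums, or observed-entry means."""
    if policy == "error":
        return f_sub.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(f_sub, axis=0)
    return np.where(np.isnan(means), -np.inf, means)


def score_split(
    y_benefit: SensitivityMatrix,
    mask: Sequence[bool],
    drug_true: str,
    drug_false: str,
    *,
    transform: TransformSpec | None = None,
    missing_policy: str = "error",
) -> float:
    """Objective A + B of assigning ``drug_true`` to masked-in patients
    and ``drug_false`` to the rest (on the benefit scale).
    """
    cfg = ODTConfig(transform=transform or TransformSpec(), missing_policy=missing_policy)
    f = _transformed_benefit(y_benefit, cfg)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (y_benefit.n_patients,):
        raise ConfigError("mask length must equal the number of patients")
    jt = y_benefit.drug_index(drug_true)
    jf = y_benefit.drug_index(drug_false)
    a = _branch_scores(f[mask], missing_policy)[jt] if mask.any() else 0.0
    b = _branch_scores(f[~mask], missing_policy)[jf] if (~mask).any() else 0.0
    return float(a + b)


def _candidate_masks(x_col: np.ndarray, kind: str, policy: str):
    """Yield (threshold, boolean mask) candidates for one marker column."""
    if kind == "binary":
        yield None, x_col == 1.0
        return
    distinct = np.unique(x_col)
    if distinct.size < 2:
        return
    if policy == "midpoints":
        thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    else:  # observed_values: x >= th is non-trivial for all but the minimum
        thresholds = distinct[1:]
    for th in thresholds:
        yield float(th), x_col >= th


def find_best_split(
    y_benefit: SensitivityMatrix,
    x: BiomarkerMatrix,
    subset: Sequence[int] | None = None,
    config: ODTConfig | None = None,
    *,
    exclude_markers: frozenset[str] = frozenset(),
) -> SplitDecision | None:
    """Exhaustive search for the objective-maximal (marker[, threshold],
    drug_true, drug_false) decision on a patient subset.

    Returns None when no marker separates the subset into two non-empty
    groups.  ``exclude_markers`` supports the no-reuse-per-path rule.
    """
    check_aligned(y_benefit, x)
    config = config or ODTConfig()
    f_full = _transformed_benefit(y_benefit, config)
    idx = np.arange(y_benefit.n_patients) if subset is None else np.asarray(subset, int)
    f = f_full[idx]
    best: SplitDecision | None = None
    for j, marker in enumerate(x.marker_names):
        if marker in exclude_markers:
            continue
        col = x.values[idx, j]
        for th, mask in _candidate_masks(col, x.column_kind[j], config.threshold_policy):
            n_true = int(mask.sum())
            n_false = mask.size - n_true
            if n_true == 0 or n_false == 0:
                continue
            st = _branch_scores(f[mask], config.missing_policy)
            sf = _branch_scores(f[~mask], config.missing_policy)
            if np.all(np.isinf(st)) or np.all(np.isinf(sf)):
                continue  # a branch with no observed response for any drug
            jt = int(np.argmax(st))
            jf = int(np.argmax(sf))
            obj = float(st[jt] + sf[jf])
            if best is None or obj > best.objective:
                best = SplitDecision(
                    marker=marker,
                    threshold=th,
                    drug_true=y_benefit.drug_names[jt],
                    drug_false=y_benefit.drug_names[jf],
                    objective=obj,
                    n_true=n_true,
                    n_false=n_false,
                )
    return best


def _best_single_drug(f_sub: np.ndarray, drug_names: list[str], policy: str) -> str:
    scores = _branch_scores(f_sub, policy)
    return drug_names[int(np.argmax(scores))]


def fit_tree(
    y: SensitivityMatrix,
    x: BiomarkerMatrix,
    config: ODTConfig | None = None,
    *,
    return_assignment: bool = False,
):
    """Fit the optimal decision tree by greedy recursive split optimization.

    The response matrix is converted to transformed benefit once up
    front.  Returns the :class:`DecisionTree` (and, when
    ``return_assignment`` is set, the fit-time per-patient leaf drugs).
    """
    check_aligned(y, x)
    config = config or ODTConfig()
    if y.n_patients == 0:
        raise FitError("cannot fit a tree on zero patients")
    f = _transformed_benefit(y, config)
    if not np.any(~np.isnan(f)):
        raise FitError("no observed response values")
    drug_names = list(y.drug_names)
    fit_drug: list[str | None] = [None] * y.n_patients

    def grow(idx: np.ndarray, used: frozenset[str], depth: int):
        leaf_drug = _best_single_drug(f[idx], drug_names, config.missing_policy)
        if (
            idx.size < config.min_group_size
            or (config.max_depth is not None and depth >= config.max_depth)
        ):
            return leaf_drug
        decision = find_best_split(y, x, idx, config, exclude_markers=used)
        if decision is None or decision.drug_true == decision.drug_false:
            # same drug on both sides -> splitting adds nothing: collapse
            return decision.drug_true if decision is not None else leaf_drug
        j = x.marker_index(decision.marker)
        col = x.values[idx, j]
        mask = (col == 1.0) if decision.threshold is None else (col >= decision.threshold)
        node = DecisionNode(
            marker=decision.marker,
            threshold=decision.threshold,
            if_true=grow(idx[mask], used | {decision.marker}, depth + 1),
            if_false=grow(idx[~mask], used | {decision.marker}, depth + 1),
            n_patients=int(idx.size),
            objective=decision.objective,
        )
        if isinstance(node.if_true, str) and node.if_true == node.if_false:
            return node.if_true  # children collapsed to the same drug
        return node

    def record(node, idx: np.ndarray) -> None:
        if isinstance(node, str):
            for i in idx:
                fit_drug[i] = node
            return
        j = x.marker_index(node.marker)
        col = x.values[idx, j]
        mask = (col == 1.0) if node.threshold is None else (col >= node.threshold)
        record(node.if_true, idx[mask])
        record(node.if_false, idx[~mask])

    all_idx = np.arange(y.n_patients)
    root = grow(all_idx, frozenset(), 0)
    tree = DecisionTree(
        root=root,
        min_group_size=config.min_group_size,
        response_transform=config.transform.kind,
        sense="maximize" if y.scale == "benefit" else "minimize",
    )
    if not return_assignment:
        return tree
    record(root, all_idx)
    assignment = Assignment(list(y.patient_ids), [d for d in fit_drug if d is not None])
    if len(assignment.patient_ids) != len(fit_drug):
        raise FitError("internal bookkeeping error: unassigned patients")
    return tree, assignment


def predict_tree(tree: DecisionTree, x: BiomarkerMatrix) -> Assignment:
    """Route each patient down the fitted tree to its leaf drug.

    Binary nodes send ``x == 1`` to the true branch; continuous nodes
    send ``x >= threshold``.
    """
    for marker in tree.markers_used():
        if marker not in x.marker_names:
            raise FeatureError(f"marker {marker!r} required by the tree is missing")
    drugs: list[str] = []
    for i in range(x.n_patients):
        node = tree.root
        while not isinstance(node, str):
            v = x.values[i, x.marker_index(node.marker)]
            go_true = (v == 1.0) if node.threshold is None else (v >= node.threshold)
            node = node.if_true if go_true else node.if_false
        drugs.append(node)
    return Assignment(list(x.patient_ids), drugs)
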