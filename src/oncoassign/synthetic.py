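"""Seeded synthetic cohorts with known ground truth.

Two generators emulate the statistical shape of an ex vivo drug screen:

* a *planted decision tree* cohort — a small hidden tree over a few
  biomarkers routes every patient to an intended drug, whose log-IC50 is
  lowered by ``effect`` relative to per-drug baselines, plus Gaussian
  noise; used for tree-recovery experiments;
* a *sparse linear* cohort — drug logits are a sparse linear function of
  standard-normal markers; responses are the negated logits (shifted to
  be strictly positive so the vote-splitting formula applies directly);
  used for multinomial support-recovery experiments.

Both draw everything from one seeded generator, so a spec plus a seed
reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BiomarkerMatrix, SensitivityMatrix
from .exceptions import ConfigError
from .tree import DecisionNode, DecisionTree

__all__ = [
    "PlantedTreeSpec",
    "SparseLinearSpec",
    "generate_planted_tree_cohort",
    "generate_sparse_linear_cohort",
]


@dataclass(frozen=True)
class PlantedTreeSpec:
    """Study conditions for the planted-tree cohort.

    ``effect`` is the log-IC50 advantage of each patient's intended drug
    over the others; ``noise_sd`` the additive Gaussian measurement
    noise; ``depth`` the planted tree depth (1-3, using 2^depth distinct
    drugs and 2^depth - 1 distinct markers).  Binary markers are
    Bernoulli(``mutation_prevalence``); a ``continuous_fraction`` of
    markers is generated standard normal instead (planted splits on
    continuous markers use threshold 0).  Missing responses are masked
    uniformly at ``missing_rate`` but never a patient's intended drug,
    so Oracle and delta stay defined.

    ``mutation_prevalence=None`` (default) uses a structured layout that
    makes the planted tree the identifiable optimum of the split
    objective: the root lesion splits the cohort evenly (0.5) while the
    refining lesions below it are rarer (0.3), as with a major
    molecular-subtype split refined by subclonal events.  With every
    prevalence at 0.5 and a flat per-leaf effect, the root and child
    markers have *identical* expected split objectives at the root
    (each isolates two half-pure drug groups), so exact structure
    recovery would hinge on noise no matter the fitter.  A scalar or
    per-marker tuple overrides the layout everywhere.
    """

    n_patients: int = 200
    n_markers: int = 30
    n_drugs: int = 4
    depth: int = 2
    effect: float = 1.0
    noise_sd: float = 0.25
    mutation_prevalence: float | tuple[float, ...] | None = None
    continuous_fraction: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ConfigError("effect must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 1 <= self.depth <= 3:
            raise ConfigError("planted depth must be 1, 2 or 3")
        if self.n_drugs < 2**self.depth:
            raise ConfigError(f"depth {self.depth} needs >= {2**self.depth} drugs")
        if self.n_markers < 2**self.depth - 1:
            raise ConfigError(f"depth {self.depth} needs >= {2**self.depth - 1} markers")
        if not 0 <= self.continuous_fraction <= 1:
            raise ConfigError("continuous_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SparseLinearSpec:
    """Study conditions for the sparse-linear (vote-structure) cohort."""

    n_patients: int = 300
    n_markers: int = 100
    n_drugs: int = 4
    n_active_markers: int = 5
    coefficient_scale: float = 2.0
    intercept_scale: float = 0.5
    noise_sd: float = 0.25
    K_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active_markers > self.n_markers:
            raise ConfigError("n_active_markers cannot exceed n_markers")
        if self.n_active_markers < 0 or self.noise_sd < 0:
            raise ConfigError("n_active_markers and noise_sd must be >= 0")


def _plant_tree(
    marker_names: list[str],
    marker_kinds: list[str],
    drug_names: list[str],
    depth: int,
    split_markers,
    leaf_drugs,
) -> DecisionTree:
    """Build a full tree of the given depth from pre-chosen distinct
    split markers (preorder, root first) and distinct leaf drugs."""
    markers = iter(list(split_markers))
    leaves = iter(list(leaf_drugs))

    def build(level: int):
        if level == depth:
            return next(leaves)
        name = next(markers)
        kind = marker_kinds[marker_names.index(name)]
        return DecisionNode(
            marker=name,
            threshold=0.0 if kind == "continuous" else None,
            if_true=build(level + 1),
            if_false=build(level + 1),
        )

    return DecisionTree(root=build(0), response_transform="identity", sense="minimize")


def _route(tree: DecisionTree, x_row: np.ndarray, marker_pos: dict[str, int]) -> str:
    node = tree.root
    while not isinstance(node, str):
        v = x_row[marker_pos[node.marker]]
        node = node.if_true if ((v == 1.0) if node.threshold is None else (v >= node.threshold)) else node.if_false
    return node


def generate_planted_tree_cohort(spec: PlantedTreeSpec):
    """Return ``(Y, X, truth)`` with ``truth = {"tree", "intended"}``.

    ``Y`` is on the log-IC50 scale: ``y_pd = baseline_d - effect * [d ==
    intended_p] + N(0, noise_sd)`` with per-drug baselines drawn N(0, 1)
    once (so the IC50* centering is exercised non-trivially).
    """
    rng = np.random.default_rng(spec.seed)
    p, m, d = spec.n_patients, spec.n_markers, spec.n_drugs
    marker_names = [f"g{j}" for j in range(m)]
    drug_names = [f"drug_{chr(ord('A') + j)}" if j < 26 else f"drug_{j}" for j in range(d)]
    patient_ids = [f"P{i:04d}" for i in range(p)]

    n_cont = int(round(spec.continuous_fraction * m))
    kinds = ["continuous"] * n_cont + ["binary"] * (m - n_cont)
    rng.shuffle(kinds)

    split_idx = rng.choice(m, size=2**spec.depth - 1, replace=False)
    leaf_idx = rng.choice(d, size=2**spec.depth, replace=False)
    if spec.mutation_prevalence is None:
        prev = np.full(m, 0.5)
        prev[split_idx[1:]] = 0.3  # rarer refining lesions below the root
    else:
        prev = np.broadcast_to(np.asarray(spec.mutation_prevalence, dtype=float), (m,))

    x = np.empty((p, m))
    for j, kind in enumerate(kinds):
        if kind == "binary":
            x[:, j] = rng.binomial(1, prev[j], size=p)
        else:
            x[:, j] = rng.standard_normal(p)

    tree = _plant_tree(
        marker_names, kinds, drug_names, spec.depth,
        [marker_names[j] for j in split_idx], [drug_names[j] for j in leaf_idx],
    )
    marker_pos = {g: j for j, g in enumerate(marker_names)}
    intended = [_route(tree, x[i], marker_pos) for i in range(p)]
    intended_idx = np.array([drug_names.index(t) for t in intended])

    baselines = rng.standard_normal(d)
    y = baselines[None, :] + rng.normal(0.0, spec.noise_sd, size=(p, d))
    y[np.arange(p), intended_idx] -= spec.effect

    if spec.missing_rate > 0:
        mask = rng.random((p, d)) < spec.missing_rate
        mask[np.arange(p), intended_idx] = False  # keep truth evaluable
        y = np.where(mask, np.nan, y)

    Y = SensitivityMatrix(y, patient_ids, drug_names, scale="log_ic50")
    X = BiomarkerMatrix(x, patient_ids, marker_names, kinds)
    return Y, X, {"tree": tree, "intended": intended}


def generate_sparse_linear_cohort(spec: SparseLinearSpec):
    """Return ``(Y, X, truth)`` with ``truth = {"active", "beta",
    "intercepts", "intended"}``.

    Logits are ``alpha_d + x_p . beta_.d`` with ``beta`` nonzero only on
    ``n_active_markers`` rows (entries of magnitude ``coefficient_scale``
    with random signs); the intended drug is the row argmax.  Responses
    are the negated logits plus noise, shifted so the global minimum is
    1.0 — strictly positive, lower response = higher logit, and the
    vote-splitting ratios stay informative.
    """
    rng = np.random.default_rng(spec.seed)
    p, m, d = spec.n_patients, spec.n_markers, spec.n_drugs
    marker_names = [f"g{j}" for j in range(m)]
    drug_names = [f"drug_{chr(ord('A') + j)}" if j < 26 else f"drug_{j}" for j in range(d)]
    patient_ids = [f"P{i:04d}" for i in range(p)]

    x = rng.standard_normal((p, m))
    active = np.sort(rng.choice(m, size=spec.n_active_markers, replace=False))
    beta = np.zeros((m, d))
    if spec.n_active_markers:
        # sign patterns constant across drugs shift every logit equally and
        # leave the softmax unchanged; resample those so each active marker
        # carries a real differential effect
        signs = np.empty((spec.n_active_markers, d))
        for r in range(spec.n_active_markers):
            row = rng.choice([-1.0, 1.0], size=d)
            while np.all(row == row[0]):
                row = rng.choice([-1.0, 1.0], size=d)
            signs[r] = row
        beta[active] = signs * spec.coefficient_scale
    intercepts = rng.normal(0.0, spec.intercept_scale, size=d)
    logits = intercepts[None, :] + x @ beta
    intended_idx = np.argmax(logits, axis=1)

    y = -logits + rng.normal(0.0, spec.noise_sd, size=(p, d))
    y = y - y.min() + 1.0  # strictly positive, global minimum exactly 1
    Y = SensitivityMatrix(y, patient_ids, drug_names, scale="log_ic50")
    X = BiomarkerMatrix(x, patient_ids, marker_names, ["continuous"] * m)
    truth = {
        "active": [marker_names[j] for j in active],
        "beta": beta,
        "intercepts": intercepts,
        "intended": [drug_names[j] for j in intended_idx],
    }
    return Y, X, truth
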