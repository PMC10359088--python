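"""Soft-label (vote-splitting) multinomial lasso drug assigner.

Rather than training a hard multiclass classifier on each patient's
single best drug — which penalizes recommending the second-best drug as
harshly as the worst — each patient casts one *vote* split across drugs.
The vote matrix Z puts on drug d the share

    z_pd = exp(-K * y_pd / min(y_p.)) / sum_i exp(-K * y_pi / min(y_p.))

(strictly positive responses required; the min is taken within the
patient's own row by default, see ``min_mode``).  K interpolates between
a uniform 1/D vote (K = 0) and a one-hot vote for the patient's most
effective drug (K >> 1).

The model X @ beta ~ Z is then fitted by minimizing the soft-label
multinomial negative log-likelihood

    -(1/P) * sum_p sum_d z_pd * log softmax_d(b_d + x_p . beta_.d)

plus a lasso penalty lambda * sum_m |beta_m.|_1 or a grouped penalty
lambda * sum_m ||beta_m.||_2.  The grouped form zeroes a marker's
coefficients jointly across all drugs, so one variable set explains the
whole panel.  Intercepts are never penalized; features are standardized
internally and coefficients reported on the original scale.

The solver is a monotone FISTA (proximal gradient with Nesterov momentum
and a fallback ISTA step whenever the accelerated step would increase
the objective), with the regularization path warm-started from lambda_max
— the smallest lambda at which the penalized solution is exactly
beta = 0 — down to ``lambda_min_ratio * lambda_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .data import Assignment, BiomarkerMatrix, SensitivityMatrix, check_aligned
from .exceptions import (
    ConfigError,
    ConvergenceError,
    DomainError,
    FeatureError,
    MissingDataError,
)

__all__ = [
    "VoteMatrix",
    "MultinomialModel",
    "build_vote_matrix",
    "fit_multinomial",
    "predict_multinomial",
    "count_selected_variables",
    "soft_multinomial_objective",
]

#: coefficients with all entries below this (original scale) count as zero
ZERO_COEF_TOL = 1e-8


@dataclass
class VoteMatrix:
    """Patient x drug probabilistic labels; every row lies on the simplex."""

    values: np.ndarray
    patient_ids: list[str]
    drug_names: list[str]
    K: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, d = self.values.shape
        if len(self.patient_ids) != p or len(self.drug_names) != d:
            raise ConfigError("vote matrix labels do not match its shape")
        if self.K < 0:
            raise ConfigError("K must be >= 0")
        if np.any(self.values < 0):
            raise ConfigError("vote matrix entries must be non-negative")
        if np.any(np.abs(self.values.sum(axis=1) - 1.0) > 1e-10):
            raise ConfigError("vote matrix rows must sum to 1 (within 1e-10)")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]


def build_vote_matrix(
    y: SensitivityMatrix,
    K: float,
    *,
    min_mode: Literal["per_patient", "per_drug"] = "per_patient",
    positivity: Literal["strict", "shift"] = "strict",
) -> VoteMatrix:
    """Turn a sensitivity matrix into simplex-row votes.

    ``min_mode='per_patient'`` (default) scales each response by the
    patient's own minimum, which yields the advertised limits exactly:
    K = 0 gives 1/D everywhere and K >> 1 concentrates the whole vote on
    the patient's minimum-y (most effective) drug.  ``per_drug`` scales
    by each drug's minimum across patients instead.

    The exponent assumes strictly positive responses.  Under the default
    ``strict`` policy non-positive values raise; ``positivity='shift'``
    first translates the whole matrix by ``-min + 1e-6 * range``.
    """
    if K < 0:
        raise ConfigError("K must be >= 0")
    if y.n_drugs < 2:
        raise ConfigError("vote splitting needs at least two drugs")
    vals = np.asarray(y.values, dtype=float)
    if np.isnan(vals).any():
        raise MissingDataError("vote matrix requires a complete response matrix")
    if positivity == "shift":
        lo, hi = vals.min(), vals.max()
        span = hi - lo if hi > lo else 1.0
        vals = vals - lo + 1e-6 * span
    elif np.any(vals <= 0):
        raise DomainError(
            "responses must be strictly positive for vote splitting; "
            "pass positivity='shift' to translate the matrix first"
        )
    if min_mode == "per_patient":
        denom = vals.min(axis=1, keepdims=True)
    elif min_mode == "per_drug":
        denom = vals.min(axis=0, keepdims=True)
    else:
        raise ConfigError(f"unknown min_mode {min_mode!r}")
    if np.any(denom == 0):
        raise DomainError("zero minimum response; cannot scale the exponent")
    logits = -K * vals / denom
    logits -= logits.max(axis=1, keepdims=True)  # stabilized softmax
    w = np.exp(logits)
    z = w / w.sum(axis=1, keepdims=True)
    return VoteMatrix(z, list(y.patient_ids), list(y.drug_names), K=float(K))


# ---------------------------------------------------------------------------
# penalized soft-label multinomial fit


@dataclass
class MultinomialModel:
    """Fitted coefficients (original feature scale) plus fit metadata."""

    beta: np.ndarray  # M x D
    intercepts: np.ndarray  # D
    penalty: str
    lam: float
    marker_names: list[str]
    drug_names: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    objective: float  # penalized objective at the solution (standardized scale)
    n_iter: int
    converged: bool
    cv_path: list[tuple[float, float]] | None = None  # (lambda, mean CV deviance)
    cv_seed: int | None = None
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_markers(self) -> int:
        return self.beta.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.beta.shape[1]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def soft_multinomial_objective(
    xs: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    intercepts: np.ndarray,
    lam: float,
    penalty: str,
) -> float:
    """Penalized soft-label negative log-likelihood (mean over patients).

    ``xs`` is the design on whatever scale ``beta`` lives on; the public
    entry point for independent-optimizer cross-checks.
    """
    p = xs.shape[0]
    logits = intercepts[None, :] + xs @ beta
    lse = logits.max(axis=1)
    lse = lse + np.log(np.exp(logits - lse[:, None]).sum(axis=1))
    nll = -(np.sum(z * logits) - np.sum(z.sum(axis=1) * lse)) / p
    if penalty == "lasso":
        pen = np.abs(beta).sum()
    elif penalty == "grouped_lasso":
        pen = np.sqrt((beta**2).sum(axis=1)).sum()
    else:
        raise ConfigError(f"unknown penalty {penalty!r}")
    return float(nll + lam * pen)


def _nll_grad(xs: np.ndarray, z: np.ndarray, beta: np.ndarray, b: np.ndarray):
    """Smooth part value and gradients wrt (beta, intercepts)."""
    p = xs.shape[0]
    logits = b[None, :] + xs @ beta
    zmax = logits.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(logits - zmax).sum(axis=1))
    nll = -(np.sum(z * logits) - lse.sum()) / p
    pi = _softmax(logits)
    r = (pi - z) / p
    return nll, xs.T @ r, r.sum(axis=0)


def _prox(beta: np.ndarray, t: float, lam: float, penalty: str) -> np.ndarray:
    if lam == 0:
        return beta
    if penalty == "lasso":
        return np.sign(beta) * np.maximum(np.abs(beta) - t * lam, 0.0)
    norms = np.sqrt((beta**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - t * lam / norms), 0.0)
    return beta * scale


def _fista(
    xs: np.ndarray,
    z: np.ndarray,
    lam: float,
    penalty: str,
    beta0: np.ndarray,
    b0: np.ndarray,
    lip: float,
    max_iter: int,
    tol: float,
):
    """Monotone FISTA: accelerated proximal gradient with an ISTA
    fallback step whenever acceleration would increase the objective."""

    def full_obj(beta, b):
        return soft_multinomial_objective(xs, z, beta, b, lam, penalty)

    t_step = 1.0 / lip
    beta, b = beta0.copy(), b0.copy()
    vb, vi = beta.copy(), b.copy()  # momentum point
    momentum = 1.0
    obj = full_obj(beta, b)
    history = [obj]
    for it in range(1, max_iter + 1):
        _, gb, gi = _nll_grad(xs, z, vb, vi)
        cand_beta = _prox(vb - t_step * gb, t_step, lam, penalty)
        cand_b = vi - t_step * gi
        cand_obj = full_obj(cand_beta, cand_b)
        if cand_obj > obj:  # fallback: plain ISTA step from the last iterate
            _, gb, gi = _nll_grad(xs, z, beta, b)
            cand_beta = _prox(beta - t_step * gb, t_step, lam, penalty)
            cand_b = b - t_step * gi
            cand_obj = full_obj(cand_beta, cand_b)
            momentum = 1.0  # restart acceleration
        m_next = (1.0 + np.sqrt(1.0 + 4.0 * momentum**2)) / 2.0
        vb = cand_beta + ((momentum - 1.0) / m_next) * (cand_beta - beta)
        vi = cand_b + ((momentum - 1.0) / m_next) * (cand_b - b)
        momentum = m_next
        done = abs(obj - cand_obj) <= tol * max(1.0, abs(obj)) and it > 1
        if cand_obj <= obj:
            beta, b, obj = cand_beta, cand_b, cand_obj
        history.append(obj)
        if done:
            return beta, b, obj, it, True, np.asarray(history)
    return beta, b, obj, max_iter, False, np.asarray(history)


def _standardize(x: np.ndarray):
    means = x.mean(axis=0)
    scales = x.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    return (x - means) / scales, means, scales


def _lambda_max(xs: np.ndarray, z: np.ndarray, penalty: str) -> float:
    """Smallest lambda with an all-zero (standardized) coefficient matrix.

    At beta = 0 the optimal intercepts reproduce the vote column means;
    the penalty must dominate the gradient of the smooth part there.
    """
    p = xs.shape[0]
    zbar = z.mean(axis=0)
    g = xs.T @ (np.tile(zbar, (p, 1)) - z) / p
    if penalty == "lasso":
        return float(np.abs(g).max())
    return float(np.sqrt((g**2).sum(axis=1)).max())


def _lipschitz(xs1: np.ndarray) -> float:
    # softmax cross-entropy Hessian in the logits is bounded by I/2
    sigma = np.linalg.svd(xs1, compute_uv=False)[0]
    return max(sigma**2 / (2.0 * xs1.shape[0]), 1e-12)


def _cv_folds(p: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(folds), int(np.ceil(p / folds)))[:p]
    return rng.permutation(labels)


def _held_out_deviance(xs, z, beta, b) -> float:
    nll, _, _ = _nll_grad(xs, z, beta, b)
    return float(nll)


def _path_fit(xs, z, lams, penalty, lip, max_iter, tol):
    """Warm-started solutions along a descending lambda path."""
    m, d = xs.shape[1], z.shape[1]
    zbar = np.clip(z.mean(axis=0), 1e-12, None)
    beta = np.zeros((m, d))
    b = np.log(zbar)
    out = []
    for lam in lams:
        beta, b, obj, _, _, _ = _fista(xs, z, lam, penalty, beta, b, lip, max_iter, tol)
        out.append((beta.copy(), b.copy(), obj))
    return out


def fit_multinomial(
    x: BiomarkerMatrix,
    z: VoteMatrix,
    penalty: Literal["lasso", "grouped_lasso"] = "grouped_lasso",
    lam: float | str = "cv",
    folds: int = 5,
    seed: int | None = None,
    *,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    cv_rule: Literal["1se", "min"] = "1se",
    max_iter: int = 2000,
    tol: float = 1e-9,
    cv_max_iter: int = 600,
    cv_tol: float = 1e-8,
) -> MultinomialModel:
    """Fit the penalized soft-label multinomial regression.

    ``lam`` is either a fixed non-negative value or ``"cv"``, which
    selects a value over a 100-point log-spaced path via seeded k-fold
    CV: with ``cv_rule='1se'`` (default) the largest lambda whose mean
    held-out deviance is within one standard error of the minimum — the
    parsimonious rule that keeps the support empty when there is no
    signal — with ``'min'`` the deviance-minimizing lambda itself (ties
    to the largest lambda).
    """
    check_aligned_votes(x, z)
    if penalty not in ("lasso", "grouped_lasso"):
        raise ConfigError(f"unknown penalty {penalty!r}")
    xs, means, scales = _standardize(x.values)
    zv = z.values
    lip = _lipschitz(xs)
    cv_path = None
    if lam == "cv":
        if folds < 2:
            raise ConfigError("cross-validation requires folds >= 2")
        if seed is None:
            raise ConfigError("a seed is required when lam='cv'")
        lam_max = _lambda_max(xs, zv, penalty)
        if lam_max <= 0:  # degenerate: votes already explained by intercepts
            lam_value = 0.0
            cv_path = []
        else:
            lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
            fold_labels = _cv_folds(x.n_patients, folds, seed)
            dev = np.zeros((folds, len(lams)))
            for fold in range(folds):
                train = fold_labels != fold
                test = ~train
                xs_tr, m_tr, s_tr = _standardize(x.values[train])
                xs_te = (x.values[test] - m_tr) / s_tr
                lip_tr = _lipschitz(xs_tr)
                sols = _path_fit(xs_tr, zv[train], lams, penalty, lip_tr, cv_max_iter, cv_tol)
                for i, (beta_i, b_i, _) in enumerate(sols):
                    dev[fold, i] = _held_out_deviance(xs_te, zv[test], beta_i, b_i)
            mean_dev = dev.mean(axis=0)
            best_i = int(np.argmin(mean_dev))  # path descends: ties -> largest lambda
            if cv_rule == "1se":
                se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
                within = np.flatnonzero(mean_dev <= mean_dev[best_i] + se[best_i])
                best_i = int(within[0])  # largest lambda inside the band
            elif cv_rule != "min":
                raise ConfigError(f"unknown cv_rule {cv_rule!r}")
            lam_value = float(lams[best_i])
            cv_path = list(zip(lams.tolist(), mean_dev.tolist()))
    else:
        lam_value = float(lam)
        if lam_value < 0:
            raise ConfigError("lambda must be >= 0")

    # final fit on all patients, warm-started down the path to lam_value
    lam_max_full = _lambda_max(xs, zv, penalty)
    if lam_value < lam_max_full and lam_value > 0:
        warm = np.geomspace(lam_max_full, lam_value, 8)
    else:
        warm = np.array([lam_value])
    zbar = np.clip(zv.mean(axis=0), 1e-12, None)
    beta, b = np.zeros((x.n_markers, z.n_drugs)), np.log(zbar)
    for lam_i in warm[:-1]:
        beta, b, _, _, _, _ = _fista(xs, zv, lam_i, penalty, beta, b, lip, cv_max_iter, cv_tol)
    beta, b, obj, n_iter, converged, history = _fista(
        xs, zv, warm[-1], penalty, beta, b, lip, max_iter, tol
    )
    if np.any(np.diff(history) > 1e-6 * max(1.0, abs(history[0]))):
        raise ConvergenceError(
            "objective increased across solver iterations beyond tolerance; "
            f"history span [{history.min():.6g}, {history.max():.6g}]"
        )
    # report coefficients on the original feature scale
    beta_orig = beta / scales[:, None]
    intercepts = b - means @ beta_orig
    return MultinomialModel(
        beta=beta_orig,
        intercepts=intercepts,
        penalty=penalty,
        lam=lam_value,
        marker_names=list(x.marker_names),
        drug_names=list(z.drug_names),
        feature_means=means,
        feature_scales=scales,
        objective=obj,
        n_iter=n_iter,
        converged=converged,
        cv_path=cv_path,
        cv_seed=seed if lam == "cv" else None,
        objective_history=history,
    )


def check_aligned_votes(x: BiomarkerMatrix, z: VoteMatrix) -> None:
    if x.patient_ids != z.patient_ids:
        from .exceptions import AlignmentError

        raise AlignmentError("biomarker and vote matrices are not aligned on patients")


def predict_multinomial(model: MultinomialModel, x: BiomarkerMatrix) -> Assignment:
    """Assign each patient the argmax-logit drug (ties -> lowest index)."""
    missing = [m for m in model.marker_names if m not in x.marker_names]
    if missing:
        raise FeatureError(f"markers required by the model are missing: {missing[:5]}")
    cols = [x.marker_index(m) for m in model.marker_names]
    logits = model.intercepts[None, :] + x.values[:, cols] @ model.beta
    picks = np.argmax(logits, axis=1)
    return Assignment(list(x.patient_ids), [model.drug_names[j] for j in picks])


def count_selected_variables(model: MultinomialModel) -> int:
    """Number of markers with any coefficient above the zero threshold."""
    return int(np.any(np.abs(model.beta) > ZERO_COEF_TOL, axis=1).sum())
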