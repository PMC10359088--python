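"""IC50* normalization and response transforms.

IC50* is the per-drug mean-centered log-IC50: for each drug the mean of
the log-IC50 over all patients with a measurement is subtracted, so every
drug's column mean is zero.  The centering deliberately removes overall
potency — a uniformly potent (often uniformly toxic) compound no longer
dominates every patient, and the methods instead prioritize drugs with a
*differential* effect across patients, the ones a companion biomarker can
act on.

Because IC50-type responses are "smaller is better" while the tree
objective maximizes a sum of responses, fitters work on a negated
``benefit`` scale: maximizing benefit is exactly minimizing IC50*.  The
optional signed square root ``sign(y) * sqrt(|y|)`` compresses the
dynamic range to limit the influence of outlying measurements; it is odd
and strictly increasing, so it preserves ordering and commutes with the
benefit negation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .data import SensitivityMatrix
from .exceptions import NormalizationError

__all__ = [
    "TransformSpec",
    "compute_ic50_star",
    "apply_transform",
    "signed_sqrt",
    "to_benefit",
]


@dataclass(frozen=True)
class TransformSpec:
    """Response transform plus the optimization sense it is applied under."""

    kind: str = "identity"  # identity | signed_sqrt
    sense: str = "maximize"  # fitters maximize benefit internally

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "signed_sqrt"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"unknown sense {self.sense!r}")


def signed_sqrt(values: np.ndarray) -> np.ndarray:
    """Odd square root ``sign(y) * sqrt(|y|)`` (defined for negative IC50*)."""
    values = np.asarray(values, dtype=float)
    return np.sign(values) * np.sqrt(np.abs(values))


def compute_ic50_star(y: SensitivityMatrix) -> SensitivityMatrix:
    """Center each drug's observed log-IC50 values to mean zero.

    Missing entries stay missing and are excluded from the means.
    Idempotent: re-centering an ``ic50_star`` matrix is a no-op (up to
    floating point).
    """
    if y.scale == "benefit":
        raise NormalizationError("IC50* is defined on the (log) IC50 scale, not benefit")
    obs = y.observed()
    if not obs.any(axis=0).all():
        bad = [y.drug_names[j] for j in np.flatnonzero(~obs.any(axis=0))]
        raise NormalizationError(f"drug(s) with no observed values: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(y.values, axis=0)
    return SensitivityMatrix(
        y.values - means[None, :],
        list(y.patient_ids),
        list(y.drug_names),
        scale="ic50_star",
    )


def apply_transform(y: SensitivityMatrix, spec: TransformSpec) -> SensitivityMatrix:
    """Apply the elementwise response transform; labels and scale are kept."""
    if spec.kind == "identity":
        return _dc_replace(
            y,
            values=y.values.copy(),
            patient_ids=list(y.patient_ids),
            drug_names=list(y.drug_names),
        )
    out = signed_sqrt(y.values)
    # construct under a scale without the zero-mean invariant (centering is
    # not preserved by a nonlinear map), then restore the original flag:
    # ordering — hence the optimization sense — is what the flag tracks
    sm = SensitivityMatrix(out, list(y.patient_ids), list(y.drug_names), scale="log_ic50")
    sm.scale = y.scale
    return sm


def to_benefit(y: SensitivityMatrix) -> SensitivityMatrix:
    """Negate responses so that larger = better.

    Maximizing the benefit of a drug assignment is then identical to
    minimizing its IC50*; calling it twice warns and returns an
    unchanged copy.
    """
    if y.scale == "benefit":
        warnings.warn("matrix is already on the benefit scale; returning unchanged")
        return _dc_replace(
            y,
            values=y.values.copy(),
            patient_ids=list(y.patient_ids),
            drug_names=list(y.drug_names),
        )
    return SensitivityMatrix(
        -y.values, list(y.patient_ids), list(y.drug_names), scale="benefit"
    )
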