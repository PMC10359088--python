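"""Core domain containers and delimited-text matrix I/O.

The two central objects mirror the shape of an ex vivo drug screen:

* :class:`SensitivityMatrix` — patients x drugs response values ``Y``
  (log-IC50, per-drug centered IC50*, or negated "benefit" values).
* :class:`BiomarkerMatrix` — patients x markers values ``X`` (binary
  mutation calls and/or continuous measurements such as expression).

Matrices live on disk as TSV/CSV with a header row of column labels and a
first column of patient identifiers; pandas does the parsing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DimensionError,
    DrugLookupError,
    LabelError,
    MatrixParseError,
)

Scale = Literal["log_ic50", "ic50_star", "benefit"]

#: tokens treated as missing in delimited files (case-insensitive), plus
#: the empty cell
MISSING_TOKENS = ("NA", "NaN", "nan", "na", "")


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise LabelError(f"duplicate {what} label(s): {dupes}")
    return labels


@dataclass
class SensitivityMatrix:
    """Patient x drug response matrix Y.

    Missing measurements are stored as NaN.  ``scale`` decides the
    optimization sense downstream: on ``benefit`` larger is better,
    otherwise smaller (lower IC50 = more sensitive).
    """

    values: np.ndarray
    patient_ids: list[str]
    drug_names: list[str]
    scale: Scale = "log_ic50"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise DimensionError("sensitivity matrix must be non-empty and 2-D")
        self.patient_ids = _check_labels(self.patient_ids, "patient")
        self.drug_names = _check_labels(self.drug_names, "drug")
        p, d = self.values.shape
        if len(self.patient_ids) != p or len(self.drug_names) != d:
            raise DimensionError(
                f"label counts ({len(self.patient_ids)}, {len(self.drug_names)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if self.scale not in ("log_ic50", "ic50_star", "benefit"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "ic50_star":
            obs = ~np.isnan(self.values)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means = np.nanmean(self.values, axis=0)
            means = np.where(obs.any(axis=0), means, 0.0)
            if np.any(np.abs(means) > 1e-8):
                bad = [self.drug_names[j] for j in np.flatnonzero(np.abs(means) > 1e-8)]
                raise ValueError(
                    f"scale=ic50_star requires zero column means; offending drugs: {bad[:5]}"
                )

    # -- conveniences -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]

    @property
    def higher_is_better(self) -> bool:
        return self.scale == "benefit"

    def drug_index(self, drug: str) -> int:
        try:
            return self.drug_names.index(drug)
        except ValueError:
            raise DrugLookupError(f"unknown drug {drug!r}") from None

    def observed(self) -> np.ndarray:
        """Boolean mask of measured entries."""
        return ~np.isnan(self.values)

    def take_patients(self, idx: Sequence[int]) -> "SensitivityMatrix":
        idx = np.asarray(idx, dtype=int)
        # zero column means is a whole-cohort invariant; a subset keeps the
        # ic50_star semantics without exact centering, so skip the re-check
        out = SensitivityMatrix(
            self.values[idx].copy(),
            [self.patient_ids[i] for i in idx],
            list(self.drug_names),
            scale="log_ic50" if self.scale == "ic50_star" else self.scale,
        )
        out.scale = self.scale
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.drug_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: Scale = "log_ic50") -> "SensitivityMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), scale)


@dataclass
class BiomarkerMatrix:
    """Patient x marker matrix X; each column is binary (0/1) or continuous."""

    values: np.ndarray
    patient_ids: list[str]
    marker_names: list[str]
    column_kind: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise DimensionError("biomarker matrix must be non-empty and 2-D")
        self.patient_ids = _check_labels(self.patient_ids, "patient")
        self.marker_names = _check_labels(self.marker_names, "marker")
        p, m = self.values.shape
        if len(self.patient_ids) != p or len(self.marker_names) != m:
            raise DimensionError(
                f"label counts ({len(self.patient_ids)}, {len(self.marker_names)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise MatrixParseError("missing biomarker values are not supported")
        if not self.column_kind:
            self.column_kind = [
                "binary" if np.isin(col, (0.0, 1.0)).all() else "continuous"
                for col in self.values.T
            ]
        if len(self.column_kind) != m:
            raise DimensionError("column_kind length does not match marker count")
        for j, kind in enumerate(self.column_kind):
            if kind not in ("binary", "continuous"):
                raise ValueError(f"unknown column kind {kind!r}")
            if kind == "binary" and not np.isin(self.values[:, j], (0.0, 1.0)).all():
                raise MatrixParseError(
                    f"marker {self.marker_names[j]!r} declared binary but has "
                    "values outside {0, 1}"
                )

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_names.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def take_patients(self, idx: Sequence[int]) -> "BiomarkerMatrix":
        idx = np.asarray(idx, dtype=int)
        return BiomarkerMatrix(
            self.values[idx].copy(),
            [self.patient_ids[i] for i in idx],
            list(self.marker_names),
            list(self.column_kind),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.marker_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, column_kind: list[str] | None = None) -> "BiomarkerMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), column_kind or [])


@dataclass
class Assignment:
    """Per-patient drug recommendation, optionally with the achieved response."""

    patient_ids: list[str]
    assigned_drug: list[str]
    achieved_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.patient_ids) != len(self.assigned_drug):
            raise DimensionError("patient_ids and assigned_drug lengths differ")
        if self.achieved_value is None:
            self.achieved_value = np.full(len(self.patient_ids), np.nan)
        self.achieved_value = np.asarray(self.achieved_value, dtype=float)
        if self.achieved_value.shape != (len(self.patient_ids),):
            raise DimensionError("achieved_value length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"assigned_drug": self.assigned_drug, "achieved_value": self.achieved_value},
            index=pd.Index(self.patient_ids, name="patient_id"),
        )


def check_aligned(y: SensitivityMatrix, x: BiomarkerMatrix) -> None:
    """Assert Y and X describe the same patients in the same order."""
    if y.patient_ids != x.patient_ids:
        raise AlignmentError(
            "sensitivity and biomarker matrices are not aligned on patients"
        )


def attach_achieved(assignment: Assignment, y: SensitivityMatrix) -> Assignment:
    """Fill ``achieved_value`` from each patient's own measurement of the
    assigned drug (NaN when unmeasured or the patient is absent from Y)."""
    pos = {p: i for i, p in enumerate(y.patient_ids)}
    achieved = np.full(len(assignment.patient_ids), np.nan)
    for i, (pid, drug) in enumerate(zip(assignment.patient_ids, assignment.assigned_drug)):
        if pid in pos:
            achieved[i] = y.values[pos[pid], y.drug_index(drug)]
    return Assignment(list(assignment.patient_ids), list(assignment.assigned_drug), achieved)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    kind: Literal["sensitivity", "biomarker"],
    *,
    delimiter: str | None = None,
    transpose: bool = False,
    scale: Scale = "log_ic50",
    column_kind: list[str] | None = None,
):
    """Read a labeled numeric matrix from TSV/CSV.

    First row = column labels, first column = row labels (patients are
    rows unless ``transpose``).  "NA" (any case) and empty cells read as
    missing; missing is only legal for sensitivity matrices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    if transpose:
        df = df.T
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DimensionError(f"empty matrix in {path}")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise LabelError(f"duplicate row or column labels in {path}")
    # locate non-numeric cells precisely rather than letting astype throw
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    if kind == "sensitivity":
        return SensitivityMatrix.from_frame(numeric, scale=scale)
    if kind == "biomarker":
        return BiomarkerMatrix.from_frame(numeric, column_kind=column_kind)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix, path: str | Path, *, delimiter: str | None = None) -> None:
    """Write a matrix container back to labeled TSV/CSV (missing -> NA)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    matrix.to_frame().to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")
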