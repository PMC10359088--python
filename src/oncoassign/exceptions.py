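"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`OncoassignError` so callers can catch the library's own failures
without swallowing programming errors.
"""


class OncoassignError(Exception):
    """Base class for all package errors."""


class LabelError(OncoassignError):
    """Duplicate or inconsistent row/column labels."""


class MatrixParseError(OncoassignError):
    """Malformed delimited-text matrix (non-numeric cell, bad schema...)."""


class DimensionError(OncoassignError):
    """Empty matrix or shape/label-count mismatch."""


class AlignmentError(OncoassignError):
    """Paired matrices do not share the same patient sequence."""


class NormalizationError(OncoassignError):
    """IC50* normalization cannot be computed (e.g. all-missing drug)."""


class MissingDataError(OncoassignError):
    """Missing entries encountered under the strict missing-data policy."""


class TreeSchemaError(OncoassignError):
    """Serialized decision tree violates the JSON schema or tree invariants."""


class NotFittedError(OncoassignError):
    """Operation requires a fitted model/tree."""


class FitError(OncoassignError):
    """Model fitting cannot proceed (e.g. zero patients)."""


class FeatureError(OncoassignError):
    """A marker required by a fitted model is absent from the input."""


class DrugLookupError(OncoassignError):
    """A requested drug is not a column of the sensitivity matrix."""


class DomainError(OncoassignError):
    """Input values outside the domain a formula requires (e.g. y <= 0)."""


class ConvergenceError(OncoassignError):
    """Optimizer diverged (objective increased beyond tolerance)."""


class ConfigError(OncoassignError):
    """Invalid configuration value."""


class EvaluationError(OncoassignError):
    """Evaluation protocol cannot be applied (e.g. all-missing patient)."""
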