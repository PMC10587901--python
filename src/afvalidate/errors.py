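"""Exception hierarchy.

Every error raised on a user-facing contract violation derives from
:class:`AFValidateError` so callers can catch the package's failures in one
clause while letting programming errors propagate.
"""


class AFValidateError(Exception):
    """Base class for all errors raised by afvalidate."""


class SchemaError(AFValidateError):
    """A required column or field is missing or malformed in an input file."""


class CohortValidationError(AFValidateError):
    """A cohort row violates a data-model invariant (e.g. age < 18)."""


class ModelSpecError(AFValidateError):
    """A risk-model coefficient file violates its schema or invariants."""


class EvaluationError(AFValidateError):
    """A risk-equation term could not be evaluated (e.g. log of non-positive)."""


class MetricError(AFValidateError):
    """A metric is undefined on the given data (e.g. no cases for an AUC)."""


class ConfigError(AFValidateError):
    """A run or simulation configuration value is invalid."""
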