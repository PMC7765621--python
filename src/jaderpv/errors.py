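"""Exception and warning types shared across the pipeline."""


class JaderPvError(Exception):
    """Base class for all package errors."""


class SchemaError(JaderPvError):
    """An input table does not match the expected column layout."""


class DataIntegrityError(JaderPvError):
    """Input data violates a structural invariant (e.g. duplicate case ids)."""


class ConfigurationError(JaderPvError):
    """A configuration value is invalid or inconsistent."""


class DegenerateDesignError(JaderPvError):
    """A regression design matrix is unusable (constant predictor, empty outcome)."""


class InsufficientDataError(JaderPvError):
    """Too few rows/columns remain after filtering to run the analysis."""


class UndefinedTestError(JaderPvError):
    """A statistical test is undefined for the given input (e.g. empty group)."""


class SeparationWarning(UserWarning):
    """Perfect or quasi-perfect separation detected in a logistic fit."""
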