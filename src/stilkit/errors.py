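"""Exception types shared across the package."""


class StilkitError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(StilkitError, ValueError):
    """A configuration value violates its documented range or consistency rule."""


class UndefinedScoreError(StilkitError, ValueError):
    """A sTIL score was requested where it is mathematically undefined
    (zero cancer-stroma area). Never silently returned as 0."""


class DegenerateStatisticError(StilkitError, ValueError):
    """A statistic is undefined on the given input (e.g. both vectors
    constant for a concordance coefficient, zero variance for a t test)."""


class SeparationError(StilkitError, RuntimeError):
    """Complete or quasi-complete separation detected during a logistic fit;
    maximum-likelihood estimates diverge."""

    def __init__(self, message: str, coefficients=None):
        super().__init__(message)
        self.coefficients = coefficients


class InvalidRecordError(StilkitError, ValueError):
    """A cohort record carries an out-of-range field (e.g. Miller-Payne grade
    outside 1..5)."""


class ParseError(StilkitError, ValueError):
    """A file could not be parsed; the message names the offending location."""
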