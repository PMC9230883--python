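"""Exception hierarchy shared by all apval stages."""


class ApvalError(Exception):
    """Base class for all apval errors."""


class SchemaError(ApvalError):
    """A required column is missing or misnamed in an input table."""


class IntegrityError(ApvalError):
    """Duplicate keys or values that violate table-level uniqueness."""


class ParseError(ApvalError):
    """Unparseable input (empty file, non-numeric response, ...)."""


class DesignError(ApvalError):
    """The experimental design is unbalanced or too small for the requested
    statistic (the variance-component formulas assume a balanced p x n grid)."""


class FitError(ApvalError):
    """A calibration model could not be fitted (too few points, zero slope)."""


class DomainError(ApvalError):
    """Input outside the mathematical domain of a transform (e.g. negative
    response under a square-root model)."""


class PeakError(ApvalError):
    """No usable chromatographic peak in the requested window."""


class BoundaryError(ApvalError):
    """A peak-width fraction level is not crossed inside the trace."""
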