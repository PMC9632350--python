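"""Exception hierarchy.

Every error raised by the package derives from :class:`TractAgeError`, so
callers (and the CLI) can catch one base class and map subclasses to exit
codes.
"""


class TractAgeError(Exception):
    """Base class for all package errors."""


class ParameterError(TractAgeError, ValueError):
    """An argument or configuration value violates its contract."""


class SchemaError(TractAgeError, ValueError):
    """A table is missing required columns or has malformed cells."""


class ContractError(TractAgeError, ValueError):
    """A precondition between modules is violated (e.g. missing ground truth)."""


class EmptyCohortError(TractAgeError):
    """A filtering step removed every subject."""


class DegenerateScalerError(TractAgeError):
    """A tract (or age) has zero variance in the training set."""


class HarmonizationError(TractAgeError):
    """Protocol harmonization has no overlapping age bins to work with."""


class NumericalError(TractAgeError, ArithmeticError):
    """A linear system is singular or a computation produced non-finite values."""


class CrossValidationError(TractAgeError):
    """A model fit failed inside a cross-validation fold."""


class PruningError(TractAgeError):
    """The pruning budget cannot be reached."""


class ConvergenceError(TractAgeError):
    """The input-correction loop hit its iteration cap before converging."""


class StallError(TractAgeError):
    """The input-correction loop stopped making progress."""


class MetricError(TractAgeError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
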