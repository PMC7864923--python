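"""Exception hierarchy for twinace."""


class TwinaceError(Exception):
    """Base class for all twinace errors."""


class SchemaError(TwinaceError):
    """A required column or schema entry is missing or malformed."""


class EmptyInputError(TwinaceError):
    """An input file or table contained no usable rows."""


class RangeError(TwinaceError):
    """A value fell outside its documented range (e.g. Likert responses)."""


class SingularDesignError(TwinaceError):
    """The covariate design matrix is singular (e.g. a constant covariate)."""


class InsufficientDataError(TwinaceError):
    """Too few observations for the requested estimator."""


class NotIdentifiedError(TwinaceError):
    """The requested model is not identified (e.g. C and D together)."""


class UnsupportedModelError(TwinaceError):
    """The requested model label is not supported (e.g. DE)."""


class ConvergenceError(TwinaceError):
    """Optimization failed to converge; carries the best value found."""

    def __init__(self, message, best_value=None):
        super().__init__(message)
        self.best_value = best_value


class ConditioningError(TwinaceError):
    """An input matrix is numerically non-positive-definite."""

    def __init__(self, message, smallest_eigenvalue=None):
        super().__init__(message)
        self.smallest_eigenvalue = smallest_eigenvalue
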