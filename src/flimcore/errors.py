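"""Exception types shared across the pipeline."""


class FLImError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(FLImError, ValueError):
    """A parameter is outside its valid range."""


class ShapeError(FLImError, ValueError):
    """Array dimensions are inconsistent."""


class DegenerateInputError(FLImError, ValueError):
    """Input carries no usable signal (e.g. an all-zero waveform)."""


class NumericalFailureError(FLImError, RuntimeError):
    """A solver failed to converge; carries the solver status message."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


class CoordinateError(FLImError, ValueError):
    """A position falls outside the coordinate system it is expressed in."""


class AlignmentError(FLImError, ValueError):
    """Paired traces are not aligned (length mismatch)."""


class InsufficientDataError(FLImError, ValueError):
    """Too few samples to compute the requested statistic."""


class ConfigurationError(FLImError, ValueError):
    """A configuration document is inconsistent or incomplete."""


class UndefinedAUCError(FLImError, ValueError):
    """ROC-AUC is undefined (a class is absent from the evaluation set)."""
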