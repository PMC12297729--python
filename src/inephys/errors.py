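"""Exception hierarchy shared across the package."""


class InephysError(Exception):
    """Base class for all package errors."""


class ValidationError(InephysError, ValueError):
    """Input data violates a structural invariant (NaNs, empty, inconsistent units)."""


class FormatError(InephysError, ValueError):
    """A file does not follow the package's exchange format."""


class ProtocolError(InephysError, ValueError):
    """A recording lacks the protocol structure an analysis requires."""


class ParameterError(InephysError, ValueError):
    """A user-supplied parameter is outside its valid domain."""


class MorphologyError(InephysError, ValueError):
    """A waveform lacks the morphology needed for spike feature extraction."""


class FitError(InephysError, RuntimeError):
    """Nonlinear fitting failed to converge or the data are degenerate.

    Carries the last parameter iterate (if any) in ``last_params``.
    """

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params
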