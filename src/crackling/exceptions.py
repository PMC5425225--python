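"""Exception hierarchy for the crackling package."""


class CracklingError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CracklingError, ValueError):
    """A parameter is outside its valid domain."""


class InvalidProbabilityError(ParameterError):
    """A derived per-event probability left [0, 1]."""


class BaselineError(CracklingError, ValueError):
    """A fluorescence baseline is non-positive; input must be raw fluorescence."""


class DegenerateInputError(CracklingError, ValueError):
    """Input carries no usable signal (e.g. pooled SD of zero)."""


class BinningError(CracklingError, ValueError):
    """Requested bin width is incompatible with the raster resolution."""


class InsufficientDataError(CracklingError, ValueError):
    """Too few samples to run the requested estimator."""


class DegenerateSupportError(CracklingError, ValueError):
    """Distribution support collapsed to fewer than two points."""


class UnstableFitError(CracklingError, RuntimeError):
    """Bootstrap refits failed too often to trust the spread."""


class PairingError(CracklingError, ValueError):
    """Subjects cannot be paired across conditions."""
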