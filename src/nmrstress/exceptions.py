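"""Exception hierarchy for the nmrstress pipeline."""


class NmrStressError(Exception):
    """Base class for all nmrstress errors."""


class InvalidParameterError(NmrStressError, ValueError):
    """A numeric parameter violates its contract (e.g. non-positive linewidth)."""


class ConfigurationError(NmrStressError, ValueError):
    """Inconsistent simulation or library configuration."""


class InvalidInputError(NmrStressError, ValueError):
    """Malformed data passed to an operation (empty spectrum, p outside [0,1], ...)."""


class DesignError(NmrStressError, ValueError):
    """Sample design table violates the crossover contract."""


class NormalizationError(NmrStressError, ValueError):
    """Reference resonance integral is missing or non-positive."""


class AlignmentError(NmrStressError, ValueError):
    """Spectra do not share a common bin grid."""


class EmptyMatrixError(NmrStressError, ValueError):
    """All bins were excluded; nothing left to analyse."""


class DegenerateInputError(NmrStressError, ValueError):
    """Matrix has no variance to model."""


class InsufficientDataError(NmrStressError, ValueError):
    """Too few samples for the requested statistic."""
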