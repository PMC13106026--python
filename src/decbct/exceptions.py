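"""Exception hierarchy shared across the pipeline stages."""


class DecbctError(Exception):
    """Base class for all package errors."""


class RangeError(DecbctError, ValueError):
    """A physical quantity fell outside its tabulated / supported range."""


class ConfigurationError(DecbctError, ValueError):
    """Unsupported or inconsistent configuration value."""


class ValidationError(DecbctError, ValueError):
    """Input violates a documented precondition."""


class LookupErrorDecbct(DecbctError, KeyError):
    """Unknown material or resource name."""


class DegenerateInputError(DecbctError, ValueError):
    """Mathematically degenerate input (all-zero spectrum, empty ROI, ...)."""


class CoverageError(DecbctError, ValueError):
    """Reconstruction/rasterization grid does not cover the object."""


class DecompositionError(DecbctError, RuntimeError):
    """Ill-conditioned or failed basis-material decomposition."""


class PairingError(DecbctError, ValueError):
    """Dual-energy inputs that are supposed to be paired do not match."""
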