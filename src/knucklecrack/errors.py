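"""Exception types used across the package."""


class KnuckleCrackError(Exception):
    """Base class for all package errors."""


class DomainError(KnuckleCrackError, ValueError):
    """An input lies outside the physical/mathematical domain of an operation."""


class InceptionError(KnuckleCrackError, ValueError):
    """Bubble inception is impossible for the requested anchoring.

    Raised when the surface-tension balance would require a negative initial
    gas pressure; the caller should re-anchor the inception pressure (see
    ``FluidProperties`` / ``inception_anchor``).
    """


class SignalError(KnuckleCrackError, ValueError):
    """An operation on a waveform is undefined (e.g. all-zero signal)."""


class BracketError(KnuckleCrackError, ValueError):
    """A bisection bracket is invalid (both endpoints on the same side)."""


class ConfigError(KnuckleCrackError, ValueError):
    """A configuration file or dictionary failed validation."""
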