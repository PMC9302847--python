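"""Exception hierarchy for ddrkit.

All domain errors derive from :class:`DDRKitError` (itself a ``ValueError``)
so callers can catch everything from this package with a single clause while
still getting sensible behaviour from generic ``except ValueError`` code.
"""


class DDRKitError(ValueError):
    """Base class for all ddrkit errors."""


class ResponseSetParseError(DDRKitError):
    """A delimited-text response table could not be parsed."""


class InsufficientDataError(DDRKitError):
    """Too few trials (or observations) for the requested operation."""


class DegenerateSignalError(DDRKitError):
    """The two condition means are indistinguishable (|delta mu| ~ 0)."""


class DegenerateNoiseError(DDRKitError):
    """The leading noise eigenvector is parallel to the signal axis."""


class DegenerateVarianceError(DDRKitError):
    """Projected responses have zero pooled variance."""


class RankError(DDRKitError):
    """More dimensions requested than the data can support."""


class ShapeError(DDRKitError):
    """Operands have incompatible dimensions."""


class ConfigError(DDRKitError):
    """Invalid simulator or experiment configuration."""
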