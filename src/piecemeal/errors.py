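"""Exception hierarchy shared across the package."""


class PiecemealError(Exception):
    """Base class for package-specific errors."""


class CapacityError(PiecemealError):
    """Raised when a request exceeds the exact-enumeration capacity."""


class ParseError(PiecemealError, ValueError):
    """Raised on malformed constraint / hypothesis / graph text."""


class PoolExhausted(PiecemealError):
    """Raised by selection policies when every study design has been performed."""
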