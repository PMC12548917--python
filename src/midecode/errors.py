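"""Exception hierarchy shared across the package."""


class MidecodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MidecodeError, ValueError):
    """An invalid parameter or specification field."""


class ShapeError(MidecodeError, ValueError):
    """Array extents incompatible with the requested operation."""


class InsufficientDataError(MidecodeError, ValueError):
    """Too few trials or subjects for the requested protocol."""


class DegenerateChannelError(MidecodeError, ValueError):
    """A channel with zero variance cannot be standardized."""


class FormatError(MidecodeError, ValueError):
    """A fixture or data file violates the expected layout."""


class LabelError(MidecodeError, ValueError):
    """A class label outside the declared range."""
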