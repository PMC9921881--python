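"""Exception types raised across the package."""


class ValenscopeError(Exception):
    """Base class for package-specific errors."""


class ArchiveValidationError(ValenscopeError, ValueError):
    """A trial archive violates a structural or range invariant."""


class ShapeMismatchError(ArchiveValidationError):
    """Stored array dimensions disagree with the declared layout."""


class ChannelLookupError(ValenscopeError, KeyError):
    """A requested channel label is not present in the montage."""


class EdfFormatError(ValenscopeError, ValueError):
    """The file is not a readable EDF/EDF+ recording."""


class UnsupportedEdfError(ValenscopeError, ValueError):
    """The EDF file is valid but uses a layout this package does not handle."""


class FilterDesignError(ValenscopeError, ValueError):
    """A band definition cannot be realized at the given sampling rate."""


class DegenerateTaskError(ValenscopeError, ValueError):
    """A classification task is degenerate (e.g. a single class present)."""
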