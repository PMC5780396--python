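"""Exception types shared across the package."""


class BspimError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(BspimError):
    """A synthetic scene could not be laid out under its separation constraints."""


class ScanFormatError(BspimError):
    """An on-disk scan directory violates the documented layout."""


class ZeroVarianceError(BspimError, ValueError):
    """A transect has zero intensity variance, so S/N is undefined."""
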