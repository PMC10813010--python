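"""Exception types shared across the package."""


class SkullrayError(Exception):
    """Base class for package-specific errors."""


class FormatError(SkullrayError, ValueError):
    """A volume or table file is malformed or missing required metadata."""


class GeometryError(SkullrayError, ValueError):
    """A requested geometry does not fit the stated constraints."""


class DegenerateNormalError(SkullrayError, ValueError):
    """The intensity gradient vanishes, so no surface normal exists."""


class InsufficientDataError(SkullrayError, ValueError):
    """Too few records to compute the requested statistic."""
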