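"""Exception hierarchy.

All halofit-specific failures derive from :class:`HalofitError` so callers
can catch the package's errors without masking programming mistakes.
"""


class HalofitError(Exception):
    """Base class for all halofit errors."""


class InputError(HalofitError):
    """An input file is missing, unreadable, or not decodable."""


class GeometryError(HalofitError):
    """Track geometry is inconsistent with the image or the plate layout."""


class ParameterError(HalofitError):
    """A parameter violates its documented constraints."""


class DataError(HalofitError):
    """The supplied data cannot support the requested computation."""


class NotADoublePeakError(DataError):
    """Automatic ring-signal detection found fewer than two maxima.

    The outer legs have to be defined manually in this case (see
    :func:`halofit.peaks.define_legs_manual`).
    """


class RangeError(HalofitError):
    """A requested quantity lies outside the fitted/valid range."""


class ConfigError(HalofitError):
    """A run configuration is incomplete or inconsistent."""
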