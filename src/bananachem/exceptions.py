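"""Exception hierarchy.

All package errors derive from :class:`BananachemError` so callers can catch
one base class; the leaves also derive from the matching builtin so idiomatic
``except ValueError`` code keeps working.
"""


class BananachemError(Exception):
    """Base class for all errors raised by bananachem."""


class ConfigurationError(BananachemError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class EnviFormatError(BananachemError, ValueError):
    """A malformed or unsupported ENVI header/data pair."""


class CalibrationError(BananachemError, ValueError):
    """Black/white reflectance calibration failed (e.g. white <= dark)."""


class DegenerateDataError(BananachemError, ValueError):
    """Input data has no usable variation for the requested operation."""
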