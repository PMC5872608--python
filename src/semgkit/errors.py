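"""Exception hierarchy.

All semgkit errors derive from :class:`SemgKitError` so callers can catch
the package's failures with a single ``except`` clause.
"""


class SemgKitError(Exception):
    """Base class for all semgkit errors."""


class FormatError(SemgKitError):
    """A file does not conform to the expected on-disk layout."""


class ParameterError(SemgKitError, ValueError):
    """An argument is outside the domain an operation supports."""


class DegenerateProfileError(ParameterError):
    """A movement profile cannot produce a usable signal (negative gains)."""


class LengthError(ParameterError):
    """A record is too short for the requested transform."""
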