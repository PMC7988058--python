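"""Exception hierarchy for texsurv.

The CLI maps :class:`ConfigurationError` to exit code 2 and every
:class:`DataError` subclass to exit code 3.
"""


class TexsurvError(Exception):
    """Base class for all texsurv errors."""


class ConfigurationError(TexsurvError):
    """Invalid or contradictory run configuration."""


class DataError(TexsurvError):
    """Problem with input data (format, geometry, content)."""


class FormatError(DataError):
    """A file could not be parsed, or required metadata is absent."""


class GeometryError(DataError):
    """Volume/mask grids are not congruent."""


class ValidationError(DataError):
    """Input values violate a documented precondition."""


class KeyingError(DataError):
    """Feature and survival tables could not be joined on patient_id."""

    def __init__(self, message: str, orphans=()):
        super().__init__(message)
        self.orphans = tuple(orphans)
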