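"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`ConfigurationError` and :class:`DataError`
exit 2, :class:`FitError` and :class:`ConsistencyError` exit 3.
"""


class MaihdaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MaihdaError):
    """A config file, scheme or column mapping is invalid. Names the key."""


class DataError(MaihdaError):
    """Input data violate a contract (bad value, bounds, duplicate id)."""

    def __init__(self, message: str, area_id: str | None = None):
        super().__init__(message)
        self.area_id = area_id


class FitError(MaihdaError):
    """Model estimation failed (singular design, non-convergence)."""


class ConsistencyError(MaihdaError):
    """Objects from different pipeline runs were combined."""
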