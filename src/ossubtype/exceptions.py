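"""Package-level exception hierarchy."""


class OssubtypeError(Exception):
    """Base class for all errors raised by ossubtype."""


class ConfigurationError(OssubtypeError, ValueError):
    """An invalid simulation or analysis configuration."""


class EmptyResultError(OssubtypeError):
    """A filter or selection removed everything; carries diagnostic counts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptyPanelError(OssubtypeError):
    """A marker panel ended up empty after thresholding / exclusivity."""


class MissingMarkersError(OssubtypeError):
    """A subtype group has no measured marker genes in the input table."""


class GroupNamingError(OssubtypeError):
    """Two consensus clusters mapped onto the same subtype group."""


class DegenerateCutError(OssubtypeError):
    """A dichotomization cut produced an empty group (e.g. constant scores)."""
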