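"""Exception hierarchy for ampliclean."""


class AmplicleanError(Exception):
    """Base class for all ampliclean errors."""


class FormatError(AmplicleanError):
    """Input file could not be parsed as a feature table / metadata table."""


class IdentifierError(AmplicleanError):
    """Duplicate or inconsistent feature/sample identifiers."""


class ValidationError(AmplicleanError):
    """Counts or metadata violate an invariant (negative, fractional, ...)."""


class MetadataError(AmplicleanError):
    """Sample metadata is missing, inconsistent, or lacks required roles."""


class UndefinedProfileError(AmplicleanError):
    """Relative abundances are undefined (all-zero sample subset)."""


class InsufficientDataError(AmplicleanError):
    """Too few observations for the requested statistical test."""


class SpecError(AmplicleanError):
    """Invalid treatment or run configuration."""
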