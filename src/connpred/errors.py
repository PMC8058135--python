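"""Exception hierarchy used across the package."""


class ConnpredError(Exception):
    """Base class for all package-specific errors."""


class DataError(ConnpredError):
    """Input data contains invalid values (non-finite, wrong type)."""


class AsymmetryError(DataError):
    """Connectivity matrix is asymmetric beyond tolerance."""


class ShapeError(ConnpredError):
    """Array dimensions are inconsistent with the expected layout."""


class FormatError(ConnpredError):
    """A file could not be parsed as any accepted format."""


class InsufficientDataError(ConnpredError):
    """Too few scored subjects to proceed."""


class ConfigError(ConnpredError):
    """Invalid configuration."""


class RankError(ConnpredError):
    """Requested number of components exceeds the retainable rank."""


class DomainError(ConnpredError):
    """Input outside the mathematical domain of the operation."""


class NumericalError(ConnpredError):
    """Numerical failure (divergence, NaN objective)."""


class ModelError(ConnpredError):
    """Model object is missing pieces required by the operation."""
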