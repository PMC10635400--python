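"""Exception hierarchy shared across the package."""


class CsPwsError(Exception):
    """Base class for package-specific errors."""


class ModelConfigError(CsPwsError):
    """A model configuration is internally inconsistent (e.g. a transfer
    window that breaks the monotone sigma-D mapping)."""


class NormalizationError(CsPwsError):
    """Reference spectrum unusable at one or more wavelengths."""


class PlacementError(CsPwsError):
    """Nucleus placement by rejection sampling failed."""


class InsufficientDataError(CsPwsError):
    """Too few observations for the requested statistic."""


class CollinearityError(CsPwsError):
    """Rank-deficient design matrix; carries the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear or degenerate columns: {self.columns}")


class QualityError(CsPwsError):
    """All pixels of a nucleus failed quality checks."""


class ProvenanceWarning(UserWarning):
    """Metadata mismatch between a LUT and the data it is applied to."""
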