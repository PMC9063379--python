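"""Exception hierarchy shared by all pipeline stages."""


class ChlorofuseError(Exception):
    """Base class for all errors raised by this package."""


class InvalidDesignError(ChlorofuseError):
    """Study design with non-positive or inconsistent counts."""


class RenderError(ChlorofuseError):
    """Scene cannot be rendered (e.g. frame too small for the silhouette)."""


class ConfigError(ChlorofuseError):
    """Invalid render or run configuration."""


class DomainError(ChlorofuseError):
    """Pixel values outside the documented domain (e.g. RGB not in [0, 1])."""


class ShapeMismatchError(ChlorofuseError):
    """Arrays that must be aligned have different shapes."""


class EmptyPlantError(ChlorofuseError):
    """A mask expected to contain plant pixels is empty."""


class UnsupportedFormatError(ChlorofuseError):
    """File declares a layout this reader does not support (e.g. non-BIL)."""


class CorruptFileError(ChlorofuseError):
    """Header and payload disagree about the data size."""


class DegenerateFrameError(ChlorofuseError):
    """A band image is constant, so min-max normalization is undefined."""


class UndefinedIndexError(ChlorofuseError):
    """A vegetation index is undefined for the given reflectances."""


class CalibrationError(ChlorofuseError):
    """Threshold calibration cannot proceed (e.g. too few images)."""


class SingularDesignError(ChlorofuseError):
    """Rank-deficient design matrix in a least-squares fit."""


class ZeroVarianceError(ChlorofuseError):
    """A predictor has zero variance and cannot be standardized."""


class DegenerateMetricError(ChlorofuseError):
    """Evaluation metric undefined (constant reference values)."""
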