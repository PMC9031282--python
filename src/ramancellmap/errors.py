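"""Exception types raised across the package."""


class RamanError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RamanError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(RamanError, ValueError):
    """A text file does not conform to the expected dialect.

    The message names the offending record (row index, pixel coordinate or
    header field) so that malformed exports can be located quickly.
    """


class AxisMismatchError(RamanError, ValueError):
    """Two objects that must share a spectral axis do not."""


class PlacementError(RamanError, RuntimeError):
    """Synthetic cells could not be placed on the requested grid."""


class DegenerateNormalizationError(RamanError, ValueError):
    """The normalization window integral is non-positive.

    This signals a background-free or inverted spectrum for which division
    by the buffer-band integral is meaningless.
    """


class ZeroVarianceError(RamanError, ValueError):
    """A matrix with (numerically) zero total variance was passed to PCA."""


class ConstantMapError(RamanError, ValueError):
    """Otsu thresholding was requested on a constant intensity map."""


class StratificationError(RamanError, ValueError):
    """A class would be absent from the training split under stratification."""


class PipelineConfigError(RamanError, ValueError):
    """An end-to-end pipeline configuration is inconsistent."""
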