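"""Exception hierarchy shared across the pipeline."""


class MrSynthCtError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(MrSynthCtError):
    """File is not a scalar 3D volume this package can read."""


class GridMismatchError(MrSynthCtError):
    """Two volumes do not share shape, spacing and origin."""


class PhantomSpecError(MrSynthCtError):
    """Phantom geometry violates a containment constraint."""


class SegmentationFailureError(MrSynthCtError):
    """Segmentation produced an empty or unusable result."""


class ConfigurationError(MrSynthCtError):
    """Incomplete or inconsistent configuration (e.g. missing HU entry)."""


class UndefinedMetricError(MrSynthCtError):
    """Metric undefined for these inputs (e.g. both masks empty)."""


class BinningMismatchError(MrSynthCtError):
    """Histograms do not share bin edges."""


class DegenerateHistogramError(MrSynthCtError):
    """Zero-variance histogram: correlation is undefined."""


class DegenerateNormalizationError(MrSynthCtError):
    """Reference image is constant inside the ROI; dynamic range is zero."""
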