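"""Exception and warning types shared across the package."""


class TorusSegError(Exception):
    """Base class for all torusseg errors."""


class InvalidImageError(TorusSegError, ValueError):
    """Image array violates a structural invariant (channels, range, shape)."""


class InvalidParameterError(TorusSegError, ValueError):
    """A scalar parameter is outside its admissible domain."""


class ImageIOError(TorusSegError, OSError):
    """A raster file could not be read or written; the message names the path."""


class DegenerateLevelError(TorusSegError):
    """A contrast level produced an identically-zero operator and must be skipped."""


class DegenerateHistogramError(TorusSegError):
    """Histogram has fewer than two occupied bins; no threshold separates classes."""


class AllLevelsDegenerateError(TorusSegError):
    """Every contrast level of a sweep was degenerate; segmentation is impossible."""


class UndefinedCorrelationError(TorusSegError, ValueError):
    """Pearson correlation is undefined because an input has zero variance."""


class InvalidSpecError(TorusSegError, ValueError):
    """A phantom specification is inconsistent (e.g. lesion outside the frame)."""


class SaturationWarning(UserWarning):
    """The grayscale image is nearly constant (saturated); results are unreliable."""
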