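"""Exception hierarchy for the inkdose pipeline.

Every stage raises a subclass of :class:`InkdoseError` so drivers can fail
with a stage name attached rather than a bare numpy traceback.
"""


class InkdoseError(Exception):
    """Base class for all package errors."""


class DimensionError(InkdoseError):
    """Axis lengths of two objects that must be aligned disagree."""


class InvalidReferenceError(InkdoseError):
    """White/black reference pair unusable (white ≤ black somewhere)."""


class EmptySelectionError(InkdoseError):
    """A wavelength window or ROI selects nothing."""


class BoundsError(InkdoseError):
    """A region of interest reaches outside the cube."""


class RangeError(InkdoseError):
    """A requested wavelength or band lies outside the grid."""


class DomainError(InkdoseError):
    """Scalar input outside its mathematical domain (e.g. v ≤ 0)."""


class DegenerateProfileError(InkdoseError):
    """Line-scan profile has no peak distinguishable from baseline."""


class NonPhysicalDeconvolutionError(InkdoseError):
    """Reference line wider than the measured response; σ² would go negative."""


class ZeroVarianceError(InkdoseError):
    """SNV requested on a constant spectrum."""


class ConfigError(InkdoseError):
    """Invalid preprocessing or run configuration."""


class LengthError(InkdoseError):
    """Spectrum shorter than the filter window."""


class NoSignalError(InkdoseError):
    """Raman map carries no band intensity to stratify on."""


class AlignmentError(InkdoseError):
    """Response-matrix pixel coordinate not addressable in its cube."""


class RankError(InkdoseError):
    """Requested PLS components exceed the achievable rank."""

    def __init__(self, message: str, achievable_rank: int | None = None):
        super().__init__(message)
        self.achievable_rank = achievable_rank


class IncompatibleModelError(InkdoseError):
    """Cube preprocessing card does not match the model's card."""


class EmptyRegionError(InkdoseError):
    """Dose integration requested over an empty mask."""


class ParseError(InkdoseError):
    """Malformed ENVI header or CSV input."""
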