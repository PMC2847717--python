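"""Exception hierarchy for the radial-positioning pipeline.

Every failure mode of the pipeline raises a subclass of
:class:`RadialPosError`, so callers can catch the package's errors
without masking programming mistakes (plain ``ValueError``/``TypeError``
are still raised for misuse of the API itself).
"""


class RadialPosError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RadialPosError):
    """An image file does not match the requested kind (2D vs 3D)."""


class NoNucleusFound(RadialPosError):
    """DAPI segmentation produced no component above the minimum area."""


class TerritoryCountError(RadialPosError):
    """Fewer probe components than the expected territory count."""


class EmptyMaskError(RadialPosError):
    """A binary mask with no foreground where foreground is required."""


class MaskTooSmall(RadialPosError):
    """Nucleus mask too small to partition into the requested shells."""


class ZeroSignalError(RadialPosError):
    """Total probe intensity inside the nucleus is zero."""


class DegenerateDapiError(RadialPosError):
    """A shell with zero DAPI signal; normalization is undefined."""


class SampleSizeError(RadialPosError):
    """A cohort or group with fewer than two members."""


class ShapeError(RadialPosError):
    """Mismatched shell counts or incongruent grids."""


class DegenerateProfileError(RadialPosError):
    """An all-zero mean profile; the position index is undefined."""


class PointOutsideNucleusError(RadialPosError):
    """A query point that does not lie inside the nucleus mask."""


class EmptyInputError(RadialPosError):
    """An empty list of measurements where at least one is required."""


class GenerationError(RadialPosError):
    """Synthetic-data parameters place a territory outside the nucleus."""
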