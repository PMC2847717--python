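"""Nucleus and territory segmentation, and nuclear morphometrics.

The nucleus is defined by the DAPI counterstain: an automatic global
threshold (Otsu's inter-class-variance criterion) on the DAPI channel,
holes filled, largest connected component kept.  Chromosome territories
are thresholded the same way but restricted to pixels inside the
nucleus, since probe background outside the nucleus is irrelevant to
radial measurements.

Morphometric axes come from the second central moments of the mask
foreground: the full axis length is ``4·sqrt(eigenvalue)`` of the
coordinate covariance, which is exact for a solid ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._welch import welch_ttest
from .errors import EmptyMaskError, NoNucleusFound, SampleSizeError, TerritoryCountError
from .imaging_io import (
    DEFAULT_MIN_AREA_2D,
    DEFAULT_MIN_VOLUME_3D,
    Image2D,
    Stack3D,
    logger,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusMask:
    """A single-nucleus binary mask with inherited physical spacing.

    ``spacing`` is ``(row, col)`` for 2D or ``(z, y, x)`` for 3D, μm per
    pixel/voxel along each axis.
    """

    mask: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if len(self.spacing) != m.ndim:
            raise ValueError("spacing length must match mask dimensionality")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def ndim(self) -> int:
        return self.mask.ndim

    @property
    def pixel_area(self) -> float:
        """Area (2D) or volume (3D) of one pixel/voxel, μm² or μm³."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class Morphometrics:
    """Nuclear size and shape measures, all in physical units.

    area is μm² (2D); axes are full (not semi-) lengths in μm;
    aspect_ratio = major/minor ≥ 1.
    """

    area: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float


@dataclass(frozen=True)
class TestResult:
    """One Welch test: statistic, degrees of freedom, p, significance."""

    t_stat: float
    df: float
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------


def _full_connectivity(ndim: int) -> np.ndarray:
    """8-connectivity in 2D, 26-connectivity in 3D."""
    return ndimage.generate_binary_structure(ndim, ndim)


def _largest_components(binary: np.ndarray, k: int) -> list[np.ndarray]:
    """The ``k`` largest connected components, each as a boolean mask.

    Components of equal size are ordered by first-encountered pixel in
    scan order (the labelling order), which makes the choice
    deterministic.
    """
    labels, n = ndimage.label(binary, structure=_full_connectivity(binary.ndim))
    if n < k:
        return []
    counts = np.bincount(labels.ravel())[1:]  # component sizes, label order
    # stable sort descending by size: ties keep label (scan) order
    order = np.argsort(-counts, kind="stable")[:k] + 1
    return [labels == lab for lab in order]


def _grid_of(image: Image2D | Stack3D) -> tuple[np.ndarray, tuple[float, ...]]:
    if isinstance(image, Image2D):
        return image.pixels, (image.pixel_size, image.pixel_size)
    return image.voxels, image.spacing


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def segment_nucleus(
    dapi: Image2D | Stack3D,
    min_area: float | None = None,
) -> NucleusMask:
    """Segment the nucleus from the DAPI channel.

    Otsu threshold on the full channel histogram, holes filled, largest
    connected component retained.  ``min_area`` is μm² in 2D and μm³ in
    3D (defaults 20 μm² / 100 μm³) and rejects debris.

    Raises
    ------
    NoNucleusFound
        If the image is constant or no component reaches ``min_area``.
    """
    grid, spacing = _grid_of(dapi)
    if min_area is None:
        min_area = DEFAULT_MIN_AREA_2D if grid.ndim == 2 else DEFAULT_MIN_VOLUME_3D
    if grid.size == 0 or grid.max() == grid.min():
        raise NoNucleusFound("constant DAPI image, nothing to threshold")
    thr = threshold_otsu(grid)
    binary = grid > thr
    binary = ndimage.binary_fill_holes(binary)
    components = _largest_components(binary, 1)
    if not components:
        raise NoNucleusFound("threshold produced no foreground")
    mask = components[0]
    pixel_area = float(np.prod(spacing))
    area = mask.sum() * pixel_area
    if area < min_area:
        raise NoNucleusFound(
            f"largest component is {area:.2f} μm^{grid.ndim}, "
            f"below min_area {min_area}"
        )
    return NucleusMask(mask=mask, spacing=spacing)


def segment_territories(
    probe: Image2D | Stack3D,
    nucleus: NucleusMask,
    expected_count: int,
) -> list[np.ndarray]:
    """Segment chromosome territories from the probe channel.

    The automatic threshold is computed from probe intensities inside
    the nucleus only; connected components are labelled and the
    ``expected_count`` largest are returned (one territory for a single
    X in male cells, two for autosome pairs).  Every returned mask is a
    subset of the nucleus mask.

    Raises
    ------
    TerritoryCountError
        If fewer components than ``expected_count`` are found.
    """
    if expected_count not in (1, 2):
        raise ValueError("expected_count must be 1 or 2")
    grid, _ = _grid_of(probe)
    if grid.shape != nucleus.mask.shape:
        raise ValueError("probe and nucleus mask are not congruent")
    inside = grid[nucleus.mask]
    if inside.size == 0:
        raise EmptyMaskError("empty nucleus mask")
    if inside.max() == inside.min():
        raise TerritoryCountError("constant probe signal inside nucleus")
    thr = threshold_otsu(inside)
    binary = (grid > thr) & nucleus.mask
    components = _largest_components(binary, expected_count)
    if len(components) < expected_count:
        raise TerritoryCountError(
            f"expected {expected_count} territories, found fewer"
        )
    return components


def measure_morphometrics(nucleus: NucleusMask) -> Morphometrics:
    """Area and ellipse-equivalent axes of a 2D nucleus mask.

    Axis lengths are ``4·sqrt(eig)`` of the foreground coordinate
    covariance in physical units — for a solid ellipse this returns the
    exact full major/minor axis lengths.

    Raises :class:`EmptyMaskError` on an empty mask.
    """
    if nucleus.ndim != 2:
        raise ValueError("measure_morphometrics expects a 2D mask; "
                         "use morphometrics_max_slice for stacks")
    coords = np.argwhere(nucleus.mask).astype(float)
    if coords.shape[0] == 0:
        raise EmptyMaskError("empty nucleus mask")
    coords *= np.asarray(nucleus.spacing)  # physical coordinates, μm
    area = nucleus.mask.sum() * nucleus.pixel_area
    if coords.shape[0] == 1:
        raise EmptyMaskError("single-pixel mask has no measurable axes")
    cov = np.cov(coords, rowvar=False, bias=True)
    eig = np.sort(np.linalg.eigvalsh(cov))  # ascending
    minor, major = 4.0 * np.sqrt(eig[0]), 4.0 * np.sqrt(eig[1])
    if minor <= 0:
        raise EmptyMaskError("degenerate (collinear) mask has no minor axis")
    return Morphometrics(
        area=float(area),
        major_axis=float(major),
        minor_axis=float(minor),
        aspect_ratio=float(major / minor),
    )


def morphometrics_max_slice(nucleus: NucleusMask) -> Morphometrics:
    """Morphometrics of a 3D nucleus measured on its maximum-area z-slice.

    Flattened fibroblast nuclei are well described by their widest
    optical section; the major/minor axis vocabulary used for 3D
    distance normalization refers to that in-plane ellipse.
    """
    if nucleus.ndim != 3:
        raise ValueError("morphometrics_max_slice expects a 3D mask")
    areas = nucleus.mask.sum(axis=(1, 2))
    if areas.max() == 0:
        raise EmptyMaskError("empty nucleus mask")
    z = int(np.argmax(areas))
    plane = NucleusMask(mask=nucleus.mask[z], spacing=nucleus.spacing[1:])
    return measure_morphometrics(plane)


def compare_morphometrics(
    group_a: list[Morphometrics],
    group_b: list[Morphometrics],
    alpha: float = 0.05,
) -> dict[str, TestResult]:
    """Welch t-test per morphometric measure between two groups of nuclei.

    Used for the control that nuclear shape and size do not differ
    between conditions.  Returns a mapping measure name → test result
    for area, major_axis, minor_axis and aspect_ratio.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise SampleSizeError("each group needs at least two nuclei")
    out: dict[str, TestResult] = {}
    for measure in ("area", "major_axis", "minor_axis", "aspect_ratio"):
        a = [getattr(m, measure) for m in group_a]
        b = [getattr(m, measure) for m in group_b]
        t, df, p = welch_ttest(a, b)
        out[measure] = TestResult(t_stat=t, df=df, p_value=p, significant=p < alpha)
    logger.debug("morphometric comparison: %s", out)
    return out
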