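"""Image and table I/O, shared configuration, and logging.

Images are plain single- or multi-page TIFF files.  Physical pixel/voxel
spacing is always supplied explicitly (CLI flag, config, or function
argument) rather than parsed from vendor metadata: the original
microscopy could come from several acquisition systems and explicit
spacing removes any metadata-dialect ambiguity.

Conventions used throughout the package:

* grids are indexed ``(row, col)`` in 2D and ``(z, y, x)`` in 3D,
  0-based;
* physical coordinates are voxel centers, in micrometers (μm);
* a 2D image carries one isotropic in-plane ``pixel_size``; a 3D stack
  carries a ``(z, y, x)`` spacing triple whose axial component may
  differ from the lateral ones (confocal stacks are anisotropic, the
  default axial step is 0.2 μm);
* result tables are plain :class:`pandas.DataFrame` objects written as
  CSV with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

logger = logging.getLogger("radialpos")

# ---------------------------------------------------------------------------
# Configuration defaults
# ---------------------------------------------------------------------------

#: In-plane pixel size for 2D images, μm/pixel.
DEFAULT_PIXEL_SIZE = 0.2

#: (z, y, x) voxel spacing for confocal stacks, μm.  The axial step of
#: 0.2 μm matches typical optical sectioning of flattened fibroblast
#: nuclei; lateral sampling is finer.
DEFAULT_SPACING = (0.2, 0.1, 0.1)

#: Number of equal-area concentric shells in the erosion analysis.
DEFAULT_N_SHELLS = 5

#: Per-shell significance level for cohort comparisons.
DEFAULT_ALPHA = 0.05

#: Minimum nucleus area (2D, μm²) and volume (3D, μm³) — rejects debris.
DEFAULT_MIN_AREA_2D = 20.0
DEFAULT_MIN_VOLUME_3D = 100.0

#: Bin width for 3D distance frequency distributions, μm.
DEFAULT_BIN_WIDTH = 0.5


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Image2D:
    """A single-channel 2D microscopy image with physical pixel size.

    Parameters
    ----------
    pixels
        Non-negative intensity grid, indexed (row, col).
    pixel_size
        Isotropic in-plane sampling, μm/pixel.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise ValueError(f"Image2D requires a 2D grid, got ndim={pix.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if pix.size and pix.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", pix)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass(frozen=True)
class Stack3D:
    """A single-channel confocal stack with anisotropic voxel spacing.

    ``spacing`` is ``(z, y, x)`` in μm; the axial step is independent of
    the lateral sampling.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"Stack3D requires a 3D grid, got ndim={vox.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive values (z, y, x)")
        if vox.size and vox.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_image(
    path: str | Path,
    kind: str,
    *,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> Image2D | Stack3D:
    """Read a TIFF as a 2D image or a 3D stack.

    ``kind='2d'`` requires exactly one plane; ``kind='3d'`` requires at
    least two.  Intensities are preserved bit-exactly.  Spacing comes
    from the keyword arguments, never from file metadata.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        If the plane count does not match ``kind``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = tifffile.imread(path)
    if kind == "2d":
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
        if data.ndim != 2:
            raise FormatError(
                f"{path}: expected a single-plane TIFF for kind='2d', "
                f"got shape {data.shape}"
            )
        return Image2D(pixels=data, pixel_size=pixel_size)
    if kind == "3d":
        if data.ndim != 3 or data.shape[0] < 2:
            raise FormatError(
                f"{path}: expected a multi-plane TIFF (≥2 planes) for "
                f"kind='3d', got shape {data.shape}"
            )
        return Stack3D(voxels=data, spacing=spacing)
    raise ValueError(f"kind must be '2d' or '3d', got {kind!r}")


def write_image(image: Image2D | Stack3D, path: str | Path) -> None:
    """Write an image or stack as a plain TIFF (lossless for integers)."""
    data = image.pixels if isinstance(image, Image2D) else image.voxels
    # planes are always single-channel grayscale, never RGB components
    tifffile.imwrite(Path(path), np.asarray(data), photometric="minisblack")


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with full float precision.

    Raises
    ------
    OSError
        If the table is empty or the path is unwritable.
    """
    if len(table) == 0:
        raise OSError("refusing to write an empty result table")
    table.to_csv(Path(path), index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a CSV result table written by :func:`write_results`."""
    return pd.read_csv(Path(path), float_precision="round_trip")
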