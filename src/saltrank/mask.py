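"""Vegetation segmentation, mixed-pixel filtering, and cube flattening.

Segmentation is a two-step procedure: (I) a primary mask is the
element-wise conjunction of an NDVI threshold and an excess-green-index
threshold; (II) mixed pixels at leaf edges are purged by binary erosion
with a 3x3 structuring element of ones, i.e. a pixel survives only if it
and all eight of its neighbors pass the primary mask. Out-of-bounds
neighbors count as absent, so image-border pixels never survive.

Surviving pixels are assigned a treatment (control or salt) from the
spatial region they fall in and flattened to a d x n matrix ``X`` whose
columns are pixel spectra, in row-major scan order, with coordinates
retained for lossless back-mapping to the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cube_io import SpectralCube

__all__ = [
    "VegetationMask",
    "PixelMatrix",
    "CONTROL",
    "SALT",
    "ndvi_image",
    "egi_image",
    "primary_mask",
    "filter_mixed_pixels",
    "build_mask",
    "assign_treatment",
    "flatten",
    "unflatten",
]

# label codes used throughout (0 = unlabeled/background)
CONTROL = 1
SALT = 2

# default index band requests (nm); resolved to the nearest kept band
DEFAULT_BLUE_NM = 470.0
DEFAULT_GREEN_NM = 550.0
DEFAULT_RED_NM = 670.0
DEFAULT_NIR_NM = 800.0


@dataclass
class VegetationMask:
    """Primary (index-threshold) and final (eroded) vegetation masks."""

    primary: np.ndarray
    final: np.ndarray
    counts: dict

    def __post_init__(self) -> None:
        if np.any(self.final & ~self.primary):
            raise ValueError("final mask must be a subset of the primary mask")


@dataclass
class PixelMatrix:
    """Masked vegetation pixels as a d x n matrix of column spectra.

    ``labels`` holds CONTROL/SALT per column; ``coords`` the (row, col)
    source pixel of each column, inverting the flattening exactly.
    """

    X: np.ndarray
    labels: np.ndarray
    coords: np.ndarray
    band_centers: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (bands x pixels)")
        if len(self.labels) != self.X.shape[1] or len(self.coords) != self.X.shape[1]:
            raise ValueError("labels/coords length must equal the number of columns")

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def n_control(self) -> int:
        return int(np.sum(self.labels == CONTROL))

    @property
    def n_salt(self) -> int:
        return int(np.sum(self.labels == SALT))

    def class_matrix(self, label: int) -> np.ndarray:
        """Columns of ``X`` belonging to one treatment class."""
        return self.X[:, self.labels == label]


def _band_image(cube: SpectralCube, nm: float) -> np.ndarray:
    return cube.values[:, :, cube.nearest_band(nm)]


def ndvi_image(cube: SpectralCube, red_nm: float = DEFAULT_RED_NM,
               nir_nm: float = DEFAULT_NIR_NM) -> np.ndarray:
    """Normalized difference vegetation index, (NIR - Red)/(NIR + Red).

    Pixels with a zero denominator map to 0 by convention.
    """
    red = _band_image(cube, red_nm)
    nir = _band_image(cube, nir_nm)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (nir - red) / np.where(denom == 0, 1, denom), 0.0)
    return out


def egi_image(cube: SpectralCube, blue_nm: float = DEFAULT_BLUE_NM,
              green_nm: float = DEFAULT_GREEN_NM,
              red_nm: float = DEFAULT_RED_NM) -> np.ndarray:
    """Excess green index, 2*Green - Red - Blue."""
    return (2.0 * _band_image(cube, green_nm)
            - _band_image(cube, red_nm) - _band_image(cube, blue_nm))


def primary_mask(ndvi_img: np.ndarray, egi_img: np.ndarray,
                 t_ndvi: float = 0.5, t_egi: float = 0.05) -> np.ndarray:
    """Conjunction of the two index thresholds (strict inequalities)."""
    if ndvi_img.shape != egi_img.shape:
        raise ValueError("index images must share a shape")
    return (ndvi_img > t_ndvi) & (egi_img > t_egi)


def filter_mixed_pixels(mask: np.ndarray) -> np.ndarray:
    """Binary erosion by a 3x3 ones element (single pass).

    A pixel is kept iff it and all 8 neighbors are True; neighbors
    outside the image count as False, so border pixels are removed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool),
                                  border_value=0)


def build_mask(cube: SpectralCube, t_ndvi: float = 0.5, t_egi: float = 0.05,
               blue_nm: float = DEFAULT_BLUE_NM, green_nm: float = DEFAULT_GREEN_NM,
               red_nm: float = DEFAULT_RED_NM,
               nir_nm: float = DEFAULT_NIR_NM) -> VegetationMask:
    """Run both segmentation steps and record stage pixel counts."""
    primary = primary_mask(ndvi_image(cube, red_nm, nir_nm),
                           egi_image(cube, blue_nm, green_nm, red_nm),
                           t_ndvi, t_egi)
    final = filter_mixed_pixels(primary)
    counts = {
        "primary": int(primary.sum()),
        "final": int(final.sum()),
        "eroded": int(primary.sum() - final.sum()),
    }
    return VegetationMask(primary, final, counts)


def _rects_overlap(a, b) -> bool:
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    return ar0 < br1 and br0 < ar1 and ac0 < bc1 and bc0 < ac1


def assign_treatment(mask: np.ndarray, control_region, salt_region):
    """Label masked pixels by the treatment rectangle they fall in.

    Rectangles are half-open ``(r0, c0, r1, c1)`` and must be disjoint.
    Masked pixels outside both rectangles are dropped; the count is
    returned so the pipeline can account for every pixel.

    Returns
    -------
    labels : int ndarray, 0 outside the mask / dropped, else CONTROL or SALT
    dropped : int, masked pixels in neither region
    """
    if _rects_overlap(control_region, salt_region):
        raise ValueError("control and salt regions overlap")
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int8)
    for rect, lab in ((control_region, CONTROL), (salt_region, SALT)):
        r0, c0, r1, c1 = rect
        region = np.zeros(mask.shape, dtype=bool)
        region[r0:r1, c0:c1] = True
        labels[mask & region] = lab
    dropped = int((mask & (labels == 0)).sum())
    return labels, dropped


def flatten(cube: SpectralCube, labels: np.ndarray) -> PixelMatrix:
    """Flatten labeled pixels to a PixelMatrix in row-major scan order."""
    if labels.shape != cube.values.shape[:2]:
        raise ValueError("label grid and cube spatial shapes differ")
    rows, cols = np.nonzero(labels > 0)  # nonzero scans row-major
    if len(rows) == 0:
        raise ValueError("empty mask: no labeled vegetation pixels")
    X = cube.values[rows, cols, :].T.copy()
    return PixelMatrix(
        X=X,
        labels=labels[rows, cols].astype(np.int8),
        coords=np.column_stack([rows, cols]),
        band_centers=cube.band_centers.copy(),
    )


def unflatten(pm: PixelMatrix, shape: tuple[int, int]) -> np.ndarray:
    """Scatter the matrix back to a (rows, cols, d) cube of NaN background."""
    out = np.full((*shape, pm.d), np.nan)
    out[pm.coords[:, 0], pm.coords[:, 1], :] = pm.X.T
    return out
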