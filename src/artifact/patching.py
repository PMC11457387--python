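"""Pre-processing of whole-slide images: foreground, grid, labels, patches.

A slide is reduced to its tissue foreground by Otsu thresholding on the HSV
value channel of a low-resolution thumbnail (tissue is darker than the white
slide background), a uniform non-overlapping patch grid is laid over the
foreground, and each grid cell can be labeled against per-class annotation
masks with the 70%-overlap rule: a patch whose window overlaps an artifact
mask on at least 70% of its area inherits that artifact's class, everything
else is artifact-free.

Coordinates are (x, y) = (column, row), 0-based, with half-open windows
``[x, x+s) x [y, y+s)`` at level 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .synthetic import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "WSIRef",
    "ForegroundMask",
    "PatchCoord",
    "LabeledPatch",
    "extract_foreground",
    "sample_grid",
    "label_patch",
    "extract_patches",
]


class WSIRef:
    """Reference to a slide: a file path (TIFF/PNG) or an in-memory RGB array.

    At desk scale the full level-0 image is held in memory; ``read_region``
    crops from it, which keeps patch extraction constant-memory in the number
    of patches.
    """

    def __init__(self, image: np.ndarray, source: str | None = None, mpp: float | None = None):
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError(f"expected an RGB (h, w, 3) image, got shape {image.shape}")
        self._image = image
        self.source = source
        self.mpp = mpp  # microns per pixel, optional metadata

    @classmethod
    def from_path(cls, path) -> "WSIRef":
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            img = tifffile.imread(path)
            if img.ndim == 3 and img.shape[0] in (3, 4) and img.shape[2] not in (3, 4):
                img = np.moveaxis(img, 0, -1)
            img = img[..., :3]
        else:
            img = np.asarray(Image.open(path).convert("RGB"))
        return cls(img, source=str(path))

    @property
    def width(self) -> int:  # m: level-0 columns
        return self._image.shape[1]

    @property
    def height(self) -> int:  # n: level-0 rows
        return self._image.shape[0]

    def thumbnail(self, downsample: int) -> np.ndarray:
        """Block-subsampled RGB thumbnail at the given integer downsample."""
        if downsample < 1:
            raise ValueError("downsample must be >= 1")
        return self._image[::downsample, ::downsample]

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
            raise IOError(f"region (x={x}, y={y}, w={w}, h={h}) outside slide bounds")
        return np.ascontiguousarray(self._image[y : y + h, x : x + w])


@dataclass(frozen=True)
class ForegroundMask:
    """Binary tissue mask at an integer downsample factor."""

    mask: np.ndarray  # (ceil(n/d), ceil(m/d)), values {0, 1}
    downsample: int

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True, order=True)
class PatchCoord:
    """Top-left corner of an s x s window on the uniform level-0 grid."""

    x: int
    y: int
    s: int

    def __post_init__(self):
        if self.x < 0 or self.y < 0 or self.s <= 0:
            raise ValueError(f"invalid patch coordinate {self}")
        if self.x % self.s or self.y % self.s:
            raise ValueError(f"({self.x}, {self.y}) not on the stride-{self.s} grid")


@dataclass
class LabeledPatch:
    image: np.ndarray  # (s, s, 3) uint8
    coord: PatchCoord
    label: int | None = None


def extract_foreground(wsi: WSIRef, downsample: int = 32) -> ForegroundMask:
    """Otsu threshold on the HSV value channel of a thumbnail.

    Foreground is the side of the split *below* the threshold (tissue is
    darker than the white background).  A uniform value channel yields an
    empty foreground with a warning.
    """
    thumb = wsi.thumbnail(downsample)
    if thumb.shape[0] < 2 or thumb.shape[1] < 2:
        raise ValueError(f"thumbnail at downsample {downsample} is smaller than 2x2")
    value = rgb2hsv(thumb)[..., 2]
    if np.ptp(value) < 1e-12:
        warnings.warn("uniform value channel; returning empty foreground", stacklevel=2)
        return ForegroundMask(np.zeros(value.shape, dtype=np.uint8), downsample)
    t = threshold_otsu(value)
    return ForegroundMask((value < t).astype(np.uint8), downsample)


def _coverage(mask: ForegroundMask, x: int, y: int, s: int) -> float:
    """Tissue area fraction of window [x, x+s) x [y, y+s), measured on the
    downsampled mask with fractional (area-weighted) border pixels."""
    d = mask.downsample
    m = mask.mask
    x0, x1 = x / d, (x + s) / d
    y0, y1 = y / d, (y + s) / d
    ia0, ia1 = int(np.floor(y0)), int(np.ceil(y1))
    ja0, ja1 = int(np.floor(x0)), int(np.ceil(x1))
    ia1, ja1 = min(ia1, m.shape[0]), min(ja1, m.shape[1])
    if ia0 >= ia1 or ja0 >= ja1:
        return 0.0
    block = m[ia0:ia1, ja0:ja1].astype(float)
    wy = np.clip(np.minimum(np.arange(ia0, ia1) + 1, y1) - np.maximum(np.arange(ia0, ia1), y0), 0, 1)
    wx = np.clip(np.minimum(np.arange(ja0, ja1) + 1, x1) - np.maximum(np.arange(ja0, ja1), x0), 0, 1)
    covered = float((block * wy[:, None] * wx[None, :]).sum())
    return covered / ((s / d) ** 2)


def sample_grid(
    mask: ForegroundMask, wsi: WSIRef, s: int = 224, min_tissue: float = 0.1
) -> list[PatchCoord]:
    """Row-major coordinates of every full grid cell with tissue coverage
    >= ``min_tissue``.  Edge cells not fully inside the slide are dropped."""
    if s <= 0:
        raise ValueError("patch size must be positive")
    if not 0.0 <= min_tissue <= 1.0:
        raise ValueError("min_tissue must be in [0, 1]")
    coords = []
    for y in range(0, wsi.height - s + 1, s):
        for x in range(0, wsi.width - s + 1, s):
            if _coverage(mask, x, y, s) >= min_tissue:
                coords.append(PatchCoord(x, y, s))
    return coords


def label_patch(coord: PatchCoord, gt: GroundTruth, overlap_threshold: float = 0.70) -> int:
    """Class of the patch window under the overlap rule.

    For each artifact class the overlap fraction is (mask pixels inside the
    window) / s^2; if the maximum overlap is >= ``overlap_threshold``
    (inclusive) the patch takes that artifact class (ties: lowest class code),
    otherwise it is artifact-free (0).
    """
    x, y, s = coord.x, coord.y, coord.s
    ref = gt.tissue_mask if gt.tissue_mask is not None else next(iter(gt.masks.values()))
    if y + s > ref.shape[0] or x + s > ref.shape[1]:
        raise ValueError(f"patch window {coord} outside mask bounds {ref.shape}")
    best_k, best_frac = 0, 0.0
    for k in sorted(gt.masks):
        frac = float(gt.masks[k][y : y + s, x : x + s].sum()) / (s * s)
        if frac > best_frac:  # strict: ties keep the lowest class code
            best_k, best_frac = k, frac
    return best_k if best_frac >= overlap_threshold else 0


def extract_patches(wsi: WSIRef, coords, labels=None):
    """Stream ``LabeledPatch`` objects for the given coordinates (lazily)."""
    if labels is None:
        labels = [None] * len(coords)
    for coord, label in zip(coords, labels):
        image = wsi.read_region(coord.x, coord.y, coord.s, coord.s)
        yield LabeledPatch(image=image, coord=coord, label=label)
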