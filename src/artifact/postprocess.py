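"""Post-processing of per-patch predictions into the four slide-level outputs.

Matrix filling turns the per-patch labels into a segmentation map with one
cell per grid position ("every filled box is a pixel" of a stride-downscaled
map); the map yields a quality-control report of per-class percentages and an
artifact-free fraction rho compared against a usability threshold tau; the
zero-class cells, after morphological closing, form the artifact-free RoI
mask; and the mask, upsampled with nearest-neighbor interpolation, multiplies
the slide (Hadamard product) into an artifact-refined image.

Cells that were never predicted (outside the tissue foreground) carry the
background sentinel -1 and are excluded from every report statistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import closing as _morph_closing

logger = logging.getLogger(__name__)

BACKGROUND = -1

#: display palette, class code -> RGB
PALETTE = {
    BACKGROUND: (255, 255, 255),
    0: (180, 220, 180),  # artifact-free: light green
    1: (200, 40, 50),    # blood: red
    2: (90, 140, 230),   # blur: blue
    3: (240, 200, 60),   # air bubble: yellow
    4: (150, 150, 150),  # damaged: gray
    5: (140, 60, 160),   # folded: purple
}

__all__ = [
    "BACKGROUND",
    "PALETTE",
    "SegmentationMap",
    "QCReport",
    "RoIMask",
    "build_segmentation_map",
    "artifact_report",
    "roi_mask",
    "refine_wsi",
]


@dataclass
class SegmentationMap:
    """Per-patch class grid; shape (ceil(n/s), ceil(m/s)) for an m x n slide."""

    grid: np.ndarray  # int, values in {-1, 0..5}
    s: int
    palette: dict = field(default_factory=lambda: dict(PALETTE))

    @property
    def n_evaluated(self) -> int:
        return int(np.sum(self.grid != BACKGROUND))

    def class_counts(self) -> dict:
        return {k: int(np.sum(self.grid == k)) for k in range(6)}

    def to_rgb(self) -> np.ndarray:
        """Render the grid with the display palette (one pixel per cell)."""
        out = np.zeros((*self.grid.shape, 3), dtype=np.uint8)
        for k, color in self.palette.items():
            out[self.grid == k] = color
        return out


@dataclass
class QCReport:
    """Per-class percentages, artifact-free fraction rho, and the accept /
    discard decision against the usability threshold tau."""

    counts: dict
    n_total: int
    percentages: dict
    rho: float
    tau: float
    decision: str

    def to_dict(self) -> dict:
        return {
            "counts": {str(k): v for k, v in self.counts.items()},
            "n_total": self.n_total,
            "percentages": {str(k): v for k, v in self.percentages.items()},
            "rho": self.rho,
            "tau": self.tau,
            "decision": self.decision,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class RoIMask:
    grid: np.ndarray  # {0, 1}, same shape as the segmentation grid
    closing_radius: int
    s: int


def build_segmentation_map(predictions, wsi_dims, s: int) -> SegmentationMap:
    """Fill the patch grid from ``(PatchCoord, class)`` pairs.

    ``wsi_dims`` is (m, n) = (width, height) at level 0.  Unvisited cells stay
    at the background sentinel; duplicate coordinates are last-write-wins with
    a logged warning.
    """
    m, n = wsi_dims
    rows = -(-n // s)
    cols = -(-m // s)
    grid = np.full((rows, cols), BACKGROUND, dtype=np.int16)
    seen = set()
    for coord, k in predictions:
        if coord.s != s or coord.x % s or coord.y % s:
            raise ValueError(f"coordinate {coord} not on the stride-{s} grid")
        r, c = coord.y // s, coord.x // s
        if r >= rows or c >= cols:
            raise ValueError(f"coordinate {coord} outside the {rows}x{cols} grid")
        if (r, c) in seen:
            logger.warning("duplicate prediction at cell (%d, %d); keeping the last", r, c)
        seen.add((r, c))
        grid[r, c] = k
    return SegmentationMap(grid=grid, s=s)


def artifact_report(seg: SegmentationMap, tau: float = 0.5) -> QCReport:
    """Per-class percentages Per_k = N_k / N_tot * 100 over evaluated cells,
    rho = N_0 / N_tot, and the decision accept iff rho >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    counts = seg.class_counts()
    n_tot = seg.n_evaluated
    if n_tot == 0:
        logger.warning("no evaluated cells; reporting an empty (discard) QC report")
        percentages = {k: 0.0 for k in counts}
        rho = 0.0
    else:
        percentages = {k: 100.0 * v / n_tot for k, v in counts.items()}
        rho = counts[0] / n_tot
    return QCReport(
        counts=counts,
        n_total=n_tot,
        percentages=percentages,
        rho=rho,
        tau=tau,
        decision="accept" if n_tot > 0 and rho >= tau else "discard",
    )


def roi_mask(seg: SegmentationMap, closing_radius: int = 1) -> RoIMask:
    """Binarize the map (1 iff artifact-free; sentinel -> 0), then close the
    artifact-free regions with a square structuring element of side
    ``2 * closing_radius + 1`` to remove small holes."""
    if closing_radius < 0:
        raise ValueError("closing radius must be non-negative")
    binary = (seg.grid == 0).astype(np.uint8)
    if closing_radius > 0:
        side = 2 * closing_radius + 1
        # mode="ignore": cells outside the grid never carve the closing result
        binary = _morph_closing(
            binary.astype(bool), footprint=np.ones((side, side)), mode="ignore"
        ).astype(np.uint8)
    return RoIMask(grid=binary, closing_radius=closing_radius, s=seg.s)


def refine_wsi(image: np.ndarray, roi: RoIMask, fill: int = 0) -> np.ndarray:
    """Hadamard product of the slide with the nearest-neighbor-upsampled RoI.

    Retained pixels are bit-identical to the input; masked-out pixels take
    ``fill`` (0 = black by default, 255 for a white background).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    s = roi.s
    rows = (np.arange(h) // s).clip(max=roi.grid.shape[0] - 1)
    cols = (np.arange(w) // s).clip(max=roi.grid.shape[1] - 1)
    if (h + s - 1) // s != roi.grid.shape[0] or (w + s - 1) // s != roi.grid.shape[1]:
        raise RuntimeError(
            f"RoI grid {roi.grid.shape} inconsistent with image {(h, w)} at stride {s}"
        )
    mask = roi.grid[rows[:, None], cols[None, :]].astype(bool)
    out = np.full_like(image, fill)
    out[mask] = image[mask]
    return out
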