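"""Synthetic H&E-like fixtures: patches, labeled datasets and composite slides.

Procedural textures stand in for the six patch classes used throughout the
pipeline (0 artifact-free tissue, 1 blood, 2 blur, 3 air bubble, 4 damaged
tissue, 5 folded tissue).  The textures make no attempt at biological realism;
they are built to be deterministic, cheap, and separable enough that a small
classifier can tell the classes apart, so every downstream module (foreground
extraction, grid labeling, expert training, post-processing) can be exercised
without any external slide data.

Conventions
-----------
* Background is pure white (255, 255, 255), matching the white slide
  background assumed by Otsu foreground extraction.
* All generators are pure functions of their arguments, including the seed.
* Class 2 (blur) is literally a low-pass-filtered rendering of the class-0
  texture for the same seed, slightly washed out, so gradient-based sanity
  checks have a known ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, ellipse

CLASS_NAMES = {
    0: "artifact_free",
    1: "blood",
    2: "blur",
    3: "air_bubble",
    4: "damaged",
    5: "folded",
}
ARTIFACT_CLASSES = (1, 2, 3, 4, 5)

__all__ = [
    "CLASS_NAMES",
    "ARTIFACT_CLASSES",
    "SyntheticWSISpec",
    "GroundTruth",
    "PatchSet",
    "generate_patch",
    "generate_wsi",
    "build_patch_dataset",
    "export_dataset",
]


# ---------------------------------------------------------------------------
# texture primitives
# ---------------------------------------------------------------------------

def _rng(*key) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _smooth_field(rng, h, w, sigma):
    """Smoothed noise field rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma)
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros((h, w))
    return (f - lo) / (hi - lo)


def _tissue(h, w, seed) -> np.ndarray:
    """Pink eosin field with purple nuclei-like ellipses; float in [0, 255]."""
    rng = _rng(7151, seed, h, w)
    t = _smooth_field(rng, h, w, sigma=8)
    # darker eosin palette keeps the HSV value channel bimodal against the
    # white slide background, as Otsu foreground extraction expects
    pink = np.array([208.0, 140.0, 178.0])
    deep = np.array([158.0, 84.0, 132.0])
    img = pink[None, None, :] * (1 - t[..., None]) + deep[None, None, :] * t[..., None]
    # nuclei: small dark-purple ellipses scattered over the field
    n_nuclei = max(4, (h * w) // 2500)
    purple = np.array([96.0, 48.0, 138.0])
    for _ in range(n_nuclei):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        ry, rx = rng.integers(2, 6), rng.integers(2, 6)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rng.uniform(0, np.pi))
        shade = rng.uniform(0.75, 1.05)
        img[rr, cc] = purple * shade
    img += rng.normal(0.0, 4.0, size=(h, w, 3))
    return np.clip(img, 0, 255)


def _blood(h, w, seed):
    rng = _rng(1, seed, h, w)
    t = _smooth_field(rng, h, w, sigma=6)
    bright = np.array([208.0, 48.0, 58.0])
    dark = np.array([142.0, 18.0, 32.0])
    img = bright[None, None, :] * (1 - t[..., None]) + dark[None, None, :] * t[..., None]
    for _ in range(max(2, (h * w) // 8000)):  # dense erythrocyte-like blobs
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.integers(3, max(4, min(h, w) // 12))
        rr, cc = disk((cy, cx), r, shape=(h, w))
        img[rr, cc] = dark * rng.uniform(0.85, 1.1)
    img += rng.normal(0.0, 5.0, size=(h, w, 3))
    return np.clip(img, 0, 255)


def _blur(h, w, seed):
    base = _tissue(h, w, seed)
    soft = gaussian_filter(base, sigma=(6, 6, 0))
    washout = np.array([250.0, 244.0, 248.0])
    return np.clip(0.72 * soft + 0.28 * washout[None, None, :], 0, 255)


def _air_bubble(h, w, seed):
    rng = _rng(3, seed, h, w)
    pale = np.array([243.0, 236.0, 240.0])
    img = pale[None, None, :] + rng.normal(0.0, 3.0, size=(h, w, 3))
    # bright ring with a dark outer edge, jittered around the patch center
    cy = h / 2 + rng.uniform(-h / 10, h / 10)
    cx = w / 2 + rng.uniform(-w / 10, w / 10)
    r = 0.42 * min(h, w) * rng.uniform(0.85, 1.05)
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - cy, xx - cx)
    band = max(2.0, 0.02 * min(h, w))
    img[np.abs(d - r) <= band] = [254.0, 252.0, 253.0]
    img[np.abs(d - (r + 1.8 * band)) <= 0.8 * band] = [88.0, 80.0, 90.0]
    return np.clip(img, 0, 255)


def _damaged(h, w, seed):
    rng = _rng(4, seed, h, w)
    base = _tissue(h, w, seed)
    gray = base.mean(axis=2, keepdims=True)
    img = 0.85 * np.repeat(gray, 3, axis=2) + 30.0  # desaturated, lifted
    tears = _smooth_field(rng, h, w, sigma=5) > 0.62  # fragmented voids
    img[tears] = [241.0, 239.0, 241.0]
    img += rng.normal(0.0, 4.0, size=(h, w, 3))
    return np.clip(img, 0, 255)


def _folded(h, w, seed):
    rng = _rng(5, seed, h, w)
    img = _tissue(h, w, seed) * 0.62  # globally darker than clean tissue
    # dark, high-contrast diagonal band where the tissue doubled over
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    axis = (xx - w / 2) * np.cos(theta) + (yy - h / 2) * np.sin(theta)
    half_width = 0.16 * min(h, w) * rng.uniform(0.8, 1.3)
    band = np.abs(axis - rng.uniform(-w / 8, w / 8)) <= half_width
    fold_color = np.array([52.0, 22.0, 66.0])
    stripes = 1.0 + 0.35 * np.sin(axis / 3.0)
    img[band] = np.clip(fold_color[None, :] * stripes[band, None], 0, 255)
    img += rng.normal(0.0, 4.0, size=(h, w, 3))
    return np.clip(img, 0, 255)


_RENDERERS = {0: _tissue, 1: _blood, 2: _blur, 3: _air_bubble, 4: _damaged, 5: _folded}


def _render(class_code, h, w, seed) -> np.ndarray:
    return _RENDERERS[class_code](h, w, seed)


def generate_patch(class_code: int, seed: int, size: int = 224) -> np.ndarray:
    """Render one synthetic patch as an (size, size, 3) uint8 RGB array.

    Deterministic for fixed ``(class_code, seed, size)``.
    """
    if class_code not in _RENDERERS:
        raise ValueError(f"class_code must be in 0..5, got {class_code}")
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    return _render(class_code, size, size, seed).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# composite slides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticWSISpec:
    """Recipe for a composite synthetic slide.

    ``regions`` is a list of ``(class_code, x, y, w, h)`` rectangles in level-0
    pixels; ``tissue_fraction`` is the fraction of the canvas covered by the
    (centered, rectangular) tissue region.
    """

    width: int
    height: int
    regions: tuple = ()
    base_texture_seed: int = 0
    tissue_fraction: float = 0.5

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if not 0.0 < self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must be in (0, 1]")
        for k, x, y, w, h in self.regions:
            if k not in ARTIFACT_CLASSES:
                raise ValueError(f"region class_code must be in 1..5, got {k}")
            if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
                raise ValueError(f"region {(k, x, y, w, h)} outside image bounds")


@dataclass
class GroundTruth:
    """Per-class binary masks registered to level-0 pixels.

    Overlapping class masks are allowed; precedence is resolved at labeling
    time.  ``tissue_mask`` defines foreground; everything else is background.
    """

    masks: dict = field(default_factory=dict)
    tissue_mask: np.ndarray | None = None

    def single_label_map(self) -> np.ndarray:
        """Rasterize to one label per pixel; higher class code wins overlaps."""
        shape = self.tissue_mask.shape
        out = np.zeros(shape, dtype=np.int16)
        for k in sorted(self.masks):
            out[self.masks[k] > 0] = k
        return out


def _tissue_rect(spec: SyntheticWSISpec):
    """Centered rectangle with area ~= tissue_fraction of the canvas."""
    tw = int(round(spec.width * np.sqrt(spec.tissue_fraction)))
    th = int(round(spec.height * np.sqrt(spec.tissue_fraction)))
    tw, th = min(tw, spec.width), min(th, spec.height)
    x0 = (spec.width - tw) // 2
    y0 = (spec.height - th) // 2
    return x0, y0, tw, th


def generate_wsi(spec: SyntheticWSISpec):
    """Render a composite slide and its ground truth.

    Returns ``(image, gt)`` where ``image`` is (height, width, 3) uint8 with a
    white background, a class-0 tissue rectangle, and each artifact region
    painted over it; ``gt.masks[k]`` equals the painted rectangles of class k
    intersected with the tissue region.
    """
    h, w = spec.height, spec.width
    image = np.full((h, w, 3), 255, dtype=np.uint8)
    x0, y0, tw, th = _tissue_rect(spec)
    tissue = np.zeros((h, w), dtype=np.uint8)
    tissue[y0 : y0 + th, x0 : x0 + tw] = 1
    image[y0 : y0 + th, x0 : x0 + tw] = (
        _render(0, th, tw, spec.base_texture_seed).round().astype(np.uint8)
    )
    masks = {k: np.zeros((h, w), dtype=np.uint8) for k in ARTIFACT_CLASSES}
    for idx, (k, rx, ry, rw, rh) in enumerate(spec.regions):
        tex = _render(k, rh, rw, spec.base_texture_seed * 1000 + idx)
        image[ry : ry + rh, rx : rx + rw] = tex.round().astype(np.uint8)
        masks[k][ry : ry + rh, rx : rx + rw] = 1
    for k in masks:
        masks[k] &= tissue
    return image, GroundTruth(masks=masks, tissue_mask=tissue)


# ---------------------------------------------------------------------------
# labeled patch datasets
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """One split of a labeled patch dataset."""

    images: np.ndarray  # (N, s, s, 3) uint8
    labels: np.ndarray  # (N,) int
    seeds: np.ndarray  # (N,) int, per-patch generator seed

    def __len__(self):
        return len(self.labels)


def build_patch_dataset(
    counts: dict,
    seed: int = 0,
    split_fractions=(0.8, 0.1, 0.1),
    size: int = 224,
) -> dict:
    """Generate disjoint train/val/test splits with the requested class counts.

    ``counts`` maps class_code -> number of patches.  Splits are per-class:
    val and test sizes are floored, the remainder goes to train.  Deterministic
    in ``seed``.
    """
    if any(n < 0 for n in counts.values()):
        raise ValueError("patch counts must be non-negative")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = _rng(9000, seed)
    splits = {name: {"images": [], "labels": [], "seeds": []} for name in ("train", "val", "test")}
    for k in sorted(counts):
        n = counts[k]
        patch_seeds = rng.integers(0, 2**31 - 1, size=n)
        n_val = int(n * split_fractions[1])
        n_test = int(n * split_fractions[2])
        n_train = n - n_val - n_test
        bounds = {"train": (0, n_train), "val": (n_train, n_train + n_val), "test": (n_train + n_val, n)}
        for name, (a, b) in bounds.items():
            for s in patch_seeds[a:b]:
                splits[name]["images"].append(generate_patch(k, int(s), size))
                splits[name]["labels"].append(k)
                splits[name]["seeds"].append(int(s))
    out = {}
    for name, d in splits.items():
        images = (
            np.stack(d["images"]) if d["images"] else np.empty((0, size, size, 3), np.uint8)
        )
        out[name] = PatchSet(
            images=images,
            labels=np.asarray(d["labels"], dtype=np.int64),
            seeds=np.asarray(d["seeds"], dtype=np.int64),
        )
    return out


def export_dataset(dataset: dict, out_dir) -> Path:
    """Write a dataset to a directory-per-class layout plus a JSON manifest.

    Layout: ``<out>/<split>/<class_name>/patch_<seed>.png``.  Returns the
    manifest path.
    """
    out_dir = Path(out_dir)
    records = []
    for split, ps in dataset.items():
        for img, label, s in zip(ps.images, ps.labels, ps.seeds):
            cls_dir = out_dir / split / CLASS_NAMES[int(label)]
            cls_dir.mkdir(parents=True, exist_ok=True)
            path = cls_dir / f"patch_{int(s):010d}.png"
            Image.fromarray(img).save(path)
            records.append(
                {
                    "path": str(path.relative_to(out_dir)),
                    "class": int(label),
                    "split": split,
                    "seed": int(s),
                }
            )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(records, indent=1, sort_keys=True))
    return manifest
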