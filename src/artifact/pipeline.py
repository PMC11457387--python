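"""End-to-end orchestration: pre-processing -> inference -> post-processing.

``run_pipeline`` takes a slide and either an :class:`~artifact.moe.ExpertBundle`
(MoE pipeline) or a six-class model (multiclass pipeline), and produces the
four slide-level outputs plus a per-patch prediction table, all written to an
output directory together with a run manifest.  Re-running with an identical
configuration reproduces bit-identical outputs.

``OracleExpert`` is a test double that answers from ground truth instead of a
trained network, optionally corrupted by patch-level label noise; it lets the
whole pipeline be verified against known synthetic slides.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .moe import ExpertBundle, predict_multiclass
from .patching import WSIRef, extract_foreground, extract_patches, label_patch, sample_grid
from .postprocess import (
    artifact_report,
    build_segmentation_map,
    refine_wsi,
    roi_mask,
)
from .synthetic import ARTIFACT_CLASSES, GroundTruth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "OracleExpert", "make_oracle_bundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    pipeline: str = "moe"  # or "multiclass"
    patch_size: int = 224
    t_s: float | None = None  # override; default = bundle's learned threshold
    tau: float = 0.5
    closing_radius: int = 1
    fill: int = 0
    foreground_downsample: int = 32
    min_tissue: float = 0.1
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.pipeline not in ("moe", "multiclass"):
            raise ValueError("pipeline must be 'moe' or 'multiclass'")
        if self.t_s is not None and not 0.0 <= self.t_s <= 1.0:
            raise ValueError("t_s must be in [0, 1]")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if self.patch_size <= 0:
            raise ValueError("patch size must be positive")


@dataclass
class PipelineResult:
    segmentation: object
    report: object
    roi: object
    refined: np.ndarray
    patch_table: pd.DataFrame
    out_dir: Path | None = None


class OracleExpert:
    """Expert that reads ground truth: artifact probability 1 inside its
    class's annotated regions (under the overlap rule), else 0."""

    def __init__(self, class_code: int, gt: GroundTruth, overlap_threshold: float = 0.70):
        self.class_code = class_code
        self.gt = gt
        self.overlap_threshold = overlap_threshold

    def artifact_proba(self, images, coords=None) -> np.ndarray:
        if coords is None:
            raise ValueError("OracleExpert needs patch coordinates")
        mask = self.gt.masks[self.class_code]
        out = np.zeros(len(coords))
        for i, c in enumerate(coords):
            frac = float(mask[c.y : c.y + c.s, c.x : c.x + c.s].sum()) / (c.s * c.s)
            out[i] = 1.0 if frac >= self.overlap_threshold else 0.0
        return out


class _CorruptedBundle(ExpertBundle):
    """Oracle bundle whose per-patch prediction is flipped to a random other
    class for a fraction of patches (patch-level label noise)."""

    def __init__(self, experts, t_s, noise_rate, seed):
        super().__init__(experts=experts, t_s=t_s)
        self.noise_rate = noise_rate
        self.seed = seed

    def predict(self, images, coords=None):
        labels, p_afree = super().predict(images, coords)
        rng = np.random.default_rng([4242, self.seed])
        flip = rng.random(len(labels)) < self.noise_rate
        for i in np.where(flip)[0]:
            others = [c for c in range(6) if c != labels[i]]
            labels[i] = rng.choice(others)
        return labels, p_afree


def make_oracle_bundle(
    gt: GroundTruth,
    t_s: float = 0.5,
    overlap_threshold: float = 0.70,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> ExpertBundle:
    """Bundle of five ground-truth oracle experts, optionally noisy."""
    experts = {k: OracleExpert(k, gt, overlap_threshold) for k in ARTIFACT_CLASSES}
    if noise_rate > 0:
        return _CorruptedBundle(experts, t_s, noise_rate, seed)
    return ExpertBundle(experts=experts, t_s=t_s)


def _predict_batches(wsi, coords, cfg, bundle=None, model=None):
    """Stream patches in batches through the configured predictor."""
    labels = np.empty(len(coords), dtype=np.int64)
    p_afree = np.empty(len(coords), dtype=float)
    for start in range(0, len(coords), cfg.batch_size):
        chunk = coords[start : start + cfg.batch_size]
        images = np.stack([p.image for p in extract_patches(wsi, chunk)]) if chunk else None
        if cfg.pipeline == "moe":
            old_t_s = bundle.t_s
            if cfg.t_s is not None:
                bundle.t_s = cfg.t_s
            try:
                lab, pa = bundle.predict(images, chunk)
            finally:
                bundle.t_s = old_t_s
        else:
            t_s = 0.5 if cfg.t_s is None else cfg.t_s
            probs = model.predict_proba(images, batch_size=cfg.batch_size)
            lab = np.array([predict_multiclass(row, t_s) for row in probs])
            pa = probs[:, 0]
        labels[start : start + len(chunk)] = lab
        p_afree[start : start + len(chunk)] = pa
        logger.info("predicted %d / %d patches", start + len(chunk), len(coords))
    return labels, p_afree


def run_pipeline(
    wsi,
    cfg: PipelineConfig,
    bundle: ExpertBundle | None = None,
    model=None,
    out_dir=None,
) -> PipelineResult:
    """Run pre-processing, inference and post-processing on one slide.

    ``wsi`` is a :class:`WSIRef`, an RGB array, or a path.  The MoE pipeline
    needs ``bundle``; the multiclass pipeline needs a six-class ``model``.
    """
    if isinstance(wsi, (str, Path)):
        wsi = WSIRef.from_path(wsi)
    elif isinstance(wsi, np.ndarray):
        wsi = WSIRef(wsi)
    if cfg.pipeline == "moe" and bundle is None:
        raise ValueError("the MoE pipeline requires an ExpertBundle")
    if cfg.pipeline == "multiclass" and model is None:
        raise ValueError("the multiclass pipeline requires a six-class model")

    fg = extract_foreground(wsi, cfg.foreground_downsample)
    coords = sample_grid(fg, wsi, s=cfg.patch_size, min_tissue=cfg.min_tissue)
    if not coords:
        logger.warning("empty foreground: emitting an empty (discard) report")
        labels = np.empty(0, dtype=np.int64)
        p_afree = np.empty(0)
    else:
        labels, p_afree = _predict_batches(wsi, coords, cfg, bundle=bundle, model=model)

    seg = build_segmentation_map(
        list(zip(coords, labels)), (wsi.width, wsi.height), cfg.patch_size
    )
    report = artifact_report(seg, tau=cfg.tau)
    roi = roi_mask(seg, closing_radius=cfg.closing_radius)
    refined = refine_wsi(wsi._image, roi, fill=cfg.fill)
    table = pd.DataFrame(
        {
            "x": [c.x for c in coords],
            "y": [c.y for c in coords],
            "s": [c.s for c in coords],
            "p_afree": p_afree,
            "predicted_class": labels,
        }
    )
    logger.info(
        "slide done: N_tot=%d rho=%.3f decision=%s", report.n_total, report.rho, report.decision
    )

    result = PipelineResult(
        segmentation=seg, report=report, roi=roi, refined=refined, patch_table=table
    )
    if out_dir is not None:
        result.out_dir = _write_outputs(result, wsi, cfg, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, wsi: WSIRef, cfg: PipelineConfig, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    seg = result.segmentation
    Image.fromarray(seg.to_rgb()).save(out_dir / "segmentation_map.png")
    (out_dir / "palette.json").write_text(
        json.dumps({str(k): list(v) for k, v in seg.palette.items()}, indent=1, sort_keys=True)
    )
    np.savetxt(out_dir / "segmentation_grid.csv", seg.grid, fmt="%d", delimiter=",")
    (out_dir / "qc_report.json").write_text(result.report.to_json(indent=1, sort_keys=True))
    pd.DataFrame(
        {
            "class": list(result.report.percentages),
            "count": [result.report.counts[k] for k in result.report.percentages],
            "percentage": list(result.report.percentages.values()),
        }
    ).to_csv(out_dir / "qc_report.csv", index=False)
    Image.fromarray((result.roi.grid * 255).astype(np.uint8)).save(out_dir / "roi_mask.png")
    Image.fromarray(result.refined).save(out_dir / "refined_wsi.png")
    result.patch_table.to_csv(out_dir / "patch_predictions.csv", index=False)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "wsi": {"source": wsi.source, "width": wsi.width, "height": wsi.height},
        "versions": {"artifact": __version__, "numpy": np.__version__},
        "class_order": "0 afree, 1 blood, 2 blur, 3 air_bubble, 4 damaged, 5 folded",
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def label_patches_against_gt(coords, gt: GroundTruth, overlap_threshold: float = 0.70):
    """Reference cell labels for a coordinate list (the 70%-overlap rule)."""
    return np.array([label_patch(c, gt, overlap_threshold) for c in coords])
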