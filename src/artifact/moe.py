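"""Mixture-of-experts fusion, threshold learning and thresholded prediction.

Five binary experts (blood, blur, air bubble, damaged, folded; class codes
1..5) each emit the probability that a patch shows *their* artifact.  The
fusion keeps the maximum artifact probability over the experts, so the fused
artifact-free probability is ``1 - max_i P_i`` (equivalently the minimum of
the experts' artifact-free probabilities).  A probability threshold t_s on
the artifact-free score is learned from validation data on the ROC curve,
by default as the most specific threshold that still meets a 98% sensitivity
floor for the artifact-free (positive) class; a max-F1 criterion is also
available.  Prediction: the patch is artifact-free iff its artifact-free
score >= t_s (inclusive), otherwise it takes the class of the expert (or
multiclass artifact entry) with the highest artifact probability, ties going
to the lowest class code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import roc_points
from .synthetic import CLASS_NAMES, ARTIFACT_CLASSES

__all__ = [
    "FusedPrediction",
    "ThresholdSelection",
    "ExpertBundle",
    "fuse_experts",
    "select_threshold",
    "predict_moe",
    "predict_multiclass",
]

DEFAULT_TARGET_SENSITIVITY = 0.98


@dataclass(frozen=True)
class FusedPrediction:
    p_afree: float
    p_artifact: float
    argmax_expert: int  # class code 1..5 of the maximizing expert


def _check_probs(values, name="probability"):
    values = np.asarray(values, dtype=float)
    if np.any(values < 0) or np.any(values > 1) or not np.all(np.isfinite(values)):
        raise ValueError(f"{name} values must lie in [0, 1]")
    return values


def fuse_experts(artifact_probs) -> FusedPrediction:
    """Max-fusion of the five experts' artifact probabilities.

    ``artifact_probs`` is ordered (blood, blur, air bubble, damaged, folded).
    """
    p = _check_probs(artifact_probs, "expert artifact")
    if p.shape != (5,):
        raise ValueError(f"expected five expert probabilities, got shape {p.shape}")
    i = int(np.argmax(p))  # np.argmax ties -> lowest index -> lowest class code
    p_art = float(p[i])
    return FusedPrediction(p_afree=1.0 - p_art, p_artifact=p_art, argmax_expert=i + 1)


@dataclass(frozen=True)
class ThresholdSelection:
    t_s: float
    tpr: float  # achieved sensitivity on the selection data
    fpr: float
    auc: float
    criterion: str


def _confusion_at(t, scores, labels):
    pred = scores >= t
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, fn, tn


def select_threshold(
    scores,
    labels,
    target_sensitivity: float | None = DEFAULT_TARGET_SENSITIVITY,
    criterion: str = "target_sensitivity",
) -> ThresholdSelection:
    """Learn t_s from validation artifact-free scores on the ROC curve.

    ``scores`` are artifact-free probabilities in [0, 1]; ``labels`` are 1 for
    artifact-free and 0 for artifact patches.  Candidate thresholds are the
    unique observed scores plus 0, with the inclusive rule
    ``score >= t -> artifact-free``.

    criterion = "target_sensitivity": return the LARGEST candidate whose TPR
    on the selection data is >= the target (maximal specificity subject to
    the sensitivity floor; t = 0 yields TPR 1, so any target <= 1 is
    attainable).  criterion = "max_f1": return the candidate maximizing the F1
    of the artifact-free class (ties -> larger t).
    """
    scores = _check_probs(scores, "score")
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to select a threshold")
    if criterion == "target_sensitivity":
        if not 0.0 <= target_sensitivity <= 1.0:
            raise ValueError("target sensitivity must be in [0, 1]")
    elif criterion != "max_f1":
        raise ValueError(f"unknown criterion {criterion!r}")

    candidates = np.unique(np.concatenate([scores, [0.0]]))
    pos = labels == 1
    n_pos = int(pos.sum())
    best_t = 0.0
    if criterion == "target_sensitivity":
        for t in candidates:  # ascending; keep the largest feasible
            tpr = np.sum(scores[pos] >= t) / n_pos
            if tpr >= target_sensitivity:
                best_t = float(t)
    else:
        best_f1 = -1.0
        for t in candidates:
            tp, fp, fn, _ = _confusion_at(t, scores, labels)
            denom = 2 * tp + fp + fn
            f1 = 2 * tp / denom if denom else 0.0
            if f1 >= best_f1:  # ties -> larger t (candidates ascend)
                best_f1, best_t = f1, float(t)

    tp, fp, fn, tn = _confusion_at(best_t, scores, labels)
    _, auc = roc_points(scores, labels)
    return ThresholdSelection(
        t_s=best_t,
        tpr=tp / (tp + fn),
        fpr=fp / (fp + tn) if (fp + tn) else 0.0,
        auc=auc,
        criterion=criterion,
    )


def predict_moe(artifact_probs, t_s: float) -> int:
    """Thresholded MoE class: 0 if the fused artifact-free score >= t_s, else
    the class code of the maximizing expert."""
    if not 0.0 <= t_s <= 1.0:
        raise ValueError("t_s must be in [0, 1]")
    fused = fuse_experts(artifact_probs)
    return 0 if fused.p_afree >= t_s else fused.argmax_expert


def predict_multiclass(p, t_s: float) -> int:
    """Thresholded six-class prediction: 0 if p[0] >= t_s, else the argmax over
    the five artifact entries (even when p[0] is the overall maximum)."""
    if not 0.0 <= t_s <= 1.0:
        raise ValueError("t_s must be in [0, 1]")
    p = _check_probs(p, "class probability")
    if p.shape != (6,):
        raise ValueError(f"expected a length-6 probability vector, got shape {p.shape}")
    if p[0] >= t_s:
        return 0
    return int(np.argmax(p[1:])) + 1


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class ExpertBundle:
    """Five binary experts keyed by class code 1..5, plus a learned t_s.

    Each expert must expose ``artifact_proba(images, coords=None) -> (n,)``;
    :class:`ClassifierExpert` adapts a trained binary classifier and
    :class:`artifact.pipeline.OracleExpert` reads ground truth directly.
    """

    experts: dict
    t_s: float = 0.5
    selection: ThresholdSelection | None = None

    def __post_init__(self):
        if sorted(self.experts) != list(ARTIFACT_CLASSES):
            raise ValueError(
                f"an ExpertBundle needs exactly the experts {list(ARTIFACT_CLASSES)}, "
                f"got {sorted(self.experts)}"
            )
        if not 0.0 <= self.t_s <= 1.0:
            raise ValueError("t_s must be in [0, 1]")

    def artifact_proba_matrix(self, images, coords=None) -> np.ndarray:
        """(n, 5) matrix of per-expert artifact probabilities in class order."""
        cols = [self.experts[k].artifact_proba(images, coords) for k in ARTIFACT_CLASSES]
        return np.stack(cols, axis=1)

    def predict(self, images, coords=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-patch (labels, p_afree) under the thresholded MoE rule."""
        probs = self.artifact_proba_matrix(images, coords)
        labels = np.array([predict_moe(row, self.t_s) for row in probs])
        p_afree = 1.0 - probs.max(axis=1)
        return labels, p_afree

    def save(self, out_dir) -> Path:
        """Write expert checkpoints plus a JSON manifest; returns its path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = {}
        for k, expert in self.experts.items():
            if not hasattr(expert, "model"):
                raise TypeError("only classifier-backed bundles can be saved")
            path = out_dir / f"expert_{CLASS_NAMES[k]}.npz"
            expert.model.save_checkpoint(path)
            entries[str(k)] = path.name
        manifest = {
            "experts": entries,
            "t_s": self.t_s,
            "selection": None
            if self.selection is None
            else {
                "criterion": self.selection.criterion,
                "tpr": self.selection.tpr,
                "fpr": self.selection.fpr,
                "auc": self.selection.auc,
            },
        }
        path = out_dir / "bundle.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, bundle_dir) -> "ExpertBundle":
        from .experts import load_checkpoint

        bundle_dir = Path(bundle_dir)
        manifest = json.loads((bundle_dir / "bundle.json").read_text())
        experts = {
            int(k): ClassifierExpert(load_checkpoint(bundle_dir / name))
            for k, name in manifest["experts"].items()
        }
        return cls(experts=experts, t_s=manifest["t_s"])


@dataclass
class ClassifierExpert:
    """Adapter: a trained binary classifier as a bundle expert.

    Binary class order is (0 artifact, 1 artifact-free), so the artifact
    probability is column 0 of ``predict_proba``.
    """

    model: object
    batch_size: int = 128

    def artifact_proba(self, images, coords=None) -> np.ndarray:
        return self.model.predict_proba(images, batch_size=self.batch_size)[:, 0]
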