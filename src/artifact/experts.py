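"""Patch classifiers: backbone + three-layer FC head, and their training loop.

A model is a feature extractor phi (backbone) followed by a three-layer fully
connected classifier (embed -> h1 -> h2 -> k) with dropout between the FC
layers and a softmax output.  Binary experts use k = 2 with the convention
index 0 = artifact (negative class) and index 1 = artifact-free (positive
class); multiclass models use k = 6 in the global class order
(0 artifact-free, 1 blood, 2 blur, 3 air bubble, 4 damaged, 5 folded).

Backbones
---------
``tiny_test_cnn``
    A three-conv-block CNN (embedding width 32) that trains on CPU in
    seconds to minutes; the backbone actually used for fitting in this
    package.
``mobilenet_v3_large``, ``vit_tiny``
    Parameter-accounting references built from per-layer tables of the
    published architectures.  They support exact trainable-parameter counts
    (e.g. MobileNetV3-Large features + the 960->512->128->2 head gives the
    familiar 3.53 M figure) but raise on inference because no pretrained
    weights ship with the package.

The training recipe is cross-entropy loss, SGD (momentum 0.9) from learning
rate 0.01 with reduce-on-plateau scheduling on validation loss, batch size
128, geometric augmentation (random 90-degree rotations and flips) refreshed
every epoch, ImageNet channel standardization, dropout 0.2, early stopping
with patience 20 on validation loss, and checkpointing at the minimum
validation loss.  Fully reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .synthetic import CLASS_NAMES, PatchSet

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ArtifactClassifier",
    "build_model",
    "predict_proba",
    "hard_label",
    "train_model",
    "count_parameters",
    "binarize_labels",
    "load_image_folder",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

BACKBONES = ("tiny_test_cnn", "mobilenet_v3_large", "vit_tiny")


@dataclass(frozen=True)
class ModelSpec:
    backbone: str = "tiny_test_cnn"
    k: int = 2
    head: tuple = (512, 128)
    dropout: float = 0.2
    pretrained: bool = False

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.k not in (2, 6):
            raise ValueError(f"k must be 2 (binary) or 6 (multiclass), got {self.k}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if any(h <= 0 for h in self.head):
            raise ValueError("head widths must be positive")

    def to_dict(self):
        return {
            "backbone": self.backbone,
            "k": self.k,
            "head": list(self.head),
            "dropout": self.dropout,
            "pretrained": self.pretrained,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            backbone=d["backbone"],
            k=d["k"],
            head=tuple(d["head"]),
            dropout=d["dropout"],
            pretrained=d.get("pretrained", False),
        )


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20  # early stopping on validation loss
    scheduler_factor: float = 0.1
    scheduler_patience: int = 5
    min_lr: float = 1e-5
    dropout_seedless_eval: bool = True
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("early-stopping patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


# ---------------------------------------------------------------------------
# parameter tables for the reference backbones
# ---------------------------------------------------------------------------

def _make_divisible(v, divisor=8):
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return int(new_v)

# MobileNetV3-Large inverted-residual settings:
# (kernel, expanded channels, out channels, squeeze-excite, stride)
_MBV3_LARGE_CFG = [
    (3, 16, 16, False, 1),
    (3, 64, 24, False, 2),
    (3, 72, 24, False, 1),
    (5, 72, 40, True, 2),
    (5, 120, 40, True, 1),
    (5, 120, 40, True, 1),
    (3, 240, 80, False, 2),
    (3, 200, 80, False, 1),
    (3, 184, 80, False, 1),
    (3, 184, 80, False, 1),
    (3, 480, 112, True, 1),
    (3, 672, 112, True, 1),
    (5, 672, 160, True, 2),
    (5, 960, 160, True, 1),
    (5, 960, 160, True, 1),
]


def _mobilenet_v3_large_layers():
    """Per-layer (name, n_params) table of the MobileNetV3-Large feature
    extractor (conv weights without bias + batch-norm scale/shift; the
    squeeze-excite 1x1 convs carry biases)."""
    layers = [("stem_conv3x3_3to16", 3 * 16 * 9 + 2 * 16)]
    cin = 16
    for i, (k, exp, cout, se, _stride) in enumerate(_MBV3_LARGE_CFG):
        n = 0
        if exp != cin:
            n += cin * exp + 2 * exp  # 1x1 expand conv + BN
        n += exp * k * k + 2 * exp  # depthwise conv + BN
        if se:
            squeeze = _make_divisible(exp // 4)
            n += exp * squeeze + squeeze + squeeze * exp + exp  # SE fc1/fc2 with bias
        n += exp * cout + 2 * cout  # 1x1 project conv + BN
        layers.append((f"bneck{i}_{k}x{k}_{cin}to{cout}", n))
        cin = cout
    layers.append(("head_conv1x1_160to960", 160 * 960 + 2 * 960))
    return layers


def _vit_tiny_layers():
    """Per-layer table of the headless ViT-Tiny/16 (224) encoder."""
    d, depth, mlp = 192, 12, 768
    layers = [
        ("patch_embed_16x16", 3 * d * 16 * 16 + d),
        ("cls_token", d),
        ("pos_embed", (196 + 1) * d),
    ]
    per_block = (
        2 * (2 * d)  # two layernorms
        + d * (3 * d) + 3 * d  # qkv projection
        + d * d + d  # attention output projection
        + d * mlp + mlp + mlp * d + d  # MLP
    )
    layers += [(f"block{i}", per_block) for i in range(depth)]
    layers.append(("final_norm", 2 * d))
    return layers


_BACKBONE_TABLES = {
    "mobilenet_v3_large": (_mobilenet_v3_large_layers, 960),
    "vit_tiny": (_vit_tiny_layers, 192),
}


def _head_layer_table(embed_dim, head, k):
    dims = (embed_dim, *head, k)
    return [
        (f"fc{i}_{a}to{b}", a * b + b) for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
    ]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class ArtifactClassifier:
    """Backbone + three-layer FC classifier over standardized 224x224 RGB."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.embed_dim = None
        self.net = None
        self._layer_table = None
        rng = np.random.default_rng([1234, seed])
        if spec.backbone == "tiny_test_cnn":
            self.embed_dim = 32
            layers = [
                nn.AvgPool2d(4),  # 224 -> 56 before the first conv
                nn.Conv2d(3, 8, 3, rng, pad=1),
                nn.ReLU(),
                nn.MaxPool2d(2),  # 28
                nn.Conv2d(8, 16, 3, rng, pad=1),
                nn.ReLU(),
                nn.MaxPool2d(2),  # 14
                nn.Conv2d(16, 32, 3, rng, pad=1),
                nn.ReLU(),
                nn.GlobalAvgPool(),
            ]
            dims = (self.embed_dim, *spec.head)
            for a, b in zip(dims[:-1], dims[1:]):
                layers += [nn.Linear(a, b, rng), nn.ReLU(), nn.Dropout(spec.dropout)]
            layers.append(nn.Linear(dims[-1], spec.k, rng))
            self.net = nn.Sequential(layers)
        else:
            table_fn, self.embed_dim = _BACKBONE_TABLES[spec.backbone]
            self._layer_table = list(table_fn()) + _head_layer_table(
                self.embed_dim, spec.head, spec.k
            )

    # -- inference ---------------------------------------------------------
    @property
    def runnable(self) -> bool:
        return self.net is not None

    def _require_runnable(self):
        if not self.runnable:
            raise RuntimeError(
                f"backbone {self.spec.backbone!r} is a parameter-accounting reference; "
                "no pretrained weights ship with this package. Use 'tiny_test_cnn' "
                "for a runnable model."
            )

    @staticmethod
    def preprocess(images: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> ImageNet-standardized float32 NCHW."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError(f"expected (N, H, W, 3) RGB batch, got {images.shape}")
        x = images.astype(np.float32) / 255.0
        x = (x - IMAGENET_MEAN) / IMAGENET_STD
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward_logits(self, x, train=False, rng=None):
        self._require_runnable()
        return self.net.forward(x, train=train, rng=rng)

    def predict_proba(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Softmax probabilities for a uint8 image batch (eval mode)."""
        self._require_runnable()
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        out = []
        for i in range(0, len(images), batch_size):
            x = self.preprocess(images[i : i + batch_size])
            out.append(nn.softmax(self.forward_logits(x)))
        return np.concatenate(out) if out else np.empty((0, self.spec.k))

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        p = self.predict_proba(images, batch_size=batch_size)
        return np.array([hard_label(row) for row in p])

    # -- bookkeeping -------------------------------------------------------
    def layer_parameter_table(self) -> list:
        """Independent per-layer (name, n_params) enumeration."""
        if self.runnable:
            table = []
            for i, layer in enumerate(self.net.layers):
                if layer.params:
                    table.append((f"{type(layer).__name__.lower()}_{i}", layer.n_params))
            return table
        return list(self._layer_table)

    @property
    def num_parameters(self) -> int:
        if self.runnable:
            return self.net.n_params
        return sum(n for _, n in self._layer_table)

    # -- persistence -------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        self._require_runnable()
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.net.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}:{k}"] = v
        meta = {
            "spec": self.spec.to_dict(),
            "seed": self.seed,
            "class_names": {str(c): n for c, n in CLASS_NAMES.items()},
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ArtifactClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = ArtifactClassifier(ModelSpec.from_dict(meta["spec"]), seed=meta["seed"])
        for i, layer in enumerate(model.net.layers):
            for k in layer.params:
                layer.params[k][...] = data[f"layer{i}:{k}"]
    return model


def build_model(spec: ModelSpec, seed: int = 0) -> ArtifactClassifier:
    """Construct a classifier from its spec."""
    return ArtifactClassifier(spec, seed=seed)


def predict_proba(model: ArtifactClassifier, images: np.ndarray, batch_size: int = 128):
    return model.predict_proba(images, batch_size=batch_size)


def hard_label(p) -> int:
    """Argmax of a probability vector; ties break toward the lowest index."""
    p = np.asarray(p)
    if p.size == 0:
        raise ValueError("empty probability vector")
    return int(np.argmax(p))


def count_parameters(models) -> int:
    """Total trainable parameters of one model or an iterable of models."""
    if hasattr(models, "num_parameters"):
        return int(models.num_parameters)
    if hasattr(models, "experts"):  # ExpertBundle
        return sum(count_parameters(m) for m in models.experts.values())
    return sum(count_parameters(m) for m in models)


def binarize_labels(labels) -> np.ndarray:
    """Six-class codes -> binary expert labels: artifact-free (0) becomes the
    positive class 1, every artifact class becomes the negative class 0."""
    labels = np.asarray(labels)
    return (labels == 0).astype(np.int64)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fresh random 90-degree rotations and horizontal/vertical flips."""
    out = np.empty_like(images)
    ks = rng.integers(0, 4, size=len(images))
    flips_h = rng.random(len(images)) < 0.5
    flips_v = rng.random(len(images)) < 0.5
    for i, img in enumerate(images):
        a = np.rot90(img, k=int(ks[i]))
        if flips_h[i]:
            a = a[:, ::-1]
        if flips_v[i]:
            a = a[::-1]
        out[i] = a
    return out


def _as_arrays(split) -> tuple:
    if isinstance(split, PatchSet):
        return split.images, split.labels
    images, labels = split
    return np.asarray(images), np.asarray(labels)


@dataclass
class TrainHistory:
    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    lr: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.__dict__)


def _epoch_eval(model, images, labels, batch_size):
    losses, correct = [], 0
    for i in range(0, len(images), batch_size):
        x = model.preprocess(images[i : i + batch_size])
        logits = model.forward_logits(x)
        loss, _ = nn.softmax_cross_entropy(logits, labels[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == labels[i : i + batch_size]).sum())
    return sum(losses) / len(images), correct / len(images)


def train_model(model: ArtifactClassifier, train_split, val_split, cfg: TrainConfig):
    """Fit with the standard recipe; returns ``(model, TrainHistory)``.

    The returned model carries the weights of the epoch with minimum
    validation loss.  Deterministic for a fixed ``cfg.seed`` on one device.
    """
    model._require_runnable()
    train_images, train_labels = _as_arrays(train_split)
    val_images, val_labels = _as_arrays(val_split)
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation splits must be non-empty")
    k = model.spec.k
    for name, labels in (("train", train_labels), ("val", val_labels)):
        if labels.min() < 0 or labels.max() >= k:
            raise ValueError(f"{name} labels outside 0..{k - 1}")

    rng = np.random.default_rng([777, cfg.seed])
    opt = nn.SGD(model.net, lr=cfg.lr, momentum=cfg.momentum)
    history = TrainHistory()
    best_loss, best_state, best_epoch = np.inf, model.net.get_state(), -1
    epochs_since_best, plateau = 0, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_images))
        images = train_images[order]
        labels = train_labels[order]
        if cfg.augment:
            images = _augment_batch(images, rng)
        epoch_losses = []
        for i in range(0, len(images), cfg.batch_size):
            x = model.preprocess(images[i : i + cfg.batch_size])
            logits = model.forward_logits(x, train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[i : i + cfg.batch_size])
            model.net.backward(dlogits)
            opt.step()
            epoch_losses.append(loss * len(logits))
        train_loss = sum(epoch_losses) / len(images)
        val_loss, val_acc = _epoch_eval(model, val_images, val_labels, cfg.batch_size)

        history.epoch.append(epoch)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.lr.append(opt.lr)

        if val_loss < best_loss - 1e-12:
            best_loss, best_state, best_epoch = val_loss, model.net.get_state(), epoch
            epochs_since_best, plateau = 0, 0
        else:
            epochs_since_best += 1
            plateau += 1
            if plateau >= cfg.scheduler_patience:
                opt.lr = max(opt.lr * cfg.scheduler_factor, cfg.min_lr)
                plateau = 0
            if epochs_since_best >= cfg.patience:
                break

    model.net.set_state(best_state)
    history.best_epoch = best_epoch
    history.best_val_loss = best_loss
    return model, history


# ---------------------------------------------------------------------------
# directory-per-class dataset reader
# ---------------------------------------------------------------------------

_NAME_TO_CODE = {v: k for k, v in CLASS_NAMES.items()}


def load_image_folder(root) -> PatchSet:
    """Read a directory-per-class layout (subdirs named after the classes)."""
    root = Path(root)
    images, labels = [], []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if sub.name not in _NAME_TO_CODE:
            raise ValueError(f"unknown class directory {sub.name!r}")
        code = _NAME_TO_CODE[sub.name]
        for f in sorted(sub.glob("*.png")):
            images.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(code)
    if not images:
        raise ValueError(f"no class directories with PNGs under {root}")
    return PatchSet(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=np.int64),
        seeds=np.zeros(len(labels), dtype=np.int64),
    )
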