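import pytest

import artifact as A
from artifact.synthetic import PatchSet


@pytest.fixture(scope="session")
def small_wsi():
    """896x896 synthetic slide: tissue over half the canvas, two grid-aligned
    artifact rectangles (blur 448x448, blood 224x224) inside the tissue."""
    spec = A.SyntheticWSISpec(
        width=896,
        height=896,
        regions=((2, 224, 224, 448, 448), (1, 224, 0, 224, 224)),
        base_texture_seed=11,
        tissue_fraction=0.9,
    )
    image, gt = A.generate_wsi(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def tiny_binary_dataset():
    """Small blur-vs-tissue dataset with binary expert labels (afree = 1)."""
    ds = A.build_patch_dataset({0: 40, 2: 40}, seed=5, split_fractions=(0.8, 0.1, 0.1))
    return {
        name: PatchSet(ps.images, A.binarize_labels(ps.labels), ps.seeds)
        for name, ps in ds.items()
    }


@pytest.fixture(scope="session")
def trained_tiny_expert(tiny_binary_dataset):
    model = A.build_model(A.ModelSpec(k=2, head=(64, 32)), seed=0)
    cfg = A.TrainConfig(max_epochs=20, batch_size=32, seed=0)
    model, history = A.train_model(
        model, tiny_binary_dataset["train"], tiny_binary_dataset["val"], cfg
    )
    return model, history
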