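"""Model construction, prediction, parameter accounting, training recipe."""

import numpy as np
import pytest

import artifact as A
from artifact import nn
from artifact.experts import load_checkpoint


@pytest.fixture(scope="module")
def tiny_model():
    return A.build_model(A.ModelSpec(k=2, head=(32, 16)), seed=1)


class TestBuildAndPredict:
    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            A.ModelSpec(backbone="resnet50")

    def test_output_rows_sum_to_one(self, tiny_model):
        rng = np.random.default_rng(0)
        images = rng.integers(0, 256, size=(5, 224, 224, 3), dtype=np.uint8)
        p = tiny_model.predict_proba(images)
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_multiclass_output_length_six(self):
        model = A.build_model(A.ModelSpec(k=6, head=(32, 16)), seed=0)
        images = np.zeros((2, 224, 224, 3), dtype=np.uint8)
        assert model.predict_proba(images).shape == (2, 6)

    def test_batch_size_invariance_and_duplicates(self, tiny_model):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(224, 224, 3), dtype=np.uint8)
        other = rng.integers(0, 256, size=(224, 224, 3), dtype=np.uint8)
        solo = tiny_model.predict_proba(img[None])[0]
        batch = tiny_model.predict_proba(np.stack([img, other, img]))
        np.testing.assert_allclose(batch[0], solo, atol=1e-6)
        np.testing.assert_allclose(batch[0], batch[2], atol=0)

    def test_wrong_image_shape_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.predict_proba(np.zeros((2, 224, 224), dtype=np.uint8))

    def test_reference_backbones_refuse_inference(self):
        model = A.build_model(A.ModelSpec(backbone="mobilenet_v3_large", k=2))
        with pytest.raises(RuntimeError, match="parameter-accounting"):
            model.predict_proba(np.zeros((1, 224, 224, 3), dtype=np.uint8))


class TestSoftmaxAndLabels:
    def test_softmax_closed_forms(self):
        np.testing.assert_allclose(nn.softmax(np.array([[0.0, 0.0]])), [[0.5, 0.5]])
        np.testing.assert_allclose(
            nn.softmax(np.array([[np.log(3.0), 0.0]])), [[0.75, 0.25]], atol=1e-12
        )

    def test_hard_label_examples_and_tie_rule(self):
        assert A.hard_label([0.2, 0.8]) == 1
        assert A.hard_label([0.5, 0.5]) == 0  # ties break toward the lowest index
        with pytest.raises(ValueError):
            A.hard_label([])

    def test_hard_label_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.random(6)
            best = 0
            for i in range(6):  # linear max scan
                if p[i] > p[best]:
                    best = i
            assert A.hard_label(p) == best

    def test_cross_entropy_closed_forms(self):
        # confident-correct prediction: loss ~ 0
        loss, _ = nn.softmax_cross_entropy(np.array([[30.0, 0.0]]), np.array([0]))
        assert loss < 1e-10
        # uniform binary prediction: loss = ln 2
        loss, _ = nn.softmax_cross_entropy(np.array([[0.0, 0.0]]), np.array([1]))
        np.testing.assert_allclose(loss, np.log(2), rtol=1e-12)


class TestParameterCounting:
    def test_single_linear_map_with_bias(self):
        rng = np.random.default_rng(0)
        assert nn.Linear(2, 3, rng).n_params == 9

    def test_tiny_model_matches_independent_layer_enumeration(self, tiny_model):
        # independent per-layer oracle: conv k*k*cin*cout + cout, fc din*dout + dout
        expected = (
            (3 * 3 * 3 * 8 + 8)
            + (3 * 3 * 8 * 16 + 16)
            + (3 * 3 * 16 * 32 + 32)
            + (32 * 32 + 32)
            + (32 * 16 + 16)
            + (16 * 2 + 2)
        )
        assert tiny_model.num_parameters == expected
        assert sum(n for _, n in tiny_model.layer_parameter_table()) == expected
        assert A.count_parameters(tiny_model) == expected

    def test_mobilenet_head_arithmetic_reproduces_published_total(self):
        model = A.build_model(A.ModelSpec(backbone="mobilenet_v3_large", k=2, head=(512, 128)))
        head = sum(n for name, n in model.layer_parameter_table() if name.startswith("fc"))
        assert head == 960 * 512 + 512 + 512 * 128 + 128 + 128 * 2 + 2
        assert round(model.num_parameters / 1e6, 2) == 3.53
        five = [model] * 5
        assert round(A.count_parameters(five) / 1e6, 2) == 17.65

    def test_vit_tiny_near_headless_count(self):
        model = A.build_model(A.ModelSpec(backbone="vit_tiny", k=2))
        backbone = sum(
            n for name, n in model.layer_parameter_table() if not name.startswith("fc")
        )
        assert backbone == 5_524_416  # headless ViT-Tiny/16 encoder
        # single-linear-head reading: six-class model 5.53 M, five binary
        # experts 27.62 M
        assert round((backbone + 192 * 6 + 6) / 1e6, 2) == 5.53
        assert round(5 * (backbone + 192 * 2 + 2) / 1e6, 2) == 27.62


class TestTraining:
    def test_overfits_a_small_two_class_set(self, trained_tiny_expert, tiny_binary_dataset):
        model, history = trained_tiny_expert
        images, labels = tiny_binary_dataset["train"].images, tiny_binary_dataset["train"].labels
        acc = (model.predict(images) == labels).mean()
        assert acc == 1.0
        assert len(history.epoch) <= 20

    def test_returned_weights_achieve_minimum_validation_loss(
        self, trained_tiny_expert, tiny_binary_dataset
    ):
        from artifact.experts import _epoch_eval

        model, history = trained_tiny_expert
        val = tiny_binary_dataset["val"]
        val_loss, _ = _epoch_eval(model, val.images, val.labels, 32)
        np.testing.assert_allclose(val_loss, min(history.val_loss), rtol=1e-6)
        assert history.best_val_loss == min(history.val_loss)

    def test_seeded_training_is_reproducible(self, tiny_binary_dataset):
        histories = []
        for _ in range(2):
            model = A.build_model(A.ModelSpec(k=2, head=(16, 8)), seed=3)
            cfg = A.TrainConfig(max_epochs=3, batch_size=16, seed=3)
            _, h = A.train_model(
                model, tiny_binary_dataset["train"], tiny_binary_dataset["val"], cfg
            )
            histories.append(h)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_loss == histories[1].val_loss

    def test_bad_inputs_rejected(self, tiny_binary_dataset):
        model = A.build_model(A.ModelSpec(k=2, head=(16, 8)), seed=0)
        cfg = A.TrainConfig(max_epochs=1, seed=0)
        empty = (np.empty((0, 224, 224, 3), np.uint8), np.empty(0, np.int64))
        with pytest.raises(ValueError):
            A.train_model(model, empty, tiny_binary_dataset["val"], cfg)
        bad = (
            tiny_binary_dataset["train"].images[:4],
            np.array([0, 1, 2, 1]),  # label 2 outside binary range
        )
        with pytest.raises(ValueError):
            A.train_model(model, bad, tiny_binary_dataset["val"], cfg)

    def test_binarize_labels_convention(self):
        # artifact-free (0) is the positive class 1; artifacts are 0
        np.testing.assert_array_equal(
            A.binarize_labels([0, 1, 2, 3, 4, 5, 0]), [1, 0, 0, 0, 0, 0, 1]
        )

    def test_checkpoint_roundtrip(self, trained_tiny_expert, tmp_path):
        model, _ = trained_tiny_expert
        path = tmp_path / "expert.npz"
        model.save_checkpoint(path)
        clone = load_checkpoint(path)
        rng = np.random.default_rng(0)
        images = rng.integers(0, 256, size=(3, 224, 224, 3), dtype=np.uint8)
        np.testing.assert_array_equal(clone.predict_proba(images), model.predict_proba(images))
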