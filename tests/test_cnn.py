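"""Architecture arithmetic, numeric-gradient check, training behavior."""

import numpy as np
import pytest

import preictal.cnn as cnn
from preictal import _nn

PRINTED_COUNTS = [608, 128, 6208, 24704, 98560, 393728, 513]
PRINTED_TOTAL = 524_449
PRINTED_DIMS = [5118, 2559, 2557, 1278, 1276, 638, 636, 318, 316, 512, 1]


class TestArchitecture:
    def test_default_stack_has_19_layers_in_order(self):
        spec = cnn.build_architecture()
        kinds = [l.kind for l in spec.layers]
        assert len(kinds) == 19
        assert kinds == [
            "conv1d", "batchnorm", "leaky_relu", "maxpool",
            "conv1d", "leaky_relu", "maxpool", "dropout",
            "conv1d", "leaky_relu", "avgpool", "dropout",
            "conv1d", "leaky_relu", "avgpool",
            "conv1d", "leaky_relu", "global_avgpool", "dense",
        ]

    def test_parameter_counts_reproduce_published_table(self):
        spec = cnn.build_architecture()
        counts, total = cnn.count_parameters(spec)
        assert [c for c in counts if c] == PRINTED_COUNTS
        assert total == PRINTED_TOTAL

    def test_shapes_reproduce_published_progression(self):
        spec = cnn.build_architecture()
        rows = cnn.output_shapes(spec)
        dims = [r["length"] if r["length"] is not None else r["channels"] for r in rows]
        progression = [d for i, d in enumerate(dims) if i == 0 or d != dims[i - 1]]
        assert progression == [5118] + PRINTED_DIMS[1:]
        assert rows[0]["length"] == spec.input_length - 2

    def test_tiny_conv_parameter_count(self):
        spec = cnn.ArchitectureSpec(
            1, 200, (cnn.LayerSpec("conv1d", filters=1, kernel=1),
                     cnn.LayerSpec("global_avgpool"), cnn.LayerSpec("dense", filters=1))
        )
        counts, total = cnn.count_parameters(spec)
        assert counts[0] == 2  # one weight + one bias

    def test_underflowing_input_rejected_naming_layer(self):
        with pytest.raises(ValueError, match="underflow|no time axis"):
            cnn.build_architecture(in_channels=1, input_length=7)

    def test_report_carries_total(self):
        df = cnn.architecture_report(cnn.build_architecture())
        assert df.attrs["total_parameters"] == PRINTED_TOTAL
        assert df["parameters"].sum() == PRINTED_TOTAL


class TestGradients:
    def test_backprop_matches_numeric_gradient(self, monkeypatch):
        """Finite-difference check of a small instance of the full layer
        stack.  Dropout is disabled so the train-mode forward is
        deterministic, and the backend runs in float64 here so the central
        difference is not dominated by float32 rounding."""
        monkeypatch.setattr(_nn, "F", np.float64)
        spec = cnn.build_architecture(
            in_channels=1, input_length=128, filters=(2, 2, 2, 2, 2),
            dropout_rate=0.0,
        )
        model = cnn.Cnn1DModel(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 1, 128))
        y = np.array([0.0, 1.0, 0.0, 1.0])

        def loss():
            logits = model._forward(x, train=True)[:, 0]
            return _nn.bce_loss(_nn.sigmoid(logits), y)

        logits = model._forward(x, train=True)[:, 0]
        p = _nn.sigmoid(logits)
        g = ((p - y) / len(y))[:, None]
        for layer in reversed(model.layers):
            g = layer.backward(g)

        eps = 1e-6
        checked = 0
        for layer in model.layers:
            for k, par in layer.params.items():
                flat = par.ravel()
                for idx in range(0, flat.size, max(1, flat.size // 4)):
                    old = flat[idx]
                    flat[idx] = old + eps
                    lp = loss()
                    flat[idx] = old - eps
                    lm = loss()
                    flat[idx] = old
                    numeric = (lp - lm) / (2 * eps)
                    analytic = layer.grads[k].ravel()[idx]
                    assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-8)
                    checked += 1
        assert checked >= 20


class TestTraining:
    @pytest.fixture(scope="class")
    def xy(self, separated_segments):
        x = np.stack([s.samples for s in separated_segments])
        y = np.array([1 if s.label == "preictal" else 0 for s in separated_segments])
        return x, y

    @pytest.fixture(scope="class")
    def reduced_spec(self):
        return cnn.build_architecture(
            in_channels=1, input_length=3840, filters=cnn.REDUCED_FILTERS
        )

    def test_separable_classes_reach_090_training_accuracy(self, xy, reduced_spec):
        model, hist = cnn.train(
            reduced_spec, *xy, cnn.TrainConfig(epochs=10, seed=0)
        )
        assert hist["accuracy"][-1] >= 0.9

    def test_identical_seed_reproduces_final_loss(self, xy, reduced_spec):
        _, h1 = cnn.train(reduced_spec, *xy, cnn.TrainConfig(epochs=3, seed=4))
        _, h2 = cnn.train(reduced_spec, *xy, cnn.TrainConfig(epochs=3, seed=4))
        assert h1["loss"][-1] == h2["loss"][-1]
        assert h1["val_loss"][-1] == h2["val_loss"][-1]

    def test_shuffled_labels_stay_at_chance(self, xy, reduced_spec):
        x, y = xy
        ys = np.random.default_rng(0).permutation(y)
        _, hist = cnn.train(reduced_spec, x, ys, cnn.TrainConfig(epochs=10, seed=0))
        assert 0.35 <= hist["val_accuracy"][-1] <= 0.65

    def test_single_class_rejected(self, xy, reduced_spec):
        x, _ = xy
        with pytest.raises(ValueError, match="both classes"):
            cnn.train(reduced_spec, x, np.zeros(len(x)), cnn.TrainConfig(epochs=1))

    def test_history_has_one_entry_per_epoch(self, xy, reduced_spec):
        _, hist = cnn.train(reduced_spec, *xy, cnn.TrainConfig(epochs=3, seed=0))
        assert {len(v) for v in hist.values()} == {3}


class TestFeatureExtraction:
    def test_full_architecture_feature_width_is_512(self, rng):
        spec = cnn.build_architecture()  # 6 x 5120
        model = cnn.Cnn1DModel(spec, seed=0)
        feats = cnn.extract_features(model, rng.standard_normal((6, 5120)))
        assert feats.shape == (512,)
        assert spec.feature_width == 512

    def test_inference_is_deterministic_despite_dropout_layers(self, rng):
        spec = cnn.build_architecture(1, 3840, filters=cnn.REDUCED_FILTERS)
        model = cnn.Cnn1DModel(spec, seed=0)
        x = rng.standard_normal((1, 3840))
        np.testing.assert_array_equal(
            cnn.extract_features(model, x), cnn.extract_features(model, x)
        )

    def test_zero_input_yields_finite_features(self):
        spec = cnn.build_architecture(1, 3840, filters=cnn.REDUCED_FILTERS)
        model = cnn.Cnn1DModel(spec, seed=0)
        feats = cnn.extract_features(model, np.zeros((1, 3840)))
        assert np.all(np.isfinite(feats))

    def test_checkpoint_round_trip(self, tmp_path, separated_segments):
        segs = separated_segments[:20] + separated_segments[-20:]
        x = np.stack([s.samples for s in segs])
        y = np.array([1 if s.label == "preictal" else 0 for s in segs])
        spec = cnn.build_architecture(1, 3840, filters=cnn.REDUCED_FILTERS)
        model, _ = cnn.train(spec, x, y, cnn.TrainConfig(epochs=2, seed=0))
        path = tmp_path / "model.npz"
        model.save(path)
        back = cnn.Cnn1DModel.load(path)
        np.testing.assert_allclose(
            model.predict_proba(x), back.predict_proba(x), atol=1e-7
        )
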