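"""Architecture specs, closed-form parameter counts, training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcglearn as pl
from pcglearn import models as M
from pcglearn.estimators import LSTMSequenceClassifier


def brute_force_count(spec: M.ModelSpec) -> int:
    """Independent oracle: enumerate every weight one by one."""
    total = 0
    shape = tuple(spec.input_shape)
    for layer in spec.layers:
        k = layer.kind
        if k == "conv2d":
            kk = layer.kernel or 3
            c_in = shape[-1]
            n = 0
            for _f in range(layer.filters):
                for _i in range(kk):
                    for _j in range(kk):
                        for _c in range(c_in):
                            n += 1
                n += 1  # bias
            total += n
            shape = (shape[0] - kk + 1, shape[1] - kk + 1, layer.filters)
        elif k == "maxpool2d":
            shape = (shape[0] // 2, shape[1] // 2, shape[2])
        elif k == "batchnorm":
            total += sum(1 for _ in range(shape[-1])) * 2
        elif k == "flatten":
            shape = (int(np.prod(shape)),)
        elif k == "flatten_seq":
            shape = (shape[0], shape[1] * shape[2])
        elif k == "lstm":
            n_in, u = shape[-1], layer.units
            n = 0
            for _gate in range(4):
                n += n_in * u + u * u + u  # W, U, bias per gate
            total += n
            shape = (shape[0], u) if layer.return_sequences else (u,)
        elif k in ("dense", "softmax"):
            total += (shape[0] + 1) * layer.units
            shape = (layer.units,)
    return total


class TestBuilders:
    def test_model1_structure(self):
        spec = M.build_model1((598, 13))
        lstms = [l for l in spec.layers if l.kind == "lstm"]
        drops = [l for l in spec.layers if l.kind == "dropout"]
        assert len(lstms) == 3 and all(l.units == 128 for l in lstms)
        assert len(drops) == 3 and all(d.rate == 0.2 for d in drops)
        assert spec.layers[-1].kind == "softmax" and spec.layers[-1].units == 2
        assert spec.train_config.epochs == 50 and spec.train_config.batch_size == 32

    def test_model2_structure(self):
        spec = M.build_model2()
        convs = [l for l in spec.layers if l.kind == "conv2d"]
        pools = [l for l in spec.layers if l.kind == "maxpool2d"]
        assert [c.filters for c in convs] == [32, 64, 128]
        assert all(c.kernel == 3 and c.stride == 1 for c in convs)
        assert all(p.kernel == 2 and p.stride == 2 for p in pools)
        assert spec.input_shape == (128, 128, 3)
        # batchnorm directly after every pooling layer
        kinds = [l.kind for l in spec.layers]
        for i, kind in enumerate(kinds):
            if kind == "maxpool2d":
                assert kinds[i + 1] == "batchnorm"
        drop = [l for l in spec.layers if l.kind == "dropout"]
        assert len(drop) == 1 and drop[0].rate == 0.5
        assert spec.train_config.epochs == 100

    def test_model3_structure(self):
        spec = M.build_model3()
        assert spec.input_shape == (64, 64, 3)
        lstms = [l for l in spec.layers if l.kind == "lstm"]
        assert [l.units for l in lstms] == [64, 128]
        assert lstms[0].return_sequences and not lstms[1].return_sequences
        convs = [l for l in spec.layers if l.kind == "conv2d"]
        assert [c.filters for c in convs] == [32, 64]
        drops = [l for l in spec.layers if l.kind == "dropout"]
        assert len(drops) == 1 and drops[0].rate == 0.2
        assert spec.train_config.epochs == 50

    def test_builders_are_pure(self):
        assert M.build_model2() == M.build_model2()
        assert M.build_model1((10, 5)) == M.build_model1((10, 5))

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            M.build_model1((0, 13))


class TestCountParameters:
    def test_dense_example(self):
        spec = M.ModelSpec(
            "model1", (10,), (M.LayerSpec("softmax", units=2),)
        )
        assert M.count_parameters(spec) == 22

    def test_conv_example(self):
        spec = M.ModelSpec(
            "model2",
            (8, 8, 3),
            (M.LayerSpec("conv2d", filters=32, kernel=3, stride=1),
             M.LayerSpec("flatten"),
             M.LayerSpec("softmax", units=2)),
        )
        # brute-force index count: (3*3*3 + 1) * 32 = 896
        assert M.count_parameters(spec) - (6 * 6 * 32 + 1) * 2 == 896

    def test_lstm_example(self):
        spec = M.ModelSpec(
            "model1",
            (5, 13),
            (M.LayerSpec("lstm", units=128), M.LayerSpec("softmax", units=2)),
        )
        assert M.count_parameters(spec) - (128 + 1) * 2 == 72704

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        units=st.integers(1, 16),
        filters=st.integers(1, 8),
        dense=st.integers(1, 16),
        side=st.integers(8, 16),
    )
    def test_matches_brute_force_enumeration(self, units, filters, dense, side):
        spec = M.ModelSpec(
            "model3",
            (side, side, 3),
            (
                M.LayerSpec("conv2d", filters=filters, kernel=3, stride=1),
                M.LayerSpec("maxpool2d", kernel=2, stride=2),
                M.LayerSpec("batchnorm"),
                M.LayerSpec("flatten_seq"),
                M.LayerSpec("lstm", units=units, return_sequences=True),
                M.LayerSpec("lstm", units=units),
                M.LayerSpec("dense", units=dense, activation="relu"),
                M.LayerSpec("softmax", units=2),
            ),
        )
        assert M.count_parameters(spec) == brute_force_count(spec)

    def test_matches_instantiated_backend(self):
        """The compiled numpy network allocates exactly the counted weights."""
        for spec in (M.build_model3(), M.build_model1((20, 13))):
            net = M.compile_network(spec, seed=0)
            assert net.n_params() == M.count_parameters(spec)

    def test_shape_error_names_layer(self):
        spec = M.ModelSpec(
            "model2", (4, 4, 3),
            (M.LayerSpec("conv2d", filters=4, kernel=3),
             M.LayerSpec("maxpool2d", kernel=2, stride=2),
             M.LayerSpec("conv2d", filters=4, kernel=3),
             M.LayerSpec("flatten"),
             M.LayerSpec("softmax", units=2)),
        )
        with pytest.raises(M.ShapeInferenceError, match="conv2d"):
            M.count_parameters(spec)


@pytest.fixture(scope="module")
def toy_sequences():
    rng = np.random.default_rng(6)
    x = rng.standard_normal((24, 10, 3))
    y = np.array(["normal", "abnormal"] * 12)
    x[y == "abnormal"] += 1.5
    return x, y


class TestTrainPredict:
    def test_history_has_one_entry_per_epoch(self, toy_sequences):
        x, y = toy_sequences
        spec = M.build_model1((10, 3), dense_units=8, lstm_units=8, epochs=4)
        _, hist = M.train(spec, x, y)
        assert hist.n_epochs == 4

    def test_zero_learning_rate_leaves_weights_untouched(self, toy_sequences):
        """No-update limit: lr=0 training returns the initial weights
        (per-epoch losses still jitter through the dropout masks)."""
        x, y = toy_sequences
        spec = M.build_model1((10, 3), dense_units=8, lstm_units=8, epochs=3)
        config = M.TrainConfig(epochs=3, learning_rate=0.0, seed=5)
        net, _ = M.train(spec, x, y, config)
        fresh = M.compile_network(spec, seed=config.seed)
        for trained_layer, fresh_layer in zip(net.layers, fresh.layers):
            for name in trained_layer.params:
                assert np.array_equal(trained_layer.params[name], fresh_layer.params[name])

    def test_single_class_rejected(self, toy_sequences):
        x, _ = toy_sequences
        spec = M.build_model1((10, 3), dense_units=8, lstm_units=8, epochs=2)
        with pytest.raises(ValueError):
            M.train(spec, x, np.array(["normal"] * len(x)))

    def test_predictions_contract(self, toy_sequences):
        x, y = toy_sequences
        spec = M.build_model1((10, 3), dense_units=8, lstm_units=8, epochs=5)
        net, _ = M.train(spec, x, y)
        probs = M.predict_proba(net, x)
        assert probs.shape == (len(x), 2)
        assert np.all(probs >= 0)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6
        labels = M.predict_label(net, x)
        assert set(labels) <= {"normal", "abnormal"}
        # batching preserves order
        assert np.array_equal(labels[:8], M.predict_label(net, x[:8]))

    def test_loss_decreases_on_separable_fixture(self, toy_sequences):
        x, y = toy_sequences
        spec = M.build_model1((10, 3), dense_units=8, lstm_units=8, epochs=15)
        _, hist = M.train(spec, x, y)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_shape_mismatch_rejected(self, toy_sequences):
        x, y = toy_sequences
        spec = M.build_model1((9, 3), dense_units=8, lstm_units=8, epochs=2)
        with pytest.raises(ValueError):
            M.train(spec, x, y)

    def test_training_reproducible(self, toy_sequences):
        x, y = toy_sequences
        spec = M.build_model1((10, 3), dense_units=8, lstm_units=8, epochs=3)
        _, h1 = M.train(spec, x, y)
        _, h2 = M.train(spec, x, y)
        assert h1.train_loss == h2.train_loss


class TestNoLeakage:
    def test_null_murmur_accuracy_near_chance(self):
        """With murmur_gain -> 0 the classes are identically distributed;
        held-out accuracy must sit at chance within sampling error."""
        rng = np.random.default_rng(0)
        recs, labels = [], []
        null = pl.MurmurPreset("VSD", (150.0, 400.0), 1e-9, 0.9)  # vanishing murmur
        for i in range(60):
            cond = "normal" if i % 2 == 0 else null
            recs.append(
                pl.synthesize_recording(cond, heart_rate=70 + ((i // 2) % 10) * 3,
                                        duration=1.0, seed=1000 + i)
            )
            labels.append("normal" if i % 2 == 0 else "abnormal")
        labels = np.array(labels)
        x = pl.MFCCSequenceExtractor(frame_length_s=0.05, hop_length_s=0.05).transform(recs)
        est = LSTMSequenceClassifier(lstm_units=8, dense_units=8, epochs=5, random_state=0)
        est.fit(x[:40], labels[:40])
        acc = float((est.predict(x[40:]) == labels[40:]).mean())
        se = np.sqrt(0.25 / 20)  # binomial sd at p=0.5, n=20
        assert abs(acc - 0.5) <= 3 * se
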