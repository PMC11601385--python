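"""The fusion classifiers: construction, training mechanics, prediction
rules, serial retraining and the logistic baseline."""

import numpy as np
import pandas as pd
import pytest

from drugsens.dataset import ModelInput
from drugsens.errors import ConfigurationError, InputError
from drugsens.models import (ArchitectureSpec, LogisticModel, NeuralClassifier,
                             TrainConfig, build, fit_logistic, predict, train,
                             train_serial)


def toy_inputs(n=60, width=12, seed=0, signal=True):
    """Linearly separable-ish toy data over two blocks."""
    rng = np.random.default_rng(seed)
    xc = rng.random((n, width), dtype=np.float32)
    xl = rng.random((n, width), dtype=np.float32)
    if signal:
        y = ((xc[:, 0] + xl[:, 0]) > 1.0).astype(np.int8)
    else:
        y = rng.integers(0, 2, n).astype(np.int8)
    ids = pd.DataFrame({"cell_line_id": [f"c{i}" for i in range(n)],
                        "compound_id": [f"d{i}" for i in range(n)]})
    return ModelInput(blocks={"compound": xc, "cell": xl}, y=y, ids=ids)


def small_spec(width=12):
    return ArchitectureSpec.fusion_mlp(width=width, hidden=(16, 8),
                                       bottleneck=4, trunk_hidden=(8,))


class TestBuild:
    def test_first_hidden_layer_parameter_count(self):
        model = build(ArchitectureSpec.fusion_mlp())
        first = model.branches[0][0]
        assert first.W.size + first.b.size == 969 * 512 + 512

    def test_total_parameter_count_matches_arithmetic(self):
        model = build(ArchitectureSpec.fusion_mlp())
        widths = [969, 512, 256, 128, 64, 32]
        branch = sum((a + 1) * b for a, b in zip(widths, widths[1:]))
        trunk = (64 + 1) * 64 + 2 * (64 + 1) * 64 + (64 + 1) * 1
        assert model.n_parameters == 2 * branch + trunk

    def test_single_feature_variant_has_one_subnetwork(self):
        model = build(ArchitectureSpec.single_feature("compound"))
        assert len(model.branches) == 1

    def test_triple_variant_has_1024_wide_third_input(self):
        spec = ArchitectureSpec.triple_ecfp4()
        assert spec.input_widths == (969, 969, 1024)
        assert len(build(spec).branches) == 3

    def test_same_seed_identical_initial_weights(self):
        a, b = build(small_spec(), seed=5), build(small_spec(), seed=5)
        for la, lb in zip(a._param_layers(), b._param_layers()):
            assert np.array_equal(la.W, lb.W)

    def test_different_seed_differs(self):
        a, b = build(small_spec(), seed=5), build(small_spec(), seed=6)
        assert not np.array_equal(a.branches[0][0].W, b.branches[0][0].W)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureSpec("fusion-mlp", (0, 969), ("compound", "cell"))


class TestTrain:
    def test_overfits_planted_signal(self):
        inputs = toy_inputs(n=50)
        model = build(small_spec(), seed=1)
        res = model.fit(inputs, TrainConfig(epochs=500, batch_size=50, seed=1))
        _, labels = model.predict(inputs)
        assert (labels == inputs.y).mean() == 1.0
        assert np.isfinite(res.history["loss"]).all()

    def test_zero_epochs_leaves_weights_unchanged(self):
        model = build(small_spec(), seed=2)
        before = [l.W.copy() for l in model._param_layers()]
        model.fit(toy_inputs(), TrainConfig(epochs=0, batch_size=10, seed=2))
        for w, l in zip(before, model._param_layers()):
            assert np.array_equal(w, l.W)

    def test_class_weights_do_not_reduce_recall(self):
        rng = np.random.default_rng(9)
        n = 400
        xc = rng.random((n, 12), dtype=np.float32)
        xl = rng.random((n, 12), dtype=np.float32)
        y = ((xc[:, 0] + xl[:, 0]) > 1.6).astype(np.int8)  # ~8% positive
        ids = pd.DataFrame({"cell_line_id": ["c"] * n, "compound_id": ["d"] * n})
        inputs = ModelInput(blocks={"compound": xc, "cell": xl}, y=y, ids=ids)

        def recall_with(cw):
            model = build(small_spec(), seed=3)
            model.fit(inputs, TrainConfig(epochs=30, batch_size=50, seed=3,
                                          class_weights=cw))
            _, labels = model.predict(inputs)
            tp = int(((labels == 1) & (y == 1)).sum())
            fn = int(((labels == 0) & (y == 1)).sum())
            return tp / (tp + fn)

        assert recall_with((5.0, 1.0)) >= recall_with((1.0, 1.0))

    def test_validation_never_contributes_gradients(self):
        inputs = toy_inputs(seed=4)
        val = toy_inputs(seed=5)
        a = build(small_spec(), seed=7)
        a.fit(inputs, TrainConfig(epochs=5, batch_size=20, seed=7))
        b = build(small_spec(), seed=7)
        res_b = b.fit(inputs, TrainConfig(epochs=5, batch_size=20, seed=7,
                                          validation=val))
        for la, lb in zip(a._param_layers(), b._param_layers()):
            assert np.array_equal(la.W, lb.W)
        assert "val_loss" in res_b.history

    def test_deterministic_history_given_seed(self):
        inputs = toy_inputs()
        r1 = build(small_spec(), seed=8).fit(
            inputs, TrainConfig(epochs=5, batch_size=16, seed=8))
        r2 = build(small_spec(), seed=8).fit(
            inputs, TrainConfig(epochs=5, batch_size=16, seed=8))
        pd.testing.assert_frame_equal(r1.history, r2.history)

    def test_summary_mentions_variant_and_params(self):
        model = build(small_spec(), seed=1)
        res = model.fit(toy_inputs(), TrainConfig(epochs=1, batch_size=30))
        text = res.summary()
        assert "fusion-mlp" in text
        assert f"{model.n_parameters:,}" in text


class TestTrainSerial:
    def test_identical_subsets_equal_one_long_run(self):
        inputs = toy_inputs(n=40, seed=6)
        serial = build(small_spec(), seed=11)
        train_serial(serial, [inputs] * 5,
                     TrainConfig(epochs=2, batch_size=10, seed=11))
        long = build(small_spec(), seed=11)
        long.fit(inputs, TrainConfig(epochs=10, batch_size=10, seed=11))
        for ls, ll in zip(serial._param_layers(), long._param_layers()):
            assert np.allclose(ls.W, ll.W, atol=1e-7)

    def test_history_records_subset_order(self):
        inputs = toy_inputs(n=40)
        res = train_serial(build(small_spec(), seed=1), [inputs] * 3,
                           TrainConfig(epochs=1, batch_size=10, seed=1))
        assert res.subset_order == (1, 2, 3)
        assert res.history["subset"].tolist() == [1, 2, 3]

    def test_differs_from_single_subset_training(self):
        full = toy_inputs(n=60, seed=1)
        parts = [full.take(np.arange(i, 60, 5)) for i in range(5)]
        serial = build(small_spec(), seed=2)
        train_serial(serial, parts, TrainConfig(epochs=3, batch_size=12, seed=2))
        single = build(small_spec(), seed=2)
        single.fit(parts[0], TrainConfig(epochs=3, batch_size=12, seed=2))
        diff = sum(np.linalg.norm(a.W - b.W) for a, b in
                   zip(serial._param_layers(), single._param_layers()))
        assert diff > 0


class TestPredict:
    def test_cutoff_rule_at_half(self):
        proba = np.array([0.5, 0.499, 0.9, 0.1])
        labels = (proba >= 0.5).astype(int)
        assert labels.tolist() == [1, 0, 1, 0]

    def test_binary_labels_from_predict(self):
        model = build(small_spec(), seed=1)
        _, labels = predict(model, toy_inputs(n=10))
        assert all(l.metric == "prediction" and l.cutoff == 0.5 for l in labels)

    def test_untrained_outputs_in_open_unit_interval(self):
        model = build(ArchitectureSpec.fusion_mlp(), seed=1)
        inputs = ModelInput(
            blocks={"compound": np.random.default_rng(0).random(
                        (5, 969), dtype=np.float32),
                    "cell": np.random.default_rng(1).random(
                        (5, 969), dtype=np.float32)},
            y=np.zeros(5, dtype=np.int8),
            ids=pd.DataFrame({"cell_line_id": ["c"] * 5,
                              "compound_id": ["d"] * 5}))
        proba = model.predict_proba(inputs)
        assert np.all((proba > 0) & (proba < 1))

    def test_order_equivariance(self):
        model = build(small_spec(), seed=1)
        inputs = toy_inputs(n=20)
        perm = np.random.default_rng(2).permutation(20)
        a = model.predict_proba(inputs)
        b = model.predict_proba(inputs.take(perm))
        assert np.allclose(a[perm], b)

    def test_width_mismatch_rejected(self):
        model = build(small_spec(width=12), seed=1)
        bad = toy_inputs(width=13)
        with pytest.raises(InputError):
            model.predict_proba(bad)

    def test_save_load_round_trip(self, tmp_path):
        model = build(small_spec(), seed=1)
        inputs = toy_inputs(n=20)
        model.fit(inputs, TrainConfig(epochs=2, batch_size=10, seed=1))
        path = tmp_path / "model.npz"
        model.save(path)
        back = NeuralClassifier.load(path)
        assert np.allclose(model.predict_proba(inputs),
                           back.predict_proba(inputs))


class TestCNNVariant:
    def test_smoke_train_and_predict(self):
        spec = ArchitectureSpec.fusion_cnn2d(width=100, conv_channels=(4, 8))
        inputs = toy_inputs(n=30, width=100, seed=3)
        model = build(spec, seed=3)
        model.fit(inputs, TrainConfig(epochs=2, batch_size=15, seed=3))
        proba = model.predict_proba(inputs)
        assert proba.shape == (30,)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_gradient_matches_finite_difference(self):
        # spot-check the conv backward pass against numerical differentiation
        from drugsens.models import _Conv3x3

        rng = np.random.default_rng(0)
        layer = _Conv3x3(1, 2, rng)
        x = rng.standard_normal((2, 6, 6, 1)).astype(np.float32)
        out = layer.forward(x, training=True)
        g = np.ones_like(out)
        layer.backward(g)
        eps = 1e-3
        i = (0, 1, 0, 1)
        w0 = layer.W[i]
        layer.W[i] = w0 + eps
        up = layer.forward(x).sum()
        layer.W[i] = w0 - eps
        down = layer.forward(x).sum()
        layer.W[i] = w0
        numeric = (up - down) / (2 * eps)
        assert layer.gW[i] == pytest.approx(numeric, rel=2e-2)


class TestLogisticBaseline:
    def test_zero_coefficients_predict_half(self):
        model = LogisticModel(intercept=0.0, coef=np.zeros(24),
                              block_names=("compound", "cell"))
        proba = model.predict_proba(toy_inputs(n=10))
        assert np.allclose(proba, 0.5)

    def test_symmetric_one_feature_mle(self):
        rng = np.random.default_rng(0)
        n = 400
        x = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        noise = rng.random(n) < 0.2  # flip 20% so the MLE is finite
        y = np.where(noise, 1 - x, x).astype(np.int8)
        inputs = ModelInput(
            blocks={"compound": x[:, None].astype(np.float32),
                    "cell": np.zeros((n, 1), np.float32)},
            y=y, ids=pd.DataFrame({"cell_line_id": ["c"] * n,
                                   "compound_id": ["d"] * n}))
        model = fit_logistic(inputs)
        mid = ModelInput(
            blocks={"compound": np.array([[0.5]], np.float32),
                    "cell": np.zeros((1, 1), np.float32)},
            y=np.zeros(1, np.int8),
            ids=pd.DataFrame({"cell_line_id": ["c"], "compound_id": ["d"]}))
        assert model.predict_proba(mid)[0] == pytest.approx(0.5, abs=0.05)

    def test_perfect_separation_triggers_regularized_fallback(self):
        x = np.array([0.0, 1.0], np.float32)
        inputs = ModelInput(
            blocks={"compound": x[:, None], "cell": np.zeros((2, 1), np.float32)},
            y=np.array([0, 1], np.int8),
            ids=pd.DataFrame({"cell_line_id": ["a", "b"],
                              "compound_id": ["x", "y"]}))
        model = fit_logistic(inputs)
        assert model.regularized

    def test_one_class_rejected(self):
        inputs = toy_inputs(n=10)
        inputs.y[:] = 0
        with pytest.raises(InputError):
            fit_logistic(inputs)


def test_fingerprint_substituted_variant_end_to_end():
    """Assemble records with a 1024-bit fingerprint block and train the
    fingerprint-for-signature substitution variant."""
    import pandas as pd
    from drugsens.chem import fingerprint_table, toy_smiles_library
    from drugsens.dataset import assemble
    from drugsens.signatures import SignatureMatrix, rescale_unit

    genes = [f"G{i}" for i in range(8)]
    lib = toy_smiles_library(3)
    fps = fingerprint_table(lib)
    fp_table = pd.DataFrame([fp.bits for fp in fps],
                            index=lib["compound_id"]).astype(np.float32)
    rng = np.random.default_rng(0)
    tcs = rescale_unit(SignatureMatrix(pd.DataFrame(
        rng.random((8, 3)) * 4, index=genes, columns=lib["compound_id"])))
    cells = rescale_unit(SignatureMatrix(pd.DataFrame(
        rng.random((8, 2)) * 4, index=genes, columns=["c1", "c2"])))
    records = pd.DataFrame({
        "cell_line_id": ["c1", "c2", "c1", "c2"],
        "compound_id": [lib["compound_id"][0], lib["compound_id"][1],
                        lib["compound_id"][2], lib["compound_id"][0]],
        "score": [0.1, 0.0, 0.2, 0.0], "metric": ["DSS3"] * 4,
        "label": [1, 0, 1, 0]})
    inputs, report = assemble(records, tcs, cells, fingerprints=fp_table)
    assert report["n_assembled"] == 4
    assert inputs.blocks["fingerprint"].shape == (4, 1024)

    spec = ArchitectureSpec.ecfp4_substituted(width=8, hidden=(8,),
                                              bottleneck=4, trunk_hidden=(8,))
    model = build(spec, seed=1)
    model.fit(inputs, TrainConfig(epochs=2, batch_size=4, seed=1))
    proba = model.predict_proba(inputs)
    assert np.all((proba > 0) & (proba < 1))
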