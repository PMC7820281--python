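import numpy as np
import pandas as pd
import pytest

from mvpscore.resnet import (
    ModelConfig,
    ResNetModel,
    build_model,
    conv_stack_param_count,
    crossvalidate,
    flattened_length,
    predict_raw,
    train,
    _bce_from_logits,
    _conv1d_forward,
    _maxpool_forward,
    _relu,
)
from mvpscore.features import FeatureOrder
from mvpscore.variants import FeatureMatrix


def _separable(n, n_features, rng, shift=3.0):
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.standard_normal((n, n_features))
    X[:, 0] += shift * y
    X[:, 1] -= shift * y
    return X, y


TINY = dict(n_kernels=8, fc_hidden=16, batch_size=32, learning_rate=1e-3,
            max_cycles=40)


class TestArchitecture:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_features=38),
            dict(n_features=21),
            dict(n_features=38, n_kernels=16, kernel_size=5),
            dict(n_features=10, n_residual_units=3, n_kernels=8),
        ],
    )
    def test_param_count_closed_form_matches_tensors(self, kwargs):
        cfg = ModelConfig(**kwargs)
        model = build_model(cfg)
        literal = sum(
            v.size for k, v in model.params.items() if not k.startswith("fc")
        )
        assert literal == conv_stack_param_count(cfg)

    def test_flattened_length_halves_with_ceiling(self):
        assert flattened_length(ModelConfig(n_features=38)) == 320  # 38->19->10
        assert flattened_length(ModelConfig(n_features=21)) == 192  # 21->11->6

    def test_fc_weight_shapes(self):
        model = build_model(ModelConfig(n_features=38))
        assert model.params["fc1_w"].shape == (320, 512)
        assert model.params["fc2_w"].shape == (512, 1)

    def test_zero_weights_forward_is_half(self):
        model = build_model(ModelConfig(n_features=38))
        for k in model.params:
            model.params[k][:] = 0.0
        out = predict_raw(model, np.zeros((4, 38)))
        assert np.all(out == 0.5)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_features=2, kernel_size=3)

    def test_residual_unit_with_zero_convs_is_pool_of_relu(self):
        # zeroing the residual-branch convolutions must leave the identity
        # shortcut: each unit reduces to pool(relu(input))
        cfg = ModelConfig(n_features=11, n_kernels=4, fc_hidden=8)
        model = build_model(cfg)
        for name in model.params:
            if name.startswith("ru"):
                model.params[name][:] = 0.0
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 11))
        h, _ = _conv1d_forward(x[:, None, :], model.params["conv0_w"],
                               model.params["conv0_b"])
        for _ in range(cfg.n_residual_units):
            h, _ = _maxpool_forward(_relu(h), cfg.pool_size)
        expected = h.reshape(3, -1) @ model.params["fc1_w"] + model.params["fc1_b"]
        expected = _relu(expected) @ model.params["fc2_w"] + model.params["fc2_b"]
        got = model.predict_logits(x)
        assert np.allclose(got, expected[:, 0], atol=1e-12)


class TestTraining:
    def test_learns_separable_data(self):
        from mvpscore.evaluation import roc_auc

        rng = np.random.default_rng(1)
        X, y = _separable(600, 8, rng)
        cfg = ModelConfig(n_features=8, seed=2, **TINY)
        model = train(build_model(cfg), X[:500], y[:500])
        auc = roc_auc(y[500:], predict_raw(model, X[500:])).auc
        assert auc >= 0.95

    def test_fixed_seed_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        X, y = _separable(200, 6, rng)
        cfg = ModelConfig(n_features=6, seed=11, max_cycles=5, n_kernels=4,
                          fc_hidden=8, batch_size=32)
        m1 = train(build_model(cfg), X, y)
        m2 = train(build_model(cfg), X, y)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])
        assert m1.history == m2.history

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 6))
        cfg = ModelConfig(n_features=6, batch_size=32)
        with pytest.raises(ValueError, match="single class"):
            train(build_model(cfg), X, np.ones(100))

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(5)
        X, y = _separable(50, 6, rng)
        with pytest.raises(ValueError, match="at least"):
            train(build_model(ModelConfig(n_features=6, batch_size=64)), X, y)

    def test_restored_weights_attain_minimum_validation_loss(self):
        rng = np.random.default_rng(6)
        X, y = _separable(300, 6, rng, shift=1.0)
        cfg = ModelConfig(n_features=6, seed=7, max_cycles=30, n_kernels=4,
                          fc_hidden=8, batch_size=32, learning_rate=3e-3)
        model = train(build_model(cfg), X, y)
        recorded = [h["val_loss"] for h in model.history]
        # reconstruct the validation split exactly as train() drew it
        split_rng = np.random.default_rng(cfg.seed)
        perm = split_rng.permutation(len(X))
        n_val = max(1, int(round(cfg.validation_fraction * len(X))))
        val = perm[:n_val]
        final = _bce_from_logits(model.predict_logits(X[val]), y[val])
        assert final == pytest.approx(min(recorded), abs=1e-12)
        assert all(final <= v + 1e-12 for v in recorded)

    def test_disjoint_partition_models_do_not_share_weights(self):
        rng = np.random.default_rng(8)
        Xa, ya = _separable(200, 6, rng)
        Xb, yb = _separable(200, 6, rng)
        cfg = ModelConfig(n_features=6, seed=9, max_cycles=5, n_kernels=4,
                          fc_hidden=8, batch_size=32)
        ma = train(build_model(cfg), Xa, ya, partition="constrained")
        mb = train(build_model(cfg), Xb, yb, partition="nonconstrained")
        assert ma.partition != mb.partition
        assert any(
            not np.array_equal(ma.params[k], mb.params[k]) for k in ma.params
        )


class TestPredictRaw:
    def test_scores_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(10)
        model = build_model(ModelConfig(n_features=8, n_kernels=4, fc_hidden=8))
        out = predict_raw(model, rng.standard_normal((20, 8)) * 10)
        assert np.all((out > 0.0) & (out < 1.0))

    def test_duplicated_rows_get_identical_scores(self):
        rng = np.random.default_rng(11)
        model = build_model(ModelConfig(n_features=8, n_kernels=4, fc_hidden=8))
        row = rng.standard_normal((1, 8))
        out = predict_raw(model, np.vstack([row, row]))
        assert out[0] == out[1]

    def test_batch_size_invariance(self):
        rng = np.random.default_rng(12)
        model = build_model(ModelConfig(n_features=8, n_kernels=4, fc_hidden=8))
        X = rng.standard_normal((40, 8))
        whole = predict_raw(model, X)
        singles = np.array([predict_raw(model, X[i : i + 1])[0] for i in range(40)])
        assert np.allclose(whole, singles, atol=1e-6)

    def test_feature_name_mismatch_rejected(self):
        model = build_model(ModelConfig(n_features=3, n_kernels=4, fc_hidden=8))
        model.feature_order = FeatureOrder(names=("a", "b", "c"))
        fm = FeatureMatrix(pd.DataFrame({"a": [0.1], "b": [0.2], "x": [0.3]}))
        with pytest.raises(ValueError, match="feature names"):
            predict_raw(model, fm)

    def test_feature_matrix_reordered_to_fitted_order(self):
        model = build_model(ModelConfig(n_features=3, n_kernels=4, fc_hidden=8))
        model.feature_order = FeatureOrder(names=("c", "a", "b"))
        fm = FeatureMatrix(pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}))
        direct = predict_raw(model, np.array([[3.0, 1.0, 2.0]]))
        assert predict_raw(model, fm)[0] == direct[0]


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        X, y = _separable(200, 6, rng)
        cfg = ModelConfig(n_features=6, seed=1, max_cycles=3, n_kernels=4,
                          fc_hidden=8, batch_size=32)
        model = train(
            build_model(cfg), X, y,
            feature_order=FeatureOrder(names=tuple(f"f{i}" for i in range(6))),
            partition="constrained",
        )
        model.save(tmp_path / "model")
        loaded = ResNetModel.load(tmp_path / "model")
        assert loaded.partition == "constrained"
        assert loaded.feature_order == model.feature_order
        assert np.array_equal(
            predict_raw(loaded, X[:10]), predict_raw(model, X[:10])
        )


class TestCrossvalidate:
    def test_perfect_feature_four_points(self):
        X = np.array(
            [[3.0, 0.0, 0.1], [3.0, 0.1, 0.0], [-3.0, 0.0, 0.1], [-3.0, 0.1, 0.0]]
        )
        y = np.array([1, 1, 0, 0])
        cfg = ModelConfig(n_features=3, n_kernels=4, fc_hidden=8, batch_size=1,
                          learning_rate=5e-2, max_cycles=60, seed=0)
        res = crossvalidate(X, y, k=2, config=cfg)
        assert res["fold_aucs"] == [1.0, 1.0]

    def test_separable_mean_auc(self):
        rng = np.random.default_rng(14)
        X, y = _separable(360, 6, rng)
        cfg = ModelConfig(n_features=6, seed=5, n_kernels=8, fc_hidden=16,
                          batch_size=32, learning_rate=1e-3, max_cycles=30)
        res = crossvalidate(X, y, k=3, config=cfg)
        assert res["mean_auc"] >= 0.95

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(15)
        X, y = _separable(360, 6, rng)
        y_shuffled = rng.permutation(y)
        cfg = ModelConfig(n_features=6, seed=5, n_kernels=4, fc_hidden=8,
                          batch_size=32, learning_rate=1e-3, max_cycles=10)
        res = crossvalidate(X, y_shuffled, k=3, config=cfg)
        assert 0.3 <= res["mean_auc"] <= 0.7

    def test_k_exceeding_class_count_rejected(self):
        X = np.zeros((6, 3))
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="smallest class"):
            crossvalidate(X, y, k=3)
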