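import math

import numpy as np
import pytest

from osteotex import (
    InputError,
    MinMaxScaler,
    NetworkModel,
    TrainConfig,
    backprop_gradient,
    evaluate,
    fit_modulus_network,
    forward,
    init_network,
    load_model,
    parametric_study,
    save_model,
    split_dataset,
    train,
)
from oracles import central_difference_gradients


def _mse(net, x, y):
    return float(np.mean((forward(net, x) - y) ** 2))


class TestInitNetwork:
    def test_same_seed_identical(self):
        a, b = init_network(5, seed=3), init_network(5, seed=3)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.b1, b.b1)
        assert np.array_equal(a.W2, b.W2) and np.array_equal(a.b2, b.b2)

    def test_parameter_ranges(self):
        net = init_network(500, seed=0, n_inputs=6)  # ~3000 weight draws
        for w in (net.W1, net.W2):
            assert w.min() >= -1.0 and w.max() <= 1.0
        for b in (net.b1, net.b2):
            assert b.min() >= 0.0 and b.max() <= 1.0

    def test_hidden_40_shapes(self):
        net = init_network(40, seed=1)
        assert net.W1.shape == (40, 6)
        assert net.W2.shape == (1, 40)

    def test_invalid_hidden_size(self):
        with pytest.raises(InputError):
            init_network(0, seed=0)


class TestForward:
    def test_null_network_outputs_zero(self):
        net = NetworkModel(
            W1=np.zeros((3, 6)), b1=np.zeros(3), W2=np.zeros((1, 3)), b2=np.zeros(1)
        )
        assert forward(net, np.zeros(6)) == 0.0

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        net = init_network(10, seed=0)
        out = forward(net, rng.uniform(-5, 5, (100, 6)))
        assert np.all(np.abs(out) < 1.0)

    def test_single_hidden_unit_hand_composition(self):
        """y = tanh(w2 * tanh(w1 . x + b1) + b2) evaluated by hand."""
        net = NetworkModel(
            W1=np.array([[0.5, -0.25, 0.1, 0.0, 0.2, -0.3]]),
            b1=np.array([0.4]),
            W2=np.array([[0.8]]),
            b2=np.array([0.1]),
        )
        x = np.array([1.0, 2.0, -1.0, 0.5, 0.0, 3.0])
        z1 = 0.5 * 1 - 0.25 * 2 + 0.1 * -1 + 0.2 * 0.0 - 0.3 * 3 + 0.4
        expected = math.tanh(0.8 * math.tanh(z1) + 0.1)
        assert forward(net, x) == pytest.approx(expected, rel=1e-15)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InputError):
            forward(init_network(2, seed=0), np.array([np.nan] * 6))


class TestBackpropGradient:
    @pytest.mark.parametrize("seed,hidden,batch", [(0, 3, 5), (1, 7, 12), (2, 10, 1)])
    def test_matches_central_finite_differences(self, seed, hidden, batch):
        rng = np.random.default_rng(seed)
        net = init_network(hidden, seed=seed)
        x = rng.uniform(-1, 1, (batch, 6))
        y = rng.uniform(-0.9, 0.9, batch)
        grads, _ = backprop_gradient(net, x, y)
        ref = central_difference_gradients(net, x, y, _mse, eps=1e-6)
        for name in ("W1", "b1", "W2", "b2"):
            a, n = getattr(grads, name), ref[name]
            assert np.linalg.norm(a - n) <= 1e-6 * max(np.linalg.norm(n), 1e-6)

    def test_zero_error_batch_zero_gradient(self):
        net = init_network(4, seed=3)
        x = np.random.default_rng(3).uniform(-1, 1, (6, 6))
        y = forward(net, x)  # targets equal outputs
        grads, mse = backprop_gradient(net, x, y)
        assert mse == 0.0
        for name in ("W1", "b1", "W2", "b2"):
            assert np.allclose(getattr(grads, name), 0.0)

    def test_single_parameter_closed_form(self):
        """1-input, 1-hidden net with only w2 nonzero: dMSE/dw2 has the
        closed form 2(yhat - y)(1 - yhat^2) h."""
        net = NetworkModel(
            W1=np.array([[0.7]]), b1=np.array([0.2]),
            W2=np.array([[0.5]]), b2=np.array([0.0]),
        )
        x, y = np.array([[0.3]]), np.array([0.1])
        h = math.tanh(0.7 * 0.3 + 0.2)
        yhat = math.tanh(0.5 * h)
        expected = 2 * (yhat - 0.1) * (1 - yhat**2) * h
        grads, _ = backprop_gradient(net, x, y)
        assert grads.W2[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(InputError):
            backprop_gradient(init_network(2, seed=0), np.empty((0, 6)), np.empty(0))


class TestSplitDataset:
    def test_paper_scale_split(self):
        tr, va, te = split_dataset(300, seed=0)
        assert (len(tr), len(va), len(te)) == (210, 45, 45)

    def test_minimum_size_split(self):
        tr, va, te = split_dataset(10, seed=0)
        assert (len(tr), len(va), len(te)) == (7, 1, 2)

    def test_same_seed_same_split(self):
        assert all(
            np.array_equal(a, b)
            for a, b in zip(split_dataset(50, seed=9), split_dataset(50, seed=9))
        )

    @pytest.mark.parametrize("seed", range(100))
    def test_disjoint_and_exhaustive(self, seed):
        tr, va, te = split_dataset(37, seed=seed)
        joined = np.concatenate([tr, va, te])
        assert len(joined) == 37
        assert len(set(joined.tolist())) == 37

    def test_too_small_rejected(self):
        with pytest.raises(InputError):
            split_dataset(9)


class TestScaler:
    @pytest.mark.parametrize("seed", range(5))
    def test_invert_after_apply_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(500, 200, (40, 6))
        s = MinMaxScaler().fit(x)
        assert np.allclose(s.inverse(s.transform(x)), x, atol=1e-12 * 1000)

    def test_transform_reaches_feature_range(self):
        x = np.array([[0.0], [10.0]])
        s = MinMaxScaler().fit(x)
        assert s.transform(x).tolist() == [[-1.0], [1.0]]

    def test_constant_column_round_trips(self):
        x = np.full((5, 2), 7.0)
        s = MinMaxScaler().fit(x)
        assert np.allclose(s.inverse(s.transform(x)), x)


class TestTrain:
    def test_converges_on_realizable_task(self):
        """A target generated by a small teacher network is driven below
        1e-3 training MSE."""
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, (60, 6))
        y = forward(init_network(3, seed=5), x)
        cfg = TrainConfig(
            max_epochs=4000, learning_rate=0.1, momentum=0.9,
            max_validation_failures=4000, seed=1,
        )
        net, hist = train(init_network(8, seed=1), x, y, cfg)
        assert min(hist.train_mse) < 1e-3
        assert hist.stop_reason in {"max_epochs", "goal"}

    def test_monotone_descent_without_momentum(self):
        """With momentum 0 and a small step, full-batch descent does not
        increase the training MSE."""
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, (30, 6))
        y = 0.3 * x[:, 0]
        cfg = TrainConfig(
            max_epochs=300, learning_rate=0.005, momentum=0.0,
            max_validation_failures=300, seed=2,
        )
        _, hist = train(init_network(4, seed=2), x, y, cfg)
        diffs = np.diff(hist.train_mse)
        assert np.all(diffs <= 1e-12)

    def test_early_stopping_returns_best_validation_epoch(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, (40, 6))
        y = 0.5 * x[:, 1] + 0.05 * rng.normal(size=40)
        xv = rng.uniform(-1, 1, (10, 6))
        yv = 0.5 * xv[:, 1]
        cfg = TrainConfig(
            max_epochs=2000, learning_rate=0.05, max_validation_failures=10, seed=4
        )
        net, hist = train(init_network(6, seed=4), x, y, cfg, val=(xv, yv))
        best_val = min(hist.val_mse)
        assert np.mean((forward(net, xv) - yv) ** 2) == pytest.approx(best_val)

    def test_zero_patience_rejected(self):
        with pytest.raises(InputError):
            TrainConfig(max_validation_failures=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        net = init_network(4, seed=0)
        x = np.random.default_rng(0).uniform(-1, 1, (20, 6))
        y = forward(net, x)
        res = evaluate(net, x, y)
        assert res.mse == 0.0
        assert res.r == pytest.approx(1.0)

    def test_anti_correlated_predictions(self):
        net = init_network(4, seed=1)
        x = np.random.default_rng(1).uniform(-1, 1, (20, 6))
        y = -forward(net, x)
        assert evaluate(net, x, y).r == pytest.approx(-1.0)

    def test_three_point_hand_pearson(self):
        """R against the closed-form Pearson formula on 3 points."""
        net = init_network(2, seed=2)
        x = np.random.default_rng(2).uniform(-1, 1, (3, 6))
        pred = forward(net, x)
        y = np.array([0.2, -0.1, 0.4])
        pm, ym = pred.mean(), y.mean()
        r_hand = np.sum((pred - pm) * (y - ym)) / math.sqrt(
            np.sum((pred - pm) ** 2) * np.sum((y - ym) ** 2)
        )
        assert evaluate(net, x, y).r == pytest.approx(r_hand, rel=1e-12)

    def test_constant_targets_flagged(self):
        net = init_network(2, seed=3)
        x = np.random.default_rng(3).uniform(-1, 1, (5, 6))
        res = evaluate(net, x, np.full(5, 0.3))
        assert not res.r_defined


class TestParametricStudy:
    @pytest.fixture(scope="class")
    def small_dataset(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-1, 1, (60, 6))
        y = np.tanh(x[:, 0] - 0.5 * x[:, 2]) + 0.05 * rng.normal(size=60)
        return x, y

    def test_table_shape_and_best_flag(self, small_dataset):
        x, y = small_dataset
        cfg = TrainConfig(max_epochs=200, learning_rate=0.05,
                          max_validation_failures=50, seed=7)
        table, best = parametric_study(x, y, [4, 8, 12], cfg)
        assert len(table) == 3
        assert table.best.sum() == 1
        assert best.net.hidden_size == table.loc[table.best, "hidden_size"].iloc[0]
        assert {"train_mse", "val_mse", "train_r", "val_r", "epochs"} <= set(
            table.columns
        )

    def test_repeated_size_identical_rows(self, small_dataset):
        x, y = small_dataset
        cfg = TrainConfig(max_epochs=100, learning_rate=0.05,
                          max_validation_failures=50, seed=7)
        table, _ = parametric_study(x, y, [6, 6], cfg)
        a, b = table.iloc[0], table.iloc[1]
        assert a.train_mse == b.train_mse and a.val_r == b.val_r

    def test_constant_targets_all_rows_flagged(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-1, 1, (30, 6))
        y = np.full(30, 1.5)
        cfg = TrainConfig(max_epochs=20, max_validation_failures=20, seed=8)
        table, _ = parametric_study(x, y, [3, 5], cfg)
        assert table.val_r.isna().all()


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, (40, 6))
        y = x[:, 0] + 0.1 * rng.normal(size=40)
        cfg = TrainConfig(max_epochs=100, learning_rate=0.05,
                          max_validation_failures=50, seed=11)
        fit = fit_modulus_network(x, y, hidden_size=5, config=cfg,
                                  texture_config={"ng": 8})
        path = tmp_path / "model.json"
        save_model(fit, path)
        loaded = load_model(path)
        xnew = rng.uniform(0, 10, (7, 6))
        assert np.allclose(fit.predict(xnew), loaded.predict(xnew), atol=1e-12)
        assert loaded.texture_config == {"ng": 8}
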