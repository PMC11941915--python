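import numpy as np
import pytest

from granarywatch import nn
from granarywatch.forecaster import (
    ConvSpec,
    ForecastConfig,
    LstmCellParams,
    WindowSample,
    build_forecaster,
    conv3d_reference,
    forecast,
    lstm_cell_reference,
    make_windows,
    persistence_baseline,
    split_windows,
    train_forecaster,
    evaluate_windows,
)
from granarywatch.nn.layers import LSTMLayer
from granarywatch.sim import SimConfig, build_forecast_dataset, simulate_series

LIGHT = ForecastConfig(
    lstm_hidden=16, lstm_layers=2, conv_channels=4, embed_dim=32,
    dropout=0.0, window=10, horizon=3, max_epochs=3, patience=2,
    batch_size=8, seed=0,
)


@pytest.fixture(scope="module")
def short_series():
    return simulate_series(SimConfig(n_days=60, seed=3))


class TestConvOracle:
    def test_identity_kernel(self):
        x = np.arange(27.0).reshape(3, 3, 3)
        out = conv3d_reference(x, ConvSpec(weights=np.ones((1, 1, 1))))
        assert np.array_equal(out, x)

    def test_counting_kernel(self):
        out = conv3d_reference(np.ones((3, 3, 3)), ConvSpec(weights=np.ones((2, 2, 2))))
        assert out.shape == (2, 2, 2)
        assert np.all(out == 8.0)

    def test_bias_added(self):
        out = conv3d_reference(np.zeros((2, 2, 2)), ConvSpec(np.ones((1, 1, 1)), bias=2.5))
        assert np.all(out == 2.5)

    def test_matches_production_convolution(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_normal((4, 3, 3))
            w = rng.standard_normal((2, 2, 2))
            b = rng.standard_normal()
            ref = conv3d_reference(x, ConvSpec(weights=w, bias=b))
            prod = nn.conv3d(
                nn.Tensor(x[None, None]), nn.Tensor(w[None, None]), nn.Tensor([b])
            ).data[0, 0]
            assert np.allclose(ref, prod, atol=1e-6)

    def test_kernel_too_large_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            conv3d_reference(np.ones((2, 2, 2)), ConvSpec(np.ones((3, 3, 3))))


class TestLstmOracle:
    def _zero_params(self, f, h):
        z = lambda *s: np.zeros(s)
        return LstmCellParams(
            w_f=z(f, h), u_f=z(h, h), b_f=z(h),
            w_i=z(f, h), u_i=z(h, h), b_i=z(h),
            w_c=z(f, h), u_c=z(h, h), b_c=z(h),
            w_o=z(f, h), u_o=z(h, h), b_o=z(h),
        )

    def test_zero_weights_half_gates(self):
        params = self._zero_params(3, 4)
        c_prev = np.full((1, 4), 0.6)
        h_t, c_t, gates = lstm_cell_reference(np.ones((1, 3)), np.zeros((1, 4)), c_prev, params)
        assert np.allclose(gates["f"], 0.5)
        assert np.allclose(gates["i"], 0.5)
        assert np.allclose(gates["o"], 0.5)
        assert np.allclose(c_t, 0.5 * c_prev)
        assert np.allclose(h_t, 0.5 * np.tanh(c_t))

    def test_saturated_gates_preserve_cell(self):
        params = self._zero_params(2, 3)
        params.b_f += 50.0  # forget gate ~ 1
        params.b_i -= 50.0  # input gate ~ 0
        c_prev = np.array([[0.3, -0.2, 0.7]])
        _, c_t, _ = lstm_cell_reference(np.ones((1, 2)), np.zeros((1, 3)), c_prev, params)
        assert np.allclose(c_t, c_prev, atol=1e-6)

    def test_matches_production_layer_over_steps(self):
        rng = np.random.default_rng(6)
        layer = LSTMLayer(5, 7, rng)
        params = LstmCellParams.from_layer(layer)
        x = rng.standard_normal((2, 10, 5))
        outputs, (h_prod, c_prod) = layer(nn.Tensor(x))
        h = np.zeros((2, 7))
        c = np.zeros((2, 7))
        for t in range(10):
            h, c, _ = lstm_cell_reference(x[:, t], h, c, params)
            assert np.allclose(h, outputs[t].data, atol=1e-5)
        assert np.allclose(h, h_prod.data, atol=1e-5)
        assert np.allclose(c, c_prod.data, atol=1e-5)

    def test_gate_ranges(self):
        rng = np.random.default_rng(1)
        params = LstmCellParams.from_layer(LSTMLayer(4, 6, rng))
        _, _, gates = lstm_cell_reference(
            rng.standard_normal((3, 4)), rng.standard_normal((3, 6)),
            rng.standard_normal((3, 6)), params,
        )
        for key in ("f", "i", "o"):
            assert np.all((gates[key] > 0) & (gates[key] < 1))
        assert np.all((gates["c_tilde"] > -1) & (gates["c_tilde"] < 1))


class TestWindows:
    def test_boundary_count(self, short_series):
        cfg = ForecastConfig(window=35, horizon=10, channels=1)
        sub = simulate_series(SimConfig(n_days=45, seed=1))
        assert len(make_windows(sub, cfg)) == 1

    def test_count_formula(self):
        cfg = ForecastConfig(window=35, horizon=10, channels=1)
        series = simulate_series(SimConfig(n_days=50, seed=1))
        assert len(make_windows(series, cfg)) == 50 - 35 - 10 + 1

    def test_contiguity(self, short_series):
        cfg = ForecastConfig(window=10, horizon=3, channels=1)
        for w in make_windows(short_series, cfg):
            assert w.input_days[-1] + 1 == w.target_days[0]

    def test_too_short_rejected(self):
        cfg = ForecastConfig(window=35, horizon=10, channels=1)
        series = simulate_series(SimConfig(n_days=40, seed=1))
        with pytest.raises(ValueError, match="needs >="):
            make_windows(series, cfg)

    def test_two_channel_inputs(self, short_series):
        cfg = ForecastConfig(window=10, horizon=3, channels=2)
        w = make_windows(short_series, cfg)[0]
        assert w.inputs.shape == (10, 10, 6, 4, 2)
        assert w.target.shape == (3, 10, 6, 4)
        # water-potential channel differs from temperature channel
        assert not np.allclose(w.inputs[..., 0], w.inputs[..., 1])

    def test_no_leakage_across_split(self, short_series):
        cfg = ForecastConfig(window=10, horizon=3, channels=1)
        train, val, test = split_windows(make_windows(short_series, cfg))
        train_input_days = set(int(d) for w in train for d in w.input_days)
        test_target_days = set(int(d) for w in test for d in w.target_days)
        assert not (train_input_days & test_target_days)

    def test_split_partitions_by_target(self, short_series):
        cfg = ForecastConfig(window=10, horizon=3, channels=1)
        windows = make_windows(short_series, cfg)
        train, val, test = split_windows(windows)
        assert len(train) + len(val) + len(test) <= len(windows)
        last_train = max(int(w.target_days[-1]) for w in train)
        first_test = min(int(w.target_days[0]) for w in test)
        assert last_train < first_test


class TestModel:
    def test_zero_input_finite_output(self):
        model = build_forecaster(LIGHT)
        out = model(nn.Tensor(np.zeros((1, LIGHT.window, 10, 6, 4, 2))))
        assert out.shape == (1, LIGHT.horizon, 10, 6, 4)
        assert np.isfinite(out.data).all()

    def test_single_channel_ablation_accepted(self):
        import dataclasses

        cfg = dataclasses.replace(LIGHT, channels=1)
        model = build_forecaster(cfg)
        out = model(nn.Tensor(np.zeros((2, cfg.window, 10, 6, 4, 1))))
        assert out.shape == (2, cfg.horizon, 10, 6, 4)

    def test_output_layer_parameter_count(self):
        model = build_forecaster(LIGHT)
        P = LIGHT.horizon
        expect = LIGHT.lstm_hidden * P * 240 + P * 240
        got = model.head.weight.data.size + model.head.bias.data.size
        assert got == expect

    def test_default_config_matches_printed_hyperparameters(self):
        cfg = ForecastConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.lstm_hidden == 128
        assert cfg.lstm_layers == 3
        assert cfg.dropout == 0.5
        assert cfg.window == 35
        assert cfg.horizon == 10


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_run(self):
        pairs = build_forecast_dataset(
            SimConfig(n_days=150), seed=2, n_granaries=2, min_days=145
        )
        import dataclasses

        cfg = dataclasses.replace(LIGHT, max_epochs=4, patience=3)
        windows = make_windows([s for s, _ in pairs], cfg)
        splits = split_windows(windows)
        model, history = train_forecaster(splits, cfg)
        return splits, cfg, model, history

    def test_history_reproducible(self, tiny_run):
        splits, cfg, _, h1 = tiny_run
        _, h2 = train_forecaster(splits, cfg)
        assert h1.train_loss == h2.train_loss

    def test_validation_beats_or_matches_persistence(self, tiny_run):
        splits, _, model, history = tiny_run
        base = persistence_baseline(splits[1])
        assert history.val_mae[history.best_epoch - 1] <= base.mae * 1.05

    def test_forecast_shape_and_determinism(self, tiny_run):
        splits, cfg, model, _ = tiny_run
        series = simulate_series(SimConfig(n_days=cfg.window + 5, seed=9))
        a = forecast(model, series)
        b = forecast(model, series)
        assert a.shape == (cfg.horizon, 10, 6, 4)
        assert np.array_equal(a, b)

    def test_forecast_tail_too_short(self, tiny_run):
        _, cfg, model, _ = tiny_run
        series = simulate_series(SimConfig(n_days=cfg.window - 2, seed=9))
        with pytest.raises(ValueError, match="window"):
            forecast(model, series)

    def test_metrics_match_hand_arithmetic_toy(self, tiny_run):
        from granarywatch.metrics import regression_metrics

        truth = np.zeros((2, 10, 6, 4))
        pred = np.zeros((2, 10, 6, 4))
        pred[0] += 3.0
        pred[1] += 4.0
        score = regression_metrics(truth, pred)
        assert score.mae == pytest.approx(3.5)
        assert score.rmse == pytest.approx(np.sqrt((9 + 16) / 2))

    def test_channel_ablation_contract(self, tiny_run):
        from granarywatch.metrics import channel_ablation

        splits, _, model, _ = tiny_run
        result = channel_ablation(model, splits[2][:10])
        assert set(result["deltas"]) == {"temperature", "water_potential"}
        assert result["baseline_mae"] > 0

    def test_ablation_requires_two_channels(self):
        import dataclasses

        from granarywatch.metrics import channel_ablation

        model = build_forecaster(dataclasses.replace(LIGHT, channels=1))
        with pytest.raises(ValueError, match="2-channel"):
            channel_ablation(model, [])


class TestAblationProperties:
    def test_constant_channel_ablation_is_neutral(self):
        # a zero-information channel replaced by its training mean moves MAE < 0.01
        import dataclasses

        from granarywatch.metrics import channel_ablation
        from granarywatch.preprocess import StandardizationStats

        rng = np.random.default_rng(8)
        cfg = dataclasses.replace(LIGHT, channels=2, max_epochs=2)
        windows = []
        for i in range(30):
            temps = rng.normal(10, 3, (cfg.window + cfg.horizon, 10, 6, 4))
            noise_channel = 7.0 + rng.normal(0, 1e-3, (cfg.window, 10, 6, 4))
            inputs = np.stack([temps[: cfg.window], noise_channel], axis=-1)
            windows.append(WindowSample(inputs=inputs, target=temps[cfg.window :]))
        model, _ = train_forecaster((windows[:20], windows[20:26], windows[26:]), cfg)
        result = channel_ablation(model, windows[26:])
        assert abs(result["deltas"]["water_potential"]) < 0.01

    def test_ablation_ordering_soft_check(self):
        """Soft, non-gating: on mildew-season data the temperature channel
        should matter at least as much as the water-potential channel, and the
        2-channel model should not trail the 1-channel ablation badly."""
        import dataclasses
        import warnings

        from granarywatch.grid_core import StorageState
        from granarywatch.metrics import channel_ablation
        from granarywatch.preprocess import CleaningConfig
        from granarywatch.sim import EventSpec, SimConfig, build_forecast_dataset

        cleaning = CleaningConfig(z_threshold=6.0)
        events = [
            [EventSpec(StorageState.MILDEW, 60 + 15 * g, 18, center=(2 + g, 2, 1))]
            for g in range(3)
        ]
        pairs = build_forecast_dataset(
            SimConfig(n_days=150), events=events, seed=4, n_granaries=3
        )
        series = [s for s, _ in pairs]
        maes = {}
        for channels in (2, 1):
            cfg = ForecastConfig(
                lstm_hidden=32, lstm_layers=1, conv_channels=8, embed_dim=64,
                dropout=0.0, max_epochs=8, patience=4, seed=4, batch_size=16,
                learning_rate=3e-4, channels=channels,
            )
            splits = split_windows(make_windows(series, cfg, cleaning=cleaning))
            model, _ = train_forecaster(splits, cfg, cleaning=cleaning)
            maes[channels] = evaluate_windows(model, splits[2]).mae
            if channels == 2:
                deltas = channel_ablation(model, splits[2])["deltas"]
        ordering_ok = deltas["temperature"] >= deltas["water_potential"]
        dual_ok = maes[2] <= maes[1] * 1.1
        if not (ordering_ok and dual_ok):
            warnings.warn(
                f"soft ablation check: deltas={deltas}, mae(2ch)={maes[2]:.3f}, "
                f"mae(1ch)={maes[1]:.3f}"
            )
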