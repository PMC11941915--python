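import numpy as np
import pytest

from granarywatch.grid_core import StorageState
from granarywatch.metrics import series_diagnostics
from granarywatch.sim import (
    EventSpec,
    SimConfig,
    ambient_trace,
    build_classification_dataset,
    build_forecast_dataset,
    inject_events,
    inject_state,
    simulate_series,
)


class TestSimConfig:
    def test_diffusivity_bounds(self):
        with pytest.raises(ValueError, match="diffusivity"):
            SimConfig(diffusivity=1.0)

    def test_rate_bounds(self):
        with pytest.raises(ValueError, match="error_code_rate"):
            SimConfig(error_code_rate=1.0)


class TestSimulate:
    def test_convergence_to_mean_without_forcing(self):
        cfg = SimConfig(
            n_days=200, ambient_mean=7.0, ambient_amplitude=0.0, daily_noise_sd=0.0,
            sensor_noise_sd=0.0, diffusivity=0.1,
        )
        s = simulate_series(cfg)
        assert np.abs(s.values_array()[-1] - 7.0).max() < 0.01

    def test_determinism_under_seed(self):
        cfg = SimConfig(n_days=40, error_code_rate=0.01, dropout_rate=0.01, seed=9)
        a, b = simulate_series(cfg), simulate_series(cfg)
        assert np.array_equal(a.values_array(), b.values_array())
        assert np.array_equal(a.mask_array(), b.mask_array())
        assert np.array_equal(a.moisture, b.moisture)

    def test_bottom_layer_lags_ambient(self):
        cfg = SimConfig(
            dims=(10, 6, 4), n_days=730, ambient_mean=7.0, ambient_amplitude=14.0,
            daily_noise_sd=1.0, seed=42,
        )
        s = simulate_series(cfg)
        amb = ambient_trace(cfg, np.random.default_rng(cfg.seed))
        bottom = s.values_array()[:, :, :, 0].mean(axis=(1, 2))
        a = amb - amb.mean()
        b = bottom - bottom.mean()
        cors = [np.corrcoef(a[: len(a) - k], b[k:])[0, 1] for k in range(60)]
        assert int(np.argmax(cors)) >= 5

    def test_error_codes_and_dropouts_present(self):
        cfg = SimConfig(n_days=60, error_code_rate=0.02, dropout_rate=0.02, seed=2)
        s = simulate_series(cfg)
        values, mask = s.values_array(), s.mask_array()
        assert mask.any()
        assert np.isin(np.round(values[~mask], 1), [888.0, -85.0, 85.0]).any()

    def test_calibration_against_printed_real_statistics(self):
        # soft calibration band bracketing the real-data summary values
        d = series_diagnostics(simulate_series(SimConfig(seed=0)), max_lag=30)
        assert 3.0 <= d.mean <= 11.0
        assert 8.0 <= d.sd <= 15.0
        assert abs(d.skewness) <= 0.6
        assert -1.5 <= d.kurtosis <= 0.2


class TestInjectors:
    @pytest.fixture
    def quiet(self):
        return simulate_series(
            SimConfig(n_days=80, daily_noise_sd=0.0, sensor_noise_sd=0.0, seed=4)
        )

    def test_event_must_fit(self, quiet):
        ev = EventSpec(StorageState.MILDEW, start_day=75, duration=10)
        with pytest.raises(ValueError, match="fit"):
            inject_state(quiet, ev)

    def test_center_must_be_inside(self, quiet):
        ev = EventSpec(StorageState.MILDEW, start_day=10, duration=5, center=(10, 0, 0))
        with pytest.raises(ValueError, match="center"):
            inject_state(quiet, ev)

    def test_mildew_ramp_closed_form(self, quiet):
        # intensity 1 degC/day for 10 days -> center excess >= 8 degC over baseline
        center = (5, 3, 2)
        ev = EventSpec(
            StorageState.MILDEW, start_day=40, duration=10, center=center,
            intensity={"rate": 1.0},
        )
        out, labels = inject_state(quiet, ev)
        before = quiet.values_array()[39][center]
        after = out.values_array()[49][center]
        drift = abs(quiet.values_array()[49][center] - before)
        assert after - before >= 8.0 - drift
        assert labels[40] is StorageState.MILDEW and labels[39] is StorageState.NORMAL

    def test_empty_spatial_sd_noise_limited(self, quiet):
        ev = EventSpec(StorageState.EMPTY, start_day=30, duration=8)
        out, labels = inject_state(quiet, ev, seed=7)
        for t in range(30, 38):
            assert out.values_array()[t].std() < 0.5
            assert labels[t] is StorageState.EMPTY

    def test_condensation_gap_reaches_threshold(self):
        s = simulate_series(SimConfig(n_days=80, seed=7))
        ev = EventSpec(
            StorageState.CONDENSATION, start_day=50, duration=12,
            intensity={"threshold": 12.0},
        )
        out, _ = inject_state(s, ev, seed=7)
        values = out.values_array()
        gaps = [
            values[t][:, :, :-1].mean() - values[t][:, :, -1].mean() for t in range(50, 62)
        ]
        assert max(gaps) >= 12.0

    def test_aeration_pulls_toward_ambient_air(self, quiet):
        ev = EventSpec(StorageState.AERATION, start_day=40, duration=10)
        out, _ = inject_state(quiet, ev)
        dev_before = np.abs(np.ptp(quiet.values_array()[49]))
        # late in the event the pile is nearly uniform at the forced-air level
        final = out.values_array()[49]
        assert final.std() < max(1.0, 0.3 * dev_before)

    def test_new_grain_step_on_upper_layers(self, quiet):
        ev = EventSpec(StorageState.NEW_GRAIN, start_day=20, duration=5)
        out, _ = inject_state(quiet, ev)
        delta = out.values_array()[22] - quiet.values_array()[22]
        assert np.all(delta[:, :, -2:] > 4.0)
        assert np.allclose(delta[:, :, :-2], 0.0)

    def test_overlapping_events_rejected(self, quiet):
        evs = [
            EventSpec(StorageState.MILDEW, start_day=10, duration=10),
            EventSpec(StorageState.EMPTY, start_day=15, duration=5),
        ]
        with pytest.raises(ValueError, match="overlap"):
            inject_events(quiet, evs)

    def test_sequential_events_label_track(self, quiet):
        evs = [
            EventSpec(StorageState.AERATION, start_day=10, duration=5),
            EventSpec(StorageState.EMPTY, start_day=30, duration=5),
        ]
        out, labels = inject_events(quiet, evs)
        assert labels[12] is StorageState.AERATION
        assert labels[32] is StorageState.EMPTY
        assert labels[20] is StorageState.NORMAL


class TestDatasetBuilders:
    def test_exact_counts_and_dims(self):
        ds = build_classification_dataset(
            {StorageState.NORMAL: 10, StorageState.MILDEW: 5}, seed=0
        )
        assert len(ds) == 15
        labels = [s.label for s in ds]
        assert labels.count(StorageState.NORMAL) == 10
        assert labels.count(StorageState.MILDEW) == 5
        for s in ds:
            assert s.grid.shape == (10, 6, 4)
            assert np.isfinite(s.grid).all()

    def test_determinism(self):
        a = build_classification_dataset({StorageState.EMPTY: 6}, seed=3)
        b = build_classification_dataset({StorageState.EMPTY: 6}, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.grid, y.grid)

    def test_nearest_centroid_separates_empty_from_mildew(self):
        # guards against a degenerate signal: a trivial baseline must succeed
        ds = build_classification_dataset(
            {StorageState.EMPTY: 100, StorageState.MILDEW: 100}, seed=1
        )
        grids = np.stack([s.grid for s in ds])
        labels = np.array([s.label.index for s in ds])
        feats = np.stack([grids.std(axis=(1, 2, 3)), np.abs(
            grids - np.median(grids, axis=(1, 2, 3), keepdims=True)
        ).max(axis=(1, 2, 3))], axis=1)
        correct = 0
        for i in range(len(ds)):  # leave-one-out nearest centroid
            rest = np.delete(np.arange(len(ds)), i)
            cents = {
                lab: feats[rest][labels[rest] == lab].mean(axis=0)
                for lab in np.unique(labels)
            }
            pred = min(cents, key=lambda lab: np.linalg.norm(feats[i] - cents[lab]))
            correct += pred == labels[i]
        assert correct / len(ds) >= 0.9

    def test_forecast_dataset_contracts(self):
        pairs = build_forecast_dataset(SimConfig(n_days=150), seed=2, n_granaries=2)
        assert len(pairs) == 2
        for series, labels in pairs:
            assert series.n_days >= 145
            assert len(labels) == series.n_days
            assert np.isfinite(series.moisture).all()

    def test_forecast_dataset_determinism(self):
        a = build_forecast_dataset(SimConfig(n_days=150), seed=5, n_granaries=1)
        b = build_forecast_dataset(SimConfig(n_days=150), seed=5, n_granaries=1)
        assert np.array_equal(a[0][0].values_array(), b[0][0].values_array())

    def test_forecast_dataset_too_short_rejected(self):
        with pytest.raises(ValueError, match="145"):
            build_forecast_dataset(SimConfig(n_days=100), seed=0)
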