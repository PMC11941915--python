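"""Synthetic granary generator.

Produces :class:`~granarywatch.grid_core.GranarySeries` with seasonal
ambient forcing, discrete heat relaxation, sensor noise / error codes /
dropouts, and injectable storage-state events, so the full pipeline trains
and tests without any external data.

Heat transport is a daily relaxation, not a PDE solve: each voxel moves a
fraction ``diffusivity`` toward the mean of its six neighbours; ghost
neighbours beyond the pile surface (top layer) and the side walls take the
ambient temperature, while the floor is held at a constant ground
temperature.  Depth lag relative to ambient emerges from the neighbour
chain.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .grid_core import GranarySeries, StorageState, TemperatureGrid, ClassSample
from .preprocess import CleaningConfig, clean_series, impute_missing, resize_grid_values

__all__ = [
    "SimConfig",
    "EventSpec",
    "simulate_series",
    "ambient_trace",
    "inject_state",
    "inject_events",
    "build_classification_dataset",
    "build_forecast_dataset",
    "MOISTURE_MEANS",
]

ERROR_CODES = (888.0, -85.0, 85.0)
MOISTURE_MEANS = {"wheat": 12.5, "corn": 14.0, "rice": 13.5}


@dataclass(frozen=True)
class SimConfig:
    dims: tuple = (10, 6, 4)
    n_days: int = 540
    ambient_mean: float = 5.0
    ambient_amplitude: float = 18.0
    ambient_period: float = 365.0
    daily_noise_sd: float = 1.0
    diffusivity: float = 0.35  # per-day relaxation fraction in (0, 1)
    sensor_noise_sd: float = 0.2
    error_code_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    variety: str = "wheat"
    phase_days: float = 0.0  # shifts the seasonal sine
    ground_temp: float | None = None  # floor boundary; None = annual ambient mean
    start_date: dt.date = dt.date(2023, 1, 1)

    def __post_init__(self):
        if not 0.0 < self.diffusivity < 1.0:
            raise ValueError("diffusivity must lie in (0, 1)")
        for name in ("error_code_rate", "dropout_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if min(self.dims) < 1:
            raise ValueError("all dims must be >= 1")


@dataclass(frozen=True)
class EventSpec:
    state: StorageState
    start_day: int  # 0-based index into the series days
    duration: int
    center: tuple | None = None  # 0-based voxel for localized events
    intensity: dict = field(default_factory=dict)  # state-specific knobs

    def days(self):
        return range(self.start_day, self.start_day + self.duration)


def ambient_trace(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Deterministic-part + noise ambient series A(t); noise drawn from rng."""
    t = np.arange(config.n_days, dtype=np.float64) + config.phase_days
    a = config.ambient_mean + config.ambient_amplitude * np.sin(
        2.0 * np.pi * t / config.ambient_period
    )
    if rng is not None and config.daily_noise_sd > 0:
        a = a + rng.normal(0.0, config.daily_noise_sd, config.n_days)
    return a


def _relax_step(u: np.ndarray, ambient: float, diffusivity: float, ground: float) -> np.ndarray:
    """One day of neighbour relaxation; ambient ghost cells above and on the
    side walls, constant ground temperature below the floor."""
    M, N, H = u.shape
    P = np.full((M + 2, N + 2, H + 2), ambient)
    P[1:-1, 1:-1, 1:-1] = u
    P[1:-1, 1:-1, 0] = ground
    nbr = (
        P[:-2, 1:-1, 1:-1]
        + P[2:, 1:-1, 1:-1]
        + P[1:-1, :-2, 1:-1]
        + P[1:-1, 2:, 1:-1]
        + P[1:-1, 1:-1, :-2]
        + P[1:-1, 1:-1, 2:]
    ) / 6.0
    return u + diffusivity * (nbr - u)


def simulate_series(config: SimConfig) -> GranarySeries:
    """Simulate one granary's daily temperature grids plus a moisture track."""
    rng = np.random.default_rng(config.seed)
    ambient = ambient_trace(config, rng)
    ground = config.ground_temp if config.ground_temp is not None else config.ambient_mean
    u = np.full(config.dims, config.ambient_mean)
    days, grids = [], []
    values = np.empty((config.n_days, *config.dims))
    for t in range(config.n_days):
        u = _relax_step(u, ambient[t], config.diffusivity, ground)
        values[t] = u
    if config.sensor_noise_sd > 0:
        values = values + rng.normal(0.0, config.sensor_noise_sd, values.shape)

    mask = np.zeros(values.shape, dtype=bool)
    if config.error_code_rate > 0:
        hits = rng.random(values.shape) < config.error_code_rate
        codes = rng.choice(ERROR_CODES, size=int(hits.sum()))
        values[hits] = codes
    if config.dropout_rate > 0:
        mask |= rng.random(values.shape) < config.dropout_rate

    m_star = MOISTURE_MEANS[config.variety]
    moisture = np.empty(config.n_days)
    m = m_star
    for t in range(config.n_days):
        m = m_star + 0.995 * (m - m_star) + rng.normal(0.0, 0.03)
        moisture[t] = np.clip(m, 5.0, 35.0)

    for t in range(config.n_days):
        d = config.start_date + dt.timedelta(days=t)
        days.append(d)
        grids.append(TemperatureGrid(values[t], mask[t], d))
    return GranarySeries(
        granary_id=f"sim-{config.seed}",
        variety=config.variety,
        days=days,
        grids=grids,
        moisture=moisture,
        region="synthetic",
    )


# ---------------------------------------------------------------------------
# Event injection


def _editable(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Voxels safe to perturb: present and not holding a sentinel code."""
    ok = ~mask
    rounded = np.round(values, 1)
    for code in ERROR_CODES:
        ok &= rounded != round(code, 1)
    return ok


def _surface_mean(values, mask, t):
    top = values[t, :, :, -1][~mask[t, :, :, -1]]
    return float(top.mean()) if top.size else float(values[t][~mask[t]].mean())


def inject_state(series: GranarySeries, event: EventSpec, seed: int = 0):
    """Return a modified copy of the series plus a per-day state-label track.

    Injector signatures (defining inequalities hold on every labelled day):

    * mildew: localized exponential ramp; centre voxel excess = rate*k on
      event day k, Gaussian footprint whose radius grows with time; the
      moisture track rises while the event runs.
    * condensation: the core/surface gap (mean over z <= H-2 minus mean
      over the top layer) is pushed up to at least
      ``threshold * max(early_fraction, k/duration)`` each day, so the max
      gap over the event reaches the threshold.
    * aeration: pile-wide exponential pull toward the forced-air
      temperature (ambient minus ``air_offset``, cooler at the floor where
      the air enters): ``v += (1 - exp(-k/tau)) * (target - v)``.
    * new_grain: step increase on the upper layers.
    * empty: every voxel tracks ambient (plus a small vertical air
      stratification) with near-zero spatial variance.
    """
    if event.start_day < 0 or event.start_day + event.duration > series.n_days:
        raise ValueError("event does not fit within the series")
    dims = series.dims
    if event.center is not None and not all(0 <= c < d for c, d in zip(event.center, dims)):
        raise ValueError(f"event center {event.center} outside dims {dims}")

    rng = np.random.default_rng(seed)
    values = series.values_array()
    mask = series.mask_array()
    labels = [StorageState.NORMAL] * series.n_days
    H = dims[2]
    p = event.intensity

    # ambient proxy per day from the pre-injection surface layer
    amb = np.array([_surface_mean(values, mask, t) for t in range(series.n_days)])

    if event.state is StorageState.MILDEW:
        rate = p.get("rate", 2.0)
        sigma0 = p.get("sigma0", 1.0)
        growth = p.get("radius_growth", 0.15)
        center = event.center if event.center is not None else tuple(d // 2 for d in dims)
        moisture_rate = p.get("moisture_rate", 0.08)  # % per event day
        grid_idx = np.indices(dims, dtype=np.float64)
        d2 = sum((grid_idx[a] - center[a]) ** 2 for a in range(3))
        moisture = series.moisture.copy()
        for k, t in enumerate(event.days(), start=1):
            sigma = sigma0 + growth * k
            delta = rate * k * np.exp(-d2 / (2.0 * sigma**2))
            ok = _editable(values[t], mask[t])
            values[t][ok] += delta[ok]
            # damp grain gets steadily damper while the mould grows
            moisture[t:] = np.minimum(moisture[t:] + moisture_rate, 34.0)
            labels[t] = StorageState.MILDEW
        out = series.replace_values(values, mask)
        out.moisture = moisture
        return out, labels
    elif event.state is StorageState.CONDENSATION:
        threshold = p.get("threshold", 12.0)
        margin = p.get("margin", 1.0)
        floor = p.get("early_fraction", 0.5)  # gap fraction already present on day 1
        for k, t in enumerate(event.days(), start=1):
            ok = _editable(values[t], mask[t])
            core = ok.copy()
            core[:, :, -1] = False
            surf = ok.copy()
            surf[:, :, :-1] = False
            target = (threshold + margin) * max(floor, k / event.duration)
            gap = values[t][core].mean() - values[t][surf].mean()
            deficit = max(0.0, target - gap)
            values[t][core] += deficit / 2.0
            values[t][surf] -= deficit / 2.0
            labels[t] = StorageState.CONDENSATION
    elif event.state is StorageState.AERATION:
        tau = p.get("tau", 2.0)
        air_offset = p.get("air_offset", 5.0)  # forced air runs cooler than the pile surface
        duct_gradient = p.get("duct_gradient", 3.0)  # air enters at the floor: bottom coolest
        z_frac = np.indices(dims)[2] / max(1, H - 1)
        for k, t in enumerate(event.days(), start=1):
            ok = _editable(values[t], mask[t])
            pull = 1.0 - np.exp(-k / tau)
            target = amb[t] - air_offset - duct_gradient * (1.0 - z_frac[ok])
            values[t][ok] += pull * (target - values[t][ok])
            labels[t] = StorageState.AERATION
    elif event.state is StorageState.NEW_GRAIN:
        delta = p.get("delta", 6.0)
        layers = p.get("layers", 2)
        for t in event.days():
            ok = _editable(values[t], mask[t])
            ok[:, :, : H - layers] = False
            values[t][ok] += delta
            labels[t] = StorageState.NEW_GRAIN
    elif event.state is StorageState.EMPTY:
        noise_sd = p.get("noise_sd", 0.1)
        stratification = p.get("stratification", 1.0)  # warm air rises in the empty shell
        z_frac = np.indices(dims)[2] / max(1, H - 1)
        for t in event.days():
            ok = _editable(values[t], mask[t])
            values[t][ok] = (
                amb[t] + stratification * z_frac[ok] + rng.normal(0.0, noise_sd, int(ok.sum()))
            )
            labels[t] = StorageState.EMPTY
    else:
        raise ValueError(f"no injector for state {event.state}")

    return series.replace_values(values, mask), labels


def inject_events(series: GranarySeries, events, seed: int = 0):
    """Inject several non-overlapping events; error on overlap."""
    taken = set()
    for ev in events:
        span = set(ev.days())
        if span & taken:
            raise ValueError(f"overlapping events at days {sorted(span & taken)}")
        taken |= span
    labels = [StorageState.NORMAL] * series.n_days
    out = series
    for i, ev in enumerate(events):
        out, ev_labels = inject_state(out, ev, seed=seed + i)
        for t in ev.days():
            labels[t] = ev_labels[t]
    return out, labels


# ---------------------------------------------------------------------------
# Dataset builders


def preprocess_series_to_grids(series: GranarySeries, cleaning: CleaningConfig | None = None) -> np.ndarray:
    """clean -> impute -> per-day spline resize; returns (n_days, 10, 6, 4)."""
    cleaned, _ = clean_series(series, cleaning)
    imputed = impute_missing(cleaned)
    vals = imputed.values_array()
    return np.stack([resize_grid_values(vals[t]) for t in range(series.n_days)])


def build_classification_dataset(
    n_per_class: dict,
    config: SimConfig | None = None,
    seed: int = 0,
    cleaning: CleaningConfig | None = None,
) -> list:
    """Generate labelled, preprocessed 10x6x4 samples with exact class counts.

    Each simulated series carries one injected event (or none, for the
    normal class) and contributes up to ``duration`` event-day samples, with
    seasonal phase randomized across series.
    """
    config = config or SimConfig(n_days=80)
    rng = np.random.default_rng(seed)
    warmup = min(30, config.n_days // 3)
    duration = 12
    samples = []
    for state, want in n_per_class.items():
        got = 0
        while got < want:
            child_seed = int(rng.integers(0, 2**31 - 1))
            phase = float(rng.uniform(0.0, config.ambient_period))
            cfg = replace(config, seed=child_seed, phase_days=phase)
            series = simulate_series(cfg)
            if state is StorageState.NORMAL:
                harvest = list(
                    rng.choice(
                        np.arange(warmup, cfg.n_days),
                        size=min(duration, want - got),
                        replace=False,
                    )
                )
                labels = [StorageState.NORMAL] * cfg.n_days
            else:
                latest = cfg.n_days - duration
                start = int(rng.integers(warmup, max(warmup + 1, latest)))
                center = tuple(int(rng.integers(1, d - 1)) if d > 2 else 0 for d in cfg.dims)
                ev = EventSpec(state=state, start_day=start, duration=duration, center=center)
                series, labels = inject_state(series, ev, seed=child_seed)
                harvest = [t for t in ev.days()][: want - got]
            grids = preprocess_series_to_grids(series, cleaning)
            for t in harvest:
                samples.append(ClassSample(grid=grids[t], label=labels[t], provenance="real"))
                got += 1
    return samples


def build_forecast_dataset(
    config: SimConfig | None = None,
    events=None,
    seed: int = 0,
    n_granaries: int = 3,
    min_days: int = 145,
):
    """Multi-granary series with moisture tracks for window extraction.

    ``events`` may be None or a list (one entry per granary) of EventSpec
    lists.  Returns a list of (GranarySeries, labels) pairs.
    """
    config = config or SimConfig(n_days=200)
    if config.n_days < min_days:
        raise ValueError(f"n_days must be >= {min_days} for window extraction")
    rng = np.random.default_rng(seed)
    out = []
    for g in range(n_granaries):
        child_seed = int(rng.integers(0, 2**31 - 1))
        phase = float(rng.uniform(0.0, config.ambient_period))
        cfg = replace(config, seed=child_seed, phase_days=phase)
        series = simulate_series(cfg)
        labels = [StorageState.NORMAL] * cfg.n_days
        if events is not None and events[g]:
            series, labels = inject_events(series, events[g], seed=child_seed)
        out.append((series, labels))
    return out
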