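"""Cleaning, imputation, spline resizing and standardization.

Pipeline order is fixed: clean -> impute -> resize -> standardize.  Each
stage's output satisfies the next stage's preconditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .grid_core import GranarySeries, TemperatureGrid, TARGET_DIMS

__all__ = [
    "CleaningConfig",
    "ZScoreReport",
    "StandardizationStats",
    "clean_series",
    "impute_missing",
    "resize_spline",
    "standardize",
    "destandardize",
]

DEFAULT_ERROR_CODES = (888.0, -85.0, 85.0)


@dataclass
class CleaningConfig:
    error_codes: tuple = DEFAULT_ERROR_CODES
    z_threshold: float = 3.0
    physical_range: tuple = (-40.0, 60.0)
    # None: repeat the Z pass to a fixed point, which makes cleaning
    # idempotent by construction; 1: literal single pass.
    max_z_passes: int | None = None

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        lo, hi = self.physical_range
        if not lo < hi:
            raise ValueError("physical_range lower bound must be below upper bound")


@dataclass
class ZScoreReport:
    mu: float
    sigma: float
    z: np.ndarray  # (n_days, M, N, H); nan where value was missing/sentinel
    removed: np.ndarray  # bool, True where the Z filter removed a value
    degenerate: bool = False  # sigma == 0: no Z removals possible
    n_code_removed: int = 0
    n_z_removed: int = 0


@dataclass
class StandardizationStats:
    """Per-channel mean / standard deviation from the training partition."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=np.float64))
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=np.float64))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have identical shape")
        if np.any(self.sd <= 0):
            raise ValueError("standardization sd must be > 0 for every channel")

    @classmethod
    def from_data(cls, data: np.ndarray, channel_axis: int | None = None) -> "StandardizationStats":
        data = np.asarray(data, dtype=np.float64)
        if channel_axis is None:
            return cls(np.array([data.mean()]), np.array([data.std()]))
        moved = np.moveaxis(data, channel_axis, -1)
        flat = moved.reshape(-1, moved.shape[-1])
        return cls(flat.mean(axis=0), flat.std(axis=0))

    def to_dict(self):
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]))


def clean_series(series: GranarySeries, config: CleaningConfig | None = None):
    """Sentinel/range removal followed by a single pooled Z-score pass.

    Step 1: values equal to an error code (exact match after rounding to
    0.1 degC) or outside the physical range become missing.  Step 2: Z-scores
    over all remaining values of the series, pooled; |Z| > threshold removed.
    """
    config = config or CleaningConfig()
    # NB: by default the Z pass repeats until no value exceeds the threshold
    # against the surviving data's own statistics, so cleaning is idempotent;
    # the reported mu/sigma/z come from the first pass.
    values = series.values_array()
    mask = series.mask_array().copy()

    rounded = np.round(values, 1)
    code_hit = np.zeros_like(mask)
    for code in config.error_codes:
        code_hit |= rounded == round(code, 1)
    lo, hi = config.physical_range
    code_hit |= (values < lo) | (values > hi)
    code_hit &= ~mask
    mask |= code_hit

    z = np.full(values.shape, np.nan)
    removed = np.zeros_like(mask)
    degenerate = False
    mu, sigma = float("nan"), float("nan")
    passes = 0
    while True:
        valid = ~mask
        if not valid.any():
            degenerate = True
            break
        pass_mu = float(values[valid].mean())
        pass_sigma = float(values[valid].std())  # population sd over the pooled series
        if passes == 0:
            mu, sigma = pass_mu, pass_sigma
            z[valid] = np.nan  # reset in case of sentinel overlap
            if pass_sigma > 0:
                z[valid] = (values[valid] - pass_mu) / pass_sigma
        passes += 1
        if pass_sigma == 0.0:
            degenerate = degenerate or passes == 1
            break
        new = np.zeros_like(mask)
        new[valid] = np.abs(values[valid] - pass_mu) > config.z_threshold * pass_sigma
        if not new.any():
            break
        removed |= new
        mask |= new
        if config.max_z_passes is not None and passes >= config.max_z_passes:
            break

    out = series.replace_values(np.where(mask, 0.0, values), mask)
    report = ZScoreReport(
        mu=mu,
        sigma=sigma,
        z=z,
        removed=removed,
        degenerate=degenerate,
        n_code_removed=int(code_hit.sum()),
        n_z_removed=int(removed.sum()),
    )
    return out, report


def impute_missing(series: GranarySeries) -> GranarySeries:
    """Fill each missing voxel-day with the mean of that voxel's nearest
    previous and nearest next non-missing values; leading/trailing gaps take
    the single nearest value."""
    values = series.values_array()
    mask = series.mask_array()
    D = values.shape[0]
    flat_v = values.reshape(D, -1)
    flat_m = mask.reshape(D, -1)
    dims = series.dims
    for v in range(flat_v.shape[1]):
        col_m = flat_m[:, v]
        if not col_m.any():
            continue
        obs = np.flatnonzero(~col_m)
        if obs.size == 0:
            coord = tuple(int(c) + 1 for c in np.unravel_index(v, dims))
            raise ValueError(f"voxel {coord} (1-based) is missing on all days; cannot impute")
        miss = np.flatnonzero(col_m)
        pos = np.searchsorted(obs, miss)
        prev_idx = obs[np.clip(pos - 1, 0, obs.size - 1)]
        next_idx = obs[np.clip(pos, 0, obs.size - 1)]
        prev_val = flat_v[prev_idx, v]
        next_val = flat_v[next_idx, v]
        has_prev = pos > 0
        has_next = pos < obs.size
        fill = np.where(
            has_prev & has_next,
            0.5 * (prev_val + next_val),
            np.where(has_prev, prev_val, next_val),
        )
        flat_v[miss, v] = fill
        flat_m[miss, v] = False
    return series.replace_values(values, np.zeros_like(mask))


def resize_grid_values(values: np.ndarray, target=TARGET_DIMS) -> np.ndarray:
    """Separable spline resize on a normalized [0,1] lattice per axis.

    Cubic where an axis has >= 4 samples, quadratic at 3, linear at 2.
    """
    out = np.asarray(values, dtype=np.float64)
    for axis in range(3):
        n = out.shape[axis]
        if n == target[axis]:
            # nodes coincide with the target lattice; identity along this axis
            continue
        if n < 2:
            raise ValueError(f"axis {axis} has {n} samples; need >= 2 to interpolate")
        xs = np.linspace(0.0, 1.0, n)
        xq = np.linspace(0.0, 1.0, target[axis])
        spline = make_interp_spline(xs, out, k=min(3, n - 1), axis=axis)
        out = spline(xq)
    return out


def resize_spline(grid: TemperatureGrid, target=TARGET_DIMS) -> TemperatureGrid:
    if grid.mask.any():
        raise ValueError("grid has missing values; impute before resizing")
    values = resize_grid_values(grid.values, target)
    return TemperatureGrid(values, np.zeros(target, dtype=bool), grid.date)


def standardize(data: np.ndarray, stats: StandardizationStats, channel_axis: int | None = None) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if channel_axis is None:
        return (data - stats.mean[0]) / stats.sd[0]
    shape = [1] * data.ndim
    shape[channel_axis] = -1
    return (data - stats.mean.reshape(shape)) / stats.sd.reshape(shape)


def destandardize(data: np.ndarray, stats: StandardizationStats, channel_axis: int | None = None) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if channel_axis is None:
        return data * stats.sd[0] + stats.mean[0]
    shape = [1] * data.ndim
    shape[channel_axis] = -1
    return data * stats.sd.reshape(shape) + stats.mean.reshape(shape)
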