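"""Domain types and file I/O for granary temperature-grid time series.

Coordinate conventions
----------------------
* Internally everything is 0-based; files and reports use 1-based sensor
  indices.
* Grids are indexed ``(x, y, z)`` with shape ``(M, N, H)``.
* ``z`` increases upward: ``z = H`` (1-based) is the pile surface layer.

On-disk layout of a series directory::

    manifest.json   {"granary_id", "variety", "region", "dims": [M, N, H]}
    temps.csv       date,x,y,z,temp_c     (1-based indices, missing rows omitted)
    moisture.csv    date,moisture_pct     (sparse; forward-filled on read)
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StorageState",
    "TemperatureGrid",
    "GranarySeries",
    "ClassSample",
    "DatasetSummary",
    "read_series",
    "write_series",
    "summarize_dataset",
    "TARGET_DIMS",
    "VARIETIES",
]

TARGET_DIMS = (10, 6, 4)
VARIETIES = ("wheat", "corn", "rice")


class StorageState(Enum):
    """The six storage states, in fixed ordinal order."""

    NORMAL = "normal"
    EMPTY = "empty"
    AERATION = "aeration"
    NEW_GRAIN = "new_grain"
    CONDENSATION = "condensation"
    MILDEW = "mildew"

    @property
    def index(self) -> int:
        return list(StorageState).index(self)

    @classmethod
    def from_index(cls, i: int) -> "StorageState":
        return list(cls)[i]


@dataclass
class TemperatureGrid:
    """One day's 3D temperature field with a missing-value mask."""

    values: np.ndarray  # (M, N, H) degrees C
    mask: np.ndarray  # (M, N, H) bool, True = missing
    date: dt.date

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"grid values must be 3D with all dims >= 1, got {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must share dims")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-missing values must be finite")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    def copy(self) -> "TemperatureGrid":
        return TemperatureGrid(self.values.copy(), self.mask.copy(), self.date)


@dataclass
class GranarySeries:
    """Date-ordered grids plus a per-day moisture track for one granary."""

    granary_id: str
    variety: str
    days: list  # list of datetime.date, strictly increasing
    grids: list  # list of TemperatureGrid, shared dims
    moisture: np.ndarray  # per-day moisture %, forward-filled; nan if never sampled
    region: str = ""

    def __post_init__(self):
        if self.variety not in VARIETIES:
            raise ValueError(f"variety must be one of {VARIETIES}, got {self.variety!r}")
        if len(self.days) != len(self.grids):
            raise ValueError("days and grids must have equal length")
        for a, b in zip(self.days, self.days[1:]):
            if not b > a:
                raise ValueError("days must be strictly increasing")
        dims = {g.dims for g in self.grids}
        if len(dims) > 1:
            raise ValueError(f"all grids must share dims, found {sorted(dims)}")
        self.moisture = np.asarray(self.moisture, dtype=np.float64)
        if self.moisture.shape != (len(self.days),):
            raise ValueError("moisture must be one value per day")
        present = self.moisture[np.isfinite(self.moisture)]
        if present.size and not np.all((present > 0) & (present < 40)):
            raise ValueError("moisture values must lie in (0, 40) %")

    @property
    def dims(self) -> tuple:
        return self.grids[0].dims

    @property
    def n_days(self) -> int:
        return len(self.days)

    def values_array(self) -> np.ndarray:
        """Stacked (n_days, M, N, H) values (missing entries as stored)."""
        return np.stack([g.values for g in self.grids])

    def mask_array(self) -> np.ndarray:
        return np.stack([g.mask for g in self.grids])

    def copy(self) -> "GranarySeries":
        return GranarySeries(
            self.granary_id,
            self.variety,
            list(self.days),
            [g.copy() for g in self.grids],
            self.moisture.copy(),
            self.region,
        )

    def replace_values(self, values: np.ndarray, mask: np.ndarray) -> "GranarySeries":
        grids = [
            TemperatureGrid(values[i], mask[i], self.days[i]) for i in range(len(self.days))
        ]
        return GranarySeries(
            self.granary_id, self.variety, list(self.days), grids, self.moisture.copy(), self.region
        )


@dataclass
class ClassSample:
    """A 10x6x4 grid with a storage-state label.

    ``grid`` is in degrees C as produced by the preprocessing chain;
    standardisation to training statistics happens inside the classifier
    training step (the stats must come from the training partition only).
    """

    grid: np.ndarray
    label: StorageState
    provenance: str = "real"  # real | flipped | gan

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.shape != TARGET_DIMS:
            raise ValueError(f"ClassSample grid must be {TARGET_DIMS}, got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("ClassSample grid must have no missing values")
        if self.provenance not in ("real", "flipped", "gan"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class DatasetSummary:
    counts: dict  # (region, StorageState) -> int
    totals: dict = field(default_factory=dict)  # StorageState -> int

    def __post_init__(self):
        totals = {s: 0 for s in StorageState}
        for (_, state), n in self.counts.items():
            if n < 0:
                raise ValueError("counts must be non-negative")
            totals[state] += n
        if self.totals:
            if self.totals != totals:
                raise ValueError("totals do not equal column sums")
        self.totals = totals


def summarize_dataset(samples: Iterable[tuple]) -> DatasetSummary:
    """Tally (region, state[, count]) records into per-region and total counts.

    Accepts 2-tuples ``(region, state)`` counting 1 each, or 3-tuples
    ``(region, state, count)``.
    """
    counts: dict = {}
    for rec in samples:
        if len(rec) == 2:
            region, state = rec
            n = 1
        else:
            region, state, n = rec
        if not isinstance(state, StorageState):
            raise TypeError(f"expected StorageState, got {state!r}")
        counts[(region, state)] = counts.get((region, state), 0) + int(n)
    return DatasetSummary(counts)


# ---------------------------------------------------------------------------
# File I/O


def write_series(series: GranarySeries, path) -> Path:
    """Write a series directory (manifest.json, temps.csv, moisture.csv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "granary_id": series.granary_id,
        "variety": series.variety,
        "region": series.region,
        "dims": list(series.dims),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    rows = []
    for day, grid in zip(series.days, series.grids):
        xs, ys, zs = np.nonzero(~grid.mask)
        for x, y, z in zip(xs, ys, zs):
            rows.append((day.isoformat(), x + 1, y + 1, z + 1, grid.values[x, y, z]))
    pd.DataFrame(rows, columns=["date", "x", "y", "z", "temp_c"]).to_csv(
        path / "temps.csv", index=False
    )

    mrows = [
        (day.isoformat(), m)
        for day, m in zip(series.days, series.moisture)
        if np.isfinite(m)
    ]
    pd.DataFrame(mrows, columns=["date", "moisture_pct"]).to_csv(
        path / "moisture.csv", index=False
    )
    return path


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(str(s))


def read_series(path) -> GranarySeries:
    """Assemble a GranarySeries from a series directory.

    Absent (date, x, y, z) rows become missing voxels.  Duplicate rows and
    sensor indices outside the manifest dims are errors.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    dims = tuple(manifest["dims"])
    df = pd.read_csv(path / "temps.csv", float_precision="round_trip")
    required = {"date", "x", "y", "z", "temp_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"temps.csv must have columns {sorted(required)}")

    dup = df.duplicated(subset=["date", "x", "y", "z"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate record at (date={date}, x={x}, y={y}, z={z})".format(
                date=first["date"], x=first["x"], y=first["y"], z=first["z"]
            )
        )
    for axis, size in zip("xyz", dims):
        col = df[axis].to_numpy()
        if col.min() < 1 or col.max() > size:
            raise ValueError(
                f"sensor index {axis} outside manifest dims (1..{size}); layout conflict"
            )

    days = sorted({_parse_date(d) for d in df["date"]})
    day_pos = {d: i for i, d in enumerate(days)}
    values = np.zeros((len(days), *dims))
    mask = np.ones((len(days), *dims), dtype=bool)
    di = df["date"].map(lambda s: day_pos[_parse_date(s)]).to_numpy()
    values[di, df["x"] - 1, df["y"] - 1, df["z"] - 1] = df["temp_c"]
    mask[di, df["x"] - 1, df["y"] - 1, df["z"] - 1] = False

    moisture = np.full(len(days), np.nan)
    mpath = path / "moisture.csv"
    if mpath.exists():
        mdf = pd.read_csv(mpath, float_precision="round_trip")
        raw = {}
        for _, row in mdf.iterrows():
            raw[_parse_date(row["date"])] = float(row["moisture_pct"])
        moisture = forward_fill_moisture(days, raw)

    grids = [TemperatureGrid(values[i], mask[i], d) for i, d in enumerate(days)]
    return GranarySeries(
        granary_id=manifest.get("granary_id", path.name),
        variety=manifest.get("variety", "wheat"),
        days=days,
        grids=grids,
        moisture=moisture,
        region=manifest.get("region", ""),
    )


def forward_fill_moisture(days: Sequence[dt.date], sampled: Mapping[dt.date, float]) -> np.ndarray:
    """Carry sparse moisture samples forward; leading gaps take the first sample."""
    out = np.full(len(days), np.nan)
    last = np.nan
    for i, d in enumerate(days):
        if d in sampled:
            last = sampled[d]
        out[i] = last
    if np.isnan(out[0]) and any(np.isfinite(out)):
        first = out[np.isfinite(out)][0]
        out[: np.flatnonzero(np.isfinite(out))[0]] = first
    return out


def write_labels(labels, days, path, centers=None) -> Path:
    """Write a per-day state-label CSV (1-based center coordinates)."""
    path = Path(path)
    rows = []
    for i, (day, state) in enumerate(zip(days, labels)):
        c = centers[i] if centers is not None and centers[i] is not None else ("", "", "")
        cx, cy, cz = (c[0] + 1, c[1] + 1, c[2] + 1) if c != ("", "", "") else c
        rows.append((day.isoformat(), state.value, cx, cy, cz))
    pd.DataFrame(rows, columns=["date", "state", "center_x", "center_y", "center_z"]).to_csv(
        path, index=False
    )
    return path
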