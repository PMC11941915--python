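"""Absolute water potential of stored grain (kJ/kg).

The quantity couples grain temperature, moisture content and
variety-specific sorption coefficients, and serves as the forecaster's
second input channel.  The published closed form is typeset ambiguously in
its source, so the evaluation lives behind a named-formula registry: the
shipped ``reconstructed-v1`` grouping is

    E = 8.31 * (Tg + 273) * ln( exp(u) * 133.3 ) / 18
    u = (D^2/22 * (e1 - e2) + 0.9854) * (1737.1 - 474242/(273 + Tg))
        + D * (1 - e1) - 68.578/7.72
    e1 = exp((B1 - M)/A1),  e2 = exp((B2 - M)/A2)

evaluated in the log domain (ln(exp(u)*133.3) = u + ln 133.3) so no
overflow can occur.  An alternative grouping can be registered without
touching callers.

The shipped per-variety coefficient sets are PLACEHOLDERS (flagged
``verified: false``); production use requires fitted sorption coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .grid_core import TemperatureGrid

__all__ = [
    "GrainCoefficients",
    "AwpField",
    "awp",
    "awp_field",
    "default_coefficients",
    "load_coefficients",
    "FORMULAS",
]

LN_133_3 = float(np.log(133.3))


@dataclass(frozen=True)
class GrainCoefficients:
    variety: str
    A1: float
    A2: float
    B1: float
    B2: float
    D: float

    def __post_init__(self):
        vals = (self.A1, self.A2, self.B1, self.B2, self.D)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all coefficients must be finite")
        if self.A1 == 0 or self.A2 == 0:
            raise ValueError("A1 and A2 must be nonzero")


@dataclass
class AwpField:
    values: np.ndarray  # (M, N, H) kJ/kg, aligned with its TemperatureGrid


def _reconstructed_v1(tg, m, c: GrainCoefficients):
    e1 = np.exp((c.B1 - m) / c.A1)
    e2 = np.exp((c.B2 - m) / c.A2)
    s = c.D**2 / 22.0 * (e1 - e2) + 0.9854
    u = s * (1737.1 - 474242.0 / (273.0 + tg)) + c.D * (1.0 - e1) - 68.578 / 7.72
    return 8.31 * (tg + 273.0) * (u + LN_133_3) / 18.0


FORMULAS = {"reconstructed-v1": _reconstructed_v1}

_DATA_FILE = Path(__file__).parent / "data" / "coefficients.yaml"


def load_coefficients(path) -> dict:
    """Load a variety -> GrainCoefficients mapping from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for variety, c in raw.items():
        out[variety] = GrainCoefficients(
            variety=variety,
            A1=float(c["A1"]),
            A2=float(c["A2"]),
            B1=float(c["B1"]),
            B2=float(c["B2"]),
            D=float(c["D"]),
        )
    return out


def default_coefficients(variety: str = "wheat") -> GrainCoefficients:
    return load_coefficients(_DATA_FILE)[variety]


def awp(tg, m, coeffs: GrainCoefficients, formula: str = "reconstructed-v1"):
    """Absolute water potential (kJ/kg) at grain temperature tg (degC) and
    moisture content m (%).  Vectorized over tg and m."""
    tg = np.asarray(tg, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    if np.any(tg < -40) or np.any(tg > 60):
        raise ValueError("grain temperature outside [-40, 60] degC")
    if np.any(m <= 0) or np.any(m >= 40):
        raise ValueError("moisture content outside (0, 40) %")
    result = FORMULAS[formula](tg, m, coeffs)
    if not np.all(np.isfinite(result)):
        bad = np.argwhere(~np.isfinite(np.atleast_1d(result)))[0]
        raise ValueError(
            f"non-finite water potential at tg={np.atleast_1d(tg).ravel()[0]}, "
            f"m={np.atleast_1d(m).ravel()[0]} (index {bad})"
        )
    return result if result.ndim else float(result)


def awp_field(grid: TemperatureGrid, moisture: float, coeffs: GrainCoefficients,
              formula: str = "reconstructed-v1") -> AwpField:
    """Element-wise water potential over an imputed temperature grid."""
    if grid.mask.any():
        raise ValueError("grid has missing values; impute before computing water potential")
    return AwpField(values=awp(grid.values, moisture, coeffs, formula=formula))
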