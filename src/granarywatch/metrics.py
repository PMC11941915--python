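"""Evaluation metrics and series diagnostics.

Classification: per-class one-vs-rest precision/recall/F1, macro- and
micro-averaged, plus accuracy and a 6x6 confusion matrix.  Regression: MAE
and RMSE over all voxel-days.  Diagnostics: pooled moments plus ACF and
PACF (Durbin-Levinson) of the daily pile-mean trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .grid_core import GranarySeries, StorageState

__all__ = [
    "ConfusionMatrix",
    "RegressionScore",
    "SeriesDiagnostics",
    "ClassificationReport",
    "classification_metrics",
    "regression_metrics",
    "series_diagnostics",
    "relative_improvement",
    "channel_ablation",
]

N_STATES = len(StorageState)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (6, 6); rows = true, columns = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STATES, N_STATES) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 6x6 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self, c: int):
        """(TP, FP, FN, TN) for class index c, one-vs-rest."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum()) - tp
        fn = int(self.counts[c, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass
class ClassificationReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_f1_from_averages: float  # 2PR/(P+R) of the macro P and R
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_class: dict  # StorageState -> {precision, recall, f1, support}
    confusion: ConfusionMatrix
    zero_division_classes: list = field(default_factory=list)


@dataclass
class RegressionScore:
    mae: float
    rmse: float
    k: int

    def __post_init__(self):
        if not (self.rmse >= self.mae - 1e-12 >= -1e-12):
            raise ValueError("RMSE >= MAE >= 0 violated")


@dataclass
class SeriesDiagnostics:
    mean: float
    median: float
    sd: float
    max: float
    min: float
    skewness: float
    kurtosis: float  # excess
    acf: np.ndarray  # lags 0..max_lag
    pacf: np.ndarray  # lags 0..max_lag (pacf[0] = 1 by convention)
    constant_trace: bool = False


def _as_index(label) -> int:
    if isinstance(label, StorageState):
        return label.index
    if isinstance(label, (int, np.integer)) and 0 <= int(label) < N_STATES:
        return int(label)
    raise ValueError(f"label outside the 6-state set: {label!r}")


def classification_metrics(truth, predicted) -> ClassificationReport:
    truth = [_as_index(t) for t in truth]
    predicted = [_as_index(p) for p in predicted]
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[t, p] += 1
    cm = ConfusionMatrix(counts)

    per_class = {}
    zero_div = []
    precisions, recalls, f1s = [], [], []
    tp_sum = fp_sum = fn_sum = 0
    for c, state in enumerate(StorageState):
        tp, fp, fn, tn = cm.per_class(c)
        tp_sum += tp
        fp_sum += fp
        fn_sum += fn
        if tp + fp == 0 or tp + fn == 0:
            zero_div.append(state)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[state] = {"precision": prec, "recall": rec, "f1": f1, "support": tp + fn}
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)

    macro_p = float(np.mean(precisions))
    macro_r = float(np.mean(recalls))
    micro_p = tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
    micro_r = tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    return ClassificationReport(
        accuracy=float(np.trace(counts) / counts.sum()) if counts.sum() else 0.0,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=float(np.mean(f1s)),
        macro_f1_from_averages=(2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r else 0.0),
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f1=float(micro_f1),
        per_class=per_class,
        confusion=cm,
        zero_division_classes=zero_div,
    )


def regression_metrics(truth, predicted) -> RegressionScore:
    truth = np.asarray(truth, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if truth.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {predicted.shape}")
    err = predicted - truth
    return RegressionScore(
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        k=int(err.size),
    )


def acf(trace: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(trace, dtype=np.float64)
    x = x - x.mean()
    denom = float(x @ x)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = float(x[k:] @ x[:-k]) / denom
    return out


def pacf_durbin_levinson(acf_vals: np.ndarray) -> np.ndarray:
    """Partial autocorrelations from an ACF via the Durbin-Levinson recursion."""
    r = np.asarray(acf_vals, dtype=np.float64)
    max_lag = r.size - 1
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    if max_lag == 0:
        return out
    phi_prev = np.array([r[1]])
    out[1] = r[1]
    for k in range(2, max_lag + 1):
        num = r[k] - phi_prev @ r[1:k][::-1]
        den = 1.0 - phi_prev @ r[1:k]
        phi_kk = num / den
        phi = np.empty(k)
        phi[: k - 1] = phi_prev - phi_kk * phi_prev[::-1]
        phi[k - 1] = phi_kk
        out[k] = phi_kk
        phi_prev = phi
    return out


def series_diagnostics(series: GranarySeries, max_lag: int = 30) -> SeriesDiagnostics:
    values = series.values_array()
    mask = series.mask_array()
    pooled = values[~mask]
    with np.errstate(invalid="ignore"):
        daily = np.array(
            [g.values[~g.mask].mean() if (~g.mask).any() else np.nan for g in series.grids]
        )
    daily = daily[np.isfinite(daily)]
    if daily.size <= max_lag:
        raise ValueError(f"series length {daily.size} must exceed max_lag {max_lag}")
    constant = bool(np.ptp(daily) == 0.0)
    if constant:
        acf_vals = np.full(max_lag + 1, np.nan)
        acf_vals[0] = 1.0
        pacf_vals = acf_vals.copy()
    else:
        acf_vals = acf(daily, max_lag)
        pacf_vals = pacf_durbin_levinson(acf_vals)
    pooled_constant = np.ptp(pooled) == 0.0
    return SeriesDiagnostics(
        mean=float(pooled.mean()),
        median=float(np.median(pooled)),
        sd=float(pooled.std()),
        max=float(pooled.max()),
        min=float(pooled.min()),
        # higher moments are undefined for constant data
        skewness=float("nan") if pooled_constant else float(sps.skew(pooled)),
        kurtosis=float("nan") if pooled_constant else float(sps.kurtosis(pooled)),  # excess
        acf=acf_vals,
        pacf=pacf_vals,
        constant_trace=constant,
    )


def relative_improvement(model_score: float, baseline_score: float, decimals: int = 2) -> float:
    """Percent reduction of the model score relative to the baseline,
    rounded half-up to `decimals`."""
    if baseline_score <= 0:
        raise ValueError("baseline score must be > 0")
    pct = 100.0 * (baseline_score - model_score) / baseline_score
    scale = 10.0**decimals
    return float(np.floor(pct * scale + 0.5) / scale)


def channel_ablation(model, windows) -> dict:
    """MAE increase when each input channel is replaced by its training mean.

    The model standardizes inputs with training-partition statistics, so a
    channel's training mean corresponds to zero in standardized space.
    Returns {"baseline_mae": m, "deltas": {channel_name: mae_delta}}.
    """
    from .forecaster import evaluate_windows  # local import to avoid a cycle

    if model.config.channels != 2:
        raise ValueError("channel ablation requires the 2-channel forecaster")
    base = evaluate_windows(model, windows).mae
    names = ["temperature", "water_potential"]
    deltas = {}
    for ch, name in enumerate(names):
        score = evaluate_windows(model, windows, ablate_channel=ch).mae
        deltas[name] = score - base
    return {"baseline_mae": base, "deltas": deltas}
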