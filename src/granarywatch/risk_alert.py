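"""Forecast -> classify early-warning chain.

Forecast P days ahead, classify each predicted grid, raise an alert on the
first horizon day classified as condensation or mildew, and localize the
risk with simple voxel rules on the predicted grids.  Aeration / new-grain /
empty detections over the horizon are reported but are operational states,
not risks, so they never trigger an alert.

Hotspot localization rules are an artifact addition (coordinates reported
1-based); they are configurable, not learned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import ClassifierModel, classify
from .forecaster import ForecasterModel, forecast
from .grid_core import GranarySeries, StorageState
from .metrics import regression_metrics

__all__ = ["AlertReport", "HotspotRule", "run_alert", "evaluate_alert", "classify_horizon"]

RISK_STATES = (StorageState.CONDENSATION, StorageState.MILDEW)


@dataclass
class HotspotRule:
    mildew_rate: float = 0.5  # degC/day predicted warming over the horizon
    mildew_excess: float = 6.0  # degC above the pile spatial median on the alert day
    condensation_gradient: float = 8.0  # degC below the core mean, top layer

    def __post_init__(self):
        if min(self.mildew_rate, self.mildew_excess, self.condensation_gradient) <= 0:
            raise ValueError("hotspot thresholds must be > 0")


@dataclass
class AlertReport:
    horizon_states: list  # per horizon day: StorageState
    horizon_probabilities: np.ndarray  # (P, 6)
    alert_day: int | None  # 1-based horizon day (= lead time from issue date)
    alert_state: StorageState | None
    lead_time_days: int | None
    hotspot: list  # list of 1-based (x, y, z) voxels
    predicted: np.ndarray  # (P, 10, 6, 4) degC
    forecast_mae: float | None = None
    forecast_rmse: float | None = None
    timing_error_days: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.alert_day is not None and self.lead_time_days is not None:
            if self.lead_time_days < 1:
                raise ValueError("lead time must be >= 1 day")


def _mildew_hotspots(predicted: np.ndarray, day_idx: int, rule: "HotspotRule"):
    """Voxels with a fast fitted warming slope over the horizon, or sitting
    well above the pile spatial median on the alerted day (hot anomaly)."""
    P = predicted.shape[0]
    t = np.arange(P) - (P - 1) / 2.0
    slope = np.tensordot(t, predicted - predicted.mean(axis=0), axes=(0, 0)) / (t @ t)
    grid = predicted[day_idx]
    excess = grid - np.median(grid)
    hits = (slope > rule.mildew_rate) | (excess > rule.mildew_excess)
    return [tuple(int(c) + 1 for c in idx) for idx in np.argwhere(hits)]


def _condensation_hotspots(predicted: np.ndarray, day_idx: int, gradient: float):
    """Top-layer voxels far below the core mean on the alerted day."""
    grid = predicted[day_idx]
    core_mean = grid[:, :, :-1].mean()
    top = grid[:, :, -1]
    H = predicted.shape[3]
    return [
        (int(x) + 1, int(y) + 1, H)
        for x, y in np.argwhere(core_mean - top > gradient)
    ]


def classify_horizon(classifier: ClassifierModel, grids: np.ndarray):
    states, probs = classify(classifier, grids)
    return states, probs


def report_from_predictions(predicted: np.ndarray, states, probs,
                            rule: HotspotRule | None = None) -> AlertReport:
    """Assemble an AlertReport from predicted grids and their per-day states."""
    rule = rule or HotspotRule()
    alert_day = None
    alert_state = None
    for d, state in enumerate(states, start=1):
        if state in RISK_STATES:
            alert_day = d
            alert_state = state
            break

    hotspot: list = []
    if alert_state is StorageState.MILDEW:
        hotspot = _mildew_hotspots(predicted, alert_day - 1, rule)
    elif alert_state is StorageState.CONDENSATION:
        hotspot = _condensation_hotspots(predicted, alert_day - 1, rule.condensation_gradient)

    return AlertReport(
        horizon_states=list(states),
        horizon_probabilities=np.asarray(probs),
        alert_day=alert_day,
        alert_state=alert_state,
        lead_time_days=alert_day,
        hotspot=hotspot,
        predicted=predicted,
    )


def run_alert(series: GranarySeries, forecaster: ForecasterModel,
              classifier: ClassifierModel, rule: HotspotRule | None = None) -> AlertReport:
    """Forecast P grids from the series tail, classify each day, and report."""
    if classifier.stats is None or forecaster.input_stats is None:
        raise ValueError("both models must be trained (standardization stats attached)")
    predicted = forecast(forecaster, series)
    states, probs = classify_horizon(classifier, predicted)
    return report_from_predictions(predicted, states, probs, rule)


def evaluate_alert(report: AlertReport, truth_labels, truth_grids) -> AlertReport:
    """Attach forecast MAE/RMSE over the horizon and the alert timing error.

    `truth_labels` / `truth_grids` cover exactly the P horizon days.
    """
    P = report.predicted.shape[0]
    truth_grids = np.asarray(truth_grids, dtype=np.float64)
    if len(truth_labels) != P or truth_grids.shape[0] != P:
        raise ValueError(f"truth must cover the {P}-day horizon")
    score = regression_metrics(truth_grids, report.predicted)
    report.forecast_mae = score.mae
    report.forecast_rmse = score.rmse
    true_day = next(
        (d for d, lab in enumerate(truth_labels, start=1) if lab in RISK_STATES), None
    )
    if true_day is not None and report.alert_day is not None:
        report.timing_error_days = report.alert_day - true_day
    report.extra["true_event_day"] = true_day
    return report
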