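"""Two-channel 3DCNN-LSTM temperature-field forecaster.

Each of the T window days is embedded by a per-frame 3D convolution +
max-pool + flatten + fully connected stage; the T embeddings feed a stacked
LSTM whose final hidden state is mapped by a fully connected output layer
to P daily 10x6x4 grids, destandardized back to degrees C.

Channel 1 is grain temperature; channel 2 is absolute water potential
(dropped in the single-channel ablation, ``channels=1``).

``conv3d_reference`` and ``lstm_cell_reference`` are deliberately naive
evaluations of the convolution sum and the LSTM gate equations; they exist
as brute-force oracles for the production layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .grid_core import GranarySeries, TARGET_DIMS
from .metrics import RegressionScore, regression_metrics
from .preprocess import StandardizationStats, destandardize, standardize
from .sim import preprocess_series_to_grids
from .water_potential import GrainCoefficients, awp, default_coefficients

__all__ = [
    "ForecastConfig",
    "WindowSample",
    "ConvSpec",
    "LstmCellParams",
    "make_windows",
    "split_windows",
    "conv3d_reference",
    "lstm_cell_reference",
    "build_forecaster",
    "train_forecaster",
    "evaluate_windows",
    "persistence_baseline",
    "forecast",
]

VOXELS = int(np.prod(TARGET_DIMS))


@dataclass
class ForecastConfig:
    learning_rate: float = 0.001
    lstm_hidden: int = 128
    lstm_layers: int = 3
    dropout: float = 0.5
    window: int = 35  # T
    horizon: int = 10  # P
    channels: int = 2  # 1 = single-channel ablation
    conv_channels: int = 16
    embed_dim: int = 256
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    dtype: str = "float64"  # float32 roughly halves training time
    # predict the residual from the last observed grid (persistence skip);
    # False = map the hidden state straight to absolute temperatures
    residual: bool = True

    def __post_init__(self):
        if self.window < 1 or self.horizon < 1:
            raise ValueError("window and horizon must be >= 1")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 or 2")


@dataclass
class WindowSample:
    """A (T, X, Y, Z, C) input block and its (P, X, Y, Z) future target.

    Values are in physical units (degC / kJ per kg); standardization happens
    inside the trainer with training-partition statistics.
    """

    inputs: np.ndarray
    target: np.ndarray
    series_id: str = ""
    input_days: np.ndarray | None = None  # absolute day indices, contiguous
    target_days: np.ndarray | None = None

    def __post_init__(self):
        if self.inputs.shape[1:4] != TARGET_DIMS or self.target.shape[1:] != TARGET_DIMS:
            raise ValueError(f"window spatial dims must be {TARGET_DIMS}")
        if self.input_days is not None and self.target_days is not None:
            both = np.concatenate([self.input_days, self.target_days])
            if not np.all(np.diff(both) == 1):
                raise ValueError("window days must be contiguous with input preceding target")


@dataclass
class ConvSpec:
    """Kernel for the brute-force convolution oracle (single channel)."""

    weights: np.ndarray  # (KX, KY, KZ)
    bias: float = 0.0


@dataclass
class LstmCellParams:
    """Gate parameter triples; matrices right-multiply row vectors."""

    w_f: np.ndarray
    u_f: np.ndarray
    b_f: np.ndarray
    w_i: np.ndarray
    u_i: np.ndarray
    b_i: np.ndarray
    w_c: np.ndarray
    u_c: np.ndarray
    b_c: np.ndarray
    w_o: np.ndarray
    u_o: np.ndarray
    b_o: np.ndarray

    @classmethod
    def from_layer(cls, layer) -> "LstmCellParams":
        """Extract reference parameters from a production LSTMLayer."""
        H = layer.hidden_size
        wx, wh, b = layer.w_x.data, layer.w_h.data, layer.bias.data
        blocks = {name: i for i, name in enumerate("fico")}
        kw = {}
        for name, i in blocks.items():
            sl = slice(i * H, (i + 1) * H)
            kw[f"w_{name}"] = wx[:, sl]
            kw[f"u_{name}"] = wh[:, sl]
            kw[f"b_{name}"] = b[sl]
        return cls(**kw)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def conv3d_reference(inputs: np.ndarray, spec: ConvSpec) -> np.ndarray:
    """Direct triple-sum valid convolution (testing oracle, O(n * k) loops)."""
    inputs = np.asarray(inputs, dtype=np.float64)
    w = np.asarray(spec.weights, dtype=np.float64)
    if inputs.ndim != 3 or w.ndim != 3:
        raise ValueError("inputs and weights must be 3D")
    kx, ky, kz = w.shape
    ox, oy, oz = (i - k + 1 for i, k in zip(inputs.shape, w.shape))
    if min(ox, oy, oz) < 1:
        raise ValueError(f"kernel {w.shape} does not fit input {inputs.shape}")
    out = np.empty((ox, oy, oz))
    for i in range(ox):
        for j in range(oy):
            for k in range(oz):
                acc = 0.0
                for m in range(kx):
                    for n in range(ky):
                        for p in range(kz):
                            acc += w[m, n, p] * inputs[i + m, j + n, k + p]
                out[i, j, k] = acc + spec.bias
    return out


def lstm_cell_reference(x_t, h_prev, c_prev, params: LstmCellParams):
    """Literal gate-equation evaluation (testing oracle).

    Returns (h_t, c_t, gates) where gates = {f, i, c_tilde, o}.
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=np.float64))
    f = _sigmoid(x_t @ params.w_f + h_prev @ params.u_f + params.b_f)
    i = _sigmoid(x_t @ params.w_i + h_prev @ params.u_i + params.b_i)
    c_tilde = np.tanh(x_t @ params.w_c + h_prev @ params.u_c + params.b_c)
    o = _sigmoid(x_t @ params.w_o + h_prev @ params.u_o + params.b_o)
    c_t = f * c_prev + i * c_tilde
    h_t = o * np.tanh(c_t)
    return h_t, c_t, {"f": f, "i": i, "c_tilde": c_tilde, "o": o}


# ---------------------------------------------------------------------------
# Window construction


def _series_channels(series: GranarySeries, config: ForecastConfig,
                     coeffs: GrainCoefficients | None,
                     cleaning=None) -> np.ndarray:
    """(L, X, Y, Z, C) preprocessed temperature (+ water potential) stack."""
    temps = preprocess_series_to_grids(series, cleaning)
    if config.channels == 1:
        return temps[..., None]
    coeffs = coeffs or default_coefficients(series.variety)
    moisture = series.moisture
    if not np.all(np.isfinite(moisture)):
        raise ValueError(f"series {series.granary_id} lacks moisture data for the AWP channel")
    pot = np.stack([awp(temps[t], moisture[t], coeffs) for t in range(len(temps))])
    return np.stack([temps, pot], axis=-1)


def make_windows(series_list, config: ForecastConfig,
                 coeffs: GrainCoefficients | None = None, cleaning=None) -> list:
    """Stride-1 sliding windows; per series, count = L - T - P + 1."""
    if isinstance(series_list, GranarySeries):
        series_list = [series_list]
    T, P = config.window, config.horizon
    windows = []
    for series in series_list:
        L = series.n_days
        if L < T + P:
            raise ValueError(
                f"series {series.granary_id} has {L} days; needs >= {T + P} for T={T}, P={P}"
            )
        data = _series_channels(series, config, coeffs, cleaning)
        for a in range(T, L - P + 1):
            windows.append(
                WindowSample(
                    inputs=data[a - T : a],
                    target=data[a : a + P, ..., 0],
                    series_id=series.granary_id,
                    input_days=np.arange(a - T, a),
                    target_days=np.arange(a, a + P),
                )
            )
    return windows


def split_windows(windows, fractions=(0.70, 0.15, 0.15)):
    """Chronological per-series split; windows whose target days cross a
    partition boundary are dropped, so no test target day can appear in any
    training input window."""
    by_series: dict = {}
    for w in windows:
        by_series.setdefault(w.series_id, []).append(w)
    parts = ([], [], [])
    for sid, ws in by_series.items():
        last_day = max(int(w.target_days[-1]) for w in ws)
        n = last_day + 1
        b1 = int(np.floor(fractions[0] * n))
        b2 = b1 + int(np.floor(fractions[1] * n))
        for w in ws:
            a, z = int(w.target_days[0]), int(w.target_days[-1])
            if z < b1:
                parts[0].append(w)
            elif a >= b1 and z < b2:
                parts[1].append(w)
            elif a >= b2:
                parts[2].append(w)
            # else: crosses a boundary -> dropped
    return parts


# ---------------------------------------------------------------------------
# Model


class ForecasterModel(nn.Module):
    def __init__(self, config: ForecastConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.channels
        self.conv = nn.Conv3d(C, config.conv_channels, 3, rng, padding=1)
        pooled = tuple(s // 2 for s in TARGET_DIMS)
        if min(pooled) < 1:
            raise ValueError("max pooling collapses the spatial dims")
        self.flat_dim = config.conv_channels * int(np.prod(pooled))
        self.embed = nn.Linear(self.flat_dim, config.embed_dim, rng)
        self.lstm = nn.LSTM(
            config.embed_dim,
            config.lstm_hidden,
            config.lstm_layers,
            rng,
            dropout_p=config.dropout,
        )
        self.drop = nn.Dropout(config.dropout, np.random.default_rng(config.seed + 1))
        self.head = nn.Linear(config.lstm_hidden, config.horizon * VOXELS, rng)
        if config.residual:
            # zero-init the head: the model starts exactly at persistence
            self.head.weight.data[:] = 0.0
            self.head.bias.data[:] = 0.0
        self.input_stats: StandardizationStats | None = None  # per channel
        self.coeffs: GrainCoefficients | None = None
        self.cleaning = None  # CleaningConfig used at training time

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(B, T, X, Y, Z, C) standardized -> (B, P, X, Y, Z) standardized."""
        B, T = x.shape[0], x.shape[1]
        C = self.config.channels
        frames = x.transpose((0, 1, 5, 2, 3, 4)).reshape(B * T, C, *TARGET_DIMS)
        h = nn.maxpool3d(self.conv(frames).relu(), 2)
        h = self.embed(h.reshape(B * T, self.flat_dim)).relu()
        seq = h.reshape(B, T, self.config.embed_dim)
        last = self.lstm(seq)
        out = self.head(self.drop(last))
        out = out.reshape(B, self.config.horizon, *TARGET_DIMS)
        if self.config.residual:
            anchor = x[:, T - 1, :, :, :, 0].reshape(B, 1, *TARGET_DIMS)
            out = out + anchor
        return out

    # -- numpy-level helpers -------------------------------------------
    def _standardize_inputs(self, inputs: np.ndarray, ablate_channel: int | None = None) -> np.ndarray:
        z = standardize(inputs, self.input_stats, channel_axis=-1)
        if ablate_channel is not None:
            z = z.copy()
            z[..., ablate_channel] = 0.0  # channel's training mean
        return z

    def predict(self, inputs: np.ndarray, ablate_channel: int | None = None) -> np.ndarray:
        """(B, T, X, Y, Z, C) physical units -> (B, P, X, Y, Z) degC."""
        self.eval()
        z = self._standardize_inputs(inputs, ablate_channel)
        out = self.forward(nn.Tensor(z)).data
        temp_stats = StandardizationStats(self.input_stats.mean[:1], self.input_stats.sd[:1])
        return destandardize(out, temp_stats)


def build_forecaster(config: ForecastConfig | None = None) -> ForecasterModel:
    return ForecasterModel(config or ForecastConfig())


@dataclass
class ForecastHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_mae: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def _stack(windows):
    x = np.stack([w.inputs for w in windows])
    y = np.stack([w.target for w in windows])
    return x, y


def train_forecaster(splits, config: ForecastConfig | None = None,
                     coeffs: GrainCoefficients | None = None, cleaning=None):
    """Adam + MSE on standardized targets with early stopping.

    `splits` is the (train, val, test) output of :func:`split_windows`.
    Returns (model, ForecastHistory).
    """
    config = config or ForecastConfig()
    train_w, val_w = splits[0], splits[1]
    if not train_w or not val_w:
        raise ValueError("empty train or validation window set")
    x_train, y_train = _stack(train_w)
    x_val, y_val = _stack(val_w)

    flat = x_train.reshape(-1, x_train.shape[-1])
    stats = StandardizationStats(flat.mean(axis=0), flat.std(axis=0))
    temp_stats = StandardizationStats(stats.mean[:1], stats.sd[:1])

    with nn.default_dtype(config.dtype):
        model = build_forecaster(config)
        model.input_stats = stats
        model.coeffs = coeffs or default_coefficients("wheat")
        model.cleaning = cleaning
        xz_train = standardize(x_train, stats, channel_axis=-1).astype(config.dtype)
        xz_val = standardize(x_val, stats, channel_axis=-1).astype(config.dtype)
        yz_train = standardize(y_train, temp_stats).astype(config.dtype)
        yz_val = standardize(y_val, temp_stats)

        opt = nn.Adam(model.parameters(), lr=config.learning_rate)
        rng = np.random.default_rng(config.seed + 2)
        history = ForecastHistory()
        best_val = np.inf
        best_arrays = None
        bad = 0
        for epoch in range(1, config.max_epochs + 1):
            model.train()
            order = rng.permutation(len(xz_train))
            losses = []
            for lo in range(0, len(order), config.batch_size):
                idx = order[lo : lo + config.batch_size]
                pred = model(nn.Tensor(xz_train[idx]))
                loss = ((pred - nn.Tensor(yz_train[idx])).pow(2.0)).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            model.eval()
            val_pred = model(nn.Tensor(xz_val)).data
            val_loss = float(((val_pred - yz_val) ** 2).mean())
            val_mae = float(np.abs(destandardize(val_pred, temp_stats) - y_val).mean())
            history.train_loss.append(float(np.mean(losses)))
            history.val_loss.append(val_loss)
            history.val_mae.append(val_mae)
            history.stopped_epoch = epoch
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                history.best_epoch = epoch
                best_arrays = [p.copy() for p in model.state_arrays()]
                bad = 0
            else:
                bad += 1
                if bad >= config.patience:
                    break
    if best_arrays is not None:
        model.load_state_arrays(best_arrays)
    model.eval()
    return model, history


def evaluate_windows(model: ForecasterModel, windows, ablate_channel: int | None = None,
                     batch_size: int = 64) -> RegressionScore:
    """Forecast-vs-truth MAE/RMSE (degC) over a window set."""
    preds, truths = [], []
    for lo in range(0, len(windows), batch_size):
        chunk = windows[lo : lo + batch_size]
        x, y = _stack(chunk)
        preds.append(model.predict(x, ablate_channel=ablate_channel))
        truths.append(y)
    return regression_metrics(np.concatenate(truths), np.concatenate(preds))


def persistence_baseline(windows) -> RegressionScore:
    """Predict the last observed temperature grid for every horizon day."""
    preds, truths = [], []
    for w in windows:
        last = w.inputs[-1, ..., 0]
        preds.append(np.broadcast_to(last, w.target.shape))
        truths.append(w.target)
    return regression_metrics(np.stack(truths), np.stack(preds))


def forecast(model: ForecasterModel, series: GranarySeries,
             coeffs: GrainCoefficients | None = None) -> np.ndarray:
    """Forecast the next P daily grids (degC) from a series tail of >= T days."""
    T = model.config.window
    if series.n_days < T:
        raise ValueError(f"series tail has {series.n_days} days; forecaster window is {T}")
    data = _series_channels(series, model.config, coeffs or model.coeffs, model.cleaning)[-T:]
    return model.predict(data[None])[0]
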