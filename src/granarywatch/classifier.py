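"""Six-way storage-state classifier: a 3D DenseNet.

Architecture: initial 3x3x3 convolution, then dense blocks (each layer's
input is the concatenation of the block input and all earlier layer
outputs; layer order BN -> ReLU -> conv) separated by transition layers
(1x1x1 channel compression then 2x average pooling), global average
pooling, a fully connected head, and softmax over the six states.

Training: Adam + class-weighted cross-entropy, stratified 70/15/15 split,
early stopping on validation loss with best-weight restore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .grid_core import ClassSample, StorageState, TARGET_DIMS
from .preprocess import StandardizationStats, standardize

__all__ = [
    "DenseNetConfig",
    "ClassifierModel",
    "TrainHistory",
    "build_classifier",
    "split_dataset",
    "class_weights",
    "train_classifier",
    "classify",
]

N_STATES = len(StorageState)


@dataclass
class DenseNetConfig:
    learning_rate: float = 0.001
    base_channels: int = 32
    dropout: float = 0.3
    num_dense_blocks: int = 3
    layers_per_block: int = 4
    compression: float = 0.5
    growth_rate: int | None = None  # defaults to base_channels
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    dtype: str = "float64"  # float32 roughly halves training time

    def __post_init__(self):
        if not 0.0 < self.compression <= 1.0:
            raise ValueError("compression must lie in (0, 1]")
        if self.num_dense_blocks < 1 or self.layers_per_block < 1:
            raise ValueError("blocks and layers per block must be >= 1")
        if self.growth_rate is None:
            self.growth_rate = self.base_channels


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class _DenseLayer(nn.Module):
    def __init__(self, in_channels, growth, rng):
        super().__init__()
        self.bn = nn.BatchNorm3d(in_channels)
        self.conv = nn.Conv3d(in_channels, growth, 3, rng, padding=1)

    def forward(self, x):
        return self.conv(self.bn(x).relu())


class _DenseBlock(nn.Module):
    def __init__(self, in_channels, n_layers, growth, rng):
        super().__init__()
        self.layers = [
            _DenseLayer(in_channels + k * growth, growth, rng) for k in range(n_layers)
        ]
        self.out_channels = in_channels + n_layers * growth
        # dense connectivity: layer k consumes in_channels + k * growth channels
        self.input_channels = [in_channels + k * growth for k in range(n_layers)]

    def forward(self, x):
        for layer in self.layers:
            x = nn.concat([x, layer(x)], axis=1)
        return x


class _Transition(nn.Module):
    def __init__(self, in_channels, compression, rng):
        super().__init__()
        self.out_channels = max(1, int(np.floor(in_channels * compression)))
        self.conv = nn.Conv3d(in_channels, self.out_channels, 1, rng)

    def forward(self, x):
        return nn.avgpool3d(self.conv(x), 2)


class ClassifierModel(nn.Module):
    def __init__(self, config: DenseNetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stem = nn.Conv3d(1, config.base_channels, 3, rng, padding=1)
        self.blocks = []
        self.transitions = []
        self.layer_shapes = []  # (stage, channels, spatial) log
        ch = config.base_channels
        spatial = list(TARGET_DIMS)
        self.layer_shapes.append(("stem", ch, tuple(spatial)))
        for b in range(config.num_dense_blocks):
            block = _DenseBlock(ch, config.layers_per_block, config.growth_rate, rng)
            self.blocks.append(block)
            ch = block.out_channels
            self.layer_shapes.append((f"dense_block_{b + 1}", ch, tuple(spatial)))
            if b < config.num_dense_blocks - 1:
                tr = _Transition(ch, config.compression, rng)
                self.transitions.append(tr)
                ch = tr.out_channels
                spatial = [s // 2 for s in spatial]
                if min(spatial) < 1:
                    raise ValueError(
                        f"transition after dense block {b + 1} collapses spatial dims to {tuple(spatial)}"
                    )
                self.layer_shapes.append((f"transition_{b + 1}", ch, tuple(spatial)))
        self.drop = nn.Dropout(config.dropout, np.random.default_rng(config.seed + 1))
        self.head = nn.Linear(ch, N_STATES, rng)
        self.stats: StandardizationStats | None = None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(B, 1, 10, 6, 4) standardized input -> (B, 6) logits."""
        x = self.stem(x)
        for b, block in enumerate(self.blocks):
            x = block(x)
            if b < len(self.transitions):
                x = self.transitions[b](x)
        x = x.mean(axis=(2, 3, 4))  # global average pooling
        return self.head(self.drop(x))

    def probabilities(self, grids: np.ndarray) -> np.ndarray:
        """Softmax probabilities for a (B, 10, 6, 4) standardized batch."""
        self.eval()
        logits = self.forward(nn.Tensor(grids.reshape(-1, 1, *TARGET_DIMS))).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def build_classifier(config: DenseNetConfig | None = None) -> ClassifierModel:
    return ClassifierModel(config or DenseNetConfig())


def split_dataset(samples, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Stratified, seeded (train, val, test) split with largest-remainder
    rounding per class."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.label, []).append(i)
    parts = ([], [], [])
    for state, idxs in by_class.items():
        n = len(idxs)
        if n < 3:
            raise ValueError(f"class {state} has {n} samples; need >= 3 to split")
        idxs = list(rng.permutation(idxs))
        exact = [f * n for f in fractions]
        base = [int(np.floor(e)) for e in exact]
        short = n - sum(base)
        order = np.argsort([b - e for b, e in zip(base, exact)])  # largest remainder first
        for j in order[:short]:
            base[j] += 1
        lo = 0
        for part, size in zip(parts, base):
            part.extend(idxs[lo : lo + size])
            lo += size
    return tuple([samples[i] for i in sorted(part)] for part in parts)


def class_weights(labels) -> np.ndarray:
    """w_c = N / (K * n_c), normalized to mean 1, over the six states."""
    counts = np.zeros(N_STATES)
    for lab in labels:
        counts[lab.index if isinstance(lab, StorageState) else int(lab)] += 1
    if (counts == 0).any():
        missing = [s.value for s, c in zip(StorageState, counts) if c == 0]
        raise ValueError(f"empty class(es): {missing}")
    w = len(labels) / (N_STATES * counts)
    return w / w.mean()


def _forward_loss(model, grids, labels, weights, train: bool):
    if train:
        model.train()
    else:
        model.eval()
    logits = model(nn.Tensor(grids.reshape(-1, 1, *TARGET_DIMS), requires_grad=False))
    loss = nn.softmax_cross_entropy(logits, labels, weights)
    acc = float((logits.data.argmax(axis=1) == labels).mean())
    return loss, acc


def train_classifier(splits, config: DenseNetConfig | None = None):
    """Train on a (train, val, test) ClassSample split.

    Standardization statistics are computed from the training partition and
    stored on the model for inference use.  Returns (model, TrainHistory).
    """
    config = config or DenseNetConfig()
    train_set, val_set = splits[0], splits[1]
    stats = StandardizationStats.from_data(np.stack([s.grid for s in train_set]))

    def prep(part):
        grids = standardize(np.stack([s.grid for s in part]), stats)
        labels = np.array([s.label.index for s in part])
        return grids, labels

    x_train, y_train = prep(train_set)
    x_val, y_val = prep(val_set)
    x_train = x_train.astype(config.dtype)
    x_val = x_val.astype(config.dtype)
    weights = class_weights([s.label for s in train_set])

    with nn.default_dtype(config.dtype):
        model = build_classifier(config)
        model.stats = stats
        opt = nn.Adam(model.parameters(), lr=config.learning_rate)
        rng = np.random.default_rng(config.seed + 2)
        history = TrainHistory()
        best_val = np.inf
        best_arrays = None
        bad_epochs = 0

        for epoch in range(1, config.max_epochs + 1):
            order = rng.permutation(len(x_train))
            losses, accs = [], []
            for lo in range(0, len(order), config.batch_size):
                idx = order[lo : lo + config.batch_size]
                loss, acc = _forward_loss(model, x_train[idx], y_train[idx], weights, train=True)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                accs.append(acc)
            val_loss, val_acc = _forward_loss(model, x_val, y_val, weights, train=False)
            history.train_loss.append(float(np.mean(losses)))
            history.train_accuracy.append(float(np.mean(accs)))
            history.val_loss.append(float(val_loss.data))
            history.val_accuracy.append(val_acc)
            history.stopped_epoch = epoch
            if val_loss.data < best_val - 1e-12:
                best_val = float(val_loss.data)
                history.best_epoch = epoch
                best_arrays = [p.copy() for p in model.state_arrays()]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    break
    if best_arrays is not None:
        model.load_state_arrays(best_arrays)
    model.eval()
    return model, history


def classify(model: ClassifierModel, grid: np.ndarray):
    """Classify one 10x6x4 grid (degrees C) or a batch of them.

    Returns (StorageState, probabilities) for a single grid, or
    (list of StorageState, (B, 6) array) for a batch.
    """
    grid = np.asarray(grid, dtype=np.float64)
    single = grid.shape == TARGET_DIMS
    if not single and grid.shape[1:] != TARGET_DIMS:
        raise ValueError(f"expected dims {TARGET_DIMS}, got {grid.shape}")
    if model.stats is None:
        raise ValueError("model has no standardization stats; train it first")
    batch = grid[None] if single else grid
    probs = model.probabilities(standardize(batch, model.stats))
    states = [StorageState.from_index(int(i)) for i in probs.argmax(axis=1)]
    if single:
        return states[0], probs[0]
    return states, probs
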