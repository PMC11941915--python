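"""Neural-network layers built on the autograd tensor.

Weight initialisation draws from an explicit ``numpy.random.Generator`` so
every model is bit-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    avgpool3d,
    batchnorm,
    conv3d,
    dropout,
    maxpool3d,
)

__all__ = [
    "Module",
    "Linear",
    "Conv3d",
    "BatchNorm3d",
    "MaxPool3d",
    "AvgPool3d",
    "Dropout",
    "LSTM",
    "Sequential",
    "ReLU",
]


class Module:
    """Tiny nn.Module analogue: parameter discovery + train/eval flag."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self):
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def state_arrays(self):
        """Flat list of parameter arrays (views) in discovery order."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=np.float64)

    def num_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng, padding=0):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size,) * 3
        fan_in = in_channels * int(np.prod(kernel_size))
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (out_channels, in_channels, *kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(rng.uniform(-bound, bound, out_channels), requires_grad=True)
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm3d(Module):
    def __init__(self, num_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return batchnorm(x, self.gamma, self.beta, mu, var, self.eps, batch_stats=True)
        return batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.eps, batch_stats=False
        )


class MaxPool3d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return maxpool3d(x, self.kernel)


class AvgPool3d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return avgpool3d(x, self.kernel)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class LSTMLayer(Module):
    """Single LSTM layer over a (B, T, F) sequence.

    Gate order in the packed weight matrices is (forget, input, candidate,
    output); all four gate transforms use the same (F,H)/(H,H) block layout
    so reference-cell parameters can be loaded directly.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        bound = 1.0 / np.sqrt(hidden_size)
        self.w_x = Tensor(rng.uniform(-bound, bound, (input_size, 4 * hidden_size)), requires_grad=True)
        self.w_h = Tensor(rng.uniform(-bound, bound, (hidden_size, 4 * hidden_size)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, 4 * hidden_size), requires_grad=True)

    def forward(self, x: Tensor):
        B, T, _ = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((B, H), dtype=x.data.dtype))
        c = Tensor(np.zeros((B, H), dtype=x.data.dtype))
        outputs = []
        for t in range(T):
            xt = x[:, t]
            z = xt @ self.w_x + h @ self.w_h + self.bias
            f = z[:, 0:H].sigmoid()
            i = z[:, H : 2 * H].sigmoid()
            ctilde = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * ctilde
            h = o * c.tanh()
            outputs.append(h)
        return outputs, (h, c)


class LSTM(Module):
    """Stacked LSTM; returns the final layer's last hidden state."""

    def __init__(self, input_size, hidden_size, num_layers, rng, dropout_p=0.0):
        super().__init__()
        self.cells = [
            LSTMLayer(input_size if k == 0 else hidden_size, hidden_size, rng)
            for k in range(num_layers)
        ]
        self.dropout_p = dropout_p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        seq = x
        h_last = None
        for k, cell in enumerate(self.cells):
            outputs, (h_last, _) = cell(seq)
            if k < len(self.cells) - 1:
                if self.dropout_p > 0:
                    outputs = [dropout(h, self.dropout_p, self.rng, self.training) for h in outputs]
                stacked = [h.reshape(h.shape[0], 1, h.shape[1]) for h in outputs]
                from .tensor import concat

                seq = concat(stacked, axis=1)
        return h_last
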