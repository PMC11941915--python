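"""Minority-class expansion: axis flips and a 3D GAN.

The flip set is {identity, flip-X, flip-Y, flip-Z} — exactly quadrupling
the sample count.  The GAN is a small DCGAN-style pair trained with the
non-saturating adversarial loss on standardized grids; generated samples
are mapped back to degrees C through the same destandardize path as real
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .grid_core import ClassSample, StorageState, TARGET_DIMS
from .preprocess import StandardizationStats, destandardize, standardize

__all__ = ["GanConfig", "GanBundle", "flip_augment", "train_gan", "generate", "rebalance"]


@dataclass
class GanConfig:
    noise_dim: int = 100
    base_channels: int = 48  # generator channels at the low-resolution root
    dropout: float = 0.3
    lr_generator: float = 2e-4
    lr_discriminator: float = 2e-4
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    flip_axes: tuple = (0, 1, 2)  # z-flip can be disabled by dropping axis 2

    def __post_init__(self):
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")


class _Generator(nn.Module):
    """noise -> FC -> (C,3,2,1) map -> three upsample+conv stages -> 10x6x4."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        C = config.base_channels
        self.C = C
        self.fc = nn.Linear(config.noise_dim, C * 3 * 2 * 1, rng)
        self.conv1 = nn.Conv3d(C, C // 2, 3, rng, padding=1)
        self.conv2 = nn.Conv3d(C // 2, C // 4, 3, rng, padding=1)
        self.conv3 = nn.Conv3d(C // 4, 1, 3, rng, padding=1)

    def forward(self, z: nn.Tensor) -> nn.Tensor:
        B = z.shape[0]
        x = self.fc(z).relu().reshape(B, self.C, 3, 2, 1)
        x = nn.nearest_resize3d(x, (5, 3, 2))
        x = self.conv1(x).relu()
        x = nn.nearest_resize3d(x, TARGET_DIMS)
        x = self.conv2(x).relu()
        return self.conv3(x)  # linear output on standardized scale


class _Discriminator(nn.Module):
    """Two 3D conv layers -> FC -> real/fake logit (sigmoid probability)."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv3d(1, 16, 3, rng, padding=1)
        self.conv2 = nn.Conv3d(16, 32, 3, rng, padding=1)
        self.drop = nn.Dropout(config.dropout, rng)
        self.fc = nn.Linear(32 * 5 * 3 * 2, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = self.drop(self.conv1(x).relu())
        x = nn.maxpool3d(x, 2)
        x = self.drop(self.conv2(x).relu())
        return self.fc(x.reshape(x.shape[0], -1))

    def probability(self, grids: np.ndarray) -> np.ndarray:
        self.eval()
        logits = self.forward(nn.Tensor(grids.reshape(-1, 1, *TARGET_DIMS)))
        return 1.0 / (1.0 + np.exp(-logits.data.ravel()))


@dataclass
class GanBundle:
    generator: _Generator
    discriminator: _Discriminator
    state: StorageState
    stats: StandardizationStats
    config: GanConfig
    history: dict = field(default_factory=dict)  # generator/discriminator loss per epoch


def flip_augment(samples, axes=(0, 1, 2)):
    """originals + one flipped copy per axis; labels preserved, provenance marked."""
    out = []
    for s in samples:
        out.append(s)
        for axis in axes:
            out.append(
                ClassSample(grid=np.flip(s.grid, axis=axis).copy(), label=s.label, provenance="flipped")
            )
    return out


def train_gan(real, config: GanConfig | None = None) -> GanBundle:
    """Adversarial training on one state's real samples (non-saturating loss)."""
    config = config or GanConfig()
    if len(real) < 8:
        raise ValueError(f"need >= 8 real samples to train a GAN, got {len(real)}")
    labels = {s.label for s in real}
    if len(labels) != 1:
        raise ValueError(f"all real samples must share one label, got {labels}")
    (state,) = labels

    data = np.stack([s.grid for s in real])
    stats = StandardizationStats.from_data(data)
    data = standardize(data, stats)

    init_rng = np.random.default_rng(config.seed)
    train_rng = np.random.default_rng(config.seed + 1)
    gen = _Generator(config, init_rng)
    disc = _Discriminator(config, init_rng)
    opt_g = nn.Adam(gen.parameters(), lr=config.lr_generator, betas=(0.5, 0.999))
    opt_d = nn.Adam(disc.parameters(), lr=config.lr_discriminator, betas=(0.5, 0.999))

    n = data.shape[0]
    bs = min(config.batch_size, n)
    history = {"generator": [], "discriminator": []}
    for _ in range(config.epochs):
        order = train_rng.permutation(n)
        d_losses, g_losses = [], []
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            real_batch = data[idx].reshape(-1, 1, *TARGET_DIMS)
            z = train_rng.standard_normal((len(idx), config.noise_dim))

            # discriminator step
            fake = gen(nn.Tensor(z)).data
            both = np.concatenate([real_batch, fake])
            targets = np.concatenate([np.ones(len(idx)), np.zeros(len(idx))])
            logits = disc(nn.Tensor(both)).reshape(-1)
            d_loss = nn.bce_with_logits(logits, targets)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # generator step (non-saturating: maximize log D(G(z)))
            z2 = train_rng.standard_normal((len(idx), config.noise_dim))
            fake_t = gen(nn.Tensor(z2))
            logits_f = disc(fake_t).reshape(-1)
            g_loss = nn.bce_with_logits(logits_f, np.ones(len(idx)))
            opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()

            d_losses.append(float(d_loss.data))
            g_losses.append(float(g_loss.data))
        history["discriminator"].append(float(np.mean(d_losses)))
        history["generator"].append(float(np.mean(g_losses)))

    return GanBundle(generator=gen, discriminator=disc, state=state, stats=stats,
                     config=config, history=history)


def generate(bundle: GanBundle, n: int, seed: int = 0):
    """Draw n synthetic samples from a trained bundle (provenance 'gan')."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, bundle.config.noise_dim))
    bundle.generator.eval()
    grids = bundle.generator(nn.Tensor(z)).data.reshape(n, *TARGET_DIMS)
    bundle.generator.train()
    grids = destandardize(grids, bundle.stats)
    return [ClassSample(grid=g, label=bundle.state, provenance="gan") for g in grids]


def rebalance(dataset, targets: dict, config: GanConfig | None = None, seed: int = 0):
    """Bring per-class counts exactly to `targets`.

    Deficits are filled by axis flips first and GAN generation for the
    remainder; surpluses are removed by seeded random downsampling.  Classes
    not named in `targets` pass through unchanged.
    """
    config = config or GanConfig()
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for s in dataset:
        by_class.setdefault(s.label, []).append(s)

    out = []
    for state, samples in by_class.items():
        if state not in targets:
            out.extend(samples)
            continue
        target = int(targets[state])
        n = len(samples)
        if target == n:
            out.extend(samples)
        elif target < n:
            keep = rng.choice(n, size=target, replace=False)
            out.extend(samples[i] for i in sorted(keep))
        else:
            pool = list(samples)
            flips = [s for s in flip_augment(samples, axes=config.flip_axes) if s.provenance == "flipped"]
            need = target - n
            take = min(need, len(flips))
            order = rng.permutation(len(flips))[:take]
            pool.extend(flips[i] for i in sorted(order))
            remainder = target - len(pool)
            if remainder > 0:
                bundle = train_gan(samples, config)
                pool.extend(generate(bundle, remainder, seed=int(rng.integers(2**31 - 1))))
            out.extend(pool)
    for state, target in targets.items():
        if state not in by_class and target > 0:
            raise ValueError(f"cannot reach target {target} for {state}: no real samples")
    return out
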