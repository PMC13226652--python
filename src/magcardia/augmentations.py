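"""Stochastic views for contrastive pretraining.

Three transforms, applied in order with independent draws per view:

(i)  additive Gaussian noise scaled to each channel's standard deviation;
(ii) random channel dropout — 10% of the valid channels replaced entirely
     by noise drawn from that channel's own distribution;
(iii) per-channel temporal masking — a contiguous run of up to 75% of the
     segment replaced by the channel mean.

All-zero (missing) channels are never selected for dropout and receive no
noise; transforms preserve the (64, 5000) shape and are deterministic for
a given random generator state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AugmentationConfig:
    noise_scale: float = 1.0           # multiplier on per-channel std
    channel_dropout_fraction: float = 0.10
    max_mask_fraction: float = 0.75
    enable_noise: bool = True
    enable_dropout: bool = True
    enable_mask: bool = True
    dropout_mode: str = "gaussian"     # or "bootstrap"

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        for name in ("channel_dropout_fraction", "max_mask_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dropout_mode not in ("gaussian", "bootstrap"):
            raise ValueError("dropout_mode must be 'gaussian' or 'bootstrap'")


def _valid_mask(x: np.ndarray, valid_channels: np.ndarray | None) -> np.ndarray:
    if valid_channels is not None:
        return np.asarray(valid_channels, dtype=bool)
    return ~np.all(x == 0.0, axis=1)


def add_gaussian_noise(x: np.ndarray, alpha: float, rng: np.random.Generator,
                       valid_channels: np.ndarray | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise with std ``alpha * sigma_c`` per channel."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0:
        return x.copy()
    y = x.copy()
    valid = _valid_mask(x, valid_channels)
    sigma = x.std(axis=1, keepdims=True)
    noise = rng.standard_normal(x.shape).astype(x.dtype)
    y[valid] = y[valid] + alpha * sigma[valid] * noise[valid]
    return y


def dropout_count(n_valid: int, fraction: float) -> int:
    """Round-half-even channel count, with a floor of 1 when fraction > 0."""
    n = int(np.round(fraction * n_valid))
    if fraction > 0 and n_valid > 0:
        n = max(n, 1)
    return n


def channel_dropout(x: np.ndarray, fraction: float, rng: np.random.Generator,
                    valid_channels: np.ndarray | None = None,
                    mode: str = "gaussian") -> np.ndarray:
    """Replace a random subset of valid channels by noise matching each
    channel's own distribution (Gaussian moment match by default, bootstrap
    resampling as an alternative)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    y = x.copy()
    if fraction == 0:
        return y
    valid = np.flatnonzero(_valid_mask(x, valid_channels))
    n = dropout_count(valid.size, fraction)
    if n == 0:
        return y
    chosen = rng.choice(valid, size=min(n, valid.size), replace=False)
    T = x.shape[1]
    for c in chosen:
        if mode == "bootstrap":
            y[c] = rng.choice(x[c], size=T, replace=True)
        else:
            y[c] = x[c].mean() + x[c].std() * rng.standard_normal(T).astype(x.dtype)
    return y


def temporal_mask(x: np.ndarray, max_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Per channel, replace a contiguous run of length L ~ U{0..floor(f*T)}
    starting at s ~ U{0..T-L} by the channel's pre-mask mean."""
    if not 0.0 <= max_fraction <= 1.0:
        raise ValueError("max_fraction must be in [0, 1]")
    y = x.copy()
    if max_fraction == 0:
        return y
    T = x.shape[1]
    L_max = int(np.floor(max_fraction * T))
    for c in range(x.shape[0]):
        L = int(rng.integers(0, L_max + 1))
        s = int(rng.integers(0, T - L + 1))
        if L > 0:
            y[c, s:s + L] = x[c].mean()
    return y


def augment(x: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator,
            valid_channels: np.ndarray | None = None) -> np.ndarray:
    """One stochastic view: noise -> channel dropout -> temporal mask."""
    y = x
    if cfg.enable_noise:
        y = add_gaussian_noise(y, cfg.noise_scale, rng, valid_channels)
    if cfg.enable_dropout:
        y = channel_dropout(y, cfg.channel_dropout_fraction, rng,
                            valid_channels, cfg.dropout_mode)
    if cfg.enable_mask:
        y = temporal_mask(y, cfg.max_mask_fraction, rng)
    return y if y is not x else x.copy()


def make_views(x: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator,
               valid_channels: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of the same segment."""
    return (augment(x, cfg, rng, valid_channels),
            augment(x, cfg, rng, valid_channels))
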