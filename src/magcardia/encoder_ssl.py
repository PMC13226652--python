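"""Temporal-convolutional MCG encoder and contrastive (NT-Xent) pretraining.

The encoder treats the 64 sensor channels as input feature maps and
convolves only over time, so every layer mixes channels while local
waveform morphology is captured by the temporal kernels.  Four residual
blocks (conv-ReLU-conv plus a 1x1 projection shortcut) progressively
downsample the 10-second segment; global average pooling over time and a
linear map produce one fixed-dimensional embedding per segment.

Pretraining follows the SimCLR recipe: two independently augmented views
per segment, a 2-layer projection head, and the normalised-temperature
cross-entropy (NT-Xent) loss over in-batch negatives, optimised with AdamW
under a cosine learning-rate schedule.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augmentations import AugmentationConfig, make_views
from .preprocess import Segment

N_CHANNELS = 64
SEGMENT_SAMPLES = 5000


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyper-parameters.

    ``default()`` is the full-scale variant (widths 32/64/128/128, kernel 15,
    stride 2 per block, 128-d embedding); ``desk()`` is a scaled-down variant
    for single-CPU experiments.
    """

    widths: tuple[int, ...] = (32, 64, 128, 128)
    kernels: tuple[int, ...] = (15, 15, 15, 15)
    strides: tuple[int, ...] = (2, 2, 2, 2)
    embed_dim: int = 128
    proj_hidden: int = 128
    proj_dim: int = 64
    use_projection_head: bool = True
    # scale each segment to unit RMS (over its non-zero channels) before the
    # first convolution; field amplitude varies with standoff and is not a
    # morphology feature, so the pipeline discards it here
    normalize_input: bool = True

    def __post_init__(self):
        if not (len(self.widths) == len(self.kernels) == len(self.strides)):
            raise ValueError("widths, kernels and strides must have equal length")
        if self.embed_dim < 8:
            raise ValueError("embed_dim must be >= 8")

    @classmethod
    def default(cls) -> "EncoderConfig":
        return cls()

    @classmethod
    def desk(cls) -> "EncoderConfig":
        return cls(widths=(8, 16, 32, 32), kernels=(8, 9, 9, 9),
                   strides=(8, 2, 2, 2), embed_dim=32, proj_hidden=32,
                   proj_dim=32)


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 100
    batch_size: int = 32
    temperature: float = 0.1
    lr0: float = 1e-3
    weight_decay: float = 1e-4
    lr_floor_frac: float = 0.01
    seed: int = 0
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


class ResidualBlock:
    """conv(k, s) -> ReLU -> conv(k, 1), added to a 1x1 stride-s shortcut."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = nn.Conv1d(c_in, c_out, kernel, stride, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv1d(c_out, c_out, kernel, 1, rng)
        self.identity_shortcut = (c_in == c_out and stride == 1)
        self.proj = None if self.identity_shortcut else nn.Conv1d(c_in, c_out, 1, stride, rng)
        self.relu2 = nn.ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=True):
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        g = self.conv2.forward(h, train)
        s = x if self.identity_shortcut else self.proj.forward(x, train)
        return self.relu2.forward(g + s, train)

    def backward(self, dy, need_dx: bool = True):
        d = self.relu2.backward(dy)
        dx_short = d if self.identity_shortcut else self.proj.backward(d, need_dx=need_dx)
        dh = self.conv2.backward(d)
        dx = self.conv1.backward(self.relu1.backward(dh), need_dx=need_dx)
        if not need_dx:
            return None
        return dx + dx_short


class MCGEncoder:
    """Maps (B, 64, 5000) float32 segments to (B, D) embeddings."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.blocks: list[ResidualBlock] = []
        c_in = N_CHANNELS
        for w, k, s in zip(cfg.widths, cfg.kernels, cfg.strides):
            self.blocks.append(ResidualBlock(c_in, w, k, s, rng))
            c_in = w
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Linear(c_in, cfg.embed_dim, rng)
        # populated by forward(capture=True): per-block output feature maps,
        # and by backward(capture=True): their gradients
        self.captured_maps: list[np.ndarray] | None = None
        self.captured_grads: list[np.ndarray] | None = None
        self.captured_input_grad: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.blocks:
            ps += b.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True,
                capture: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != N_CHANNELS or x.shape[2] != SEGMENT_SAMPLES:
            raise ValueError(
                f"expected input of shape (B, {N_CHANNELS}, {SEGMENT_SAMPLES}), "
                f"got {x.shape}")
        if not np.isfinite(x).all():
            raise ValueError("non-finite values in encoder input")
        if self.cfg.normalize_input:
            rms = np.sqrt((x**2).mean(axis=(1, 2), keepdims=True))
            x = x / np.maximum(rms, np.finfo(nn.DTYPE).tiny)
        maps = []
        h = x
        for b in self.blocks:
            h = b.forward(h, train)
            if capture:
                maps.append(h)
        emb = self.head.forward(self.pool.forward(h, train), train)
        if capture:
            self.captured_maps = maps
        return emb

    def backward(self, demb: np.ndarray, capture: bool = False) -> np.ndarray | None:
        d = self.pool.backward(self.head.backward(demb))
        grads = []
        for i, b in enumerate(reversed(self.blocks)):
            if capture:
                grads.append(d)
            first = (i == len(self.blocks) - 1)
            # the input gradient is only needed for attribution (capture)
            d = b.backward(d, need_dx=capture or not first)
        if capture:
            self.captured_grads = grads[::-1]
            self.captured_input_grad = d
        return d

    # -- parameter (de)serialisation ------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        if len(ps) != len(state):
            raise ValueError("state length mismatch")
        for p, v in zip(ps, state):
            p.v[...] = v

    def checksum(self) -> float:
        return float(sum(np.abs(p.v).sum() for p in self.params()))


class ProjectionHead:
    """SimCLR-style 2-layer MLP used only for the contrastive loss."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.lin1 = nn.Linear(cfg.embed_dim, cfg.proj_hidden, rng)
        self.relu = nn.ReLU()
        self.lin2 = nn.Linear(cfg.proj_hidden, cfg.proj_dim, rng)

    def params(self):
        return self.lin1.params() + self.lin2.params()

    def forward(self, e, train=True):
        return self.lin2.forward(self.relu.forward(self.lin1.forward(e, train), train), train)

    def backward(self, dz):
        return self.lin1.backward(self.relu.backward(self.lin2.backward(dz)))


def nt_xent_loss(projections: np.ndarray, temperature: float = 0.1,
                 return_grad: bool = False):
    """NT-Xent loss over 2B projections paired as (i, i+B).

    Vectors are L2-normalised internally; for each anchor the positive is
    its partner view and the 2B-2 remaining vectors are negatives.  Returns
    the mean loss over all 2B anchors (and, optionally, the gradient with
    respect to the raw, un-normalised projections).
    """
    z = np.asarray(projections, dtype=np.float64)
    n = z.shape[0]
    if n < 4 or n % 2:
        raise ValueError("need 2B projections with B >= 2")
    B = n // 2
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm projection")
    zn = z / norms
    sim = (zn @ zn.T) / temperature
    np.fill_diagonal(sim, -np.inf)
    partner = np.concatenate([np.arange(B) + B, np.arange(B)])
    row_max = sim.max(axis=1, keepdims=True)
    exps = np.exp(sim - row_max)
    denom = exps.sum(axis=1)
    logprob = sim[np.arange(n), partner] - (row_max[:, 0] + np.log(denom))
    loss = float(-logprob.mean())
    if not return_grad:
        return loss
    soft = exps / denom[:, None]
    soft[np.arange(n), partner] -= 1.0
    dsim = soft / n  # d loss / d sim[i, j]
    dzn = (dsim + dsim.T) @ zn / temperature
    # back through row-wise normalisation
    dz = (dzn - zn * (dzn * zn).sum(axis=1, keepdims=True)) / norms
    return loss, dz.astype(nn.DTYPE)


def cosine_lr(epoch: float, total: int = 100, lr0: float = 1e-3,
              floor_frac: float = 0.01) -> float:
    """Cosine decay from ``lr0`` at epoch 0 to ``floor_frac * lr0`` at ``total``."""
    if not 0 <= epoch <= total:
        raise ValueError(f"epoch {epoch} outside [0, {total}]")
    lr_floor = floor_frac * lr0
    return lr_floor + 0.5 * (lr0 - lr_floor) * (1.0 + np.cos(np.pi * epoch / total))


@dataclass
class PretrainResult:
    encoder: MCGEncoder
    projection: ProjectionHead
    loss_trace: list[float]
    config: PretrainConfig
    encoder_config: EncoderConfig


def _segment_stack(segments: list[Segment]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.signal for s in segments]).astype(nn.DTYPE)
    valid = np.stack([s.valid_channels for s in segments])
    return x, valid


def pretrain(segments: list[Segment], enc_cfg: EncoderConfig,
             cfg: PretrainConfig, verbose: bool = False) -> PretrainResult:
    """Contrastive pretraining; fully deterministic given ``cfg.seed``."""
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to pretrain")
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_order, rng_aug = [np.random.default_rng(s) for s in ss.spawn(3)]
    encoder = MCGEncoder(enc_cfg, rng_init)
    projection = ProjectionHead(enc_cfg, rng_init)
    params = encoder.params() + projection.params()
    opt = nn.AdamW(params, lr=cfg.lr0, weight_decay=cfg.weight_decay)
    x_all, valid_all = _segment_stack(segments)
    n = len(segments)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng_order.permutation(n)
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.lr_floor_frac)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                warnings.warn("skipping trailing batch with a single segment "
                              "(no in-batch negatives)")
                continue
            v1, v2 = [], []
            for i in idx:
                a, b = make_views(x_all[i], cfg.augment, rng_aug,
                                  valid_channels=valid_all[i])
                v1.append(a)
                v2.append(b)
            batch = np.stack(v1 + v2)
            emb = encoder.forward(batch, train=True)
            proj = projection.forward(emb, train=True) if enc_cfg.use_projection_head else emb
            loss, dproj = nt_xent_loss(proj, cfg.temperature, return_grad=True)
            opt.zero_grad()
            demb = projection.backward(dproj) if enc_cfg.use_projection_head else dproj
            encoder.backward(demb)
            opt.step(lr=lr)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  loss {trace[-1]:.4f}  lr {lr:.2e}")
    return PretrainResult(encoder, projection, trace, cfg, enc_cfg)


def encode_segments(encoder: MCGEncoder, segments: list[Segment],
                    batch_size: int = 64) -> np.ndarray:
    """Deterministic inference-mode embeddings, shape (n_segments, D)."""
    out = []
    for start in range(0, len(segments), batch_size):
        x = np.stack([s.signal for s in segments[start:start + batch_size]])
        out.append(encoder.forward(x.astype(nn.DTYPE), train=False))
    emb = np.concatenate(out, axis=0)
    if not np.isfinite(emb).all():
        raise ValueError("non-finite embedding")
    return emb


def save_checkpoint(path: str | Path, result: PretrainResult) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    state = {f"enc_{i}": v for i, v in enumerate(result.encoder.get_state())}
    state.update({f"proj_{i}": p.v for i, p in enumerate(result.projection.params())})
    np.savez(path / "weights.npz", **state)
    sidecar = {
        "encoder_config": dataclasses.asdict(result.encoder_config),
        "pretrain_config": {k: v for k, v in dataclasses.asdict(result.config).items()
                            if k != "augment"},
        "augment_config": dataclasses.asdict(result.config.augment),
        "loss_trace": result.loss_trace,
    }
    (path / "checkpoint.json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> PretrainResult:
    path = Path(path)
    sidecar = json.loads((path / "checkpoint.json").read_text())
    enc_cfg = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in sidecar["encoder_config"].items()})
    cfg = PretrainConfig(augment=AugmentationConfig(**sidecar["augment_config"]),
                         **sidecar["pretrain_config"])
    rng = np.random.default_rng(0)
    encoder = MCGEncoder(enc_cfg, rng)
    projection = ProjectionHead(enc_cfg, rng)
    with np.load(path / "weights.npz") as data:
        encoder.set_state([data[f"enc_{i}"] for i in range(len(encoder.params()))])
        for i, p in enumerate(projection.params()):
            p.v[...] = data[f"proj_{i}"]
    return PretrainResult(encoder, projection, sidecar["loss_trace"], cfg, enc_cfg)
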