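"""Grad-CAM attribution over the encoder's temporal feature maps.

Temporal importance: gradients of the probe logit are pooled over time to
weight the target layer's feature maps; the rectified weighted sum is
linearly upsampled to the 5000-sample segment grid.  Importance maps are
aligned to R-peaks and averaged into beat-resolved profiles.

Channel importance: Grad-CAM's map lives after channel mixing, so
per-channel scores use time-aggregated |gradient x input| at the input
tensor, projected onto the sensor-array coordinates.  Missing (all-zero)
channels score exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder_ssl import MCGEncoder, SEGMENT_SAMPLES
from .fieldsim import SensorArray
from .probing import ProbeHead


@dataclass
class AttributionMap:
    temporal: np.ndarray            # (5000,), >= 0
    channel: np.ndarray             # (64,), >= 0
    beat_profile: np.ndarray | None = None
    n_beats: int = 0


def _upsample(map_1d: np.ndarray, n_out: int) -> np.ndarray:
    n_in = map_1d.size
    if n_in == n_out:
        return map_1d.copy()
    x_in = (np.arange(n_in) + 0.5) / n_in
    x_out = (np.arange(n_out) + 0.5) / n_out
    return np.interp(x_out, x_in, map_1d)


def grad_cam(x: np.ndarray, encoder: MCGEncoder, head: ProbeHead,
             target_layer: int = -1, channel_mode: str = "grad_x_input",
             channel_time_mask: np.ndarray | None = None) -> AttributionMap:
    """Grad-CAM temporal map plus channel scores for one segment
    (64 x 5000) in inference mode.  ``channel_mode`` is ``grad_x_input``
    (default) or ``saliency`` (time-aggregated |gradient| only); an optional
    boolean ``channel_time_mask`` restricts the channel aggregation to a
    phase of interest (e.g. the ST-T interval around each beat)."""
    if channel_mode not in ("grad_x_input", "saliency"):
        raise ValueError("channel_mode must be 'grad_x_input' or 'saliency'")
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    emb = encoder.forward(x, train=True, capture=True)
    logit = head.forward(emb, train=True)  # dropout inactive without rng
    dlogit = np.ones_like(logit)
    demb = head.backward(dlogit)
    encoder.backward(demb, capture=True)

    A = encoder.captured_maps[target_layer]        # (1, C_f, L_f)
    dA = encoder.captured_grads[target_layer]
    if A.ndim != 3:
        raise ValueError("target layer does not emit a temporal feature map")
    alpha = dA.mean(axis=2)                        # (1, C_f)
    cam = np.maximum((alpha[:, :, None] * A).sum(axis=1), 0.0)[0]
    temporal = _upsample(cam.astype(float), SEGMENT_SAMPLES)

    dx = encoder.captured_input_grad               # (1, 64, 5000)
    attr = np.abs(dx[0]) if channel_mode == "saliency" else np.abs(dx[0] * x[0])
    if channel_time_mask is not None:
        attr = attr[:, np.asarray(channel_time_mask, bool)]
    channel = attr.sum(axis=1).astype(float)
    return AttributionMap(temporal=temporal, channel=channel)


def st_t_time_mask(r_peaks: np.ndarray, n_samples: int = SEGMENT_SAMPLES,
                   start: int = 30, stop: int = 175) -> np.ndarray:
    """Boolean mask covering [r+start, r+stop) around every R peak
    (defaults: 60-350 ms after R at 500 Hz)."""
    mask = np.zeros(n_samples, bool)
    for r in np.asarray(r_peaks, dtype=int):
        mask[max(r + start, 0):min(r + stop, n_samples)] = True
    return mask


def beat_align_importance(temporal: np.ndarray, r_peaks: np.ndarray,
                          pre_samples: int = 75, post_samples: int = 225
                          ) -> tuple[np.ndarray, int]:
    """Average importance snippets around each complete beat; profile is
    max-normalised when nonzero.  Returns (profile, n_beats)."""
    T = temporal.size
    snippets = [temporal[r - pre_samples:r + post_samples]
                for r in np.asarray(r_peaks, dtype=int)
                if r - pre_samples >= 0 and r + post_samples <= T]
    if not snippets:
        return np.zeros(pre_samples + post_samples), 0
    profile = np.mean(snippets, axis=0)
    peak = profile.max()
    if peak > 0:
        profile = profile / peak
    return profile, len(snippets)


def cohort_beat_profile(maps_and_peaks: list[tuple[np.ndarray, np.ndarray]],
                        pre_samples: int = 75, post_samples: int = 225
                        ) -> tuple[np.ndarray, int]:
    """Beat-count-weighted mean profile over segments, max-normalised."""
    total = np.zeros(pre_samples + post_samples)
    n = 0
    for temporal, r_peaks in maps_and_peaks:
        T = temporal.size
        for r in np.asarray(r_peaks, dtype=int):
            if r - pre_samples >= 0 and r + post_samples <= T:
                total += temporal[r - pre_samples:r + post_samples]
                n += 1
    if n == 0:
        return total, 0
    profile = total / n
    peak = profile.max()
    if peak > 0:
        profile = profile / peak
    return profile, n


def spatial_importance(x: np.ndarray, encoder: MCGEncoder, head: ProbeHead,
                       array: SensorArray) -> tuple[np.ndarray, np.ndarray]:
    """Channel importance rendered at sensor positions: (positions, values)."""
    amap = grad_cam(x, encoder, head)
    return array.positions.copy(), amap.channel


def importance_centroid(channel_importance: np.ndarray,
                        array: SensorArray) -> np.ndarray:
    """Importance-weighted centroid (x, y) over the sensor plane."""
    w = np.asarray(channel_importance, dtype=float)
    if w.sum() <= 0:
        raise ValueError("importance must have positive mass")
    return (array.positions[:, :2] * w[:, None]).sum(axis=0) / w.sum()
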