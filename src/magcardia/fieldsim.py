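"""Current-dipole forward simulator for 64-channel magnetocardiography.

The heart is modelled as a point current dipole whose moment traces out a
P-QRS-T cycle built from Gaussian bumps in beat phase (the classic
dynamical-ECG construction), with a fixed in-plane direction per wave so
the field map rotates over the cardiac cycle.  Sensors sit on a circular
grid a small standoff above the chest plane and record the normal field
component Bz of a free-space dipole,

    B(r) = mu0/4pi * m x (r - r0) / |r - r0|^3 ,

so Bz depends only on the in-plane moment components.  Volume currents are
omitted: for a horizontally layered conductor the normal component is
dominated by the primary (intracellular) currents.

Class-conditional effects stand in for the clinical phenotypes probed
downstream:

* ``cad_lad`` / ``cad_lcx`` / ``cad_rca`` — a secondary dipole active during
  the ST-T interval, displaced toward the anterior-septal / lateral /
  inferior territory respectively;
* ``low_ef`` — reduced R amplitude and broadened QRS;
* ``af_substrate`` — prolonged, duplicated P wave with beat-to-beat
  morphology jitter.

Noise comprises additive white Gaussian noise, slow sinusoidal baseline
drift, 50 Hz line interference, and randomly dropped (zeroed) channels.
Amplitudes are in arbitrary consistent field units; noise levels are
specified relative to the clean recording's peak amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

MU0_OVER_4PI = 1e-7
FS = 500
N_CHANNELS = 64

CLASS_NAMES = ("control", "cad_lad", "cad_lcx", "cad_rca", "low_ef", "af_substrate")
TASKS = ("cad_multivessel", "lvef_reduced", "af_risk", "lad", "lcx", "rca")

# territory displacement of the secondary ST-T dipole, metres (x: left-lateral,
# y: superior/anterior-septal)
TERRITORY_OFFSETS = {
    "cad_lad": np.array([0.0, 0.05, 0.0]),
    "cad_lcx": np.array([0.05, 0.0, 0.0]),
    "cad_rca": np.array([0.0, -0.05, 0.0]),
}

# territory direction in the sensor plane (radians) toward which regional
# repolarization heterogeneity pulls the T-wave axis
TERRITORY_ANGLES = {"cad_lad": np.pi / 2, "cad_lcx": 0.0, "cad_rca": -np.pi / 2}


@dataclass(frozen=True)
class SensorArray:
    """64 planar sensors at a common standoff, measuring Bz."""

    positions: np.ndarray  # (64, 3), metres
    component: str = "Bz"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.shape != (N_CHANNELS, 3):
            raise ValueError(f"expected (64, 3) positions, got {pos.shape}")
        if len({tuple(p) for p in np.round(pos, 12)}) != N_CHANNELS:
            raise ValueError("sensor positions must be distinct")
        if np.any(pos[:, 2] <= 0):
            raise ValueError("standoff z must be positive")

    @property
    def standoff(self) -> float:
        return float(self.positions[0, 2])


def default_sensor_array(radii=(0.035, 0.07, 0.105, 0.14), n_per_ring=16,
                         standoff=0.01) -> SensorArray:
    """Concentric-ring layout over the anterior thorax (4 x 16 by default)."""
    if len(radii) * n_per_ring != N_CHANNELS:
        raise ValueError("layout must contain exactly 64 sensors")
    pos = []
    for i, r in enumerate(radii):
        # half-step offset on alternate rings avoids radial alignment
        ang = 2 * np.pi * (np.arange(n_per_ring) + 0.5 * (i % 2)) / n_per_ring
        for a in ang:
            pos.append((r * np.cos(a), r * np.sin(a), standoff))
    return SensorArray(np.array(pos))


def dipole_bz(moment, source_pos, sensor_pos) -> float:
    """Bz of a free-space current dipole at one sensor.

    Linear in the moment; only the in-plane moment components contribute:
    Bz = mu0/4pi * (m_x r_y - m_y r_x) / |r|^3 with r = sensor - source.
    """
    m = np.asarray(moment, dtype=float)
    r = np.asarray(sensor_pos, dtype=float) - np.asarray(source_pos, dtype=float)
    d = np.linalg.norm(r)
    if d == 0:
        raise ValueError("sensor coincides with source")
    return MU0_OVER_4PI * (m[0] * r[1] - m[1] * r[0]) / d**3


def _lead_field(array: SensorArray, source_pos: np.ndarray) -> np.ndarray:
    """(64, 3) matrix G with Bz = G @ m for a dipole at ``source_pos``."""
    r = array.positions - np.asarray(source_pos, dtype=float)
    d3 = np.linalg.norm(r, axis=1) ** 3
    if np.any(d3 == 0):
        raise ValueError("sensor coincides with source")
    G = np.zeros((N_CHANNELS, 3))
    G[:, 0] = r[:, 1] / d3
    G[:, 1] = -r[:, 0] / d3
    return MU0_OVER_4PI * G


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump of the dipole-moment cycle, in beat phase (rad)."""

    amplitude: float
    center: float
    width: float
    direction: tuple[float, float, float]

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("wave width must be positive")


def default_waves() -> dict[str, WaveComponent]:
    """P-QRS-T moment dynamics with per-wave in-plane directions."""
    def d(angle_deg):
        a = np.deg2rad(angle_deg)
        return (float(np.cos(a)), float(np.sin(a)), 0.0)

    return {
        "P": WaveComponent(1.2, -np.pi / 3, 0.25, d(80)),
        "Q": WaveComponent(-5.0, -np.pi / 12, 0.10, d(10)),
        "R": WaveComponent(30.0, 0.0, 0.10, d(0)),
        "S": WaveComponent(-7.5, np.pi / 12, 0.10, d(-10)),
        "T": WaveComponent(0.75, np.pi / 2, 0.40, d(45)),
    }


# secondary ST-T dipole used for the coronary-territory effects: centred
# between the S and T waves, wide enough to span the ST segment
ST_WAVE = WaveComponent(3.5, 1.1, 0.35, (np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0.0))

HEART_POS = np.array([0.0, 0.0, -0.06])  # ~6 cm below the sensor plane


@dataclass(frozen=True)
class NoiseSpec:
    """Noise amplitudes relative to the clean recording's peak |Bz|."""

    white_sigma: float = 0.05
    drift_amplitude: float = 0.5
    line_amplitude: float = 0.2
    missing_channel_prob: float = 0.03

    def __post_init__(self):
        for name in ("white_sigma", "drift_amplitude", "line_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.missing_channel_prob <= 1:
            raise ValueError("missing_channel_prob must be in [0, 1]")


@dataclass(frozen=True)
class PatientSpec:
    patient_id: str
    class_label: str = "control"
    minutes: float = 3.0
    effect_size: float = 1.0
    rr_mean: float = 0.85
    rr_sd: float = 0.04
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    # scale of inter-patient anatomy/morphology variation (0 disables):
    # per-wave amplitude, width and direction, and heart position all vary
    # between patients so that no two hearts produce the same field maps
    morph_variability: float = 1.0

    def __post_init__(self):
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.minutes <= 0 or self.rr_mean <= 0:
            raise ValueError("duration and rr_mean must be positive")
        if self.effect_size < 0 or self.morph_variability < 0:
            raise ValueError("effect_size and morph_variability must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description of one synthetic cohort.

    ``class_counts`` maps class label to number of patients; per-patient
    seeds are derived deterministically from ``seed``.
    """

    class_counts: Mapping[str, int]
    minutes_per_patient: float = 3.0
    effect_size: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    rr_mean: float = 0.85
    rr_sd: float = 0.04
    morph_variability: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for c in self.class_counts:
            if c not in CLASS_NAMES:
                raise ValueError(f"unknown class {c!r}")
        if sum(self.class_counts.values()) <= 0:
            raise ValueError("cohort must contain at least one patient")

    @property
    def n_patients(self) -> int:
        return int(sum(self.class_counts.values()))


def labels_for_class(class_label: str) -> dict[str, int]:
    labels = {t: 0 for t in TASKS}
    if class_label.startswith("cad_"):
        labels["cad_multivessel"] = 1
        labels[class_label.removeprefix("cad_")] = 1
    elif class_label == "low_ef":
        labels["lvef_reduced"] = 1
    elif class_label == "af_substrate":
        labels["af_risk"] = 1
    return labels


@dataclass
class Recording:
    """Continuous multichannel recording plus metadata and ground truth."""

    signal: np.ndarray  # (64, N) float32
    fs: int
    sensor_array: SensorArray
    patient_id: str
    labels: dict[str, int]
    valid_channels: np.ndarray  # (64,) bool
    ground_truth_r_peaks: np.ndarray | None = None
    class_label: str = "control"

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


def _beat_phase(duration: float, rr_mean: float, rr_sd: float,
                rng: np.random.Generator, fs: int = FS):
    """Per-sample beat phase in [-pi, pi) plus R-peak sample indices."""
    n = int(round(duration * fs))
    t_r, r_times = 0.0, []
    boundaries = [0.0]
    while boundaries[-1] < duration + 2:  # one spare beat past the end
        rr = rr_mean + np.clip(rng.normal(0.0, rr_sd), -3 * rr_sd, 3 * rr_sd)
        boundaries.append(boundaries[-1] + rr)
    boundaries = np.array(boundaries)
    t = np.arange(n) / fs
    beat_idx = np.searchsorted(boundaries, t, side="right") - 1
    rr_here = boundaries[beat_idx + 1] - boundaries[beat_idx]
    frac = (t - boundaries[beat_idx]) / rr_here
    phase = 2 * np.pi * frac - np.pi
    # R peak at phase 0, i.e. mid-beat
    r_peaks = []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        s = int(round((b0 + 0.5 * (b1 - b0)) * fs))
        if 0 <= s < n:
            r_peaks.append(s)
    return phase, beat_idx, np.array(r_peaks, dtype=int), n


def _moment_from_waves(phase: np.ndarray, waves: Mapping[str, WaveComponent]) -> np.ndarray:
    """(T, 3) dipole moment time-series from Gaussian bumps in phase."""
    m = np.zeros((phase.size, 3))
    for w in waves.values():
        dphi = np.angle(np.exp(1j * (phase - w.center)))  # wrapped difference
        bump = w.amplitude * np.exp(-0.5 * (dphi / w.width) ** 2)
        m += bump[:, None] * np.asarray(w.direction)
    return m


def _apply_class_waves(waves: dict[str, WaveComponent], class_label: str,
                       es: float) -> dict[str, WaveComponent]:
    waves = dict(waves)
    if class_label in TERRITORY_ANGLES:
        # regional repolarization heterogeneity: the T-wave axis rotates
        # toward the affected territory and the wave grows and broadens
        t = waves["T"]
        dx, dy, dz = t.direction
        angle = np.arctan2(dy, dx)
        target = TERRITORY_ANGLES[class_label]
        rot = angle + np.clip(0.3 * es, 0.0, 1.0) * np.angle(
            np.exp(1j * (target - angle)))
        r = np.hypot(dx, dy)
        waves["T"] = replace(t, amplitude=t.amplitude * (1 + 0.3 * es),
                             width=t.width * (1 + 0.2 * es),
                             direction=(r * np.cos(rot), r * np.sin(rot), dz))
    elif class_label == "low_ef":
        for k in ("Q", "R", "S"):
            w = waves[k]
            amp = w.amplitude * (1 - 0.35 * es) if k == "R" else w.amplitude
            waves[k] = replace(w, amplitude=amp, width=w.width * (1 + 0.5 * es))
    elif class_label == "af_substrate":
        p = waves["P"]
        waves["P"] = replace(p, width=p.width * (1 + 0.8 * es))
        waves["P2"] = replace(p, center=p.center + 0.25,
                              amplitude=0.5 * p.amplitude * es)
    return waves


def _patient_morphology(rng: np.random.Generator, v: float
                        ) -> tuple[dict[str, WaveComponent], np.ndarray]:
    """Per-patient heart: jittered wave amplitudes, widths, directions and a
    displaced dipole position.  ``v`` scales the variation; 0 returns the
    template heart.  Draws a fixed number of variates regardless of ``v``."""
    waves = {}
    for name, w in default_waves().items():
        amp = w.amplitude * (1.0 + 0.2 * v * np.clip(rng.standard_normal(), -2.5, 2.5))
        width = w.width * (1.0 + 0.1 * v * np.clip(rng.standard_normal(), -2.5, 2.5))
        rot = np.deg2rad(10.0) * v * np.clip(rng.standard_normal(), -2.5, 2.5)
        c, s = np.cos(rot), np.sin(rot)
        dx, dy, dz = w.direction
        waves[name] = WaveComponent(amp, w.center, max(width, 1e-3),
                                    (c * dx - s * dy, s * dx + c * dy, dz))
    offset = 0.01 * v * np.clip(rng.standard_normal(2), -2.5, 2.5)
    heart_pos = HEART_POS + np.array([offset[0], offset[1], 0.0])
    return waves, heart_pos


def simulate_recording(spec: PatientSpec, seed: int,
                       array: SensorArray | None = None) -> Recording:
    """Simulate one patient's recording; bit-reproducible given ``seed``."""
    array = array or default_sensor_array()
    ss = np.random.SeedSequence(seed)
    rng_rr, rng_noise, rng_class, rng_morph = [
        np.random.default_rng(s) for s in ss.spawn(4)]
    duration = spec.minutes * 60.0
    phase, beat_idx, r_peaks, n = _beat_phase(duration, spec.rr_mean, spec.rr_sd, rng_rr)

    base_waves, heart_pos = _patient_morphology(rng_morph, spec.morph_variability)
    waves = _apply_class_waves(base_waves, spec.class_label, spec.effect_size)
    if spec.class_label == "af_substrate" and spec.effect_size > 0:
        # beat-to-beat P-wave morphology jitter
        n_beats = beat_idx.max() + 1
        amp_j = 1.0 + 0.2 * spec.effect_size * rng_class.standard_normal(n_beats)
        ctr_j = 0.05 * spec.effect_size * rng_class.standard_normal(n_beats)
        base = {k: w for k, w in waves.items() if not k.startswith("P")}
        m = _moment_from_waves(phase, base)
        for k in ("P", "P2"):
            w = waves[k]
            dphi = np.angle(np.exp(1j * (phase - (w.center + ctr_j[beat_idx]))))
            bump = w.amplitude * amp_j[beat_idx] * np.exp(-0.5 * (dphi / w.width) ** 2)
            m += bump[:, None] * np.asarray(w.direction)
    else:
        m = _moment_from_waves(phase, waves)

    G = _lead_field(array, heart_pos)
    signal = G @ m.T  # (64, N)

    if spec.class_label in TERRITORY_OFFSETS and spec.effect_size > 0:
        w = ST_WAVE
        dphi = np.angle(np.exp(1j * (phase - w.center)))
        bump = spec.effect_size * w.amplitude * np.exp(-0.5 * (dphi / w.width) ** 2)
        m2 = bump[:, None] * np.asarray(w.direction)
        G2 = _lead_field(array, heart_pos + TERRITORY_OFFSETS[spec.class_label])
        signal = signal + G2 @ m2.T

    scale = float(np.abs(signal).max()) or 1.0
    noise = spec.noise
    t = np.arange(n) / FS
    if noise.white_sigma > 0:
        signal = signal + noise.white_sigma * scale * rng_noise.standard_normal(signal.shape)
    if noise.drift_amplitude > 0:
        f = rng_noise.uniform(0.05, 0.3, size=N_CHANNELS)
        ph = rng_noise.uniform(0, 2 * np.pi, size=N_CHANNELS)
        amp = rng_noise.uniform(0.5, 1.0, size=N_CHANNELS) * noise.drift_amplitude * scale
        signal = signal + amp[:, None] * np.sin(2 * np.pi * f[:, None] * t + ph[:, None])
    if noise.line_amplitude > 0:
        ph = rng_noise.uniform(0, 2 * np.pi, size=N_CHANNELS)
        amp = rng_noise.uniform(0.5, 1.0, size=N_CHANNELS) * noise.line_amplitude * scale
        signal = signal + amp[:, None] * np.sin(2 * np.pi * 50.0 * t + ph[:, None])
    valid = rng_noise.random(N_CHANNELS) >= noise.missing_channel_prob
    if not valid.any():
        valid[0] = True  # never drop the whole array
    signal[~valid] = 0.0

    return Recording(signal=signal.astype(np.float32), fs=FS, sensor_array=array,
                     patient_id=spec.patient_id, labels=labels_for_class(spec.class_label),
                     valid_channels=valid, ground_truth_r_peaks=r_peaks,
                     class_label=spec.class_label)


def simulate_cohort(spec: CohortSpec, array: SensorArray | None = None) -> list[Recording]:
    """Simulate all patients of a cohort with deterministic per-patient seeds."""
    array = array or default_sensor_array()
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_patients) % (2**31)
    recordings = []
    i = 0
    for class_label in sorted(spec.class_counts):
        for _ in range(int(spec.class_counts[class_label])):
            ps = PatientSpec(patient_id=f"P{i:04d}", class_label=class_label,
                             minutes=spec.minutes_per_patient,
                             effect_size=spec.effect_size, rr_mean=spec.rr_mean,
                             rr_sd=spec.rr_sd, noise=spec.noise,
                             morph_variability=spec.morph_variability)
            recordings.append(simulate_recording(ps, int(seeds[i]), array))
            i += 1
    return recordings
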