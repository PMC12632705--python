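"""Seeded synthetic duplex-ultrasound data generator.

Three generators provide ground-truthed inputs for the rest of the
package:

``generate_waveform``
    Umbilical-artery-like velocity waveforms: a smooth systolic upstroke
    to PSV followed by a gradual diastolic decay to EDV, repeated at the
    fetal heart rate.  Each beat occupies an integer number of samples,
    so the per-beat maximum and minimum hit PSV and EDV exactly.  A
    configurable fraction of beats has absent (or reversed) end
    diastolic flow, emulating placental insufficiency.

``render_sequence``
    Duplex image sequences of a moving vessel pair: a pulsatile artery
    carrying the instantaneous waveform velocity and a steady vein with
    constant counter-flow, over a speckle B-mode background with darker
    vessel lumina.  The artery centroid trajectory is recorded as ground
    truth.

``synthesize_spectrogram``
    Spectral-Doppler spectrograms: per time bin, a Gaussian ridge at the
    velocity bin of the instantaneous waveform velocity, with optional
    spectral broadening and an additive exponential noise floor.
    Velocities beyond the Nyquist limit wrap (alias) to the opposite
    side of the velocity axis, exactly as pulsed-wave Doppler aliases.

Coordinate convention (stated in every output): lateral = mm from the
left field edge, axial = depth in mm from the transducer face, both at
pixel centers with 0-based indices.  Flow toward the transducer is
positive.  Sound speed is fixed at 1540 m/s unless overridden.

All randomness is threaded through a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "WaveformSpec",
    "SceneSpec",
    "DuplexFrame",
    "FrameSequence",
    "Spectrogram",
    "GroundTruth",
    "Waveform",
    "ConfigurationError",
    "generate_waveform",
    "render_sequence",
    "synthesize_spectrogram",
    "nyquist_velocity",
    "noise_floor_for_snr",
]

SOUND_SPEED_M_S = 1540.0  # soft-tissue convention

#: Acquisition constants mirrored from the monitored system.
DEFAULT_CARRIER_MHZ = 2.5
DEFAULT_PRF_HZ = 3000.0
DEFAULT_GATE_MM = 2.0
DEFAULT_ENSEMBLE = 14


class ConfigurationError(ValueError):
    """A scene/waveform configuration that cannot be rendered."""


# --------------------------------------------------------------------------
# specs and containers


@dataclass(frozen=True)
class WaveformSpec:
    """Umbilical-artery waveform parameters.

    fhr is in beats/min, velocities in cm/s, duration in s.
    ``systolic_fraction`` is the fraction of the cycle spent on the
    systolic upstroke; ``decay_rate`` shapes the diastolic decay
    (dimensionless, larger = faster early decay).  ``absent_edv_fraction``
    of beats get their end-diastolic velocity forced to zero, or to
    ``-0.5*edv`` when ``reversed_edv`` is set.
    """

    fhr: float = 140.0
    psv: float = 52.2
    edv: float = 20.0
    systolic_fraction: float = 0.3
    duration: float = 10.0
    sample_rate: float = 200.0
    absent_edv_fraction: float = 0.0
    reversed_edv: bool = False
    decay_rate: float = 2.5

    def validate(self) -> None:
        if not (30.0 <= self.fhr <= 300.0):
            raise ValueError(f"fhr must be within [30, 300] bpm, got {self.fhr}")
        if not (0.0 <= self.absent_edv_fraction <= 1.0):
            raise ValueError("absent_edv_fraction must be in [0, 1]")
        if self.sample_rate < 10.0 * self.fhr / 60.0:
            raise ValueError("sample_rate must resolve >= 10 samples per beat")
        if not (0.05 <= self.systolic_fraction <= 0.8):
            raise ValueError("systolic_fraction must be in [0.05, 0.8]")
        if self.psv <= 0 or self.psv < self.edv:
            raise ValueError("require psv > 0 and psv >= edv")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    """Duplex scene geometry and texture parameters (mm, frames/s).

    ``trajectory`` selects the artery-centroid path: a dict such as
    ``{"kind": "static"}``, ``{"kind": "linear", "velocity": (vx, vy)}``,
    ``{"kind": "sinusoid", "amplitude": 10, "period": 10, "axis": "lateral"}``,
    ``{"kind": "random_walk", "max_speed": 2.0}`` (mm/s), or any callable
    ``t -> (lateral_mm, axial_mm)`` giving the absolute artery center.
    The vein rides at a fixed offset from the artery.
    """

    field_width: float = 50.0
    field_depth: float = 70.0
    pixel_pitch: float = 0.5
    frame_rate: float = 20.0
    n_frames: int = 100
    artery_radius: float = 3.0
    vein_radius: float = 4.0
    artery_center: tuple[float, float] = (20.0, 35.0)
    vein_offset: tuple[float, float] = (11.0, 0.0)
    vein_velocity: float = -10.0
    trajectory: object = field(default_factory=lambda: {"kind": "static"})
    speckle_mean: float = 120.0
    speckle_var: float = 400.0
    lumen_attenuation: float = 0.2
    color_noise_sd: float = 2.0
    color_nyquist: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.artery_radius, self.vein_radius) <= 0:
            raise ValueError("vessel radii must be > 0")


@dataclass(frozen=True)
class DuplexFrame:
    """One co-registered B-mode + color-Doppler frame."""

    bmode: np.ndarray
    color_velocity: np.ndarray
    timestamp: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        if self.bmode.shape != self.color_velocity.shape:
            raise ValueError("bmode and color grids must share a shape")


@dataclass
class FrameSequence:
    """A stack of duplex frames with shared geometry.

    ``bmode`` and ``color`` have shape (n_frames, n_axial, n_lateral);
    row index = axial (depth), column index = lateral.
    """

    bmode: np.ndarray
    color: np.ndarray
    pixel_pitch: float
    frame_rate: float
    timestamps: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.bmode.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.bmode.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[DuplexFrame]:
        for k in range(self.n_frames):
            yield self[k]

    def __getitem__(self, k: int) -> DuplexFrame:
        return DuplexFrame(
            bmode=self.bmode[k],
            color_velocity=self.color[k],
            timestamp=float(self.timestamps[k]),
            pixel_pitch=self.pixel_pitch,
        )


@dataclass
class Spectrogram:
    """Spectral-Doppler power matrix: rows = time bins, cols = velocity bins."""

    power: np.ndarray
    time_step: float
    velocity_axis: np.ndarray
    prf: float
    carrier_mhz: float
    angle_deg: float = 0.0
    sound_speed: float = SOUND_SPEED_M_S

    @property
    def nyquist(self) -> float:
        return nyquist_velocity(
            self.prf, self.carrier_mhz, self.angle_deg, self.sound_speed
        )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.power.shape[0]) * self.time_step


@dataclass
class GroundTruth:
    """Ground truth emitted by the generators.

    ``beats``: per-beat table (start_s, end_s, psv, edv, tav, fhr,
    edv_absent, edv_reversed).  ``centroids``: per-frame artery centroid
    (frame, time_s, lateral_mm, axial_mm).  ``frame_velocity``: the
    noise-free artery velocity at each frame time.
    """

    beats: pd.DataFrame | None = None
    centroids: pd.DataFrame | None = None
    frame_velocity: np.ndarray | None = None


@dataclass
class Waveform:
    """A sampled velocity series (cm/s) at a fixed sample rate."""

    velocity: np.ndarray
    sample_rate: float

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.velocity.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.velocity.size / self.sample_rate


# --------------------------------------------------------------------------
# waveform generation


def _beat_shapes(
    n: int, systolic_fraction: float, decay_rate: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Normalized upstroke/decay shapes of one n-sample beat.

    Upstroke (samples 0..i_pk): sin^2 rise 0 -> 1 with zero slope at the
    peak.  Decay (samples i_pk..n-1): smooth quadratic-exponential fall
    1 -> 0, reaching 0 exactly at the beat's last sample, so
    end-diastole sits at the end of the cycle and the next upstroke
    starts from it.
    """
    i_pk = int(round(systolic_fraction * n))
    i_pk = min(max(i_pk, 1), n - 2)
    up = np.sin(0.5 * np.pi * np.arange(i_pk + 1) / i_pk) ** 2
    u = np.arange(n - i_pk) / (n - 1 - i_pk)
    k = decay_rate
    dec = (np.exp(-k * u**2) - math.exp(-k)) / (1.0 - math.exp(-k))
    up[-1] = dec[0] = 1.0
    dec[-1] = 0.0
    return up, dec, i_pk


def generate_waveform(
    spec: WaveformSpec, seed: int | None = None
) -> tuple[Waveform, GroundTruth]:
    """Generate a periodic UA-like velocity waveform with per-beat truth.

    Each beat spans ``round(sample_rate * 60/fhr)`` samples; the realized
    (slightly quantized) per-beat FHR is recorded in the ground truth.
    A beat's end-diastolic velocity is reached exactly at its last
    sample, and the next beat's upstroke rises from that level.  Beats
    selected for absent EDV (a seeded draw of exactly
    ``round(absent_edv_fraction * n_beats)`` beats) have their diastolic
    endpoint forced to 0, or to ``-0.5*edv`` when ``reversed_edv``.
    """
    spec.validate()
    fs = spec.sample_rate
    n = int(round(fs * 60.0 / spec.fhr))
    n_beats = max(1, int(round(spec.duration * fs / n)))
    up, dec, i_pk = _beat_shapes(n, spec.systolic_fraction, spec.decay_rate)

    n_absent = int(round(spec.absent_edv_fraction * n_beats))
    rng = np.random.default_rng(seed)
    absent_idx = np.zeros(n_beats, dtype=bool)
    if n_absent:
        absent_idx[rng.choice(n_beats, size=n_absent, replace=False)] = True

    edv_flagged = -0.5 * abs(spec.edv) if spec.reversed_edv else 0.0
    velocity = np.empty(n_beats * n)
    rows = []
    beat_fhr = 60.0 * fs / n
    edv_prev = edv_flagged if absent_idx[0] else spec.edv  # steady state before t=0
    for b in range(n_beats):
        edv_b = edv_flagged if absent_idx[b] else spec.edv
        seg = np.empty(n)
        seg[: i_pk + 1] = edv_prev + (spec.psv - edv_prev) * up
        seg[i_pk:] = edv_b + (spec.psv - edv_b) * dec
        velocity[b * n : (b + 1) * n] = seg
        edv_prev = edv_b
        rows.append(
            {
                "beat_index": b,
                "start_s": b * n / fs,
                "end_s": (b + 1) * n / fs,
                "psv": spec.psv,
                "edv": edv_b,
                "tav": float(seg.mean()),
                "fhr": beat_fhr,
                "edv_absent": bool(absent_idx[b]),
                "edv_reversed": bool(absent_idx[b] and spec.reversed_edv),
            }
        )
    beats = pd.DataFrame(rows)
    return Waveform(velocity=velocity, sample_rate=fs), GroundTruth(beats=beats)


# --------------------------------------------------------------------------
# duplex scene rendering


def _trajectory_fn(
    scene: SceneSpec, rng: np.random.Generator
) -> Callable[[np.ndarray], np.ndarray]:
    """Resolve the trajectory parameter to frame-times -> (n, 2) mm path."""
    traj = scene.trajectory
    base = np.asarray(scene.artery_center, dtype=float)

    if callable(traj):
        def path(t: np.ndarray) -> np.ndarray:
            return np.asarray([traj(tk) for tk in t], dtype=float)
        return path

    kind = traj.get("kind", "static") if isinstance(traj, dict) else "static"
    if kind == "static":
        return lambda t: np.tile(base, (t.size, 1))
    if kind == "linear":
        vel = np.asarray(traj.get("velocity", (1.0, 0.0)), dtype=float)
        return lambda t: base + np.outer(t, vel)
    if kind == "sinusoid":
        amp = float(traj.get("amplitude", 10.0))
        period = float(traj.get("period", 10.0))
        axis = 0 if traj.get("axis", "lateral") == "lateral" else 1
        def path(t: np.ndarray) -> np.ndarray:
            out = np.tile(base, (t.size, 1))
            out[:, axis] += amp * np.sin(2.0 * np.pi * t / period)
            return out
        return path
    if kind == "random_walk":
        max_speed = float(traj.get("max_speed", 2.0))
        smoothness = float(traj.get("smoothness", 0.85))
        def path(t: np.ndarray) -> np.ndarray:
            dt = np.diff(t, prepend=t[0])
            v = np.zeros((t.size, 2))
            step_sd = max_speed * math.sqrt(1.0 - smoothness**2) / 2.0
            for k in range(1, t.size):
                v[k] = smoothness * v[k - 1] + rng.normal(0.0, step_sd, 2)
                speed = math.hypot(*v[k])
                if speed > max_speed:
                    v[k] *= max_speed / speed
            return base + np.cumsum(v * dt[:, None], axis=0)
        return path
    raise ConfigurationError(f"unknown trajectory kind: {kind!r}")


def _wrap_velocity(v: np.ndarray, v_nyq: float) -> np.ndarray:
    """Alias velocities onto the circular axis [-v_nyq, v_nyq)."""
    return np.mod(v + v_nyq, 2.0 * v_nyq) - v_nyq


def render_sequence(
    scene: SceneSpec, wave: WaveformSpec | Waveform, seed: int | None = None
) -> tuple[FrameSequence, GroundTruth]:
    """Render a duplex sequence of a moving artery + steady vein.

    The artery's color pixels carry the instantaneous waveform velocity
    (resampled at frame times by nearest sample) plus zero-mean Gaussian
    noise; the vein carries a constant counter-flow; background color is
    zero-mean noise.  B-mode is gamma-distributed speckle with darker
    vessel lumina.  The seed argument overrides ``scene.seed``.

    Raises ``ConfigurationError`` naming the first frame at which a
    vessel would leave the field.
    """
    scene.validate()
    rng = np.random.default_rng(scene.seed if seed is None else seed)

    if isinstance(wave, WaveformSpec):
        wf, wave_truth = generate_waveform(wave, seed=rng.integers(2**31))
    else:
        wf, wave_truth = wave, GroundTruth()

    n_lat = int(round(scene.field_width / scene.pixel_pitch))
    n_ax = int(round(scene.field_depth / scene.pixel_pitch))
    lat = np.arange(n_lat) * scene.pixel_pitch
    ax = np.arange(n_ax) * scene.pixel_pitch
    lat_extent, ax_extent = lat[-1], ax[-1]
    lat_g, ax_g = np.meshgrid(lat, ax)

    t_frames = np.arange(scene.n_frames) / scene.frame_rate
    centers = _trajectory_fn(scene, rng)(t_frames)
    vein_centers = centers + np.asarray(scene.vein_offset)

    for k in range(scene.n_frames):
        for name, (cl, ca), r in (
            ("artery", centers[k], scene.artery_radius),
            ("vein", vein_centers[k], scene.vein_radius),
        ):
            if cl - r < 0 or cl + r > lat_extent or ca - r < 0 or ca + r > ax_extent:
                raise ConfigurationError(
                    f"{name} leaves the field at frame {k} "
                    f"(center=({cl:.2f}, {ca:.2f}) mm, radius {r} mm)"
                )

    # nearest-sample resampling of the waveform at frame times
    idx = np.minimum(
        np.round(t_frames * wf.sample_rate).astype(int), wf.velocity.size - 1
    )
    v_frames = wf.velocity[idx]

    # speckle texture: gamma with the configured mean/variance
    shape_p = scene.speckle_mean**2 / scene.speckle_var
    scale_p = scene.speckle_var / scene.speckle_mean

    bmode = np.empty((scene.n_frames, n_ax, n_lat))
    color = np.empty_like(bmode)
    for k in range(scene.n_frames):
        a_mask = (lat_g - centers[k, 0]) ** 2 + (ax_g - centers[k, 1]) ** 2 <= (
            scene.artery_radius**2
        )
        v_mask = (lat_g - vein_centers[k, 0]) ** 2 + (
            ax_g - vein_centers[k, 1]
        ) ** 2 <= scene.vein_radius**2

        frame_b = rng.gamma(shape_p, scale_p, size=(n_ax, n_lat))
        frame_b[a_mask | v_mask] *= scene.lumen_attenuation

        if scene.color_noise_sd > 0:
            frame_c = rng.normal(0.0, scene.color_noise_sd, size=(n_ax, n_lat))
        else:
            frame_c = np.zeros((n_ax, n_lat))
        frame_c[a_mask] += v_frames[k]
        frame_c[v_mask] += scene.vein_velocity
        if scene.color_nyquist is not None:
            frame_c = _wrap_velocity(frame_c, scene.color_nyquist)

        bmode[k] = frame_b
        color[k] = frame_c

    frames = FrameSequence(
        bmode=bmode,
        color=color,
        pixel_pitch=scene.pixel_pitch,
        frame_rate=scene.frame_rate,
        timestamps=t_frames,
    )
    truth = GroundTruth(
        beats=wave_truth.beats,
        centroids=pd.DataFrame(
            {
                "frame": np.arange(scene.n_frames),
                "time_s": t_frames,
                "lateral_mm": centers[:, 0],
                "axial_mm": centers[:, 1],
            }
        ),
        frame_velocity=v_frames,
    )
    return frames, truth


# --------------------------------------------------------------------------
# spectral-Doppler synthesis


def nyquist_velocity(
    prf: float,
    carrier_mhz: float,
    angle_deg: float = 0.0,
    sound_speed: float = SOUND_SPEED_M_S,
) -> float:
    """Nyquist velocity (cm/s) of pulsed-wave Doppler.

    v_nyq = (PRF/2) * c / (2 * f0 * cos(theta)); the Doppler shift of a
    scatterer at v_nyq equals PRF/2.
    """
    if prf <= 0 or carrier_mhz <= 0:
        raise ValueError("prf and carrier must be > 0")
    cos_t = math.cos(math.radians(angle_deg))
    if abs(cos_t) < 1e-9:
        raise ValueError("Doppler angle of 90 degrees has no velocity projection")
    return (prf / 2.0) * sound_speed / (2.0 * carrier_mhz * 1e6 * cos_t) * 100.0


def noise_floor_for_snr(snr_db: float, n_velocity_bins: int = 256) -> float:
    """Per-bin exponential noise mean giving the requested column SNR.

    SNR is defined as ridge column power (normalized to 1) over total
    expected noise power in the column.
    """
    return 10.0 ** (-snr_db / 10.0) / n_velocity_bins


def synthesize_spectrogram(
    wave: Waveform | np.ndarray,
    sample_rate: float | None = None,
    prf: float = DEFAULT_PRF_HZ,
    carrier_mhz: float = DEFAULT_CARRIER_MHZ,
    angle_deg: float = 0.0,
    broadening_sd: float = 0.0,
    noise_floor: float = 0.0,
    seed: int | None = None,
    n_velocity_bins: int = 256,
    sound_speed: float = SOUND_SPEED_M_S,
) -> Spectrogram:
    """Synthesize a spectral-Doppler spectrogram from a velocity series.

    Each time bin holds a Gaussian ridge (sd = ``broadening_sd`` cm/s,
    floored at half a velocity bin so the ridge has finite spectral
    width) centered at the aliased position of the instantaneous
    velocity on the circular velocity axis spanning +/- Nyquist.  Ridge
    column power is normalized to 1.  ``noise_floor`` adds i.i.d.
    exponential noise with that per-bin mean.
    """
    if isinstance(wave, Waveform):
        velocity, fs = wave.velocity, wave.sample_rate
    else:
        velocity = np.asarray(wave, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required when wave is a bare array")
        fs = sample_rate
    v_nyq = nyquist_velocity(prf, carrier_mhz, angle_deg, sound_speed)

    n_bins = int(n_velocity_bins)
    bin_width = 2.0 * v_nyq / n_bins
    axis = -v_nyq + (np.arange(n_bins) + 0.5) * bin_width
    sigma = max(broadening_sd, bin_width / 2.0)

    v_wrapped = _wrap_velocity(velocity, v_nyq)
    # circular distance of each bin center from the wrapped ridge center
    d = _wrap_velocity(axis[None, :] - v_wrapped[:, None], v_nyq)
    power = np.exp(-0.5 * (d / sigma) ** 2)
    power /= power.sum(axis=1, keepdims=True)

    if noise_floor > 0.0:
        rng = np.random.default_rng(seed)
        power = power + rng.exponential(noise_floor, size=power.shape)

    return Spectrogram(
        power=power,
        time_step=1.0 / fs,
        velocity_axis=axis,
        prf=prf,
        carrier_mhz=carrier_mhz,
        angle_deg=angle_deg,
        sound_speed=sound_speed,
    )
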