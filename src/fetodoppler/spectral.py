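"""Spectral-Doppler envelope extraction and per-beat hemodynamics.

``extract_envelope`` turns a spectrogram (time x velocity power matrix)
into a velocity trace.  Per time column it (1) subtracts an estimated
noise floor, (2) walks the velocity axis outward from zero along the
dominant flow direction, treating the axis as circular so that aliased
(wrapped) flow is unwrapped past the Nyquist limit, (3) finds the bin at
which cumulative above-floor power reaches ``power_fraction`` of the
column total, and (4) refines that bin to sub-bin precision with a local
power-weighted centroid.  Columns with no above-floor power are flagged
and set to zero velocity.

``detect_beats`` segments the envelope into cardiac cycles from systolic
peak to systolic peak.  Peaks are picked on a median-smoothed copy of the
envelope (robust to single-column dropouts); amplitudes are then
measured on the unsmoothed envelope in a small neighborhood of each
detected landmark, so the smoothing cannot clip the systolic peak or the
end-diastolic trough.  Per beat: PSV (peak), EDV (trough immediately
before the next systolic upstroke), TAV (cycle mean), and FHR = 60 /
peak interval.

``detect_accelerations`` applies the cardiotocography convention: an
acceleration is a rise of the FHR >= 15 bpm above a rolling-median
baseline sustained for >= 15 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from fetodoppler.indices import VelocitySummary, compute_pi, compute_ri, compute_sd_ratio
from fetodoppler.synth import Spectrogram

__all__ = [
    "Envelope",
    "NoBeatsError",
    "extract_envelope",
    "detect_beats",
    "add_indices",
    "absent_edv_fraction",
    "detect_accelerations",
]

#: EDV at or below this (cm/s) counts as absent end-diastolic flow.
EDV_ZERO_THRESHOLD = 2.0


class NoBeatsError(RuntimeError):
    """Fewer than two systolic peaks: non-pulsatile gate placement."""


@dataclass
class Envelope:
    """Maximum-velocity trace extracted from a spectrogram.

    ``velocity`` is signed (flow toward the transducer positive) and may
    exceed the Nyquist velocity when aliased flow was unwrapped.
    ``flagged`` marks all-noise columns (velocity set to 0).
    """

    time: np.ndarray
    velocity: np.ndarray
    flagged: np.ndarray
    noise_floor: float
    time_step: float
    nyquist: float

    @property
    def duration(self) -> float:
        return self.velocity.size * self.time_step


def _flow_side(power: np.ndarray, axis: np.ndarray) -> int:
    """+1 if most above-floor power sits at positive velocities, else -1."""
    pos = power[:, axis > 0].sum()
    neg = power[:, axis < 0].sum()
    return 1 if pos >= neg else -1


def extract_envelope(
    spec: Spectrogram,
    power_fraction: float = 0.95,
    smooth_window: int = 1,
    noise_floor: float | None = None,
    refine_bins: int = 3,
    unwrap_alias: bool = True,
    alias_limit: float = 1.5,
) -> Envelope:
    """Extract the velocity envelope of a spectrogram.

    Parameters
    ----------
    power_fraction
        Fraction of above-floor column power at which the cumulative
        outward walk stops (the envelope percentile).
    smooth_window
        Optional moving-median smoothing of the trace (odd, in time
        bins; 1 = off).
    noise_floor
        Per-bin noise level to subtract.  Default: estimated as 3x the
        median power of the whole spectrogram (~2.1x the mean of an
        exponential noise background; exactly 0 for a noise-free
        spectrogram).  The estimate scales with the data, so the
        envelope is invariant to uniform power scaling.
    refine_bins
        Half-width (bins) of the centroid refinement window around the
        percentile-crossing bin; 0 disables refinement.
    unwrap_alias
        Continue the outward walk circularly past the Nyquist limit so
        aliased flow is reported at its unwrapped velocity.
    alias_limit
        Baseline cut of the circular axis, in Nyquist units (default
        1.5).  Unwrapped velocities beyond ``alias_limit * nyquist`` are
        reinterpreted as counter-flow (e.g. a ridge at -0.2 Nyquist on a
        forward-flow record is reported as true reverse flow, not as
        1.8x Nyquist aliased forward flow).
    """
    if not (0.0 < power_fraction <= 1.0):
        raise ValueError("power_fraction must be in (0, 1]")
    power = np.asarray(spec.power, dtype=float)
    axis = np.asarray(spec.velocity_axis, dtype=float)
    n_t, n_v = power.shape
    v_nyq = spec.nyquist

    floor = 3.0 * float(np.median(power)) if noise_floor is None else noise_floor
    p = np.clip(power - floor, 0.0, None)

    side = _flow_side(p, axis)
    # outward path from 0 along the flow direction; circular continuation
    # represents aliased velocities beyond +/- Nyquist.
    if side > 0:
        path = np.concatenate([np.nonzero(axis >= 0)[0], np.nonzero(axis < 0)[0]])
        unwrapped = axis[path].copy()
        unwrapped[axis[path] < 0] += 2.0 * v_nyq
    else:
        path = np.concatenate(
            [np.nonzero(axis <= 0)[0][::-1], np.nonzero(axis > 0)[0][::-1]]
        )
        unwrapped = axis[path].copy()
        unwrapped[axis[path] > 0] -= 2.0 * v_nyq
    if not unwrap_alias:
        n_keep = int(np.count_nonzero((axis >= 0) if side > 0 else (axis <= 0)))
        path, unwrapped = path[:n_keep], unwrapped[:n_keep]

    pp = p[:, path]
    totals = pp.sum(axis=1)
    max_total = float(totals.max()) if n_t else 0.0
    flagged = totals <= 1e-12 * max(max_total, 1e-300)

    velocity = np.zeros(n_t)
    cum = np.cumsum(pp, axis=1)
    ok = ~flagged
    if ok.any():
        target = power_fraction * totals[ok]
        cross = np.argmax(cum[ok] >= target[:, None] - 1e-15, axis=1)
        if refine_bins > 0:
            lo = np.maximum(cross - refine_bins, 0)
            hi = np.minimum(cross + refine_bins, len(path) - 1)
            vals = np.zeros(cross.size)
            rows = np.nonzero(ok)[0]
            for i, (r, a, b) in enumerate(zip(rows, lo, hi)):
                w = pp[r, a : b + 1]
                s = w.sum()
                vals[i] = (
                    (w @ unwrapped[a : b + 1]) / s if s > 0 else unwrapped[cross[i]]
                )
            velocity[ok] = vals
        else:
            velocity[ok] = unwrapped[cross]

    # baseline cut: the tail of the circular axis is counter-flow
    if unwrap_alias:
        limit = alias_limit * v_nyq
        if side > 0:
            velocity[velocity > limit] -= 2.0 * v_nyq
        else:
            velocity[velocity < -limit] += 2.0 * v_nyq

    if smooth_window > 1:
        size = smooth_window + (smooth_window % 2 == 0)  # force odd
        velocity = median_filter(velocity, size=size, mode="nearest")

    return Envelope(
        time=np.arange(n_t) * spec.time_step,
        velocity=velocity,
        flagged=flagged,
        noise_floor=floor,
        time_step=spec.time_step,
        nyquist=v_nyq,
    )


def detect_beats(
    env: Envelope,
    fhr_band: tuple[float, float] = (60.0, 240.0),
    prominence_fraction: float = 0.3,
    detect_smooth: int = 3,
    edv_zero_threshold: float = EDV_ZERO_THRESHOLD,
) -> pd.DataFrame:
    """Segment the envelope into beats and measure per-beat hemodynamics.

    Returns a BeatTable DataFrame with columns beat_index, start_s,
    end_s, psv, edv, tav, interval_s, fhr, edv_absent, edv_reversed
    (velocities cm/s, magnitudes along the flow direction).  Beats whose
    FHR falls outside ``fhr_band`` are rejected.  Raises ``NoBeatsError``
    when fewer than two systolic peaks are found.
    """
    if env.duration < 2.0:
        raise ValueError("envelope must span at least 2 s to detect beats")
    dt = env.time_step
    flow_sign = 1.0 if np.median(env.velocity) >= 0 else -1.0
    v = env.velocity * flow_sign

    v_det = median_filter(v, size=detect_smooth + (detect_smooth % 2 == 0), mode="nearest") \
        if detect_smooth > 1 else v
    vrange = float(v_det.max() - v_det.min())
    if vrange <= 0.0:
        raise NoBeatsError("constant envelope: no systolic peaks")
    min_dist = max(1, int(round(60.0 / fhr_band[1] / dt)))
    peaks, _ = find_peaks(
        v_det, distance=min_dist, prominence=prominence_fraction * vrange
    )
    if peaks.size < 2:
        raise NoBeatsError(f"found {peaks.size} systolic peak(s); need >= 2")

    w = max(1, detect_smooth)
    rows = []
    for b, (p0, p1) in enumerate(zip(peaks[:-1], peaks[1:])):
        interval = (p1 - p0) * dt
        fhr = 60.0 / interval
        if not (fhr_band[0] <= fhr <= fhr_band[1]):
            continue
        psv = float(v[max(p0 - w, 0) : p0 + w + 1].max())
        # end-diastole: trough in the second half of the cycle, just
        # before the next systolic upstroke
        mid = p0 + (p1 - p0) // 2
        j = mid + int(np.argmin(v_det[mid : p1 + 1]))
        edv = float(v[max(j - w, 0) : min(j + w, p1) + 1].min())
        tav = float(v[p0:p1].mean())
        rows.append(
            {
                "beat_index": b,
                "start_s": p0 * dt,
                "end_s": p1 * dt,
                "psv": psv,
                "edv": edv,
                "tav": tav,
                "interval_s": interval,
                "fhr": fhr,
                "edv_absent": edv <= edv_zero_threshold,
                "edv_reversed": edv < -edv_zero_threshold,
            }
        )
    if not rows:
        raise NoBeatsError("all detected beats fell outside the FHR band")
    beats = pd.DataFrame(rows)
    beats["beat_index"] = np.arange(len(beats))
    return beats


def add_indices(beats: pd.DataFrame) -> pd.DataFrame:
    """Append per-beat sd_ratio, pi, ri columns (NaN S/D at absent EDV)."""
    out = beats.copy()
    sd, pi, ri = [], [], []
    for _, r in beats.iterrows():
        vs = VelocitySummary(psv=r.psv, edv=r.edv, tav=r.tav)
        sd.append(compute_sd_ratio(vs))
        pi.append(compute_pi(vs) if r.tav > 0 else math.nan)
        ri.append(compute_ri(vs))
    out["sd_ratio"], out["pi"], out["ri"] = sd, pi, ri
    return out


def absent_edv_fraction(
    beats: pd.DataFrame, edv_zero_threshold: float = EDV_ZERO_THRESHOLD
) -> float:
    """Fraction of beats whose EDV is at or below the absent-flow threshold."""
    if len(beats) == 0:
        raise ValueError("empty beat table")
    return float((beats["edv"] <= edv_zero_threshold).mean())


def detect_accelerations(
    time_s: np.ndarray,
    fhr_bpm: np.ndarray,
    baseline_window: float = 120.0,
    rise_threshold: float = 15.0,
    min_duration: float = 15.0,
) -> pd.DataFrame:
    """Transient FHR accelerations over a rolling-median baseline.

    An event is a maximal run of samples with
    ``fhr - rolling_median(fhr, baseline_window) >= rise_threshold``
    spanning at least ``min_duration`` seconds.  Returns a DataFrame with
    start_s, end_s, duration_s, max_rise_bpm.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(fhr_bpm, dtype=float)
    if t.size != f.size or t.size < 2:
        raise ValueError("time and FHR series must be equal length >= 2")
    if t[-1] - t[0] < baseline_window:
        raise ValueError("series shorter than the baseline window")

    half = baseline_window / 2.0
    baseline = np.empty_like(f)
    for i, ti in enumerate(t):  # centered rolling median on uneven samples
        lo = np.searchsorted(t, ti - half, side="left")
        hi = np.searchsorted(t, ti + half, side="right")
        baseline[i] = np.median(f[lo:hi])

    above = (f - baseline) >= rise_threshold
    rows = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            duration = t[j] - t[i]
            if duration >= min_duration:
                rows.append(
                    {
                        "start_s": t[i],
                        "end_s": t[j],
                        "duration_s": duration,
                        "max_rise_bpm": float((f - baseline)[i : j + 1].max()),
                    }
                )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s", "max_rise_bpm"])
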