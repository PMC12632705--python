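"""Autonomous vessel tracking on duplex image sequences.

A pulsatile artery modulates its color-Doppler signal over the cardiac
cycle, while veins and background do not.  The tracker exploits this:

1. ``pulsatility_map`` - per-pixel temporal variance of color-Doppler
   intensity (|velocity|) over a short window of consecutive frames.
   Magnitude is used so aliased sign flips still register as pulsatile.
2. ``segment_pulsatile`` - threshold the map (fraction-of-max by
   default, Otsu as an alternative), label connected components, and
   discard small regions.
3. ``select_primary`` - the primary region is the largest segmented
   area (ties: higher mean variance, then shallower centroid).
4. ``register_gate`` - the sample gate is placed at the unweighted
   spatial centroid of the primary region (default 2-mm gate length).
5. ``track_sequence`` - slides the window over the sequence, emitting a
   gate per step; when no pulsatile region is found the last valid gate
   is held and the step is flagged "lost".

Coordinates: lateral = column index * pitch (mm from the left edge),
axial = row index * pitch (mm of depth), pixel centers, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from fetodoppler.synth import DEFAULT_GATE_MM, FrameSequence

__all__ = [
    "PulsatilityMap",
    "SegmentedRegion",
    "SampleGate",
    "TrackerConfig",
    "NoPulsatileRegionError",
    "pulsatility_map",
    "segment_pulsatile",
    "select_primary",
    "register_gate",
    "track_sequence",
]


class NoPulsatileRegionError(RuntimeError):
    """No supra-threshold pulsatile region: the target is lost."""


@dataclass
class PulsatilityMap:
    """Per-pixel temporal variance of color-Doppler intensity."""

    variance: np.ndarray
    window_length: int
    pixel_pitch: float


@dataclass(frozen=True)
class SegmentedRegion:
    """A connected pulsatile region of the map."""

    label: int
    area: int
    mean_variance: float
    centroid_lateral_mm: float
    centroid_axial_mm: float


@dataclass(frozen=True)
class SampleGate:
    """Spectral-Doppler sample gate position (mm) and length (mm)."""

    lateral_mm: float
    axial_mm: float
    length_mm: float = DEFAULT_GATE_MM


@dataclass(frozen=True)
class TrackerConfig:
    """Tracking parameters.

    ``window`` frames (default 10: >= one cardiac cycle at 20 frames/s
    and FHR >= 120 bpm) feed the variance map; the map is thresholded at
    ``threshold`` of its maximum (policy ``fraction_of_max``) or by Otsu;
    components below ``min_region_area`` pixels are discarded.
    """

    window: int = 10
    step: int = 1
    threshold_policy: str = "fraction_of_max"
    threshold: float = 0.3
    min_region_area: int = 20
    connectivity: int = 8
    presmooth_px: int = 1
    gate_length_mm: float = DEFAULT_GATE_MM


def pulsatility_map(
    frames: FrameSequence | Sequence[np.ndarray] | np.ndarray,
    pixel_pitch: float | None = None,
) -> PulsatilityMap:
    """Population variance of |color velocity| across a frame window.

    ``frames`` is a FrameSequence (its color channel is used), an array
    of shape (window, H, W), or a sequence of equally-shaped 2-D grids.
    """
    if isinstance(frames, FrameSequence):
        stack = frames.color
        pitch = frames.pixel_pitch
    else:
        arrs = [np.asarray(f, dtype=float) for f in frames]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError(f"mismatched frame shapes in window: {sorted(shapes)}")
        stack = np.stack(arrs)
        pitch = pixel_pitch if pixel_pitch is not None else 1.0
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("pulsatility map needs a window of >= 2 frames")
    variance = np.var(np.abs(stack.astype(float)), axis=0)  # ddof=0
    return PulsatilityMap(
        variance=variance, window_length=stack.shape[0], pixel_pitch=pitch
    )


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def segment_pulsatile(
    pmap: PulsatilityMap,
    threshold_policy: str = "fraction_of_max",
    threshold: float = 0.3,
    min_region_area: int = 20,
    connectivity: int = 8,
    presmooth_px: int = 1,
) -> list[SegmentedRegion]:
    """Binarize the pulsatility map and return regions by area, descending.

    ``presmooth_px`` applies a (2r+1)^2 box filter to the variance map
    before thresholding (0 disables).  Pixels at a moving vessel's edge
    toggle between flow and background, giving them several times the
    variance of the vessel interior; without smoothing a fraction-of-max
    threshold locks onto those edge slivers and fragments the vessel.

    An all-zero (or fully sub-threshold) map returns an empty list.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    var = pmap.variance
    if presmooth_px > 0:
        var = ndimage.uniform_filter(var, size=2 * presmooth_px + 1, mode="constant")
    vmax = float(var.max()) if var.size else 0.0
    if vmax <= 0.0:
        return []
    if threshold_policy == "fraction_of_max":
        level = threshold * vmax
    elif threshold_policy == "otsu":
        from skimage.filters import threshold_otsu

        level = float(threshold_otsu(var))
    else:
        raise ValueError(f"unknown threshold policy: {threshold_policy!r}")
    mask = var >= level

    labels, n_labels = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    regions: list[SegmentedRegion] = []
    for lab in range(1, n_labels + 1):
        rows, cols = np.nonzero(labels == lab)
        area = rows.size
        if area < min_region_area:
            continue
        regions.append(
            SegmentedRegion(
                label=lab,
                area=int(area),
                mean_variance=float(var[rows, cols].mean()),
                centroid_lateral_mm=float(cols.mean() * pmap.pixel_pitch),
                centroid_axial_mm=float(rows.mean() * pmap.pixel_pitch),
            )
        )
    regions.sort(key=lambda r: -r.area)
    return regions


def select_primary(regions: Sequence[SegmentedRegion]) -> SegmentedRegion:
    """Largest-area region; ties broken by mean variance, then shallower depth."""
    if not regions:
        raise NoPulsatileRegionError("no pulsatile region above threshold")
    return min(
        regions,
        key=lambda r: (-r.area, -r.mean_variance, r.centroid_axial_mm),
    )


def register_gate(
    region: SegmentedRegion, gate_length_mm: float = DEFAULT_GATE_MM
) -> SampleGate:
    """Place the sample gate at the region's unweighted pixel centroid."""
    return SampleGate(
        lateral_mm=region.centroid_lateral_mm,
        axial_mm=region.centroid_axial_mm,
        length_mm=gate_length_mm,
    )


def track_sequence(
    frames: FrameSequence, config: TrackerConfig | None = None
) -> pd.DataFrame:
    """Track the pulsatile vessel through a sequence.

    Applies the variance-map pipeline to each sliding window and emits
    one gate per evaluation step, reported at the window's last frame.
    On target loss the last valid gate is held (NaN before the first
    acquisition) with status "lost"; tracking resumes on reacquisition.

    Returns a DataFrame with columns frame_index, time_s, lateral_mm,
    axial_mm, status.
    """
    cfg = config or TrackerConfig()
    if cfg.window < 2:
        raise ValueError("tracker window must be >= 2 frames")
    if frames.n_frames < cfg.window:
        raise ValueError(
            f"sequence of {frames.n_frames} frames is shorter than the "
            f"{cfg.window}-frame tracking window"
        )
    rows = []
    last_gate: SampleGate | None = None
    for end in range(cfg.window - 1, frames.n_frames, cfg.step):
        window = frames.color[end - cfg.window + 1 : end + 1]
        pmap = PulsatilityMap(
            variance=np.var(np.abs(window.astype(float)), axis=0),
            window_length=cfg.window,
            pixel_pitch=frames.pixel_pitch,
        )
        regions = segment_pulsatile(
            pmap,
            threshold_policy=cfg.threshold_policy,
            threshold=cfg.threshold,
            min_region_area=cfg.min_region_area,
            connectivity=cfg.connectivity,
            presmooth_px=cfg.presmooth_px,
        )
        try:
            gate = register_gate(select_primary(regions), cfg.gate_length_mm)
            status = "ok"
            last_gate = gate
        except NoPulsatileRegionError:
            gate = last_gate
            status = "lost"
        rows.append(
            {
                "frame_index": end,
                "time_s": float(frames.timestamps[end]),
                "lateral_mm": gate.lateral_mm if gate else np.nan,
                "axial_mm": gate.axial_mm if gate else np.nan,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
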