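"""File formats: duplex frame containers, beat/trajectory tables, spectrograms.

Frame sequences are stored as multi-page TIFF with shape
(n_frames, 2, H, W) — channel 0 = B-mode, channel 1 = color velocity —
and a JSON metadata block (pixel pitch, frame rate, timestamps,
coordinate convention, config) in the ImageDescription tag.  Tables are
CSV with unit-suffixed headers and a single leading ``#`` metadata line
holding the config and seed, so every output embeds its provenance.
Spectrograms use ``.npz`` with the same JSON metadata convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from fetodoppler.synth import FrameSequence, Spectrogram

__all__ = [
    "COORDINATE_CONVENTION",
    "read_frames",
    "write_frames",
    "read_table",
    "write_table",
    "read_spectrogram",
    "write_spectrogram",
    "write_json",
]

COORDINATE_CONVENTION = (
    "lateral = mm from field left edge; axial = depth in mm from the "
    "transducer face; pixel centers, 0-based indices; flow toward the "
    "transducer positive"
)

#: Beat tables are written with these unit-suffixed headers.
BEAT_HEADER = {
    "beat_index": "beat_index",
    "start_s": "start_s",
    "end_s": "end_s",
    "psv": "psv_cms",
    "edv": "edv_cms",
    "tav": "tav_cms",
    "fhr": "fhr_bpm",
    "sd_ratio": "sd_ratio",
    "pi": "pi",
    "ri": "ri",
    "edv_absent": "edv_absent",
    "edv_reversed": "edv_reversed",
}

_REQUIRED_FRAME_META = ("pixel_pitch_mm", "frame_rate_hz", "timestamps_s", "convention")


def write_frames(
    path: str | Path, frames: FrameSequence, config: dict | None = None
) -> None:
    """Write a frame sequence as a multi-page float TIFF with metadata."""
    stack = np.stack([frames.bmode, frames.color], axis=1)
    meta = {
        "pixel_pitch_mm": frames.pixel_pitch,
        "frame_rate_hz": frames.frame_rate,
        "timestamps_s": [float(t) for t in frames.timestamps],
        "convention": COORDINATE_CONVENTION,
        "channels": ["bmode", "color_velocity_cms"],
        "config": config or {},
    }
    tifffile.imwrite(path, stack, description=json.dumps(meta, sort_keys=True))


def read_frames(path: str | Path) -> tuple[FrameSequence, dict]:
    """Read a frame container; hard error naming any missing metadata field."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc)
    missing = [k for k in _REQUIRED_FRAME_META if k not in meta]
    if missing:
        raise ValueError(f"frame container {path} is missing metadata: {missing}")
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError(
            f"expected (n_frames, 2, H, W) paired B-mode/color stack, "
            f"got shape {stack.shape}"
        )
    timestamps = np.asarray(meta["timestamps_s"], dtype=float)
    if timestamps.size != stack.shape[0]:
        raise ValueError(
            f"frame count mismatch: {stack.shape[0]} frames vs "
            f"{timestamps.size} timestamps"
        )
    frames = FrameSequence(
        bmode=stack[:, 0],
        color=stack[:, 1],
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        frame_rate=float(meta["frame_rate_hz"]),
        timestamps=timestamps,
    )
    return frames, meta


def write_table(
    path: str | Path,
    df: pd.DataFrame,
    meta: dict | None = None,
    rename: dict | None = None,
) -> None:
    """CSV with a leading ``# fetodoppler`` JSON metadata line.

    Floats are written with 12 significant digits so a round trip is
    lossless at that precision; identical config + seed therefore yield
    byte-identical files.
    """
    out = df.rename(columns=rename) if rename else df
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# fetodoppler " + json.dumps(meta or {}, sort_keys=True) + "\n")
        out.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_table(path: str | Path, rename_back: bool = True) -> tuple[pd.DataFrame, dict]:
    """Read a metadata-bearing CSV; returns (table, metadata)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("# fetodoppler "):
            meta = json.loads(first[len("# fetodoppler "):])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, comment="#")
    if rename_back:
        inverse = {v: k for k, v in BEAT_HEADER.items()}
        df = df.rename(columns=inverse)
    return df, meta


def write_spectrogram(
    path: str | Path, spec: Spectrogram, config: dict | None = None
) -> None:
    """Write a spectrogram as ``.npz`` with JSON metadata."""
    meta = {
        "time_step_s": spec.time_step,
        "prf_hz": spec.prf,
        "carrier_mhz": spec.carrier_mhz,
        "angle_deg": spec.angle_deg,
        "sound_speed_m_s": spec.sound_speed,
        "convention": COORDINATE_CONVENTION,
        "config": config or {},
    }
    np.savez(
        path,
        power=spec.power,
        velocity_axis_cms=spec.velocity_axis,
        meta=json.dumps(meta, sort_keys=True),
    )


def read_spectrogram(path: str | Path) -> tuple[Spectrogram, dict]:
    """Read a ``.npz`` spectrogram container."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        missing = [
            k for k in ("time_step_s", "prf_hz", "carrier_mhz") if k not in meta
        ]
        if missing:
            raise ValueError(f"spectrogram {path} is missing metadata: {missing}")
        spec = Spectrogram(
            power=z["power"],
            time_step=float(meta["time_step_s"]),
            velocity_axis=z["velocity_axis_cms"],
            prf=float(meta["prf_hz"]),
            carrier_mhz=float(meta["carrier_mhz"]),
            angle_deg=float(meta.get("angle_deg", 0.0)),
            sound_speed=float(meta.get("sound_speed_m_s", 1540.0)),
        )
    return spec, meta


def write_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON output (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
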