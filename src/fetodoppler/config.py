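"""Run configuration: defaults, YAML loading, and canonical hashing.

A run configuration is a nested dict with one section per pipeline
stage.  User YAML files override defaults key-by-key; the merged config
(with the seed) is serialized verbatim into every output's metadata
block so results are reproducible from their own files.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "merge_config", "config_hash"]

_DEFAULTS: dict = {
    "seed": 0,
    "acquisition": {
        "carrier_mhz": 2.5,       # transmit frequency
        "prf_hz": 3000.0,         # Doppler pulse repetition frequency
        "gate_mm": 2.0,           # spectral sample-gate length
        "frame_rate": 20.0,       # duplex frames/s
        "sound_speed_m_s": 1540.0,
    },
    "waveform": {
        "fhr": 140.0,             # bpm
        "psv": 52.2,              # cm/s
        "edv": 20.0,              # cm/s
        "systolic_fraction": 0.3,
        "duration": 10.0,         # s
        "sample_rate": 200.0,     # Hz
        "absent_edv_fraction": 0.0,
        "reversed_edv": False,
    },
    "scene": {
        "field_width": 50.0,      # mm
        "field_depth": 70.0,      # mm
        "pixel_pitch": 0.5,       # mm
        "n_frames": 100,
        "artery_radius": 3.0,     # mm
        "vein_radius": 4.0,       # mm
        "artery_center": [20.0, 35.0],
        "vein_offset": [11.0, 0.0],
        "vein_velocity": -10.0,   # cm/s
        "color_noise_sd": 2.0,    # cm/s
        "speckle_mean": 120.0,
        "speckle_var": 400.0,
        "trajectory": {"kind": "random_walk", "max_speed": 2.0},
    },
    "spectrogram": {
        "n_velocity_bins": 256,
        "broadening_sd": 0.0,     # cm/s
        "noise_floor": 0.0,       # per-bin mean power
        "angle_deg": 0.0,
    },
    "tracking": {
        "window": 10,             # frames
        "step": 1,
        "threshold_policy": "fraction_of_max",
        "threshold": 0.3,
        "min_region_area": 20,    # px
        "connectivity": 8,
    },
    "spectral": {
        "power_fraction": 0.95,
        "smooth_window": 1,       # time bins
        "fhr_min": 60.0,          # bpm
        "fhr_max": 240.0,
        "edv_zero_threshold": 2.0,  # cm/s
    },
    "monitoring": {
        "interval_s": 600.0,
        "min_beats": 10,
        "variability": "sd",      # within-segment SD of per-beat FHR
        "percentile_rule": "linear",
    },
}


def default_config() -> dict:
    """A deep copy of the package default configuration."""
    return copy.deepcopy(_DEFAULTS)


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg = merge_config(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()
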