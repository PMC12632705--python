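"""Shared fixtures: canonical synthetic scenes and pipeline products."""

import numpy as np
import pytest

from fetodoppler import (
    SceneSpec,
    WaveformSpec,
    generate_waveform,
    render_sequence,
    synthesize_spectrogram,
)
from fetodoppler.spectral import add_indices, detect_beats, extract_envelope


@pytest.fixture(scope="session")
def healthy_waveform():
    """Default UA waveform: PSV 52.2, EDV 20 cm/s, FHR 140, 10 s."""
    spec = WaveformSpec()
    wf, truth = generate_waveform(spec, seed=1)
    return spec, wf, truth


@pytest.fixture(scope="session")
def healthy_beats(healthy_waveform):
    """End-to-end beats for the noise-free healthy waveform."""
    _, wf, truth = healthy_waveform
    spec = synthesize_spectrogram(wf)
    env = extract_envelope(spec)
    return add_indices(detect_beats(env)), truth


@pytest.fixture(scope="session")
def moving_scene():
    """A random-walk vessel-pair sequence with ground truth (seed 0)."""
    scene = SceneSpec(trajectory={"kind": "random_walk", "max_speed": 2.0}, seed=0)
    frames, truth = render_sequence(scene, WaveformSpec())
    return scene, frames, truth


def beats_frame(n_beats, fhr=140.0, psv=52.2, edv=20.0, tav=31.0, t0=0.0):
    """Hand-built beat table at a constant rate (test helper)."""
    import pandas as pd

    interval = 60.0 / fhr
    start = t0 + np.arange(n_beats) * interval
    return pd.DataFrame(
        {
            "beat_index": np.arange(n_beats),
            "start_s": start,
            "end_s": start + interval,
            "psv": np.full(n_beats, float(psv)),
            "edv": np.full(n_beats, float(edv)),
            "tav": np.full(n_beats, float(tav)),
            "interval_s": np.full(n_beats, interval),
            "fhr": np.full(n_beats, float(fhr)),
        }
    )
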