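"""Envelope extraction, beat detection, and FHR acceleration analysis."""

import numpy as np
import pytest

from fetodoppler import WaveformSpec, generate_waveform, synthesize_spectrogram
from fetodoppler.synth import Spectrogram, nyquist_velocity
from fetodoppler.spectral import (
    NoBeatsError,
    absent_edv_fraction,
    detect_accelerations,
    detect_beats,
    extract_envelope,
)


def make_spectrogram(power, prf=3000.0, carrier=2.5, fs=100.0):
    n_bins = power.shape[1]
    v_nyq = nyquist_velocity(prf, carrier)
    axis = -v_nyq + (np.arange(n_bins) + 0.5) * 2 * v_nyq / n_bins
    return Spectrogram(
        power=power, time_step=1.0 / fs, velocity_axis=axis, prf=prf, carrier_mhz=carrier
    )


class TestEnvelope:
    def test_constant_ridge_recovered_within_bin(self):
        wf = np.full(100, 30.0)
        spec = synthesize_spectrogram(wf, sample_rate=100.0)
        env = extract_envelope(spec)
        bin_w = spec.velocity_axis[1] - spec.velocity_axis[0]
        assert np.allclose(env.velocity, 30.0, atol=bin_w)
        assert not env.flagged.any()

    def test_zero_signal_all_flagged(self):
        spec = make_spectrogram(np.zeros((40, 64)))
        env = extract_envelope(spec)
        assert env.flagged.all()
        assert np.all(env.velocity == 0.0)

    def test_scale_invariance(self):
        wf, _ = generate_waveform(WaveformSpec(duration=3.0), seed=0)
        spec = synthesize_spectrogram(wf, noise_floor=1e-4, seed=2)
        env1 = extract_envelope(spec)
        spec.power = spec.power * 37.5
        env2 = extract_envelope(spec)
        assert np.allclose(env1.velocity, env2.velocity, atol=1e-12)

    def test_tracks_true_waveform_within_5pct_of_psv(self):
        spec_w = WaveformSpec()
        wf, _ = generate_waveform(spec_w, seed=1)
        spec = synthesize_spectrogram(wf, seed=1)
        env = extract_envelope(spec)
        assert np.max(np.abs(env.velocity - wf.velocity)) <= 0.05 * spec_w.psv

    def test_aliased_systolic_peak_unwrapped(self):
        """Supra-Nyquist excursions of forward flow are unwrapped.

        Most of the record flows at 30 cm/s, so the flow direction is
        unambiguous; the samples at 1.1 Nyquist wrap to -0.9 Nyquist in
        the spectrogram and must be reported back at 1.1 Nyquist.
        """
        v_nyq = nyquist_velocity(3000.0, 2.5)
        wf = np.full(100, 30.0)
        wf[40:50] = 1.1 * v_nyq
        env = extract_envelope(synthesize_spectrogram(wf, sample_rate=100.0))
        assert np.allclose(env.velocity, wf, atol=2 * 2 * v_nyq / 256)

    def test_reverse_flow_negative_envelope(self):
        wf = np.full(60, -25.0)
        env = extract_envelope(synthesize_spectrogram(wf, sample_rate=100.0))
        assert np.allclose(env.velocity, -25.0, atol=2 * 2 * 46.2 / 256)


class TestBeats:
    def test_fhr_recovered_within_2bpm(self, healthy_beats):
        beats, truth = healthy_beats
        assert beats.fhr.mean() == pytest.approx(truth.beats.fhr.mean(), abs=2.0)

    def test_psv_edv_recovered(self, healthy_beats):
        beats, _ = healthy_beats
        assert beats.psv.mean() == pytest.approx(52.2, rel=0.02)
        assert beats.edv.mean() == pytest.approx(20.0, rel=0.02)

    def test_constant_envelope_raises(self):
        spec = synthesize_spectrogram(np.full(300, 30.0), sample_rate=100.0)
        with pytest.raises(NoBeatsError):
            detect_beats(extract_envelope(spec))

    def test_short_envelope_rejected(self):
        spec = synthesize_spectrogram(np.full(30, 30.0), sample_rate=100.0)
        with pytest.raises(ValueError, match="2 s"):
            detect_beats(extract_envelope(spec))

    def test_absent_edv_beats_counted(self):
        """25 of 100 absent-EDV beats are recovered through the pipeline."""
        spec_w = WaveformSpec(
            absent_edv_fraction=0.25, duration=100 * 60.0 / 140.0
        )
        wf, truth = generate_waveform(spec_w, seed=3)
        env = extract_envelope(synthesize_spectrogram(wf))
        beats = detect_beats(env)
        # peak-to-peak segmentation sees 99 complete cycles of the 100;
        # detected beat k ends at the end-diastole of generator beat k
        assert len(beats) >= 98
        true_absent = int(truth.beats.edv_absent.iloc[: len(beats)].sum())
        assert abs(int(beats.edv_absent.sum()) - true_absent) <= 1

    def test_intervals_partition_spanned_time(self, healthy_beats):
        beats, _ = healthy_beats
        spanned = beats.end_s.iloc[-1] - beats.start_s.iloc[0]
        assert beats.interval_s.sum() == pytest.approx(spanned, abs=0.01)

    def test_add_indices_matches_formulas(self, healthy_beats):
        beats, _ = healthy_beats
        assert np.allclose(beats.ri, (beats.psv - beats.edv) / beats.psv)
        assert np.allclose(beats.pi, (beats.psv - beats.edv) / beats.tav)
        assert np.allclose(beats.sd_ratio, beats.psv / beats.edv)


class TestAbsentFraction:
    def test_no_absent(self, healthy_beats):
        beats, _ = healthy_beats
        assert absent_edv_fraction(beats) == 0.0

    def test_counting(self, healthy_beats):
        beats, _ = healthy_beats
        modified = beats.copy()
        modified.loc[modified.index[:5], "edv"] = 0.5
        assert absent_edv_fraction(modified) == pytest.approx(5 / len(modified))

    def test_generator_fraction_recovered(self):
        """1000-beat stream at absent fraction 0.249."""
        spec_w = WaveformSpec(
            absent_edv_fraction=0.249, duration=1000 * 60.0 / 140.0
        )
        _, truth = generate_waveform(spec_w, seed=7)
        frac = float(truth.beats.edv_absent.mean())
        assert frac == pytest.approx(0.249, abs=0.001)

    def test_empty_rejected(self, healthy_beats):
        beats, _ = healthy_beats
        with pytest.raises(ValueError):
            absent_edv_fraction(beats.iloc[0:0])


def accel_oracle(t, f, baseline, rise, min_dur):
    """Brute-force scan for sustained rises (independent of the implementation)."""
    above = (f - baseline) >= rise
    events = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if t[j] - t[i] >= min_dur:
                events.append((t[i], t[j]))
            i = j + 1
        else:
            i += 1
    return events


class TestAccelerations:
    def _series(self, bumps, duration=600.0, dt=0.5, base=140.0):
        t = np.arange(0.0, duration, dt)
        f = np.full_like(t, base)
        for (t0, t1, amp) in bumps:
            f[(t >= t0) & (t < t1)] += amp
        return t, f

    def test_constant_fhr_no_events(self):
        t, f = self._series([])
        assert len(detect_accelerations(t, f)) == 0

    def test_single_bump_single_event(self):
        t, f = self._series([(300.0, 330.0, 20.0)])
        ev = detect_accelerations(t, f)
        assert len(ev) == 1
        assert ev.start_s.iloc[0] == pytest.approx(300.0, abs=1.0)
        assert ev.end_s.iloc[0] == pytest.approx(329.5, abs=1.0)
        assert ev.max_rise_bpm.iloc[0] == pytest.approx(20.0, abs=1.0)

    def test_two_bumps_with_subthreshold_dip(self):
        t, f = self._series([(200.0, 220.0, 20.0), (240.0, 260.0, 20.0)])
        ev = detect_accelerations(t, f)
        assert len(ev) == 2
        # brute-force oracle agrees on the event spans
        base = np.full_like(f, 140.0)
        oracle = accel_oracle(t, f, base, 15.0, 15.0)
        assert len(oracle) == 2
        assert np.allclose(ev.start_s.to_numpy(), [o[0] for o in oracle], atol=2.0)

    def test_short_bump_ignored(self):
        t, f = self._series([(300.0, 308.0, 25.0)])
        assert len(detect_accelerations(t, f)) == 0
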