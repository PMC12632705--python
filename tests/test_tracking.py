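"""Vessel tracking: variance map, segmentation, gate registration, sequences."""

import numpy as np
import pytest

from fetodoppler import SceneSpec, WaveformSpec, render_sequence
from fetodoppler.synth import Waveform
from fetodoppler.tracking import (
    NoPulsatileRegionError,
    PulsatilityMap,
    TrackerConfig,
    pulsatility_map,
    register_gate,
    segment_pulsatile,
    select_primary,
    track_sequence,
)


def variance_oracle(stack):
    """Two-pass per-pixel population variance of |values| (independent)."""
    mag = np.abs(np.asarray(stack, dtype=float))
    mean = mag.mean(axis=0)
    return ((mag - mean) ** 2).mean(axis=0)


class TestPulsatilityMap:
    def test_identical_frames_zero_map(self):
        stack = np.tile(np.random.default_rng(0).normal(size=(8, 9)), (5, 1, 1))
        assert np.allclose(pulsatility_map(stack).variance, 0.0)

    def test_alternating_pixel_variance_quarter(self):
        stack = np.zeros((4, 3, 3))
        stack[1::2, 1, 1] = 1.0  # 0,1,0,1
        pmap = pulsatility_map(stack)
        assert pmap.variance[1, 1] == pytest.approx(0.25)
        assert pmap.variance[0, 0] == 0.0

    def test_matches_two_pass_oracle_on_random_windows(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            shape = (rng.integers(2, 9), rng.integers(4, 17), rng.integers(4, 17))
            stack = rng.normal(scale=rng.uniform(0.5, 50), size=shape)
            got = pulsatility_map(stack).variance
            assert np.allclose(got, variance_oracle(stack), atol=1e-10)

    def test_signed_aliasing_flips_still_pulsatile(self):
        """Variance acts on |v|: a +40/-40 alias flip is not pulsatility."""
        stack = np.zeros((4, 5, 5))
        stack[:, 2, 2] = [40.0, -40.0, 40.0, -40.0]
        assert pulsatility_map(stack).variance[2, 2] == 0.0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pulsatility_map([np.zeros((4, 4)), np.zeros((5, 4))])

    def test_window_of_one_rejected(self):
        with pytest.raises(ValueError):
            pulsatility_map(np.zeros((1, 4, 4)))

    def test_argmax_inside_artery_on_scene(self, moving_scene):
        scene, frames, truth = moving_scene
        pmap = pulsatility_map(frames.color[:10], pixel_pitch=scene.pixel_pitch)
        r, c = np.unravel_index(pmap.variance.argmax(), pmap.variance.shape)
        cl = truth.centroids.lateral_mm.iloc[:10].mean()
        ca = truth.centroids.axial_mm.iloc[:10].mean()
        dist = np.hypot(c * scene.pixel_pitch - cl, r * scene.pixel_pitch - ca)
        assert dist <= scene.artery_radius + 2 * scene.pixel_pitch


def disk_map(shape, centers_radii, value=10.0, pitch=1.0):
    var = np.zeros(shape)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for (r0, c0, rad) in centers_radii:
        var[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = value
    return PulsatilityMap(variance=var, window_length=10, pixel_pitch=pitch)


class TestSegmentation:
    def test_all_zero_map_empty(self):
        pmap = PulsatilityMap(np.zeros((20, 20)), 10, 1.0)
        assert segment_pulsatile(pmap) == []

    def test_two_disks_ordered_by_area(self):
        pmap = disk_map((60, 60), [(20, 15, 9.5), (45, 45, 6.0)])
        regions = segment_pulsatile(pmap, presmooth_px=0)
        assert len(regions) == 2
        assert regions[0].area > regions[1].area
        assert regions[0].area == pytest.approx(np.pi * 9.5**2, rel=0.1)

    def test_min_area_filter(self):
        pmap = disk_map((40, 40), [(10, 10, 8.0), (30, 30, 2.0)])
        regions = segment_pulsatile(pmap, min_region_area=20, presmooth_px=0)
        assert len(regions) == 1

    def test_artery_outranks_vein_flicker(self, moving_scene):
        scene, frames, truth = moving_scene
        pmap = pulsatility_map(frames.color[:10], pixel_pitch=scene.pixel_pitch)
        regions = segment_pulsatile(pmap)
        primary = select_primary(regions)
        cl = truth.centroids.lateral_mm.iloc[:10].mean()
        ca = truth.centroids.axial_mm.iloc[:10].mean()
        assert abs(primary.centroid_lateral_mm - cl) < scene.artery_radius
        assert abs(primary.centroid_axial_mm - ca) < scene.artery_radius


class TestPrimaryAndGate:
    def test_largest_area_wins(self):
        pmap = disk_map((60, 60), [(20, 15, 9.5), (45, 45, 6.0)])
        regions = segment_pulsatile(pmap, presmooth_px=0)
        assert select_primary(regions).area == regions[0].area

    def test_tie_broken_by_mean_variance(self):
        var = np.zeros((20, 40))
        var[5:10, 2:12] = 5.0    # 50 px, mean 5
        var[12:17, 20:30] = 2.0  # 50 px, mean 2
        pmap = PulsatilityMap(var, 10, 1.0)
        regions = segment_pulsatile(pmap, threshold=0.1, presmooth_px=0)
        assert select_primary(regions).mean_variance == pytest.approx(5.0)

    def test_empty_regions_raise_loss(self):
        with pytest.raises(NoPulsatileRegionError):
            select_primary([])

    def test_gate_at_symmetric_disk_center(self):
        pmap = disk_map((200, 140), [(160, 60, 12.0)], pitch=0.5)
        gate = register_gate(select_primary(segment_pulsatile(pmap, presmooth_px=0)))
        assert gate.lateral_mm == pytest.approx(60 * 0.5, abs=0.25)
        assert gate.axial_mm == pytest.approx(160 * 0.5, abs=0.25)
        assert gate.length_mm == 2.0

    def test_l_shaped_region_centroid(self):
        var = np.zeros((4, 4))
        var[0, 0] = var[0, 1] = var[1, 0] = 1.0
        pmap = PulsatilityMap(var, 10, 1.0)
        gate = register_gate(
            select_primary(segment_pulsatile(pmap, min_region_area=1, presmooth_px=0))
        )
        assert gate.lateral_mm == pytest.approx(1 / 3)
        assert gate.axial_mm == pytest.approx(1 / 3)


class TestTrackSequence:
    def test_static_scene_constant_trajectory(self):
        scene = SceneSpec(trajectory={"kind": "static"}, n_frames=30, seed=2)
        frames, _ = render_sequence(scene, WaveformSpec())
        traj = track_sequence(frames)
        assert (traj.status == "ok").all()
        assert traj.lateral_mm.std() < 0.5
        assert traj.axial_mm.std() < 0.5

    def test_sinusoid_trajectory_correlates_with_truth(self):
        scene = SceneSpec(
            trajectory={"kind": "sinusoid", "amplitude": 10.0, "period": 10.0},
            n_frames=200,  # one full 10-s period at 20 frames/s
            seed=3,
        )
        frames, truth = render_sequence(scene, WaveformSpec(duration=11.0))
        traj = track_sequence(frames)
        # the variance window estimates the window-average position, so
        # compare against ground truth at the window center
        centered = truth.centroids.copy()
        centered["frame"] += 4  # window 10, reported at the last frame
        merged = traj.merge(centered, left_on="frame_index", right_on="frame")
        r = np.corrcoef(merged.lateral_mm_x, merged.lateral_mm_y)[0, 1]
        assert r > 0.99

    def test_vein_only_scene_all_lost(self):
        """Non-pulsatile flow: every status 'lost', no gate ever acquired."""
        scene = SceneSpec(color_noise_sd=0.0, n_frames=20, seed=0)
        steady = Waveform(velocity=np.full(400, 0.0), sample_rate=200.0)
        frames, _ = render_sequence(scene, steady)
        # vein flows steadily but nothing pulses
        traj = track_sequence(frames)
        assert (traj.status == "lost").all()
        assert traj.lateral_mm.isna().all()

    def test_translation_equivariance(self, moving_scene):
        """Shifting frames by (di, dj) px shifts gates by exactly that."""
        scene, frames, _ = moving_scene
        di, dj = 7, -5
        shifted = type(frames)(
            bmode=np.roll(frames.bmode, (di, dj), axis=(1, 2)),
            color=np.roll(frames.color, (di, dj), axis=(1, 2)),
            pixel_pitch=frames.pixel_pitch,
            frame_rate=frames.frame_rate,
            timestamps=frames.timestamps,
        )
        t0 = track_sequence(frames)
        t1 = track_sequence(shifted)
        assert np.allclose(
            t1.lateral_mm - t0.lateral_mm, dj * frames.pixel_pitch, atol=1e-9
        )
        assert np.allclose(
            t1.axial_mm - t0.axial_mm, di * frames.pixel_pitch, atol=1e-9
        )

    def test_noise_never_helps_accuracy(self):
        """Within-2mm fraction is non-increasing in color noise (same seeds)."""
        fracs = []
        for noise in (0.0, 6.0, 18.0):
            hits = total = 0
            for seed in range(2):
                scene = SceneSpec(
                    trajectory={"kind": "random_walk", "max_speed": 2.0},
                    n_frames=60,
                    color_noise_sd=noise,
                    seed=seed,
                )
                frames, truth = render_sequence(scene, WaveformSpec(duration=3.0))
                traj = track_sequence(frames)
                m = traj.merge(
                    truth.centroids, left_on="frame_index", right_on="frame"
                )
                d = np.hypot(
                    m.lateral_mm_x - m.lateral_mm_y, m.axial_mm_x - m.axial_mm_y
                )
                hits += int((d <= 2.0).sum())
                total += len(m)
            fracs.append(hits / total)
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_short_sequence_rejected(self):
        scene = SceneSpec(n_frames=5, seed=0)
        frames, _ = render_sequence(scene, WaveformSpec(duration=1.0))
        with pytest.raises(ValueError, match="shorter"):
            track_sequence(frames, TrackerConfig(window=10))
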