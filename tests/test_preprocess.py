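import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmsm.errors import (
    DegenerateSkeletonError,
    NoSwingDetectedError,
    ParameterError,
    ValidationError,
)
from dmsm.preprocess import (
    PreprocessConfig,
    Trajectory,
    align_address,
    crop_swing_window,
    detect_onset,
    mirror_sequence,
    normalize_body_scale,
    preprocess_sequence,
    resample_uniform,
    smooth_moving_average,
    smooth_sequence,
)
from dmsm.synth import SwingStyle, generate_swing

from conftest import ADDRESS_POSE, make_static_sequence

trajectories = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=2, max_size=60
).map(lambda v: Trajectory(np.asarray(v), 0.0, 1 / 30))


class TestNormalizeBodyScale:
    def test_shoulder_width_becomes_unity(self):
        seq = make_static_sequence(units="pixels", scale=100.0)
        out = normalize_body_scale(seq)
        d = np.linalg.norm(out.xy("left_shoulder") - out.xy("right_shoulder"), axis=1)
        np.testing.assert_allclose(d, 1.0, atol=1e-12)
        assert out.units == "body_scale"

    def test_uniform_scale_invariance(self):
        a = make_static_sequence(units="pixels", scale=100.0)
        b = make_static_sequence(units="pixels", scale=200.0)
        np.testing.assert_allclose(
            normalize_body_scale(a).coords, normalize_body_scale(b).coords, atol=1e-9
        )

    def test_idempotent(self, default_clip):
        once = normalize_body_scale(default_clip.sequence)
        twice = normalize_body_scale(once)
        np.testing.assert_allclose(once.coords, twice.coords, atol=1e-9)

    def test_overlapping_shoulders_degenerate(self):
        pose = dict(ADDRESS_POSE)
        pose["right_shoulder"] = pose["left_shoulder"]
        seq = make_static_sequence(pose=pose, units="pixels", scale=100.0)
        with pytest.raises(DegenerateSkeletonError):
            normalize_body_scale(seq)


class TestSmoothing:
    def test_window_one_is_identity(self):
        tr = Trajectory(np.arange(10.0), 0, 1 / 30)
        np.testing.assert_array_equal(smooth_moving_average(tr, 1).values, tr.values)

    def test_constant_unchanged(self):
        tr = Trajectory(np.full(20, 3.7), 0, 1 / 30)
        np.testing.assert_allclose(smooth_moving_average(tr, 7).values, 3.7)

    def test_impulse_closed_form(self):
        v = np.zeros(9)
        v[4] = 1.0
        out = smooth_moving_average(Trajectory(v, 0, 1 / 30), 3).values
        expected = np.zeros(9)
        expected[3:6] = 1 / 3
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_moving_average(Trajectory(np.arange(10.0), 0, 1 / 30), 4)

    @given(trajectories, st.sampled_from([1, 3, 5, 7]))
    def test_range_containment(self, tr, window):
        if window > len(tr):
            return
        out = smooth_moving_average(tr, window).values
        assert out.min() >= tr.values.min() - 1e-12
        assert out.max() <= tr.values.max() + 1e-12

    def test_length_preserved(self, default_clip):
        out = smooth_sequence(normalize_body_scale(default_clip.sequence), 5)
        assert out.n_frames == default_clip.sequence.n_frames


class TestResample:
    def test_linear_ramp_reproduced(self):
        tr = Trajectory(np.linspace(0, 5, 16), 0, 1 / 30)
        for n in (2, 7, 16, 101):
            out = resample_uniform(tr, n)
            np.testing.assert_allclose(out.values, np.linspace(0, 5, n), atol=1e-9)

    def test_constant(self):
        out = resample_uniform(Trajectory(np.full(10, 2.2), 0, 1 / 30), 37)
        np.testing.assert_allclose(out.values, 2.2, atol=1e-12)

    def test_cubic_beats_linear_on_sine(self):
        t = np.arange(0, 1.0001, 1 / 30)
        tr = Trajectory(np.sin(2 * np.pi * t), 0.0, 1 / 30)
        out = resample_uniform(tr, 121, kind="cubic")
        analytic = np.sin(2 * np.pi * out.times)
        cubic_err = np.max(np.abs(out.values - analytic))
        # worst-case linear interpolation error bound: h^2 max|f''| / 8
        linear_err = (1 / 30) ** 2 * (2 * np.pi) ** 2 / 8
        assert cubic_err < linear_err

    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(0)
        tr = Trajectory(rng.normal(size=25), 0.0, 1 / 30)
        out = resample_uniform(tr, 25)
        np.testing.assert_allclose(out.values, tr.values, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            resample_uniform(Trajectory(np.arange(5.0), 0, 1 / 30), 1)


class TestResampleSequence:
    def test_densify_to_120hz(self, noiseless_clip):
        from dmsm.preprocess import resample_sequence

        out = resample_sequence(noiseless_clip.sequence, 120.0)
        assert out.fps == pytest.approx(120.0, rel=0.01)
        assert out.duration == pytest.approx(noiseless_clip.sequence.duration)
        # original samples are interpolation knots: endpoints reproduced
        np.testing.assert_allclose(out.coords[0], noiseless_clip.sequence.coords[0], atol=1e-9)
        np.testing.assert_allclose(out.coords[-1], noiseless_clip.sequence.coords[-1], atol=1e-9)

    def test_downsampling_rejected(self, noiseless_clip):
        from dmsm.preprocess import resample_sequence

        with pytest.raises(ParameterError):
            resample_sequence(noiseless_clip.sequence, 15.0)


class TestCropAndOnset:
    def test_known_onset_window(self):
        # takeaway begins lead_in + address = 4.5 + 0.5 = 5.0 s
        clip = generate_swing(SwingStyle(lead_in_s=4.5, noise_sigma=0.005, seed=1))
        seq = normalize_body_scale(clip.sequence)
        cropped = crop_swing_window(seq, PreprocessConfig())
        assert cropped.times[0] == pytest.approx(3.0, abs=0.15)
        assert cropped.times[-1] == pytest.approx(6.0, abs=0.15)

    def test_motionless_raises(self):
        seq = make_static_sequence(n=90)
        with pytest.raises(NoSwingDetectedError):
            crop_swing_window(seq)

    def test_early_onset_clamped_to_start(self):
        clip = generate_swing(SwingStyle(lead_in_s=0.0, noise_sigma=0.0, seed=1))
        seq = normalize_body_scale(clip.sequence)
        cropped = crop_swing_window(seq, PreprocessConfig())
        assert cropped.times[0] == seq.times[0]

    def test_auto_crop_skips_trimmed_clips(self, default_clip):
        out = preprocess_sequence(default_clip.sequence)
        assert out.n_frames == default_clip.sequence.n_frames


class TestAlignAddress:
    def test_self_alignment_identical(self, default_clip):
        seq = normalize_body_scale(default_clip.sequence)
        a, b = align_address(seq, seq.copy())
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-12)

    def test_translation_invariance(self, default_clip):
        seq = normalize_body_scale(default_clip.sequence)
        shifted = seq.copy()
        shifted.coords = shifted.coords + np.array([3.2, -1.7])
        a, b = align_address(seq, shifted)
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    def test_mid_hips_at_origin(self, default_clip):
        a = normalize_body_scale(default_clip.sequence)
        b = normalize_body_scale(generate_swing(SwingStyle(seed=99)).sequence)
        for out in align_address(a, b):
            address = out.midpoint("left_hip", "right_hip")[: out.n_frames // 10]
            np.testing.assert_allclose(address.mean(axis=0), 0.0, atol=1e-9)


class TestMirrorAndDeterminism:
    def test_double_mirror_is_identity(self, default_clip):
        seq = default_clip.sequence
        back = mirror_sequence(mirror_sequence(seq))
        assert back.joints == seq.joints
        assert back.handedness == seq.handedness
        np.testing.assert_allclose(back.coords, seq.coords, atol=1e-9)

    def test_chain_deterministic(self, default_clip):
        a = preprocess_sequence(default_clip.sequence)
        b = preprocess_sequence(default_clip.sequence)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.times, b.times)
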