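import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmsm.errors import (
    ContractError,
    ParameterError,
    UndefinedSimilarityError,
    ValidationError,
)
from dmsm.io_pose import PoseSequence
from dmsm.phases import detect_phases, phase_slices
from dmsm.preprocess import (
    Trajectory,
    align_address,
    normalize_body_scale,
    preprocess_sequence,
)
from dmsm.similarity import (
    SimilarityConfig,
    compare,
    dissimilarity_to_similarity,
    dmsm_compare,
    dtw_align,
    dtw_cosine_similarity,
    euclidean_similarity,
    joint_angle_trajectories,
    joint_angle_similarity,
    pearson_phase_correlation,
    phase_dissimilarity,
    trajectory_area_dissimilarity,
)
from dmsm.synth import SwingStyle, generate_swing

from conftest import ADDRESS_POSE, make_static_sequence


def tr(values, dt=None):
    values = np.asarray(values, dtype=float)
    return Trajectory(values, 0.0, dt if dt else 1.0 / (len(values) - 1))


grids = st.integers(5, 40)
traj_triples = st.tuples(grids, st.integers(0, 2**31 - 1)).map(
    lambda args: tuple(
        tr(np.random.default_rng(args[1] + k).uniform(-10, 10, args[0]))
        for k in range(3)
    )
)


class TestAreaDissimilarity:
    def test_identical_is_zero(self):
        x = tr(np.sin(np.linspace(0, 3, 50)))
        assert trajectory_area_dissimilarity(x, x) == 0.0

    def test_constant_offset_closed_form(self):
        x = tr(np.full(11, 0.3))
        y = tr(np.full(11, 0.8))
        assert trajectory_area_dissimilarity(x, y) == pytest.approx(0.5, abs=1e-12)

    def test_sine_integral_oracle(self):
        t = np.linspace(0, 1, 10001)
        x = tr(np.sin(2 * np.pi * t))
        y = tr(np.zeros_like(t))
        assert trajectory_area_dissimilarity(x, y) == pytest.approx(2 / np.pi, abs=1e-6)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ContractError):
            trajectory_area_dissimilarity(tr(np.zeros(10)), tr(np.zeros(11)))
        with pytest.raises(ContractError):
            trajectory_area_dissimilarity(
                tr(np.zeros(10)), Trajectory(np.zeros(10), 0.0, 0.5)
            )

    @given(traj_triples)
    def test_l1_metric_properties(self, triple):
        x, y, z = triple
        dxy = trajectory_area_dissimilarity(x, y)
        dyx = trajectory_area_dissimilarity(y, x)
        dxz = trajectory_area_dissimilarity(x, z)
        dzy = trajectory_area_dissimilarity(z, y)
        assert dxy >= 0
        assert dxy == dyx
        assert trajectory_area_dissimilarity(x, x) == 0.0
        assert dxy <= dxz + dzy + 1e-9

    def test_trapezoid_agrees_with_fine_riemann(self):
        from scipy.interpolate import CubicSpline

        rng = np.random.default_rng(3)
        for _ in range(5):
            # spline family mimicking smoothed normalized joint paths: a few
            # undulations per phase, sub-shoulder-width excursions
            knots = np.linspace(0, 1, 6)
            fx = CubicSpline(knots, 0.3 * rng.normal(size=6))
            fy = CubicSpline(knots, 0.3 * rng.normal(size=6))
            tc = np.linspace(0, 1, 100)
            tf = np.linspace(0, 1, 100000)
            coarse = trajectory_area_dissimilarity(
                Trajectory(fx(tc), 0, tc[1]), Trajectory(fy(tc), 0, tc[1])
            )
            riemann = float(np.trapezoid(np.abs(fx(tf) - fy(tf)), tf))
            assert coarse == pytest.approx(riemann, abs=1e-3)


class TestSimilarityMap:
    def test_anchor_points(self):
        assert dissimilarity_to_similarity(0.0, 1.0) == 1.0
        assert dissimilarity_to_similarity(2.5, 2.5) == 0.5

    def test_strictly_decreasing(self):
        vals = [dissimilarity_to_similarity(d, 1.0) for d in np.arange(0, 2.01, 0.1)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ContractError):
            dissimilarity_to_similarity(-0.1, 1.0)


@pytest.fixture(scope="module")
def slices(default_clip):
    seq = preprocess_sequence(default_clip.sequence)
    seq, _ = align_address(seq, seq)
    return phase_slices(seq, detect_phases(seq))


class TestPhaseDissimilarity:
    def test_self_is_zero(self, slices):
        score = phase_dissimilarity(slices[4], slices[4])
        assert all(v == 0 for v in score.per_joint_DS.values())
        assert score.similarity == 1.0

    def test_uniform_weights_match_mean(self, slices):
        score = phase_dissimilarity(slices[1], slices[4])
        assert score.weighted_DS == pytest.approx(
            np.mean(list(score.per_joint_DS.values()))
        )

    def test_constant_wrist_shift_closed_form(self, slices):
        import dataclasses

        sl = slices[2]
        k = sl.joints.index("left_wrist")
        shifted_coords = sl.coords.copy()
        shifted_coords[:, k, 0] += 0.2
        shifted = dataclasses.replace(sl, coords=shifted_coords)
        score = phase_dissimilarity(sl, shifted)
        assert score.per_joint_DS["left_wrist"] == pytest.approx(0.1, abs=1e-9)
        others = [v for j, v in score.per_joint_DS.items() if j != "left_wrist"]
        assert np.allclose(others, 0.0, atol=1e-12)


class TestDmsmCompare:
    def test_self_similarity_one(self, default_clip):
        rep = dmsm_compare(default_clip.sequence, default_clip.sequence.copy())
        assert rep.overall_similarity == pytest.approx(1.0, abs=1e-12)
        assert rep.overall_DS == pytest.approx(0.0, abs=1e-12)
        assert len(rep.phase_scores) == 7

    def test_same_style_closer_than_cross_style(self):
        a1 = generate_swing(SwingStyle(seed=1)).sequence
        a2 = generate_swing(SwingStyle(seed=2)).sequence
        b = generate_swing(
            SwingStyle(arc_radius=1.5, top_height=2.0, plane_offset=0.08, seed=3)
        ).sequence
        same = dmsm_compare(a1, a2).overall_DS
        cross = dmsm_compare(a1, b).overall_DS
        assert same < cross

    def test_disjoint_joint_sets_rejected(self, default_clip):
        cfg = SimilarityConfig(joints=("left_wrist", "left_pinky"))
        with pytest.raises(ValidationError):
            dmsm_compare(default_clip.sequence, default_clip.sequence.copy(), cfg)

    def test_scale_and_translation_invariance(self, default_clip):
        seq = default_clip.sequence
        other = generate_swing(SwingStyle(seed=23)).sequence
        base = dmsm_compare(seq, other)
        moved = other.copy()
        moved.coords = moved.coords * 2.0 + np.array([100.0, -40.0])
        rep = dmsm_compare(seq, moved)
        assert rep.overall_DS == pytest.approx(base.overall_DS, abs=1e-6)


class TestDtw:
    def test_identical_sequences_diagonal(self):
        a = np.arange(5.0)
        path, cost = dtw_align(a, a)
        assert cost == 0.0
        assert path == [(i, i) for i in range(5)]

    def test_textbook_example(self):
        path, cost = dtw_align(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0]))
        assert cost == 0.0
        assert path == [(0, 0), (1, 0), (2, 1)]

    def test_single_element_forced_path(self):
        b = np.array([1.0, 2.0, 4.0])
        path, cost = dtw_align(np.array([0.0]), b)
        assert cost == pytest.approx(np.sum(np.abs(b)))
        assert path == [(0, 0), (0, 1), (0, 2)]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            dtw_align(np.array([]), np.array([1.0]))

    @staticmethod
    def brute_force_cost(a, b):
        """Minimum cost over exhaustively enumerated monotone paths."""
        n, m = len(a), len(b)
        local = np.abs(a[:, None] - b[None, :])
        best = {}

        def rec(i, j):
            if (i, j) in best:
                return best[(i, j)]
            if i == 0 and j == 0:
                val = local[0, 0]
            else:
                prev = []
                if i > 0:
                    prev.append(rec(i - 1, j))
                if j > 0:
                    prev.append(rec(i, j - 1))
                if i > 0 and j > 0:
                    prev.append(rec(i - 1, j - 1))
                val = local[i, j] + min(prev)
            best[(i, j)] = val
            return val

        return rec(n - 1, m - 1)

    def test_dp_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n, m = rng.integers(1, 7, size=2)
            a = rng.integers(0, 10, n).astype(float)
            b = rng.integers(0, 10, m).astype(float)
            _, cost = dtw_align(a, b)
            assert cost == pytest.approx(self.brute_force_cost(a, b), abs=1e-9)


class TestDtwCosine:
    def _single_joint_motion(self, reverse=False):
        n = 20
        joints = tuple(ADDRESS_POSE)
        coords = np.zeros((n, len(joints), 2))
        for k, j in enumerate(joints):
            coords[:, k] = ADDRESS_POSE[j]
        k = joints.index("left_wrist")
        ramp = np.linspace(0.0, 1.0, n)
        coords[:, k, 0] = ramp[::-1] if reverse else ramp
        return PoseSequence(
            np.arange(n) / 30.0, coords * 100 + 300, joints, fps=30.0, clip_id="m"
        )

    def test_self_is_one(self, default_clip):
        s = dtw_cosine_similarity(default_clip.sequence, default_clip.sequence.copy())
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_reversed_monotone_motion_is_minus_one(self):
        cfg = SimilarityConfig(joints=("left_wrist",))
        s = dtw_cosine_similarity(
            self._single_joint_motion(), self._single_joint_motion(reverse=True), cfg
        )
        assert s == pytest.approx(-1.0, abs=1e-9)

    def test_static_clip_undefined(self):
        seq = make_static_sequence(units="pixels", scale=100.0)
        with pytest.raises(UndefinedSimilarityError):
            dtw_cosine_similarity(seq, seq.copy())

    def test_bit_exact_reproducibility(self):
        a = generate_swing(SwingStyle(seed=4)).sequence
        b = generate_swing(SwingStyle(seed=5, arc_radius=1.7, top_height=2.2)).sequence
        assert dtw_cosine_similarity(a, b) == dtw_cosine_similarity(a.copy(), b.copy())


class TestEuclidean:
    def test_self_is_one(self, default_clip):
        s = euclidean_similarity(default_clip.sequence, default_clip.sequence.copy())
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_global_offset_closed_form(self, noiseless_clip):
        # noiseless so the measured shoulder width is exactly the pixel scale
        seq = noiseless_clip.sequence
        moved = seq.copy()
        moved.coords = moved.coords + np.array([30.0, 0.0])  # 0.3 shoulder widths
        s = euclidean_similarity(seq, moved, align=False)
        assert 1.0 / s - 1.0 == pytest.approx(0.3, abs=1e-6)

    def test_symmetry(self, default_clip):
        a = default_clip.sequence
        b = generate_swing(SwingStyle(seed=77)).sequence
        assert euclidean_similarity(a, b) == pytest.approx(
            euclidean_similarity(b, a), abs=1e-12
        )


class TestPearson:
    def test_self_is_one(self, slices):
        assert pearson_phase_correlation(slices[4], slices[4]) == pytest.approx(1.0)

    def test_negated_copy_is_minus_one(self, slices):
        import dataclasses

        sl = slices[4]
        mean = sl.coords.mean(axis=0, keepdims=True)
        negated = dataclasses.replace(sl, coords=2 * mean - sl.coords)
        assert pearson_phase_correlation(sl, negated) == pytest.approx(-1.0)

    def test_all_constant_undefined(self):
        seq = make_static_sequence()
        from dmsm.phases import PhaseSegmentation

        sl = phase_slices(seq, PhaseSegmentation((0, 4, 8, 12, 16, 20, 24, 30)))
        with pytest.warns(UserWarning):
            with pytest.raises(UndefinedSimilarityError):
                pearson_phase_correlation(sl[0], sl[1])


class TestJointAngles:
    def _arm_pose(self, elbow_angle_deg):
        # left arm: shoulder at origin-ish, elbow below, wrist placed to give
        # the requested interior angle at the elbow
        pose = dict(ADDRESS_POSE)
        pose["left_elbow"] = (-0.5, -0.9)
        ang = np.deg2rad(180.0 - elbow_angle_deg)
        pose["left_wrist"] = (-0.5 + 0.5 * np.sin(ang), -0.9 + 0.5 * np.cos(ang))
        pose["right_elbow"] = (0.5, -0.9)
        pose["right_wrist"] = (0.5, -0.4)
        return pose

    def test_interior_angle_values(self):
        straight = make_static_sequence(pose=self._arm_pose(180.0))
        bent = make_static_sequence(pose=self._arm_pose(90.0))
        a = joint_angle_trajectories(straight)["left_elbow"]
        b = joint_angle_trajectories(bent)["left_elbow"]
        np.testing.assert_allclose(a, np.pi, atol=1e-9)
        np.testing.assert_allclose(b, np.pi / 2, atol=1e-9)

    def test_self_is_one(self, default_clip):
        s = joint_angle_similarity(default_clip.sequence, default_clip.sequence.copy())
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_similarity_invariant_to_scale_and_translation(self, default_clip):
        a = default_clip.sequence
        b = generate_swing(SwingStyle(seed=8)).sequence
        base = joint_angle_similarity(a, b)
        moved = b.copy()
        moved.coords = moved.coords * 3.0 + np.array([11.0, 7.0])
        assert joint_angle_similarity(a, moved) == pytest.approx(base, abs=1e-9)


class TestDispatch:
    @pytest.mark.parametrize("method", ["dmsm", "dtw_cosine", "euclidean", "pearson", "joint_angle"])
    def test_all_methods_run_and_self_similarity_is_max(self, method, default_clip):
        a = default_clip.sequence
        sim_self, ds_self, _ = compare(a, a.copy(), method)
        b = generate_swing(SwingStyle(seed=31, arc_radius=1.6, top_height=2.1)).sequence
        sim_other, ds_other, _ = compare(a, b, method)
        assert sim_self == pytest.approx(1.0, abs=1e-9)
        assert ds_self <= ds_other

    def test_unknown_method_rejected(self, default_clip):
        with pytest.raises(ParameterError):
            compare(default_clip.sequence, default_clip.sequence.copy(), "hausdorff")


class TestPerturbationMonotonicity:
    def test_ds_strictly_increasing_in_wrist_perturbation(self, default_clip):
        seq = default_clip.sequence
        bump = np.sin(2 * np.pi * seq.times / seq.times[-1])
        prev = -np.inf
        for amp in (0.0, 0.1, 0.2, 0.3, 0.5):
            pert = seq.copy()
            for j in ("left_wrist", "right_wrist"):
                k = pert.joint_index(j)
                pert.coords[:, k, 0] += amp * 100.0 * bump  # 100 px per body unit
            ds = dmsm_compare(seq, pert).overall_DS
            assert ds > prev
            prev = ds
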