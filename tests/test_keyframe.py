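"""Posture descriptor Θ and keyframe selection."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fms_aqa as f
from fms_aqa.skeleton import KEYPOINT_INDEX, RIGHT_HIP

from .conftest import brute_force_keyframe, oracle_theta, random_sequence, random_skeleton


def _skeleton_from_coords(coords) -> f.Skeleton:
    return f.Skeleton(
        np.asarray(coords, float), np.ones(17), meta={"frame": "normalized"}
    )


class TestPostureTheta:
    def test_fully_collinear_gives_sixteen(self):
        # every keypoint on the ray through the right hip → each cosine is 1
        coords = np.outer(np.arange(1, 18, dtype=float), [1.0, 1.0])
        theta = f.posture_theta(_skeleton_from_coords(coords))
        assert theta.theta == pytest.approx(16.0, abs=1e-12)
        assert theta.n_terms == 16

    def test_one_orthogonal_term_contributes_zero(self):
        coords = np.outer(np.arange(1, 18, dtype=float), [1.0, 1.0])
        coords[KEYPOINT_INDEX["nose"]] = [1.0, -1.0]  # ⟂ to the hip ray
        theta = f.posture_theta(_skeleton_from_coords(coords))
        assert theta.theta == pytest.approx(15.0, abs=1e-12)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(0.0, 1.0, size=(17, 2)) + 0.05
        s = _skeleton_from_coords(coords)
        assert f.posture_theta(s).theta == pytest.approx(
            oracle_theta(s), abs=1e-12
        )

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, max_examples=40)
    def test_scale_invariant(self, c):
        rng = np.random.default_rng(5)
        s = random_skeleton(rng)
        scaled = replace(s, coords=s.coords * c)
        assert f.posture_theta(scaled).theta == pytest.approx(
            f.posture_theta(s).theta, abs=1e-9
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=60)
    def test_bounded_by_sixteen(self, seed):
        s = random_skeleton(np.random.default_rng(seed))
        assert abs(f.posture_theta(s).theta) <= 16.0

    def test_zero_norm_reference_raises(self):
        coords = np.ones((17, 2))
        coords[RIGHT_HIP] = [0.0, 0.0]
        with pytest.raises(f.GeometryError):
            f.posture_theta(_skeleton_from_coords(coords))


class TestKeyframeDistance:
    def test_identity_and_absolute_difference(self):
        d10 = f.PostureDescriptor(10.0)
        d12 = f.PostureDescriptor(12.0)
        assert f.keyframe_distance(d10, d10) == 0.0
        assert f.keyframe_distance(d10, d12) == 2.0
        assert f.keyframe_distance(d12, d10) == 2.0

    def test_mismatched_term_counts_rejected(self):
        with pytest.raises(f.ContractError, match="term counts"):
            f.keyframe_distance(
                f.PostureDescriptor(1.0, n_terms=16),
                f.PostureDescriptor(1.0, n_terms=17),
            )


class TestExtractKeyframe:
    def test_planted_exact_copy(self):
        rng = np.random.default_rng(0)
        std_skel = random_skeleton(rng)
        frames = [random_skeleton(rng, i) for i in range(12)]
        frames[7] = replace(std_skel, frame_index=7)
        seq = f.SkeletonSequence(tuple(frames), movement_id="m01")
        std = f.StandardKeyframe("m01", std_skel)
        result = f.extract_keyframe(seq, std)
        assert result.index == 7
        assert result.distance == pytest.approx(0.0, abs=1e-12)
        assert len(result.theta_trace) == 12

    def test_singleton_sequence(self):
        rng = np.random.default_rng(1)
        seq = random_sequence(rng, 1)
        std = f.StandardKeyframe("m01", random_skeleton(rng))
        assert f.extract_keyframe(seq, std).index == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 200)
        std = f.StandardKeyframe("m01", random_skeleton(rng))
        result = f.extract_keyframe(seq, std)
        assert result.index == brute_force_keyframe(seq, std)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_brute_force_equivalence_property(self, seed, n):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, n)
        std = f.StandardKeyframe("m01", random_skeleton(rng))
        assert f.extract_keyframe(seq, std).index == brute_force_keyframe(seq, std)

    def test_theta_trace_equals_scalar_calls(self):
        rng = np.random.default_rng(9)
        seq = random_sequence(rng, 25)
        std = f.StandardKeyframe("m01", random_skeleton(rng))
        trace = f.extract_keyframe(seq, std).theta_trace
        for frame, t in zip(seq.frames, trace):
            assert t == f.posture_theta(frame).theta

    def test_appending_worse_frames_preserves_selection(self):
        rng = np.random.default_rng(21)
        seq = random_sequence(rng, 30)
        std = f.StandardKeyframe("m01", random_skeleton(rng))
        base = f.extract_keyframe(seq, std)
        theta_n = std.theta_n.theta
        # append frames engineered to sit farther from Θ_N than the minimum
        far = []
        for i in range(5):
            s = random_skeleton(rng, 30 + i)
            while abs(f.posture_theta(s).theta - theta_n) <= base.distance:
                s = random_skeleton(rng, 30 + i)
            far.append(s)
        longer = f.SkeletonSequence(seq.frames + tuple(far), movement_id="m01")
        assert f.extract_keyframe(longer, std).index == base.index

    def test_self_term_inclusion_immaterial(self):
        # Including the constant self term (cos ≡ 1) in both Θ_K and Θ_N
        # shifts every descriptor by 1 and leaves all distances unchanged.
        rng = np.random.default_rng(33)
        seq = random_sequence(rng, 40)
        std_skel = random_skeleton(rng)
        t_n16 = f.posture_theta(std_skel)
        t_n17 = f.posture_theta(std_skel, include_self_term=True)
        d16, d17 = [], []
        for frame in seq.frames:
            d16.append(f.keyframe_distance(f.posture_theta(frame), t_n16))
            d17.append(f.keyframe_distance(
                f.posture_theta(frame, include_self_term=True), t_n17
            ))
        np.testing.assert_allclose(d16, d17, atol=1e-12)
        assert int(np.argmin(d16)) == int(np.argmin(d17))

    def test_movement_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        seq = random_sequence(rng, 5, movement_id="m02")
        std = f.StandardKeyframe("m01", random_skeleton(rng))
        with pytest.raises(f.ContractError, match="movement mismatch"):
            f.extract_keyframe(seq, std)

    def test_degenerate_frames_skipped_then_error(self):
        # a frame whose right hip sits at the origin has no descriptor
        bad_coords = np.ones((17, 2))
        bad_coords[RIGHT_HIP] = [0.0, 0.0]
        bad = f.Skeleton(bad_coords, np.ones(17), frame_index=0,
                         meta={"frame": "normalized"})
        rng = np.random.default_rng(6)
        good = random_skeleton(rng, 1)
        seq = f.SkeletonSequence((bad, good), movement_id="m01")
        std = f.StandardKeyframe("m01", random_skeleton(rng))
        result = f.extract_keyframe(seq, std)
        assert result.index == 1
        assert math.isnan(result.theta_trace[0])
        only_bad = f.SkeletonSequence((bad,), movement_id="m01")
        with pytest.raises(f.ExtractionError):
            f.extract_keyframe(only_bad, std)

    def test_selection_gates_prefilter_and_fallback(self):
        rng = np.random.default_rng(8)
        spec_rb = f.default_rulebase().spec("m01")
        seq = f.make_sequence(spec_rb.standard, n_frames=20, seed=3)
        # gate admitting only implausible trunk-shank angles excludes all
        # frames → fall back to the ungated argmin
        tight = f.StandardKeyframe(
            "m01",
            spec_rb.standard.skeleton,
            (f.SelectionGate(
                kind="angle",
                keypoints=("left_shoulder", "left_hip", "left_knee", "left_ankle"),
                min_value=170.0, max_value=180.0,
            ),),
        )
        ungated = f.extract_keyframe(seq, spec_rb.standard)
        assert f.extract_keyframe(seq, tight).index == ungated.index
        # a permissive gate changes nothing
        loose = f.StandardKeyframe(
            "m01",
            spec_rb.standard.skeleton,
            (f.SelectionGate(
                kind="distance",
                keypoints=("nose", "left_ankle"),
                min_value=0.0, max_value=100.0,
            ),),
        )
        assert f.extract_keyframe(seq, loose).index == ungated.index
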