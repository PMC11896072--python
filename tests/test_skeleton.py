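"""Geometric primitives: normalization, angles, orderings, distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fms_aqa as f
from fms_aqa.skeleton import KEYPOINT_INDEX

from .conftest import random_skeleton


def _image_skeleton(shoulder_y=50.0, hip_y=150.0, height_sep=20.0):
    """Image-frame (y-down) skeleton with mid-shoulder (100, shoulder_y)
    and mid-hip (100, hip_y)."""
    coords = np.tile([200.0, 250.0], (17, 1))
    coords[KEYPOINT_INDEX["left_shoulder"]] = [90.0, shoulder_y]
    coords[KEYPOINT_INDEX["right_shoulder"]] = [110.0, shoulder_y]
    coords[KEYPOINT_INDEX["left_hip"]] = [90.0, hip_y]
    coords[KEYPOINT_INDEX["right_hip"]] = [110.0, hip_y]
    coords[KEYPOINT_INDEX["left_knee"]] = [95.0, hip_y + height_sep]
    coords[KEYPOINT_INDEX["right_knee"]] = [115.0, hip_y + height_sep]
    return f.Skeleton(coords, np.ones(17), meta={"frame": "image"})


class TestNormalize:
    def test_torso_scale_and_y_flip(self):
        raw = _image_skeleton()
        norm = f.normalize_skeleton(raw, image_height=480.0)
        assert norm.torso_length() == pytest.approx(1.0, abs=1e-9)
        # shoulder pixel y=50 in a 480px image → (480−50)/100 = 4.3 torso units
        assert norm.point("left_shoulder")[1] == pytest.approx(4.3, abs=1e-12)
        assert norm.point("left_shoulder")[0] == pytest.approx(0.9, abs=1e-12)
        # y-up: the knee (lower in the image) now has the smaller y
        assert norm.point("left_knee")[1] < norm.point("left_hip")[1]
        assert norm.is_normalized()

    def test_idempotent(self):
        norm = f.normalize_skeleton(_image_skeleton(), image_height=480.0)
        again = f.normalize_skeleton(norm, image_height=480.0)
        np.testing.assert_allclose(again.coords, norm.coords, atol=1e-12)

    def test_translation_leaves_angles_unchanged(self):
        rng = np.random.default_rng(7)
        quad = ("left_shoulder", "left_hip", "left_knee", "left_ankle")
        for _ in range(100):
            coords = rng.uniform(10.0, 300.0, size=(17, 2))
            raw = f.Skeleton(coords, np.ones(17), meta={"frame": "image"})
            shift = rng.uniform(-50.0, 50.0, size=2)
            moved = f.Skeleton(coords + shift, np.ones(17), meta={"frame": "image"})
            a0 = f.joint_angle(f.normalize_skeleton(raw, 480.0), *quad)
            a1 = f.joint_angle(f.normalize_skeleton(moved, 480.0), *quad)
            assert a1 == pytest.approx(a0, abs=1e-9)

    def test_degenerate_torso_raises(self):
        coords = np.tile([100.0, 100.0], (17, 1))
        raw = f.Skeleton(coords, np.ones(17), meta={"frame": "image"})
        with pytest.raises(f.GeometryError, match="torso"):
            f.normalize_skeleton(raw, 480.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(derandomize=True, max_examples=30)
    def test_scaling_raw_coordinates_is_immaterial(self, c):
        raw = _image_skeleton()
        scaled = f.Skeleton(raw.coords * c, np.ones(17), meta={"frame": "image"})
        quad = ("left_shoulder", "left_hip", "left_knee", "left_ankle")
        a0 = f.joint_angle(f.normalize_skeleton(raw, 480.0), *quad)
        a1 = f.joint_angle(f.normalize_skeleton(scaled, 480.0 * c), *quad)
        assert a1 == pytest.approx(a0, abs=1e-9)
        o0 = f.relative_position(
            f.normalize_skeleton(raw, 480.0), "left_hip", "left_knee", "y"
        )
        o1 = f.relative_position(
            f.normalize_skeleton(scaled, 480.0 * c), "left_hip", "left_knee", "y"
        )
        assert o0 == o1


def _skeleton_with(points: dict) -> f.Skeleton:
    coords = np.tile([5.0, 5.0], (17, 1))
    for name, xy in points.items():
        coords[KEYPOINT_INDEX[name]] = xy
    return f.Skeleton(coords, np.ones(17), meta={"frame": "normalized"})


class TestJointAngle:
    def test_parallel_trunk_and_shank_is_zero(self):
        # shoulder→hip vector (0,-1), knee→ankle vector (0,-1): trunk
        # parallel to the shins
        s = _skeleton_with({
            "left_shoulder": [1.0, 2.0], "left_hip": [1.0, 1.0],
            "left_knee": [1.5, 1.0], "left_ankle": [1.5, 0.0],
        })
        angle = f.joint_angle(s, "left_shoulder", "left_hip", "left_knee", "left_ankle")
        assert angle == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        s = _skeleton_with({
            "left_shoulder": [0.0, 0.1], "left_hip": [0.0, 1.1],
            "left_knee": [1.0, 1.0], "left_ankle": [2.0, 1.0],
        })
        assert f.joint_angle(
            s, "left_shoulder", "left_hip", "left_knee", "left_ankle"
        ) == pytest.approx(90.0, abs=1e-12)

    def test_matches_atan2_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            u, v = rng.uniform(-3.0, 3.0, size=(2, 2))
            if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
                continue
            s = _skeleton_with({
                "left_shoulder": [1.0, 1.0], "left_hip": 1.0 + u,
                "left_knee": [1.0, 1.0], "left_ankle": 1.0 + v,
            })
            got = f.joint_angle(
                s, "left_shoulder", "left_hip", "left_knee", "left_ankle"
            )
            # oracle: difference of atan2 directions, folded to [0, 180]
            diff = math.atan2(u[1], u[0]) - math.atan2(v[1], v[0])
            expected = math.degrees(abs((diff + math.pi) % (2 * math.pi) - math.pi))
            assert got == pytest.approx(expected, abs=1e-9)
            assert 0.0 <= got <= 180.0

    def test_symmetric_under_vector_swap(self):
        rng = np.random.default_rng(2)
        s = random_skeleton(rng)
        a = f.joint_angle(s, "nose", "left_wrist", "right_knee", "left_ankle")
        b = f.joint_angle(s, "right_knee", "left_ankle", "nose", "left_wrist")
        assert a == b  # bitwise: same symmetric expression

    def test_zero_length_vector_names_pair(self):
        s = _skeleton_with({"left_shoulder": [1.0, 1.0], "left_hip": [1.0, 1.0]})
        with pytest.raises(f.GeometryError, match="left_shoulder.*left_hip"):
            f.joint_angle(s, "left_shoulder", "left_hip", "left_knee", "left_ankle")

    def test_low_confidence_keypoint_raises(self):
        s = _skeleton_with({})
        conf = np.ones(17)
        conf[KEYPOINT_INDEX["left_hip"]] = 0.1
        s = f.Skeleton(s.coords, conf, meta={"frame": "normalized"})
        with pytest.raises(f.InsufficientPoseError) as err:
            f.joint_angle(s, "left_shoulder", "left_hip", "left_knee", "left_ankle")
        assert err.value.keypoint == "left_hip"


class TestRelativePosition:
    def test_hip_below_knee(self):
        s = _skeleton_with({"left_hip": [1.0, 0.40], "left_knee": [1.0, 0.55]})
        assert (
            f.relative_position(s, "left_hip", "left_knee", "y")
            is f.PositionOrdering.BELOW
        )

    def test_exact_tie_is_level(self):
        s = _skeleton_with({"left_hip": [1.0, 0.5], "left_knee": [2.0, 0.5]})
        assert (
            f.relative_position(s, "left_hip", "left_knee", "y")
            is f.PositionOrdering.LEVEL
        )

    def test_wrist_right_of_knee(self):
        s = _skeleton_with({"left_wrist": [0.9, 1.0], "left_knee": [0.6, 0.5]})
        assert (
            f.relative_position(s, "left_wrist", "left_knee", "x")
            is f.PositionOrdering.RIGHT_OF
        )

    @given(
        st.floats(-1.0, 1.0), st.floats(-1.0, 1.0),
        st.sampled_from(["x", "y"]),
    )
    @settings(derandomize=True, max_examples=60)
    def test_mirror_property(self, vi, vj, axis):
        s = _skeleton_with({"left_hip": [vi, vi], "left_knee": [vj, vj]})
        fwd = f.relative_position(s, "left_hip", "left_knee", axis)
        rev = f.relative_position(s, "left_knee", "left_hip", axis)
        assert rev == fwd.mirrored()


class TestJointDistance:
    def test_coincident_is_zero(self):
        s = _skeleton_with({"left_hip": [1.0, 1.0], "left_knee": [1.0, 1.0]})
        assert f.joint_distance(s, "left_hip", "left_knee") == 0.0

    def test_three_four_five(self):
        s = _skeleton_with({"left_hip": [0.0, 0.1], "left_knee": [3.0, 4.1]})
        assert f.joint_distance(s, "left_hip", "left_knee") == pytest.approx(5.0)

    def test_scales_inversely_with_torso(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            coords = rng.uniform(10.0, 300.0, size=(17, 2))
            raw = f.Skeleton(coords, np.ones(17), meta={"frame": "image"})
            torso = raw.torso_length()
            d_raw = float(np.linalg.norm(
                coords[KEYPOINT_INDEX["nose"]] - coords[KEYPOINT_INDEX["left_ankle"]]
            ))
            norm = f.normalize_skeleton(raw, 480.0)
            assert f.joint_distance(norm, "nose", "left_ankle") == pytest.approx(
                d_raw / torso, rel=1e-9
            )
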