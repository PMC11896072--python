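from importlib import resources
from pathlib import Path

import numpy as np
import pytest

import fms_aqa as f

DATA_DIR = Path(__file__).parent / "data"

#: Path of the shipped deep-squat rule file (the published criteria).
DEEP_SQUAT_RULES = resources.files("fms_aqa.data") / "deep_squat.yaml"


def random_skeleton(rng: np.random.Generator, frame_index: int = 0) -> f.Skeleton:
    """A random but geometrically safe skeleton: positive coordinates keep
    every descriptor-frame position vector well away from zero norm."""
    coords = rng.uniform(0.1, 2.0, size=(17, 2))
    return f.Skeleton(
        coords, np.ones(17), frame_index=frame_index, meta={"frame": "normalized"}
    )


def random_sequence(
    rng: np.random.Generator, n_frames: int, movement_id: str = "m01"
) -> f.SkeletonSequence:
    return f.SkeletonSequence(
        frames=tuple(random_skeleton(rng, i) for i in range(n_frames)),
        movement_id=movement_id,
        subject_id="rand",
    )


def oracle_theta(s: f.Skeleton) -> float:
    """Independent posture-descriptor oracle: per-term polar angles via
    atan2 in extended precision, instead of the vectorized dot-product path."""
    import math

    coords = np.asarray(s.coords, dtype=np.longdouble)
    hx, hy = coords[f.COCO_KEYPOINTS.index("right_hip")]
    phi_hip = math.atan2(float(hy), float(hx))
    total = np.longdouble(0.0)
    for i, (x, y) in enumerate(coords):
        if f.COCO_KEYPOINTS[i] == "right_hip":
            continue
        total += np.cos(np.longdouble(math.atan2(float(y), float(x)) - phi_hip))
    return float(total)


def brute_force_keyframe(seq: f.SkeletonSequence, std: f.StandardKeyframe) -> int:
    """Independent argmin scan: explicit loop, first-minimum tie-break."""
    theta_n = f.posture_theta(std.skeleton).theta
    best, best_d = None, None
    for pos, frame in enumerate(seq.frames):
        d = abs(f.posture_theta(frame).theta - theta_n)
        if best_d is None or d < best_d:
            best, best_d = pos, d
    assert best is not None
    return best


@pytest.fixture(scope="session")
def rulebase() -> f.RuleBase:
    return f.default_rulebase()


@pytest.fixture(scope="session")
def m01(rulebase) -> f.MovementSpec:
    return rulebase.spec("m01")


@pytest.fixture(scope="session")
def deep_squat_rules() -> f.RuleBase:
    return f.load_rulebase(str(DEEP_SQUAT_RULES))
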