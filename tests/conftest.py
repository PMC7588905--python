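import pytest

from posedelta import (
    ActivitySegment,
    COCO_PARTS,
    Keypoint,
    PoseFrame,
    SimConfig,
    simulate,
)
from posedelta.simulator import skeleton_template


def frame_at(
    timestamp: int,
    x0: float = 160.0,
    y0: float = 200.0,
    activity: str = "stand",
    score: float = 0.9,
    persons: int = 1,
    kp_score: float = 0.9,
) -> PoseFrame:
    """A full 17-keypoint frame with the figure anchored at (x0, y0)."""
    tpl = skeleton_template(activity)
    kps = tuple(
        Keypoint(part=p, x=x0 + tpl[p][0], y=y0 + tpl[p][1], score=kp_score)
        for p in COCO_PARTS
    )
    return PoseFrame(timestamp=timestamp, score=score, persons=persons, keypoints=kps)


def empty_frame(timestamp: int) -> PoseFrame:
    return PoseFrame(timestamp=timestamp, score=0.0, persons=0, keypoints=())


@pytest.fixture(scope="session")
def two_day_sim():
    """3600 present seconds on day one, 1800 on day two (rest absent)."""
    cfg = SimConfig(
        schedule=(
            ActivitySegment(start=0, end=3600, activity="stand"),
            ActivitySegment(start=86400, end=88200, activity="stand"),
        ),
        noise_sd=2.0,
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def demo_sim_noisy():
    """The 2 h mixed-activity benchmark schedule at 2 px coordinate noise."""
    from posedelta import demo_schedule

    cfg = SimConfig(schedule=demo_schedule(), noise_sd=2.0, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def demo_sim_clean():
    """The same 2 h schedule without coordinate noise."""
    from posedelta import demo_schedule

    cfg = SimConfig(schedule=demo_schedule(), noise_sd=0.0, seed=7)
    return simulate(cfg)
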