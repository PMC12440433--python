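import numpy as np
import pytest

from romkin import (
    JointName,
    Landmark,
    LandmarkFrame,
    LandmarkSequence,
    MotionTask,
    Side,
    SyntheticMotionConfig,
    generate,
)


@pytest.fixture
def simple_frame() -> LandmarkFrame:
    """Right arm raised at a right angle to a vertical trunk."""
    return LandmarkFrame(
        frame_index=0,
        timestamp=0.0,
        joints={
            JointName.RIGHT_SHOULDER: Landmark(100.0, 100.0, 0.9),
            JointName.RIGHT_ELBOW: Landmark(180.0, 100.0, 0.8),
            JointName.RIGHT_WRIST: Landmark(250.0, 100.0, 0.7),
            JointName.RIGHT_HIP: Landmark(100.0, 220.0, 0.95),
        },
    )


@pytest.fixture
def noisy_sequence() -> LandmarkSequence:
    """61-frame jittered shoulder-abduction clip, fixed seed."""
    seq, _ = generate(
        SyntheticMotionConfig(peak_angle=120.0, n_frames=61, jitter_sd=2.0, seed=7)
    )
    return seq


@pytest.fixture
def clean_sequence_and_truth():
    seq, truth = generate(SyntheticMotionConfig(peak_angle=90.0, n_frames=61))
    return seq, truth


def make_sequence(frames: list[LandmarkFrame], fps: float = 30.0) -> LandmarkSequence:
    return LandmarkSequence(frames=frames, fps=fps, width=480, height=480, source_id="test")
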