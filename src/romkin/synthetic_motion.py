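"""Ground-truthed generator of planar two-segment arm motion.

Emulates a subject performing one motion task in a plane parallel to the
camera — the planarity every measurement in this package assumes — with
the camera at roughly shoulder height a few feet away, so segment lengths
land at plausible pixel scales (upper arm ~80 px on a 480×480 canvas).

The arm is a rigid two-segment chain.  For shoulder tasks the whole arm
(elbow kept straight) rotates about a fixed shoulder from the trunk line
out to ``peak_angle`` and back; for elbow flexion the shoulder and elbow
stay fixed (the study instruction: minimise elbow displacement) and only
the forearm rotates, so flexion runs 0 → peak → 0.  Noise-free landmarks
are then degraded by i.i.d. Gaussian jitter, per-frame dropout and a
configurable confidence model, all reproducible from one seed.

Real videos differ from this model in ways the generator deliberately
does not emulate: out-of-plane motion (the known elbow-flexion failure
mode), soft-tissue and clothing artefacts, and pose-network error
structure that is correlated across frames rather than i.i.d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .core import (
    JointName,
    Landmark,
    LandmarkFrame,
    LandmarkSequence,
    MotionTask,
    Side,
)
from .errors import ConfigError
from .pose_backends import MarkerPalette, default_palette

__all__ = ["SyntheticMotionConfig", "SyntheticTruth", "generate", "render"]


@dataclass(frozen=True)
class SyntheticMotionConfig:
    """Generative parameters for one simulated motion-task clip.

    ``peak_angle`` (degrees) is attained exactly at the trajectory apex
    frame.  ``jitter_sd`` is the per-coordinate Gaussian noise in pixels;
    ``dropout_prob`` drops a whole frame's arm landmarks (simulating a
    per-frame detection failure); per-joint dropout is available via
    ``dropout_per_joint``.
    """

    task: MotionTask = MotionTask.SHOULDER_ABDUCTION
    side: Side = Side.RIGHT
    peak_angle: float = 90.0
    n_frames: int = 61
    fps: float = 30.0
    trajectory: str = "raised-cosine"  # raised-cosine | linear-ramp
    upper_arm_len: float = 80.0
    forearm_len: float = 70.0
    trunk_len: float = 120.0
    shoulder_pos: tuple[float, float] = (240.0, 160.0)
    canvas: tuple[int, int] = (480, 480)  # (width, height)
    jitter_sd: float = 0.0
    dropout_prob: float = 0.0
    dropout_per_joint: bool = False
    confidence_model: str = "constant"  # constant | distance-decay
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_angle <= 180.0):
            raise ConfigError(f"peak_angle must lie in (0, 180], got {self.peak_angle}")
        if self.n_frames < 2:
            raise ConfigError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.fps <= 0:
            raise ConfigError(f"fps must be > 0, got {self.fps}")
        for name in ("upper_arm_len", "forearm_len", "trunk_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.jitter_sd < 0:
            raise ConfigError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ConfigError(f"dropout_prob must lie in [0, 1], got {self.dropout_prob}")
        if self.trajectory not in ("raised-cosine", "linear-ramp"):
            raise ConfigError(f"unknown trajectory {self.trajectory!r}")
        if self.confidence_model not in ("constant", "distance-decay"):
            raise ConfigError(f"unknown confidence model {self.confidence_model!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated sequence."""

    config: SyntheticMotionConfig
    true_angle_series: tuple[float, ...]
    true_max: float
    apex_frame: int


def _trajectory(config: SyntheticMotionConfig) -> tuple[np.ndarray, int]:
    """Per-frame task angle in degrees, 0 → peak → 0, and the apex frame.

    raised-cosine: two half-cosine arcs meeting at the apex — smooth, and
    the peak is hit exactly at an integer frame for any n_frames.
    linear-ramp: a trapezoid whose plateau sits at the peak (useful for
    exercising argmax tie-breaking); the apex frame is the first plateau
    frame.
    """
    n = config.n_frames
    last = n - 1
    apex = last // 2
    t = np.arange(n, dtype=float)
    if config.trajectory == "raised-cosine":
        rise = 0.5 * (1.0 - np.cos(np.pi * t[: apex + 1] / max(apex, 1)))
        fall = 0.5 * (1.0 + np.cos(np.pi * (t[apex + 1 :] - apex) / max(last - apex, 1)))
        profile = np.concatenate([rise, fall])
    else:
        up_end = max(last // 3, 1)
        down_start = last - up_end
        profile = np.ones(n)
        profile[: up_end + 1] = t[: up_end + 1] / up_end
        profile[down_start:] = (last - t[down_start:]) / up_end
        apex = up_end
    profile = np.clip(profile, 0.0, 1.0)
    profile[apex] = 1.0
    return config.peak_angle * profile, apex


def _rotate_from_down(angle_deg: float, side: Side) -> tuple[float, float]:
    """Unit vector at ``angle_deg`` from straight down (image y grows down).

    The right arm swings toward larger x, the left toward smaller x; the
    sign is irrelevant to the measured (unsigned) angles.
    """
    a = math.radians(angle_deg)
    sign = 1.0 if side is Side.RIGHT else -1.0
    return (sign * math.sin(a), math.cos(a))


def _noise_free_joints(
    config: SyntheticMotionConfig, angle_deg: float
) -> dict[JointName, tuple[float, float]]:
    sx, sy = config.shoulder_pos
    side = config.side
    shoulder = (sx, sy)
    hip = (sx, sy + config.trunk_len)
    if config.task is MotionTask.ELBOW_FLEXION:
        # Upper arm hangs along the trunk; only the forearm rotates.
        elbow = (sx, sy + config.upper_arm_len)
        dx, dy = _rotate_from_down(angle_deg, side)
        # flexion = 180 - angle(elbow->wrist, elbow->shoulder); rotating the
        # forearm `angle_deg` away from straight-down achieves exactly that.
        wrist = (elbow[0] + config.forearm_len * dx, elbow[1] + config.forearm_len * dy)
    else:
        dx, dy = _rotate_from_down(angle_deg, side)
        elbow = (sx + config.upper_arm_len * dx, sy + config.upper_arm_len * dy)
        wrist = (elbow[0] + config.forearm_len * dx, elbow[1] + config.forearm_len * dy)
    return {
        JointName.of(side, "shoulder"): shoulder,
        JointName.of(side, "elbow"): elbow,
        JointName.of(side, "wrist"): wrist,
        JointName.of(side, "hip"): hip,
    }


def _confidence(config: SyntheticMotionConfig, x: float, y: float) -> float:
    if config.confidence_model == "constant":
        return 1.0
    w, h = config.canvas
    d = math.hypot(x - w / 2.0, y - h / 2.0)
    return max(0.0, min(1.0, math.exp(-d / math.hypot(w, h))))


def generate(config: SyntheticMotionConfig) -> tuple[LandmarkSequence, SyntheticTruth]:
    """Generate a landmark sequence plus its ground truth.

    With ``jitter_sd = 0`` and ``dropout_prob = 0`` the per-frame task
    angles recomputed from the landmarks reproduce ``true_angle_series``
    to floating-point accuracy, and the maximum equals ``peak_angle``
    exactly at ``apex_frame``.
    """
    angles, apex = _trajectory(config)
    rng = np.random.default_rng(config.seed)
    frames: list[LandmarkFrame] = []
    for i, theta in enumerate(angles):
        joints = _noise_free_joints(config, float(theta))
        frame = LandmarkFrame(frame_index=i, timestamp=i / config.fps)
        if config.dropout_per_joint:
            dropped = {j for j in joints if rng.random() < config.dropout_prob}
        elif rng.random() < config.dropout_prob:
            dropped = set(joints)
        else:
            dropped = set()
        for joint, (x, y) in joints.items():
            jx = x + (rng.normal(0.0, config.jitter_sd) if config.jitter_sd > 0 else 0.0)
            jy = y + (rng.normal(0.0, config.jitter_sd) if config.jitter_sd > 0 else 0.0)
            if joint in dropped:
                continue
            frame.joints[joint] = Landmark(jx, jy, _confidence(config, jx, jy))
        frames.append(frame)
    seq = LandmarkSequence(
        frames=frames,
        fps=config.fps,
        width=config.canvas[0],
        height=config.canvas[1],
        source_id=f"synthetic:{config.task.value}:{config.side.value}:seed={config.seed}",
    )
    truth = SyntheticTruth(
        config=config,
        true_angle_series=tuple(float(a) for a in angles),
        true_max=float(config.peak_angle),
        apex_frame=int(apex),
    )
    return seq, truth


#: Neutral limb-segment colour for stick rendering; far (>= 120 in every
#: channel comparison that matters) from every default palette colour.
_STICK_COLOR = (120, 120, 120)

_LIMB_SEGMENTS = [("shoulder", "elbow"), ("elbow", "wrist"), ("shoulder", "hip")]


def _draw_disk(canvas: np.ndarray, cx: float, cy: float, radius: float,
               color: tuple[int, int, int]) -> None:
    h, w = canvas.shape[:2]
    r0 = max(int(math.floor(cy - radius)) - 1, 0)
    r1 = min(int(math.ceil(cy + radius)) + 2, h)
    c0 = max(int(math.floor(cx - radius)) - 1, 0)
    c1 = min(int(math.ceil(cx + radius)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    canvas[r0:r1, c0:c1][mask] = color


def _draw_segment(canvas: np.ndarray, p0, p1, color, thickness: float = 2.0) -> None:
    length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = max(int(length * 2), 2)
    for t in np.linspace(0.0, 1.0, n):
        x = p0[0] + t * (p1[0] - p0[0])
        y = p0[1] + t * (p1[1] - p0[1])
        _draw_disk(canvas, x, y, thickness / 2.0, color)


def render(
    seq: LandmarkSequence,
    palette: Optional[MarkerPalette] = None,
    style: str = "dots",
    radius: float = 5.0,
) -> Iterator[np.ndarray]:
    """Render a landmark sequence as colour-coded marker frames.

    Each joint is drawn as a filled disk of its palette colour on a black
    canvas; ``style="stick"`` adds neutral-grey limb segments underneath
    (drawn first, so markers always sit on top).  Landmarks outside the
    canvas are clipped with a warning.  Yields uint8 H×W×3 arrays, one
    per frame.
    """
    import warnings

    if palette is None:
        palette = default_palette()
    if style not in ("dots", "stick"):
        raise ConfigError(f"unknown render style {style!r}")
    w, h = seq.width or 480, seq.height or 480
    for frame in seq.frames:
        canvas = np.zeros((h, w, 3), dtype=np.uint8)
        if style == "stick":
            by_label = {j.label: lm for j, lm in frame.joints.items()}
            for a, b in _LIMB_SEGMENTS:
                if a in by_label and b in by_label:
                    _draw_segment(
                        canvas,
                        (by_label[a].x, by_label[a].y),
                        (by_label[b].x, by_label[b].y),
                        _STICK_COLOR,
                    )
        for joint, lm in frame.joints.items():
            if joint not in palette.colors:
                continue
            if not (0 <= lm.x < w and 0 <= lm.y < h):
                warnings.warn(
                    f"landmark {joint.value} at ({lm.x:.1f}, {lm.y:.1f}) lies outside "
                    f"the {w}×{h} canvas; clipped",
                    stacklevel=2,
                )
            _draw_disk(canvas, lm.x, lm.y, radius, palette.colors[joint])
        yield canvas
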