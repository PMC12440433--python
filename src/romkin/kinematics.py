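"""Per-frame joint angles from landmark vectors and maximum-ROM extraction.

The measured angle at a vertex joint B, subtended by two other joints A
and C, is

    angle = | (180/pi) * atan2(BA x BC, BA . BC) |   in [0, 180] degrees,

where ``x`` is the scalar 2D cross product and ``.`` the dot product.
Taking the absolute value makes the result independent of body side,
winding direction and the image-coordinate convention, matching how a
goniometer reads an angle.  For elbow flexion the anatomical convention
puts 0° at full extension, so the reported value is the supplement
(180° − raw).

The maximum ROM for a motion task is simply the largest per-frame angle
over the whole video; frames where a required landmark is missing, has
low confidence, or degenerates to a zero-length vector are carried as
explicitly invalid samples rather than aborting the analysis.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .core import (
    AngleSample,
    AngleSeries,
    InvalidReason,
    JointName,
    LandmarkFrame,
    LandmarkSequence,
    MotionTask,
    RomResult,
    Side,
)
from .errors import ConfigError, DegenerateGeometryError, InsufficientDataError

__all__ = [
    "Vector2",
    "EPS_LEN",
    "angle_between",
    "task_angle",
    "compute_series",
    "max_rom",
    "measure",
]

#: Vectors shorter than this (pixels) do not define a direction.
EPS_LEN = 1e-9


@dataclass(frozen=True)
class Vector2:
    """A 2D displacement in pixels."""

    dx: float
    dy: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)

    @property
    def degenerate(self) -> bool:
        return self.magnitude < EPS_LEN

    def dot(self, other: "Vector2") -> float:
        return self.dx * other.dx + self.dy * other.dy

    def cross(self, other: "Vector2") -> float:
        """Scalar 2D cross product (z component of the 3D cross product)."""
        return self.dx * other.dy - self.dy * other.dx


def angle_between(ba: Vector2, bc: Vector2) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180].

    Computed as |(180/pi)·atan2(ba×bc, ba·bc)|, which is numerically stable
    for near-parallel vectors where the arccos form loses precision.

    Raises :class:`DegenerateGeometryError` if either vector is shorter
    than :data:`EPS_LEN`.
    """
    if ba.degenerate or bc.degenerate:
        raise DegenerateGeometryError(
            f"cannot measure an angle with a near-zero vector "
            f"(|ba|={ba.magnitude:.3g}, |bc|={bc.magnitude:.3g} px)"
        )
    return abs(math.degrees(math.atan2(ba.cross(bc), ba.dot(bc))))


def task_angle(
    frame: LandmarkFrame,
    task: MotionTask,
    side: Union[Side, str],
    confidence_threshold: float = 0.0,
) -> AngleSample:
    """Angle of one motion task in one frame, as an :class:`AngleSample`.

    Shoulder tasks measure the angle between the shoulder→elbow and
    shoulder→hip vectors; elbow flexion measures 180° minus the angle
    between the elbow→wrist and elbow→shoulder vectors.

    Invalidity (absent landmark, confidence below threshold, degenerate
    vector) is data, not an exception: the returned sample carries the
    reason.  ``confidence_threshold`` of 0 disables the confidence check.
    """
    definition = task.definition
    vertex, a_end, c_end = definition.resolve(side)

    landmarks = []
    for joint in (vertex, a_end, c_end):
        lm = frame.get(joint)
        if lm is None:
            return AngleSample(frame.frame_index, None, InvalidReason.ABSENT_LANDMARK)
        landmarks.append(lm)
    if confidence_threshold > 0:
        for lm in landmarks:
            if lm.confidence is not None and lm.confidence < confidence_threshold:
                return AngleSample(frame.frame_index, None, InvalidReason.LOW_CONFIDENCE)

    b, a, c = landmarks
    ba = Vector2(a.x - b.x, a.y - b.y)
    bc = Vector2(c.x - b.x, c.y - b.y)
    try:
        raw = angle_between(ba, bc)
    except DegenerateGeometryError:
        return AngleSample(frame.frame_index, None, InvalidReason.DEGENERATE_GEOMETRY)
    angle = 180.0 - raw if definition.transform == "supplement" else raw
    # Clamp numerical dust at the domain edges (e.g. 180.0000000000001).
    angle = min(180.0, max(0.0, angle))
    return AngleSample(frame.frame_index, angle, None)


def _median_filter_valid(samples: list[AngleSample], window: int) -> list[AngleSample]:
    """Median-filter the valid samples only; invalid samples pass through.

    The filter runs over the subsequence of valid samples (invalid frames
    do not contribute neighbours); positions where the full window does
    not fit keep their original value.
    """
    valid_idx = [i for i, s in enumerate(samples) if s.valid]
    if len(valid_idx) < window:
        return list(samples)
    half = window // 2
    out = list(samples)
    values = [samples[i].angle for i in valid_idx]
    for pos in range(half, len(valid_idx) - half):
        med = statistics.median(values[pos - half : pos + half + 1])
        i = valid_idx[pos]
        out[i] = AngleSample(samples[i].frame_index, med, None)
    return out


def compute_series(
    seq: LandmarkSequence,
    task: MotionTask,
    side: Union[Side, str],
    smoothing: Optional[int] = None,
    confidence_threshold: float = 0.0,
) -> AngleSeries:
    """Compute one :class:`AngleSample` per frame of the sequence.

    ``smoothing`` is an odd median-filter window length (>= 3) applied to
    the valid samples only, or None (the default: raw per-frame angles,
    which is how the single-frame maximum is defined).
    """
    if smoothing is not None and (smoothing < 3 or smoothing % 2 == 0):
        raise ConfigError(f"median smoothing window must be an odd integer >= 3, got {smoothing}")
    samples = [task_angle(f, task, side, confidence_threshold) for f in seq.frames]
    if smoothing is not None:
        samples = _median_filter_valid(samples, smoothing)
    return AngleSeries(task=task, side=Side(side), samples=samples,
                       source=seq.source_id, fps=seq.fps)


def max_rom(series: AngleSeries, min_valid: int = 1) -> RomResult:
    """Maximum ROM: the largest valid per-frame angle and the earliest
    frame attaining it.

    Raises :class:`InsufficientDataError` when fewer than ``min_valid``
    frames are valid.
    """
    valid = series.valid_samples()
    if len(valid) < max(min_valid, 1):
        raise InsufficientDataError(
            f"only {len(valid)} of {len(series.samples)} frames have a valid angle "
            f"(need at least {max(min_valid, 1)})"
        )
    best = max(valid, key=lambda s: s.angle)  # max() keeps the earliest tie
    return RomResult(
        max_angle=best.angle,
        argmax_frame=best.frame_index,
        n_valid_frames=len(valid),
        n_total_frames=len(series.samples),
    )


def measure(
    source,
    task: MotionTask,
    side: Union[Side, str],
    backend=None,
    smoothing: Optional[int] = None,
    confidence_threshold: float = 0.0,
    min_valid: int = 1,
    fps: Optional[float] = None,
) -> tuple[RomResult, AngleSeries]:
    """End-to-end measurement: landmarks → angle series → maximum ROM.

    ``source`` is either a :class:`LandmarkSequence` or a video/frame
    source understood by :func:`romkin.pose_backends.estimate_sequence`
    (then ``backend`` is required).
    """
    if isinstance(source, LandmarkSequence):
        seq = source
    else:
        if backend is None:
            raise ConfigError("a pose backend is required when measuring from video frames")
        from .pose_backends import estimate_sequence

        seq = estimate_sequence(source, backend, fps=fps)
    series = compute_series(seq, task, side, smoothing=smoothing,
                            confidence_threshold=confidence_threshold)
    return max_rom(series, min_valid=min_valid), series
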