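"""Domain types for landmark sequences and angle series, plus file I/O.

The package measures joint range of motion from per-frame 2D body
landmarks.  Coordinates follow the video-frame convention: origin at the
top-left corner, x to the right, y *downward*, units of pixels.  All angle
computations are absolute, so the convention only affects rendering and
file readers.

A joint that was not detected in a frame is *absent* — never encoded as a
(0, 0) placeholder, which is a perfectly valid pixel position.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import FormatError, InputError

__all__ = [
    "JointName",
    "Side",
    "Landmark",
    "LandmarkFrame",
    "LandmarkSequence",
    "MotionTask",
    "AngleDefinition",
    "InvalidReason",
    "AngleSample",
    "AngleSeries",
    "RomResult",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_landmark_json",
    "write_landmark_json",
    "read_angle_csv",
    "write_angle_csv",
]


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class JointName(str, Enum):
    """The tracked joint set: wrists, elbows, shoulders, hips, knees, ankles."""

    LEFT_WRIST = "left_wrist"
    RIGHT_WRIST = "right_wrist"
    LEFT_ELBOW = "left_elbow"
    RIGHT_ELBOW = "right_elbow"
    LEFT_SHOULDER = "left_shoulder"
    RIGHT_SHOULDER = "right_shoulder"
    LEFT_HIP = "left_hip"
    RIGHT_HIP = "right_hip"
    LEFT_KNEE = "left_knee"
    RIGHT_KNEE = "right_knee"
    LEFT_ANKLE = "left_ankle"
    RIGHT_ANKLE = "right_ankle"

    @property
    def side(self) -> Side:
        return Side(self.value.split("_", 1)[0])

    @property
    def label(self) -> str:
        """Anatomical label without the side prefix (e.g. ``"elbow"``)."""
        return self.value.split("_", 1)[1]

    @staticmethod
    def of(side: Union[Side, str], label: str) -> "JointName":
        return JointName(f"{Side(side).value}_{label}")


@dataclass(frozen=True)
class Landmark:
    """A 2D image point in pixels with an optional confidence in [0, 1]."""

    x: float
    y: float
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"landmark coordinates must be finite, got ({self.x}, {self.y})")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise InputError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass
class LandmarkFrame:
    """One video frame's detected joints.

    ``joints`` is a partial mapping: joints the backend did not detect are
    simply missing from it.
    """

    frame_index: int
    timestamp: float
    joints: dict[JointName, Landmark] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise InputError(f"frame_index must be >= 0, got {self.frame_index}")
        self.joints = {JointName(k): v for k, v in self.joints.items()}

    def get(self, joint: JointName) -> Optional[Landmark]:
        return self.joints.get(joint)


@dataclass
class LandmarkSequence:
    """An ordered, contiguous run of landmark frames from one video."""

    frames: list[LandmarkFrame]
    fps: float
    width: int = 0
    height: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise InputError(f"fps must be > 0, got {self.fps}")
        for i, frame in enumerate(self.frames):
            if frame.frame_index != i:
                raise InputError(
                    f"frame indices must be contiguous from 0; "
                    f"position {i} holds frame_index {frame.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


class MotionTask(str, Enum):
    """The three upper-extremity motion tasks.

    Shoulder abduction is filmed from the anterior view; both flexion
    tasks from the lateral view on the measured side.
    """

    SHOULDER_ABDUCTION = "shoulder_abduction"
    SHOULDER_FLEXION = "shoulder_flexion"
    ELBOW_FLEXION = "elbow_flexion"

    @property
    def camera_view(self) -> str:
        return "anterior" if self is MotionTask.SHOULDER_ABDUCTION else "lateral"

    @property
    def definition(self) -> "AngleDefinition":
        return _ANGLE_DEFINITIONS[self]


@dataclass(frozen=True)
class AngleDefinition:
    """Which joints form the measured angle and how the raw value maps to ROM.

    The angle at vertex B is subtended by rays BA and BC.  ``supplement``
    reports 180° − raw: used for elbow flexion, where anatomical 0° means
    full extension (forearm collinear with the upper arm).
    """

    vertex: str
    ray_a_end: str
    ray_c_end: str
    transform: str = "identity"  # identity | supplement

    def resolve(self, side: Union[Side, str]) -> tuple[JointName, JointName, JointName]:
        """Map joint roles to concrete sided joints: (vertex, A, C)."""
        return (
            JointName.of(side, self.vertex),
            JointName.of(side, self.ray_a_end),
            JointName.of(side, self.ray_c_end),
        )


_ANGLE_DEFINITIONS: dict[MotionTask, AngleDefinition] = {
    # Shoulder tasks: angle between the shoulder->elbow and shoulder->hip vectors.
    MotionTask.SHOULDER_ABDUCTION: AngleDefinition("shoulder", "elbow", "hip", "identity"),
    MotionTask.SHOULDER_FLEXION: AngleDefinition("shoulder", "elbow", "hip", "identity"),
    # Elbow flexion: 180° minus the angle between elbow->wrist and elbow->shoulder.
    MotionTask.ELBOW_FLEXION: AngleDefinition("elbow", "wrist", "shoulder", "supplement"),
}


class InvalidReason(str, Enum):
    ABSENT_LANDMARK = "absent-landmark"
    LOW_CONFIDENCE = "low-confidence"
    DEGENERATE_GEOMETRY = "degenerate-geometry"


@dataclass(frozen=True)
class AngleSample:
    """A per-frame angle in degrees, or an explicit reason it is missing."""

    frame_index: int
    angle: Optional[float] = None
    invalid_reason: Optional[InvalidReason] = None

    def __post_init__(self) -> None:
        if (self.angle is None) == (self.invalid_reason is None):
            raise InputError("exactly one of angle / invalid_reason must be set")
        if self.angle is not None and not (0.0 <= self.angle <= 180.0):
            raise InputError(f"angle must lie in [0, 180] degrees, got {self.angle}")

    @property
    def valid(self) -> bool:
        return self.invalid_reason is None


@dataclass
class AngleSeries:
    """Per-frame joint-angle samples for one motion task, one per source frame."""

    task: MotionTask
    side: Side
    samples: list[AngleSample]
    source: str = ""
    fps: float = 30.0

    def valid_samples(self) -> list[AngleSample]:
        return [s for s in self.samples if s.valid]

    def angles(self) -> list[Optional[float]]:
        return [s.angle for s in self.samples]


@dataclass(frozen=True)
class RomResult:
    """Maximum range of motion: the largest per-frame angle and its frame."""

    max_angle: float
    argmax_frame: int
    n_valid_frames: int
    n_total_frames: int

    @property
    def valid_fraction(self) -> float:
        return self.n_valid_frames / self.n_total_frames if self.n_total_frames else 0.0


# ---------------------------------------------------------------------------
# Landmark CSV dialect
#
# Comment header lines:   # fps=<float>  # width=<int>  # height=<int>  # source=<text>
# then a column header:   frame,joint,x,y,confidence
# One row per (frame, joint); confidence may be empty.  A frame in which no
# joint was detected is recorded as a single row with an empty joint column,
# so empty frames survive a round trip and frame indices stay contiguous.
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["frame", "joint", "x", "y", "confidence"]


def write_landmark_csv(seq: LandmarkSequence, path: Union[str, Path]) -> None:
    """Write a landmark sequence in the package's CSV dialect.

    Joints absent from a frame are omitted (never written as sentinel
    coordinates); a frame with no joints at all becomes one placeholder row
    with an empty joint column.  The output re-reads value-equal.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# fps={seq.fps!r}\n")
        fh.write(f"# width={seq.width}\n")
        fh.write(f"# height={seq.height}\n")
        fh.write(f"# source={seq.source_id}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for frame in seq.frames:
            if not frame.joints:
                writer.writerow([frame.frame_index, "", "", "", ""])
                continue
            for joint in sorted(frame.joints, key=lambda j: j.value):
                lm = frame.joints[joint]
                conf = "" if lm.confidence is None else repr(lm.confidence)
                writer.writerow([frame.frame_index, joint.value, repr(lm.x), repr(lm.y), conf])


def read_landmark_csv(path: Union[str, Path]) -> LandmarkSequence:
    """Read a landmark sequence written by :func:`write_landmark_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(f"malformed header line: {line!r}")
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            elif line.strip():
                rows.append(next(csv.reader([line])))
    if "fps" not in meta:
        raise FormatError("missing required header '# fps=<float>'")
    try:
        fps = float(meta["fps"])
        width = int(meta.get("width", 0))
        height = int(meta.get("height", 0))
    except ValueError as exc:
        raise FormatError(f"malformed header value: {exc}") from exc
    if not rows or rows[0] != _CSV_COLUMNS:
        raise FormatError(f"expected column header {_CSV_COLUMNS}, got {rows[0] if rows else 'nothing'}")

    frames: list[LandmarkFrame] = []
    current: Optional[LandmarkFrame] = None
    for row in rows[1:]:
        if len(row) != 5:
            raise FormatError(f"expected 5 columns, got {row!r}")
        try:
            idx = int(row[0])
        except ValueError as exc:
            raise FormatError(f"non-integer frame index in {row!r}") from exc
        if current is None or idx != current.frame_index:
            expected = 0 if current is None else current.frame_index + 1
            if idx != expected:
                raise FormatError(
                    f"non-contiguous frame indices: expected {expected}, got {idx}"
                )
            current = LandmarkFrame(frame_index=idx, timestamp=idx / fps)
            frames.append(current)
        if row[1] == "":
            if current.joints:
                raise FormatError(f"empty-frame placeholder amid joint rows at frame {idx}")
            continue
        try:
            joint = JointName(row[1])
        except ValueError as exc:
            raise FormatError(f"unknown joint name {row[1]!r}") from exc
        if joint in current.joints:
            raise FormatError(f"duplicate joint {joint.value} in frame {idx}")
        try:
            x, y = float(row[2]), float(row[3])
            conf = None if row[4] == "" else float(row[4])
        except ValueError as exc:
            raise FormatError(f"malformed numeric field in {row!r}") from exc
        current.joints[joint] = Landmark(x, y, conf)
    return LandmarkSequence(frames=frames, fps=fps, width=width, height=height,
                            source_id=meta.get("source", ""))


def write_landmark_json(seq: LandmarkSequence, path: Union[str, Path]) -> None:
    """Write a landmark sequence as JSON (same content as the CSV dialect)."""
    obj = {
        "fps": seq.fps,
        "width": seq.width,
        "height": seq.height,
        "source": seq.source_id,
        "frames": [
            {
                "frame": f.frame_index,
                "timestamp": f.timestamp,
                "joints": {
                    j.value: {"x": lm.x, "y": lm.y, "confidence": lm.confidence}
                    for j, lm in sorted(f.joints.items(), key=lambda kv: kv[0].value)
                },
            }
            for f in seq.frames
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1), encoding="utf-8")


def read_landmark_json(path: Union[str, Path]) -> LandmarkSequence:
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from exc
    try:
        frames = [
            LandmarkFrame(
                frame_index=f["frame"],
                timestamp=f["timestamp"],
                joints={
                    JointName(name): Landmark(d["x"], d["y"], d.get("confidence"))
                    for name, d in f.get("joints", {}).items()
                },
            )
            for f in obj["frames"]
        ]
        return LandmarkSequence(frames=frames, fps=obj["fps"], width=obj.get("width", 0),
                                height=obj.get("height", 0), source_id=obj.get("source", ""))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed landmark JSON: {exc}") from exc


def write_angle_csv(series: AngleSeries, path: Union[str, Path]) -> None:
    """Write one row per frame: ``frame,time_s,angle_deg,invalid_reason``.

    The angle cell is empty for invalid samples; the reason cell is empty
    for valid ones.
    """
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# task={series.task.value}\n")
        fh.write(f"# side={series.side.value}\n")
        fh.write(f"# fps={series.fps!r}\n")
        fh.write(f"# source={series.source}\n")
        writer = csv.writer(fh)
        writer.writerow(["frame", "time_s", "angle_deg", "invalid_reason"])
        for s in series.samples:
            t = s.frame_index / series.fps
            angle = "" if s.angle is None else repr(s.angle)
            reason = "" if s.invalid_reason is None else s.invalid_reason.value
            writer.writerow([s.frame_index, repr(t), angle, reason])


def read_angle_csv(path: Union[str, Path]) -> AngleSeries:
    """Read an angle series written by :func:`write_angle_csv`."""
    meta: dict[str, str] = {}
    samples: list[AngleSample] = []
    with Path(path).open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header_seen = False
        for row in reader:
            if not row:
                continue
            if row[0].startswith("#"):
                body = row[0][1:].strip()
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if row != ["frame", "time_s", "angle_deg", "invalid_reason"]:
                    raise FormatError(f"unexpected angle CSV header {row!r}")
                header_seen = True
                continue
            idx = int(row[0])
            if row[2] == "":
                samples.append(AngleSample(idx, None, InvalidReason(row[3])))
            else:
                samples.append(AngleSample(idx, float(row[2]), None))
    try:
        return AngleSeries(
            task=MotionTask(meta["task"]),
            side=Side(meta["side"]),
            samples=samples,
            source=meta.get("source", ""),
            fps=float(meta.get("fps", 30.0)),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed angle CSV metadata: {exc}") from exc
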