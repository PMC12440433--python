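"""Pluggable pose backends turning video frames into landmark frames.

Two backends honour the same contract:

* ``marker`` — a deterministic colour-blob fiducial detector.  Each joint
  is assigned a reference colour; the detector finds pixels within a
  per-channel tolerance of that colour, takes the largest connected
  component, and reports its centroid.  This makes the full video
  pipeline testable at desk scale with rendered synthetic clips.
* ``dnn`` — an adapter contract for a pretrained pose-estimation network
  (user-supplied model files; an optional extra, never required by the
  test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Protocol, Union, runtime_checkable

import numpy as np
from scipy import ndimage

from .core import JointName, Landmark, LandmarkFrame, LandmarkSequence
from .errors import ConfigError, InputError

__all__ = [
    "PoseBackend",
    "MarkerPalette",
    "MarkerBackend",
    "DnnBackend",
    "default_palette",
    "detect_markers",
    "estimate_sequence",
    "dnn_backend",
]


@runtime_checkable
class PoseBackend(Protocol):
    """Contract: map one H×W×3 colour image to a partial landmark frame.

    Implementations never fabricate joints they did not detect, and all
    returned coordinates lie within the image bounds.
    """

    name: str
    deterministic: bool

    def estimate(self, image: np.ndarray) -> LandmarkFrame: ...


@dataclass(frozen=True)
class MarkerPalette:
    """Joint → reference colour mapping for the fiducial-marker backend.

    Colours must be pairwise separable: for every pair, at least one
    channel differs by more than twice ``match_tolerance``, so no pixel
    can match two joints at once.
    """

    colors: dict[JointName, tuple[int, int, int]]
    match_tolerance: int = 30

    def __post_init__(self) -> None:
        if not self.colors:
            raise ConfigError("palette must map at least one joint")
        items = list(self.colors.items())
        for i, (j1, c1) in enumerate(items):
            for j2, c2 in items[i + 1 :]:
                if max(abs(a - b) for a, b in zip(c1, c2)) <= 2 * self.match_tolerance:
                    raise ConfigError(
                        f"palette colours for {j1.value} {c1} and {j2.value} {c2} are "
                        f"not separable at tolerance {self.match_tolerance}"
                    )


#: Colour grid with pairwise per-channel separation >= 120 at the default
#: tolerance 30; black (the render background) is excluded.
_DEFAULT_COLORS = [
    (255, 0, 0), (0, 255, 0), (0, 0, 255),
    (255, 255, 0), (255, 0, 255), (0, 255, 255),
    (255, 255, 255), (255, 120, 0), (0, 120, 255),
    (120, 255, 0), (120, 0, 255), (255, 0, 120),
]


def default_palette(match_tolerance: int = 30) -> MarkerPalette:
    """A ready-made palette covering all 12 tracked joints."""
    return MarkerPalette(
        colors={joint: _DEFAULT_COLORS[i] for i, joint in enumerate(JointName)},
        match_tolerance=match_tolerance,
    )


def detect_markers(
    image: np.ndarray,
    palette: MarkerPalette,
    min_blob_area: int = 4,
    frame_index: int = 0,
    timestamp: float = 0.0,
) -> LandmarkFrame:
    """Detect colour-coded joint markers in one image.

    For each palette joint, pixels within the per-channel tolerance of its
    reference colour are grouped into 8-connected components.  If the
    largest component has at least ``min_blob_area`` pixels, the joint's
    landmark is that component's centroid, with confidence = component
    area / total matching area.  Equal-size components are broken by the
    smallest (row, col) of their top-left pixel.  Undetected joints are
    absent from the result.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise InputError(f"expected a non-empty H×W×3 image, got shape {img.shape}")
    img = img.astype(np.int16)

    frame = LandmarkFrame(frame_index=frame_index, timestamp=timestamp)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    for joint, color in palette.colors.items():
        diff = np.abs(img - np.asarray(color, dtype=np.int16))
        mask = (diff <= palette.match_tolerance).all(axis=2)
        total = int(mask.sum())
        if total < min_blob_area:
            continue
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        best_area = areas.max()
        if best_area < min_blob_area:
            continue
        candidates = np.flatnonzero(areas == best_area) + 1
        if len(candidates) == 1:
            best = candidates[0]
        else:
            # Tie: component whose top-left-most pixel has the smallest (row, col).
            best = min(
                candidates,
                key=lambda lab: min(zip(*np.nonzero(labels == lab))),
            )
        rows, cols = np.nonzero(labels == best)
        frame.joints[joint] = Landmark(
            x=float(cols.mean()),
            y=float(rows.mean()),
            confidence=float(best_area / total),
        )
    return frame


@dataclass
class MarkerBackend:
    """Deterministic fiducial-marker pose backend (see :func:`detect_markers`)."""

    palette: MarkerPalette = field(default_factory=default_palette)
    min_blob_area: int = 4
    name: str = "marker"
    deterministic: bool = True

    def estimate(self, image: np.ndarray) -> LandmarkFrame:
        return detect_markers(image, self.palette, self.min_blob_area)


def _iter_frames(video, fps: Optional[float]) -> tuple[Iterator[np.ndarray], float]:
    """Resolve a video path or frame iterable into (frame iterator, fps)."""
    if isinstance(video, (str, Path)):
        import imageio.v3 as iio

        path = Path(video)
        if not path.exists():
            raise InputError(f"video file not found: {path}")
        if fps is None:
            try:
                meta = iio.immeta(path, plugin="pyav")
            except Exception:
                meta = {}
            fps = float(meta.get("fps", 0) or 0)
            if fps <= 0:
                raise InputError(
                    f"frame rate not recoverable from {path}; pass fps explicitly"
                )
        return iter(iio.imiter(path)), fps
    if fps is None or fps <= 0:
        raise InputError("fps must be supplied (> 0) when reading from a frame iterator")
    return iter(video), fps


def estimate_sequence(
    video: Union[str, Path, Iterable[np.ndarray]],
    backend: PoseBackend,
    fps: Optional[float] = None,
    source_id: str = "",
) -> LandmarkSequence:
    """Run a pose backend over every frame, in order.

    ``video`` is a container path (frame rate read from the container
    unless ``fps`` is given) or any iterable of H×W×3 arrays (``fps``
    required).  Raises on zero decodable frames.
    """
    frames_iter, fps = _iter_frames(video, fps)
    frames: list[LandmarkFrame] = []
    width = height = 0
    for i, image in enumerate(frames_iter):
        lf = backend.estimate(np.asarray(image))
        lf.frame_index = i
        lf.timestamp = i / fps
        frames.append(lf)
        height, width = image.shape[0], image.shape[1]
    if not frames:
        raise InputError("no decodable frames in input")
    if not source_id:
        source_id = str(video) if isinstance(video, (str, Path)) else f"frames:{backend.name}"
    return LandmarkSequence(frames=frames, fps=fps, width=width, height=height,
                            source_id=source_id)


#: COCO-18 style keypoint index → joint mapping used as the default for
#: pretrained pose networks; indices not listed here are ignored.
DEFAULT_KEYPOINT_MAP: dict[int, JointName] = {
    2: JointName.RIGHT_SHOULDER, 3: JointName.RIGHT_ELBOW, 4: JointName.RIGHT_WRIST,
    5: JointName.LEFT_SHOULDER, 6: JointName.LEFT_ELBOW, 7: JointName.LEFT_WRIST,
    8: JointName.RIGHT_HIP, 9: JointName.RIGHT_KNEE, 10: JointName.RIGHT_ANKLE,
    11: JointName.LEFT_HIP, 12: JointName.LEFT_KNEE, 13: JointName.LEFT_ANKLE,
}


@dataclass
class DnnBackend:
    """Adapter for a pretrained pose-estimation network.

    Construction validates the configuration (model files present,
    keypoint map covering the tracked joints or explicitly declaring the
    missing ones); inference loads the network lazily.
    """

    prototxt: Path
    weights: Path
    keypoint_map: dict[int, JointName]
    confidence_threshold: float = 0.1
    input_size: tuple[int, int] = (368, 368)
    missing_joints: frozenset[JointName] = frozenset()
    name: str = "dnn"
    deterministic: bool = True

    def estimate(self, image: np.ndarray) -> LandmarkFrame:
        net = self._load()
        h, w = image.shape[:2]
        blob = self._cv2.dnn.blobFromImage(
            image, 1.0 / 255, self.input_size, (0, 0, 0), swapRB=False, crop=False
        )
        net.setInput(blob)
        out = net.forward()
        frame = LandmarkFrame(frame_index=0, timestamp=0.0)
        for idx, joint in self.keypoint_map.items():
            if idx >= out.shape[1]:
                continue
            heat = out[0, idx]
            conf = float(heat.max())
            if conf < self.confidence_threshold:
                continue
            r, c = np.unravel_index(int(heat.argmax()), heat.shape)
            x = min(max(c * w / heat.shape[1], 0.0), w - 1.0)
            y = min(max(r * h / heat.shape[0], 0.0), h - 1.0)
            frame.joints[joint] = Landmark(x, y, min(conf, 1.0))
        return frame

    def _load(self):
        try:
            import cv2
        except ImportError as exc:
            raise ConfigError(
                "the dnn backend needs the optional 'dnn' extra (opencv-python)"
            ) from exc
        self._cv2 = cv2
        if not hasattr(self, "_net"):
            self._net = cv2.dnn.readNetFromCaffe(str(self.prototxt), str(self.weights))
        return self._net


def dnn_backend(
    prototxt: Union[str, Path],
    weights: Union[str, Path],
    keypoint_map: Optional[dict[int, JointName]] = None,
    confidence_threshold: float = 0.1,
    missing_joints: Iterable[JointName] = (),
) -> DnnBackend:
    """Build the pretrained-network adapter, validating its configuration.

    Model files are user-supplied and never downloaded.  The keypoint map
    must either cover all 12 tracked joints or explicitly declare the
    uncovered ones in ``missing_joints``.
    """
    prototxt, weights = Path(prototxt), Path(weights)
    missing_files = [str(p) for p in (prototxt, weights) if not p.is_file()]
    if missing_files:
        raise ConfigError(
            "dnn backend model files not found: " + ", ".join(missing_files)
            + " — supply the network definition (.prototxt) and weights (.caffemodel)"
        )
    kp_map = dict(keypoint_map) if keypoint_map is not None else dict(DEFAULT_KEYPOINT_MAP)
    declared_missing = frozenset(missing_joints)
    covered = set(kp_map.values()) | declared_missing
    uncovered = set(JointName) - covered
    if uncovered:
        raise ConfigError(
            "keypoint map neither covers nor declares missing: "
            + ", ".join(sorted(j.value for j in uncovered))
        )
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ConfigError(f"confidence_threshold must lie in [0, 1], got {confidence_threshold}")
    return DnnBackend(
        prototxt=prototxt,
        weights=weights,
        keypoint_map=kp_map,
        confidence_threshold=confidence_threshold,
        missing_joints=declared_missing,
    )
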