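"""Readers and writers for pose-keypoint streams, activity manifests and score tables.

The on-disk keypoint dialect is the OpenPose BODY_25 JSON convention: each
frame is a JSON document with a ``people`` array, and each person carries a
``pose_keypoints_2d`` field of 75 floats (25 keypoints x (x, y, confidence)).
Streams may be stored either as one ``*_keypoints.json`` file per frame (the
OpenPose demo layout) or as a single JSON-lines file with one frame document
per line.

Activity manifests are CSV (``activity, start_s, end_s``), video metadata is
JSON (``fps, origin_A_x, origin_A_y, width, height``) and score tables are CSV
(``child_id, activity_level_score, ados_total``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_KEYPOINTS = 25
#: BODY_25 indices of the three body parts the analysis tracks.
NECK = 1
RIGHT_WRIST = 4
MID_HIP = 8
ANALYSIS_KEYPOINTS = (NECK, RIGHT_WRIST, MID_HIP)
KEYPOINT_NAMES = {NECK: "neck", RIGHT_WRIST: "right_wrist", MID_HIP: "mid_hip"}

TABLE_PLAY = "Table-play"
#: Activities that never belong to the table-based composite: free play and the
#: response-to-name press do not require the child to stay at the table, the
#: balloon and bubble presses explicitly invite movement, and the snack is not
#: scored for activity level.
NON_TABLE_ACTIVITIES = frozenset(
    {"Free-play", "Response-to-name", "Balloon-play", "Bubble-play", "Snack"}
)


class StreamFormatError(ValueError):
    """A keypoint stream file violates the expected JSON layout."""


class ValidationError(ValueError):
    """A manifest, score table or metadata record violates an invariant."""


@dataclass
class PersonDetection:
    """One skeleton in one frame: a (25, 3) array of (x, y, confidence).

    Confidence 0 marks an undetected keypoint; its coordinates are meaningless.
    """

    keypoints: np.ndarray

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise StreamFormatError(
                f"person detection needs shape ({N_KEYPOINTS}, 3), got {kp.shape}"
            )
        self.keypoints = kp

    @classmethod
    def from_flat(cls, flat: Sequence[float]) -> "PersonDetection":
        arr = np.asarray(flat, dtype=float)
        if arr.size != 3 * N_KEYPOINTS:
            raise StreamFormatError(
                f"pose_keypoints_2d must hold {3 * N_KEYPOINTS} floats, got {arr.size}"
            )
        return cls(arr.reshape(N_KEYPOINTS, 3))

    def to_flat(self) -> list[float]:
        return [float(v) for v in self.keypoints.ravel()]

    def keypoint(self, index: int) -> tuple[float, float, float]:
        x, y, c = self.keypoints[index]
        return float(x), float(y), float(c)


@dataclass
class KeypointFrame:
    """All detections of one video frame; ``time`` is frame_index / fps."""

    frame_index: int
    time: float
    people: list[PersonDetection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise StreamFormatError("frame_index must be >= 0")


@dataclass(frozen=True)
class ActivitySegment:
    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"segment {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )

    def contains(self, time: float) -> bool:
        """Half-open membership: a frame belongs to [start, end)."""
        return self.start <= time < self.end


@dataclass
class Timeline:
    """Named activity intervals plus composite activities.

    Segments may overlap (the response-to-name press sits inside free play);
    each named segment is analysed independently.  A composite maps a name to
    the set of member segment names; its frames are the union of the members'.
    """

    segments: list[ActivitySegment]
    composites: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {s.name for s in self.segments}
        for comp, members in self.composites.items():
            missing = set(members) - names
            if missing:
                raise ValidationError(
                    f"composite {comp!r} references unknown segments: {sorted(missing)}"
                )
            self.composites[comp] = frozenset(members)

    @property
    def segment_names(self) -> list[str]:
        return [s.name for s in self.segments]

    @property
    def end(self) -> float:
        return max(s.end for s in self.segments)

    def segment(self, name: str) -> ActivitySegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def activities(self) -> list[str]:
        """All analysable activity names: plain segments then composites."""
        return self.segment_names + list(self.composites)

    def members(self, activity: str) -> list[ActivitySegment]:
        """The segments whose frames make up ``activity``."""
        if activity in self.composites:
            return [self.segment(m) for m in sorted(self.composites[activity])]
        return [self.segment(activity)]

    def with_table_play(self) -> "Timeline":
        """Return a timeline whose table-based segments form a composite.

        Every segment not named in :data:`NON_TABLE_ACTIVITIES` becomes a
        member of the combined table-based activity.
        """
        members = frozenset(
            s.name for s in self.segments if s.name not in NON_TABLE_ACTIVITIES
        )
        composites = dict(self.composites)
        if members:
            composites[TABLE_PLAY] = members
        return Timeline(list(self.segments), composites)


@dataclass(frozen=True)
class ScoreRecord:
    """One child's clinician-rated activity-level score (0, 1 or 2)."""

    child_id: str
    activity_level_score: int
    ados_total: int | None = None

    def __post_init__(self) -> None:
        if self.activity_level_score not in (0, 1, 2):
            raise ValidationError(
                f"{self.child_id}: activity_level_score must be 0, 1 or 2, "
                f"got {self.activity_level_score}"
            )


@dataclass(frozen=True)
class VideoMeta:
    """Camera-frame metadata; ``origin_a`` is the analysis origin in pixels,
    the centre of the table edge next to the participant."""

    fps: float
    origin_a: tuple[float, float]
    resolution: tuple[int, int]

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        w, h = self.resolution
        x, y = self.origin_a
        if not (0 <= x <= w and 0 <= y <= h):
            raise ValidationError(
                f"origin_A ({x}, {y}) lies outside the {w}x{h} image"
            )

    @property
    def diagonal(self) -> float:
        return float(np.hypot(*self.resolution))


# ---------------------------------------------------------------------------
# keypoint streams


def _frame_from_doc(doc: Mapping, frame_index: int, fps: float) -> KeypointFrame:
    people_raw = doc.get("people", [])
    people = []
    for j, person in enumerate(people_raw):
        try:
            people.append(PersonDetection.from_flat(person["pose_keypoints_2d"]))
        except (KeyError, StreamFormatError) as exc:
            raise StreamFormatError(
                f"frame {frame_index}, person {j}: {exc}"
            ) from exc
    return KeypointFrame(frame_index=frame_index, time=frame_index / fps, people=people)


_FRAME_FILE_RE = re.compile(r"(\d+)_keypoints\.json$")


def read_keypoint_stream(path: str | Path, fps: float) -> list[KeypointFrame]:
    """Read a keypoint stream from a JSON-lines file or a per-frame directory.

    Frames come back ordered by frame index.  Indices must be strictly
    increasing; the index is taken from each line's ``frame_index`` field
    (JSON-lines) or from the trailing digits of each file name (directory).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames: list[KeypointFrame] = []
    if path.is_dir():
        entries = []
        for f in path.iterdir():
            m = _FRAME_FILE_RE.search(f.name)
            if m:
                entries.append((int(m.group(1)), f))
        entries.sort()
        for idx, f in entries:
            with open(f) as fh:
                try:
                    doc = json.load(fh)
                except json.JSONDecodeError as exc:
                    raise StreamFormatError(f"{f}: malformed JSON: {exc}") from exc
            frames.append(_frame_from_doc(doc, idx, fps))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    doc = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise StreamFormatError(
                        f"{path}:{lineno}: malformed JSON: {exc}"
                    ) from exc
                idx = doc.get("frame_index", lineno - 1)
                frames.append(_frame_from_doc(doc, int(idx), fps))
    indices = [f.frame_index for f in frames]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise StreamFormatError(f"{path}: frame indices are not strictly increasing")
    return frames


def write_keypoint_stream(frames: Iterable[KeypointFrame], path: str | Path) -> None:
    """Write frames as JSON lines, one OpenPose-style document per frame."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for frame in frames:
            doc = {
                "version": 1.3,
                "frame_index": frame.frame_index,
                "people": [{"pose_keypoints_2d": p.to_flat()} for p in frame.people],
            }
            fh.write(json.dumps(doc) + "\n")


# ---------------------------------------------------------------------------
# manifests, metadata, scores


def read_manifest(
    manifest_path: str | Path, meta_path: str | Path
) -> tuple[Timeline, VideoMeta]:
    """Read the activity manifest CSV and video-metadata JSON.

    The table-based composite activity is materialised by default.
    """
    df = pd.read_csv(manifest_path)
    required = {"activity", "start_s", "end_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{manifest_path}: missing columns {sorted(missing)}")
    segments = [
        ActivitySegment(str(r.activity), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]
    timeline = Timeline(segments).with_table_play()

    with open(meta_path) as fh:
        meta_doc = json.load(fh)
    for key in ("fps", "origin_A_x", "origin_A_y", "width", "height"):
        if key not in meta_doc:
            raise ValidationError(f"{meta_path}: missing field {key!r}")
    meta = VideoMeta(
        fps=float(meta_doc["fps"]),
        origin_a=(float(meta_doc["origin_A_x"]), float(meta_doc["origin_A_y"])),
        resolution=(int(meta_doc["width"]), int(meta_doc["height"])),
    )
    return timeline, meta


def write_manifest(
    timeline: Timeline, meta: VideoMeta, manifest_path: str | Path, meta_path: str | Path
) -> None:
    pd.DataFrame(
        [(s.name, s.start, s.end) for s in timeline.segments],
        columns=["activity", "start_s", "end_s"],
    ).to_csv(manifest_path, index=False)
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "fps": meta.fps,
                "origin_A_x": meta.origin_a[0],
                "origin_A_y": meta.origin_a[1],
                "width": meta.resolution[0],
                "height": meta.resolution[1],
            },
            fh,
            indent=2,
        )


def read_scores(path: str | Path) -> list[ScoreRecord]:
    df = pd.read_csv(path)
    required = {"child_id", "activity_level_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for r in df.itertuples():
        ados = getattr(r, "ados_total", None)
        records.append(
            ScoreRecord(
                child_id=str(r.child_id),
                activity_level_score=int(r.activity_level_score),
                ados_total=None if ados is None or pd.isna(ados) else int(ados),
            )
        )
    return records


def write_scores(records: Sequence[ScoreRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.child_id, r.activity_level_score, r.ados_total)
            for r in records
        ],
        columns=["child_id", "activity_level_score", "ados_total"],
    ).to_csv(path, index=False)
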