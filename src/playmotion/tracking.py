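"""Select the participating child among multi-person detections.

A multi-person pose detector emits every skeleton in the frame; downstream
features need only the participating child's.  The filter tracks the child by
nearest-neighbour gating on the neck keypoint: in each frame the candidate
whose neck (at sufficient confidence) lies closest to the last confirmed
child neck is selected, provided the jump does not exceed ``gate_radius``.
The neck anchors the track because it is the most reliably visible of the
tracked keypoints in seated interaction scenes.

Frames with no admissible candidate become gaps; the anchor is held through
short gaps and, after ``max_gap`` consecutive gap frames, the track
re-initialises to the candidate nearest the configured initial position (the
child's seat), which keeps long recordings usable after extended occlusion.

``mismatch_rate`` audits the selection against identity labels the way a
manual review would: up to ``n_audit`` selected frames are sampled uniformly
without replacement and the fraction attributed to the wrong person reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ANALYSIS_KEYPOINTS, NECK, KeypointFrame, VideoMeta

#: Default gate radius as a fraction of the image diagonal.  At 10 fps this
#: still covers the largest plausible per-frame displacement of a child while
#: rejecting jumps to bystanders across the scene.
DEFAULT_GATE_FRACTION = 0.10


@dataclass
class FilterParams:
    """Gating parameters for child selection.

    gate_radius : float
        Maximum allowed neck displacement (pixels) between the anchor and a
        newly selected skeleton.
    min_confidence : float
        Necks below this detector confidence are not candidates.
    max_gap : int
        Consecutive gap frames tolerated before the track re-initialises
        towards ``init_position``.
    init_position : (float, float)
        Where the child is expected at the start (and after track loss) —
        typically the seat next to the table.
    """

    gate_radius: float
    init_position: tuple[float, float]
    min_confidence: float = 0.1
    max_gap: int = 20

    def __post_init__(self) -> None:
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must lie in [0, 1]")

    @classmethod
    def for_video(
        cls,
        meta: VideoMeta,
        init_position: tuple[float, float] | None = None,
        **overrides,
    ) -> "FilterParams":
        """Defaults scaled to the video: gate = 10% of the image diagonal,
        initial position = the table-edge origin unless given."""
        return cls(
            gate_radius=DEFAULT_GATE_FRACTION * meta.diagonal,
            init_position=init_position or meta.origin_a,
            **overrides,
        )


@dataclass
class Trajectory:
    """Time-ordered samples of one keypoint of the selected child.

    Frames where the keypoint was missing or no skeleton was selected are
    simply absent; ``frames`` is strictly increasing.
    """

    keypoint: int
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.frames.shape[0] != self.xy.shape[0]:
            raise ValueError("frames and xy must have equal length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class SelectionRecord:
    """Per-frame audit trail of the filter's choices.

    ``selected`` holds the index into ``frame.people`` (-1 for a gap),
    ``distance`` the anchor-to-neck distance of the selection (NaN for gaps).
    """

    frame_index: np.ndarray
    selected: np.ndarray
    distance: np.ndarray
    gap_flag: np.ndarray
    all_gaps: bool = field(default=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "selected_person_index": self.selected,
                "distance": self.distance,
                "gap_flag": self.gap_flag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def filter_stream(
    frames: list[KeypointFrame], params: FilterParams
) -> tuple[dict[int, Trajectory], SelectionRecord]:
    """Track the child through ``frames``; return one trajectory per tracked
    keypoint (neck, right wrist, mid hip) and the per-frame selection record.

    The wrist and hip are read off the selected skeleton; their own missing
    keypoints become gaps in their trajectories without invalidating the
    neck track.
    """
    if not frames:
        raise ValueError("empty keypoint stream")

    n = len(frames)
    sel = np.full(n, -1, dtype=np.int64)
    dist = np.full(n, np.nan)
    gap = np.zeros(n, dtype=bool)
    samples: dict[int, tuple[list[int], list[tuple[float, float]]]] = {
        k: ([], []) for k in ANALYSIS_KEYPOINTS
    }

    # Candidate neck rows per frame, extracted once for the tracking loop.
    necks = [
        [p.keypoints[NECK] for p in frame.people] for frame in frames
    ]
    anchor = tuple(map(float, params.init_position))
    init = anchor
    gap_run = 0
    min_conf = params.min_confidence
    gate = params.gate_radius

    for t, frame in enumerate(frames):
        best_j, best_d = -1, math.inf
        reinit = gap_run > params.max_gap
        tx, ty = init if reinit else anchor
        for j, (x, y, c) in enumerate(necks[t]):
            if c < min_conf:
                continue
            d = math.hypot(x - tx, y - ty)
            if d < best_d:
                best_j, best_d = j, d
        # After a long gap the track re-initialises: the nearest candidate to
        # the initial position is accepted without the jump gate.
        if best_j >= 0 and (reinit or best_d <= gate):
            sel[t] = best_j
            dist[t] = best_d
            gap_run = 0
            kp = frame.people[best_j].keypoints
            anchor = (float(kp[NECK, 0]), float(kp[NECK, 1]))
            for k in ANALYSIS_KEYPOINTS:
                if kp[k, 2] >= min_conf:
                    samples[k][0].append(frame.frame_index)
                    samples[k][1].append((kp[k, 0], kp[k, 1]))
        else:
            gap[t] = True
            gap_run += 1

    trajectories = {
        k: Trajectory(keypoint=k, frames=np.array(f, dtype=np.int64), xy=np.array(p).reshape(-1, 2))
        for k, (f, p) in samples.items()
    }
    record = SelectionRecord(
        frame_index=np.array([f.frame_index for f in frames], dtype=np.int64),
        selected=sel,
        distance=dist,
        gap_flag=gap,
        all_gaps=bool(gap.all()),
    )
    return trajectories, record


def mismatch_rate(
    record: SelectionRecord,
    truth: list[list[str]],
    n_audit: int = 100,
    seed: int | np.random.SeedSequence = 0,
    child_label: str = "child",
) -> float:
    """Fraction of audited selections attributed to the wrong person.

    Up to ``n_audit`` frames with a selection are sampled uniformly without
    replacement (all of them if fewer exist); a selection whose ground-truth
    identity differs from ``child_label`` counts as a mismatch.
    """
    if n_audit < 1:
        raise ValueError("n_audit must be >= 1")
    selected_frames = np.flatnonzero(record.selected >= 0)
    if selected_frames.size == 0:
        raise ValueError("no selected frames to audit")
    rng = np.random.default_rng(seed)
    k = min(n_audit, selected_frames.size)
    audit = rng.choice(selected_frames, size=k, replace=False)
    wrong = 0
    for t in audit:
        j = int(record.selected[t])
        if truth[t][j] != child_label:
            wrong += 1
    return wrong / k
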