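"""Synthetic multi-person skeleton cohorts with score-dependent movement.

Real assessment recordings cannot be redistributed, so every downstream stage
is exercised on generated data with the same statistical structure the
analysis assumes: a child whose gross body motion is a mean-reverting (AR(1))
random walk around their seat, with both the stationary excursion from the
seat and the per-frame step size increasing with the clinician-rated activity
level (0 = sits appropriately, 2 = almost impossible to hold still);
independent wrist fidgeting on top of the body trajectory; occlusion-induced
keypoint dropout; and slow-moving distractor skeletons (clinician, parent)
stationed elsewhere in the scene.

The AR(1) walk is parameterised by two interpretable pixel scales per score
level: the stationary spread ``s_x`` (drives distance-from-origin features)
and the per-frame step SD ``s_d`` (drives velocity features).  Per axis,

    z[t] = phi * z[t-1] + eps[t],   eps ~ N(0, sigma^2),

with ``phi = 1 - s_d^2 / (2 s_x^2)`` and ``sigma^2 = s_x^2 (1 - phi^2)`` so
that Var(z) = s_x^2 in stationarity and SD(z[t] - z[t-1]) = s_d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    ANALYSIS_KEYPOINTS,
    MID_HIP,
    N_KEYPOINTS,
    NECK,
    RIGHT_WRIST,
    ActivitySegment,
    KeypointFrame,
    PersonDetection,
    ScoreRecord,
    Timeline,
    VideoMeta,
    write_keypoint_stream,
    write_manifest,
    write_scores,
)

CHILD_LABEL = "child"

#: Default camera frame: 720p with the table-edge origin at image centre and
#: the child's seat 120 px below it (image y grows downward).
DEFAULT_META = VideoMeta(fps=10.0, origin_a=(640.0, 360.0), resolution=(1280, 720))
DEFAULT_HOME = (640.0, 480.0)

#: Mean activity durations in minutes as observed across assessment videos;
#: the three table activities without a published individual mean share the
#: remainder of the table-based total (11.89 minutes).
FULL_SCALE_DURATIONS_MIN = {
    "Joint-attention": (1.08, 0.87),
    "Anticipation-routine": (1.8266666666666667, 0.9),
    "Balloon-play": (2.73, 1.12),
    "Birthday-party": (5.33, 2.22),
    "Bubble-play": (2.96, 1.17),
    "Imitation": (1.8266666666666667, 0.9),
    "Pretend-play": (1.8266666666666667, 0.9),
}
#: Order in which activities occur in the default session.
DEFAULT_ACTIVITY_ORDER = (
    "Joint-attention",
    "Anticipation-routine",
    "Balloon-play",
    "Birthday-party",
    "Bubble-play",
    "Imitation",
    "Pretend-play",
)
#: Presses that invite the child away from the table; the generator boosts
#: the excursion scale there to mimic the higher observed movement levels.
ACTIVE_ACTIVITIES = frozenset({"Balloon-play", "Bubble-play"})

#: Observed group sizes by activity-level score in the reference cohort.
DEFAULT_GROUP_SIZES = {0: 18, 1: 25, 2: 9}


def _as_score_table(table: dict) -> dict[int, float]:
    return {int(k): float(v) for k, v in table.items()}


@dataclass
class MotionModel:
    """Pixel-scale parameters of the synthetic motion process.

    ``excursion_scale_by_score`` and ``step_scale_by_score`` must be
    non-decreasing in the score; the defaults increase strictly, doubling per
    score level.  ``wrist_jitter_scale`` is the median of a per-child
    log-normal fidget scale (sigma ``wrist_jitter_sigma`` on the log scale),
    so wrist velocity carries a per-child component independent of gross body
    motion.  Distractors perform small AR(1) motion around fixed stations.
    """

    home_position: tuple[float, float] = DEFAULT_HOME
    excursion_scale_by_score: dict[int, float] = field(
        default_factory=lambda: {0: 30.0, 1: 60.0, 2: 120.0}
    )
    step_scale_by_score: dict[int, float] = field(
        default_factory=lambda: {0: 9.0, 1: 18.0, 2: 36.0}
    )
    wrist_jitter_scale: float = 6.0
    wrist_jitter_sigma: float = 0.35
    #: Negative lag-1 autocorrelation of the wrist fidget: oscillatory
    #: hand motion adds velocity without adding much positional spread.
    wrist_jitter_phi: float = -0.6
    #: Range of the per-child hip smoothing factor: the hip follows an
    #: exponentially smoothed copy of the body trajectory (a seated child's
    #: hip is anchored to the chair and attenuates fast upper-body motion),
    #: so hip velocity is a child-specific fraction of neck velocity while
    #: hip position stays nearly interchangeable with the neck's.
    hip_smoothing_range: tuple[float, float] = (0.25, 0.8)
    body_jitter_scale: float = 2.0
    missingness_prob: float = 0.03
    distractor_stations: list[tuple[float, float]] = field(
        default_factory=lambda: [(640.0, 80.0), (140.0, 500.0)]
    )
    distractor_excursion_scale: float = 15.0
    distractor_step_scale: float = 4.0
    #: Mean durations (seconds) of a distractor's detectable / undetectable
    #: bouts: bystanders drift in and out of detectability as they are
    #: occluded by furniture or leave the camera's view.
    distractor_present_bout_s: float = 20.0
    distractor_absent_bout_s: float = 10.0
    active_excursion_boost: float = 1.5
    active_activities: frozenset[str] = ACTIVE_ACTIVITIES
    #: Keep-inside margin (pixels) from the image border; trajectories are
    #: reflected back into the frame, since a detector cannot report a person
    #: outside it.
    frame_margin: float = 40.0

    def __post_init__(self) -> None:
        self.excursion_scale_by_score = _as_score_table(self.excursion_scale_by_score)
        self.step_scale_by_score = _as_score_table(self.step_scale_by_score)
        if set(self.excursion_scale_by_score) != set(self.step_scale_by_score):
            raise ValueError("excursion and step tables must cover the same scores")
        for table, label in (
            (self.excursion_scale_by_score, "excursion"),
            (self.step_scale_by_score, "step"),
        ):
            vals = [table[s] for s in sorted(table)]
            if any(v < 0 for v in vals):
                raise ValueError(f"{label} scales must be >= 0")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{label} scales must be non-decreasing in score")
        for score in self.excursion_scale_by_score:
            s_x = self.excursion_scale_by_score[score]
            s_d = self.step_scale_by_score[score]
            if s_d > 0 and s_d > s_x * math.sqrt(2.0):
                raise ValueError(
                    f"score {score}: step scale {s_d} exceeds the AR(1) maximum "
                    f"sqrt(2) * excursion scale ({s_x * math.sqrt(2.0):.3g})"
                )
        if not 0.0 <= self.missingness_prob <= 1.0:
            raise ValueError("missingness_prob must lie in [0, 1]")
        for scale in (
            self.wrist_jitter_scale,
            self.body_jitter_scale,
            self.distractor_excursion_scale,
            self.distractor_step_scale,
        ):
            if scale < 0:
                raise ValueError("scales must be >= 0")

    def scores(self) -> list[int]:
        return sorted(self.excursion_scale_by_score)


def null_motion_model(**overrides) -> MotionModel:
    """A model with no score effect: every score shares the score-1 scales.

    Used for type-I-error checks of the correlation stage.
    """
    base = MotionModel()
    flat_exc = {s: base.excursion_scale_by_score[1] for s in base.scores()}
    flat_step = {s: base.step_scale_by_score[1] for s in base.scores()}
    return replace(
        base,
        excursion_scale_by_score=flat_exc,
        step_scale_by_score=flat_step,
        **overrides,
    )


@dataclass
class CohortSpec:
    """Cohort layout: group sizes per score, frame rate and timing scale.

    ``duration_scale`` shrinks the observed full-length activity durations so
    a whole cohort simulates in seconds; 1.0 reproduces full-session lengths.
    If ``timeline_template`` is given every child uses it verbatim, otherwise
    each child's activity durations are drawn around the scaled means.
    """

    group_sizes: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    fps: float = 10.0
    duration_scale: float = 0.1
    timeline_template: Timeline | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = {int(k): int(v) for k, v in self.group_sizes.items()}
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.n_children == 0:
            raise ValueError("cohort must contain at least one child")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be > 0")

    @property
    def n_children(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class ChildStream:
    """One child's generated frames plus per-frame ground-truth labels.

    ``truth[t][j]`` is the identity ("child" or "distractor_<k>") of
    ``frames[t].people[j]``; every emitted skeleton is labelled.
    """

    frames: list[KeypointFrame]
    truth: list[list[str]]


@dataclass
class SyntheticCohort:
    """A full generated cohort with ground truth and generation metadata."""

    streams: dict[str, ChildStream]
    timelines: dict[str, Timeline]
    scores: list[ScoreRecord]
    meta: VideoMeta
    spec: CohortSpec
    model: MotionModel

    @property
    def child_ids(self) -> list[str]:
        return [r.child_id for r in self.scores]

    def write(self, outdir: str | Path) -> None:
        """Write streams, per-child manifests and the score table to disk."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for child_id, stream in self.streams.items():
            write_keypoint_stream(stream.frames, outdir / f"{child_id}.jsonl")
            write_manifest(
                self.timelines[child_id],
                self.meta,
                outdir / f"{child_id}_manifest.csv",
                outdir / f"{child_id}_meta.json",
            )
        write_scores(self.scores, outdir / "scores.csv")


# ---------------------------------------------------------------------------
# trajectory simulation


def _ar1_path(
    rng: np.random.Generator,
    n_frames: int,
    s_x: np.ndarray,
    s_d: np.ndarray,
) -> np.ndarray:
    """Simulate a 2-D AR(1) walk with per-frame scale schedules, from z=0.

    ``s_x``/``s_d`` are length-``n_frames`` arrays (constant in the common
    case); the walk starts at the origin (the child begins seated).
    """
    from scipy.signal import lfilter

    phi = np.ones(n_frames)
    sigma = np.zeros(n_frames)
    positive = s_x > 0
    phi[positive] = 1.0 - (s_d[positive] ** 2) / (2.0 * s_x[positive] ** 2)
    np.clip(phi, 0.0, 1.0, out=phi)
    sigma[positive] = s_x[positive] * np.sqrt(1.0 - phi[positive] ** 2)
    eps = rng.standard_normal((n_frames, 2))
    eps[0] = 0.0  # the walk starts at the origin
    driven = sigma[:, None] * eps
    z = np.empty((n_frames, 2))
    # Filter piecewise over maximal constant-phi blocks, chaining state.
    boundaries = np.flatnonzero(np.diff(phi) != 0) + 1
    starts = np.concatenate(([0], boundaries, [n_frames]))
    y_last = np.zeros(2)
    for a, b in zip(starts[:-1], starts[1:]):
        block, _ = lfilter(
            [1.0], [1.0, -phi[a]], driven[a:b], axis=0, zi=(phi[a] * y_last)[None, :]
        )
        z[a:b] = block
        y_last = block[-1]
    return z


def _reflect_into_frame(
    body: np.ndarray, resolution: tuple[int, int], margin: float
) -> np.ndarray:
    """Fold trajectories back into the visible frame by reflection."""
    out = body.copy()
    for axis, bound in enumerate(resolution):
        a, b = margin, bound - margin
        span = b - a
        m = np.mod(out[:, axis] - a, 2.0 * span)
        out[:, axis] = a + np.minimum(m, 2.0 * span - m)
    return out


def _presence_mask(
    rng: np.random.Generator, n_frames: int, fps: float, present_s: float, absent_s: float
) -> np.ndarray:
    """Alternating exponential present/absent bouts, starting present."""
    mask = np.zeros(n_frames, dtype=bool)
    t, present = 0, True
    while t < n_frames:
        mean = present_s if present else absent_s
        length = max(1, int(round(rng.exponential(mean) * fps)))
        if present:
            mask[t : t + length] = True
        t += length
        present = not present
    return mask


def _excursion_schedule(
    timeline: Timeline, n_frames: int, fps: float, model: MotionModel, base: float
) -> np.ndarray:
    """Per-frame excursion scale: boosted during away-from-table presses."""
    s_x = np.full(n_frames, base)
    if model.active_excursion_boost == 1.0:
        return s_x
    times = np.arange(n_frames) / fps
    for seg in timeline.segments:
        if seg.name in model.active_activities:
            mask = (times >= seg.start) & (times < seg.end)
            s_x[mask] = base * model.active_excursion_boost
    return s_x


def generate_child_stream(
    score: int,
    timeline: Timeline,
    model: MotionModel,
    fps: float,
    seed: int | np.random.SeedSequence,
    wrist_jitter_scale: float | None = None,
    hip_smoothing: float | None = None,
    resolution: tuple[int, int] = DEFAULT_META.resolution,
) -> ChildStream:
    """Generate one child's skeleton per frame over the whole timeline.

    Keypoints 1 (neck), 4 (right wrist) and 8 (mid hip) are populated; the
    remaining BODY_25 slots are zero-confidence placeholders.  Each of the
    three keypoints independently drops out (confidence 0) with probability
    ``model.missingness_prob`` per frame.
    """
    if score not in model.excursion_scale_by_score:
        raise ValueError(
            f"unknown score level {score}; model defines {model.scores()}"
        )
    if not timeline.segments:
        raise ValueError("timeline must contain at least one segment")
    rng = np.random.default_rng(seed)
    n_frames = int(math.ceil(timeline.end * fps))
    s_x = _excursion_schedule(
        timeline, n_frames, fps, model, model.excursion_scale_by_score[score]
    )
    s_d = np.full(n_frames, model.step_scale_by_score[score])
    body = np.asarray(model.home_position) + _ar1_path(rng, n_frames, s_x, s_d)
    body = _reflect_into_frame(body, resolution, model.frame_margin)

    if wrist_jitter_scale is None:
        wrist_jitter_scale = model.wrist_jitter_scale
    # Wrist fidget: AR(1) with negative lag-1 correlation and stationary SD
    # equal to the per-child fidget scale.
    phi_j = model.wrist_jitter_phi
    eps = rng.standard_normal((n_frames, 2)) * (
        wrist_jitter_scale * math.sqrt(max(0.0, 1.0 - phi_j**2))
    )
    wrist_jitter = np.empty((n_frames, 2))
    cur = np.zeros(2)
    for t in range(n_frames):
        cur = phi_j * cur + eps[t]
        wrist_jitter[t] = cur
    jitter = {
        NECK: rng.standard_normal((n_frames, 2)) * model.body_jitter_scale,
        RIGHT_WRIST: wrist_jitter,
        MID_HIP: rng.standard_normal((n_frames, 2)) * model.body_jitter_scale,
    }
    if hip_smoothing is None:
        hip_smoothing = float(np.mean(model.hip_smoothing_range))
    hip_body = np.empty_like(body)
    cur = body[0].copy()
    for t in range(n_frames):
        cur = (1.0 - hip_smoothing) * cur + hip_smoothing * body[t]
        hip_body[t] = cur
    positions = {NECK: body, RIGHT_WRIST: body, MID_HIP: hip_body}
    # Fixed anatomical offsets from the neck, in image coordinates.
    offsets = {NECK: (0.0, 0.0), RIGHT_WRIST: (40.0, 30.0), MID_HIP: (0.0, 60.0)}
    missing = rng.random((n_frames, len(ANALYSIS_KEYPOINTS))) < model.missingness_prob
    conf_draw = rng.uniform(0.5, 1.0, size=(n_frames, len(ANALYSIS_KEYPOINTS)))

    kp = np.zeros((n_frames, N_KEYPOINTS, 3))
    for k, idx in enumerate(ANALYSIS_KEYPOINTS):
        kp[:, idx, 0:2] = positions[idx] + np.asarray(offsets[idx]) + jitter[idx]
        kp[:, idx, 2] = conf_draw[:, k]
        kp[missing[:, k], idx, :] = 0.0
    frames = [
        KeypointFrame(frame_index=t, time=t / fps, people=[PersonDetection(kp[t])])
        for t in range(n_frames)
    ]
    truth = [[CHILD_LABEL] for _ in range(n_frames)]
    return ChildStream(frames=frames, truth=truth)


def generate_distractors(
    model: MotionModel,
    n_frames: int,
    seed: int | np.random.SeedSequence,
    fps: float = 10.0,
    resolution: tuple[int, int] = DEFAULT_META.resolution,
) -> tuple[list[list[PersonDetection]], list[list[str]]]:
    """Generate one slow-moving skeleton per distractor station per frame.

    Each distractor is only intermittently detectable (alternating
    exponential bouts), as bystanders drift behind furniture or out of view.
    """
    rng = np.random.default_rng(seed)
    people: list[list[PersonDetection]] = [[] for _ in range(n_frames)]
    labels: list[list[str]] = [[] for _ in range(n_frames)]
    offsets = {NECK: (0.0, 0.0), RIGHT_WRIST: (-40.0, 30.0), MID_HIP: (0.0, 60.0)}
    for d, station in enumerate(model.distractor_stations):
        s_x = np.full(n_frames, model.distractor_excursion_scale)
        s_d = np.full(n_frames, model.distractor_step_scale)
        body = np.asarray(station, dtype=float) + _ar1_path(rng, n_frames, s_x, s_d)
        body = _reflect_into_frame(body, resolution, model.frame_margin)
        present = _presence_mask(
            rng,
            n_frames,
            fps,
            model.distractor_present_bout_s,
            model.distractor_absent_bout_s,
        )
        missing = rng.random((n_frames, len(ANALYSIS_KEYPOINTS))) < model.missingness_prob
        conf_draw = rng.uniform(0.5, 1.0, size=(n_frames, len(ANALYSIS_KEYPOINTS)))
        kp = np.zeros((n_frames, N_KEYPOINTS, 3))
        for k, idx in enumerate(ANALYSIS_KEYPOINTS):
            kp[:, idx, 0:2] = body + np.asarray(offsets[idx])
            kp[:, idx, 2] = conf_draw[:, k]
            kp[missing[:, k], idx, :] = 0.0
        label = f"distractor_{d}"
        for t in np.flatnonzero(present):
            people[t].append(PersonDetection(kp[t]))
            labels[t].append(label)
    return people, labels


def merge_scene(
    child: ChildStream,
    distractor_people: list[list[PersonDetection]],
    distractor_labels: list[list[str]],
    seed: int | np.random.SeedSequence,
) -> ChildStream:
    """Interleave child and distractor skeletons in a per-frame random order,
    as a multi-person pose detector would emit them."""
    rng = np.random.default_rng(seed)
    n = len(child.frames)
    counts = np.array(
        [len(child.frames[t].people) + len(distractor_people[t]) for t in range(n)]
    )
    orders = np.argsort(rng.random((n, counts.max() if n else 0)), axis=1)
    frames: list[KeypointFrame] = []
    truth: list[list[str]] = []
    for t, frame in enumerate(child.frames):
        people = list(frame.people) + list(distractor_people[t])
        labels = list(child.truth[t]) + list(distractor_labels[t])
        order = [i for i in orders[t] if i < counts[t]]
        frames.append(
            KeypointFrame(
                frame_index=frame.frame_index,
                time=frame.time,
                people=[people[i] for i in order],
            )
        )
        truth.append([labels[i] for i in order])
    return ChildStream(frames=frames, truth=truth)


def generate_scene(
    score: int,
    timeline: Timeline,
    model: MotionModel,
    fps: float,
    seed: int | np.random.SeedSequence,
    wrist_jitter_scale: float | None = None,
    hip_smoothing: float | None = None,
) -> ChildStream:
    """One child plus the model's distractors, merged into a single stream."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_ss, distract_ss, merge_ss = ss.spawn(3)
    child = generate_child_stream(
        score,
        timeline,
        model,
        fps,
        child_ss,
        wrist_jitter_scale=wrist_jitter_scale,
        hip_smoothing=hip_smoothing,
    )
    if not model.distractor_stations:
        return child
    people, labels = generate_distractors(
        model, len(child.frames), distract_ss, fps=fps
    )
    return merge_scene(child, people, labels, merge_ss)


# ---------------------------------------------------------------------------
# timelines and cohorts


def default_timeline(
    duration_scale: float = 0.1,
    rng: np.random.Generator | None = None,
) -> Timeline:
    """The default session timeline at the given timing scale.

    With ``rng`` given, each activity's duration is drawn from a normal
    distribution around its scaled mean (SD scaled likewise, truncated at 30%
    of the mean); otherwise the scaled means are used exactly.  Activities run
    back to back; the table-based composite is materialised.
    """
    segments = []
    t = 0.0
    for name in DEFAULT_ACTIVITY_ORDER:
        mean_min, sd_min = FULL_SCALE_DURATIONS_MIN[name]
        mean_s = mean_min * 60.0 * duration_scale
        if rng is None:
            dur = mean_s
        else:
            dur = float(rng.normal(mean_s, sd_min * 60.0 * duration_scale))
            dur = max(dur, 0.3 * mean_s)
        segments.append(ActivitySegment(name, t, t + dur))
        t += dur
    return Timeline(segments).with_table_play()


def generate_cohort(spec: CohortSpec, model: MotionModel | None = None) -> SyntheticCohort:
    """Generate a full cohort: streams, per-child timelines and score table.

    Per-child randomness is spawned deterministically from ``spec.seed`` and
    the child index, so cohorts are reproducible and children independent.
    """
    if model is None:
        model = MotionModel()
    for score in spec.group_sizes:
        if score not in model.excursion_scale_by_score:
            raise ValueError(f"model defines no scales for score {score}")
    root = np.random.SeedSequence(spec.seed)
    score_assignment: list[int] = []
    for score in sorted(spec.group_sizes):
        score_assignment.extend([score] * spec.group_sizes[score])

    streams: dict[str, ChildStream] = {}
    timelines: dict[str, Timeline] = {}
    scores: list[ScoreRecord] = []
    for i, score in enumerate(score_assignment):
        child_id = f"child_{i:03d}"
        child_root = np.random.SeedSequence(entropy=spec.seed, spawn_key=(i,))
        timeline_ss, jitter_ss, scene_ss = child_root.spawn(3)
        if spec.timeline_template is not None:
            timeline = spec.timeline_template
        else:
            timeline = default_timeline(
                spec.duration_scale, np.random.default_rng(timeline_ss)
            )
        jitter_rng = np.random.default_rng(jitter_ss)
        wjs = float(
            model.wrist_jitter_scale
            * np.exp(jitter_rng.normal(0.0, model.wrist_jitter_sigma))
        )
        alpha = float(jitter_rng.uniform(*model.hip_smoothing_range))
        streams[child_id] = generate_scene(
            score,
            timeline,
            model,
            spec.fps,
            scene_ss,
            wrist_jitter_scale=wjs,
            hip_smoothing=alpha,
        )
        timelines[child_id] = timeline
        scores.append(ScoreRecord(child_id=child_id, activity_level_score=score))
    meta = VideoMeta(fps=spec.fps, origin_a=DEFAULT_META.origin_a, resolution=DEFAULT_META.resolution)
    return SyntheticCohort(
        streams=streams,
        timelines=timelines,
        scores=scores,
        meta=meta,
        spec=spec,
        model=model,
    )
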