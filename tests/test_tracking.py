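import dataclasses

import numpy as np
import pytest

from playmotion.io import NECK, KeypointFrame, PersonDetection
from playmotion.synth import (
    DEFAULT_META,
    MotionModel,
    default_timeline,
    generate_child_stream,
    generate_scene,
)
from playmotion.tracking import (
    DEFAULT_GATE_FRACTION,
    FilterParams,
    filter_stream,
    mismatch_rate,
)


def person_at(x, y, conf=0.9):
    kp = np.zeros((25, 3))
    kp[NECK] = [x, y, conf]
    return kp


def frames_from_positions(positions):
    """positions[t] is a list of (x, y, conf) necks for frame t."""
    frames = []
    for t, people in enumerate(positions):
        frames.append(
            KeypointFrame(
                frame_index=t,
                time=t / 10.0,
                people=[PersonDetection(person_at(*p)) for p in people],
            )
        )
    return frames


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FilterParams(gate_radius=0, init_position=(0, 0))
    with pytest.raises(ValueError):
        FilterParams(gate_radius=10, init_position=(0, 0), max_gap=-1)
    with pytest.raises(ValueError):
        FilterParams(gate_radius=10, init_position=(0, 0), min_confidence=2.0)


def test_for_video_scales_gate_to_diagonal():
    params = FilterParams.for_video(DEFAULT_META)
    assert params.gate_radius == pytest.approx(DEFAULT_GATE_FRACTION * DEFAULT_META.diagonal)
    assert params.init_position == DEFAULT_META.origin_a


def test_empty_stream_rejected():
    with pytest.raises(ValueError):
        filter_stream([], FilterParams(gate_radius=10, init_position=(0, 0)))


def test_selects_nearest_candidate_and_follows_it():
    positions = [
        [(100, 100), (400, 400)],
        [(105, 101), (401, 399)],
        [(111, 99), (402, 401)],
    ]
    params = FilterParams(gate_radius=50, init_position=(100, 100))
    trajs, record = filter_stream(frames_from_positions(positions), params)
    assert list(record.selected) == [0, 0, 0]
    assert np.array_equal(trajs[NECK].xy[:, 0], [100, 105, 111])


def test_gate_rejects_large_jump():
    positions = [[(100, 100)], [(300, 300)]]
    params = FilterParams(gate_radius=50, init_position=(100, 100))
    _, record = filter_stream(frames_from_positions(positions), params)
    assert list(record.selected) == [0, -1]
    assert list(record.gap_flag) == [False, True]


def test_low_confidence_neck_is_not_a_candidate():
    positions = [[(100, 100)], [(101, 100, 0.05)]]
    params = FilterParams(gate_radius=50, init_position=(100, 100), min_confidence=0.1)
    _, record = filter_stream(frames_from_positions(positions), params)
    assert list(record.selected) == [0, -1]


def test_reinitialises_after_long_gap():
    # Child at (100,100), vanishes, then someone appears near init position
    # while a far person is also present: re-init must pick the near one
    # even though the far one was never gated out by the stale anchor.
    positions = [[(100, 100)]] + [[]] * 5 + [[(500, 500), (102, 98)]]
    params = FilterParams(gate_radius=50, init_position=(100, 100), max_gap=3)
    trajs, record = filter_stream(frames_from_positions(positions), params)
    assert record.selected[0] == 0
    assert all(record.gap_flag[1:6])
    assert record.selected[6] == 1  # nearest to init_position, gate waived
    assert trajs[NECK].frames[-1] == 6


def test_short_gap_keeps_anchor():
    # Track moves to (140,100), drops for one frame, then two candidates
    # appear: one near the last anchor, one near the initial position.  A
    # short gap must keep the moved anchor, not reset to init_position.
    positions = [[(100, 100)], [(140, 100)], [], [(144, 100), (100, 100)]]
    params = FilterParams(gate_radius=50, init_position=(100, 100), max_gap=3)
    _, record = filter_stream(frames_from_positions(positions), params)
    assert list(record.selected) == [0, 0, -1, 0]


def test_all_gaps_flag():
    positions = [[(500, 500, 0.05)], []]
    params = FilterParams(gate_radius=50, init_position=(0, 0))
    _, record = filter_stream(frames_from_positions(positions), params)
    assert record.all_gaps
    with pytest.raises(ValueError):
        mismatch_rate(record, [["child"], []])


def test_selection_record_to_frame():
    positions = [[(100, 100)], [(101, 101)]]
    params = FilterParams(gate_radius=50, init_position=(100, 100))
    _, record = filter_stream(frames_from_positions(positions), params)
    df = record.to_frame()
    assert list(df.columns) == [
        "frame_index",
        "selected_person_index",
        "distance",
        "gap_flag",
    ]
    assert len(df) == 2


def test_far_distractors_recover_ground_truth_exactly():
    # With distractors stationed far from the child's seat, every selected
    # frame is the child and the neck trajectory equals the child's own.
    tl = default_timeline(0.05)
    model = dataclasses.replace(
        MotionModel(),
        excursion_scale_by_score={0: 20, 1: 20, 2: 20},
        step_scale_by_score={0: 6, 1: 6, 2: 6},
    )
    child_ss = np.random.SeedSequence(99).spawn(3)[0]
    child_only = generate_child_stream(1, tl, model, 10.0, child_ss)
    scene = generate_scene(1, tl, model, 10.0, np.random.SeedSequence(99))
    params = FilterParams.for_video(DEFAULT_META, init_position=model.home_position)
    trajs, record = filter_stream(scene.frames, params)
    assert mismatch_rate(record, scene.truth, n_audit=10_000, seed=0) == 0.0
    truth_neck = {
        f.frame_index: f.people[0].keypoints[NECK, :2]
        for f in child_only.frames
        if f.people[0].keypoints[NECK, 2] > 0
    }
    for frame_idx, xy in zip(trajs[NECK].frames, trajs[NECK].xy):
        assert np.allclose(xy, truth_neck[int(frame_idx)])


def test_distractor_overlapping_seat_causes_mismatches():
    # A distractor parked on the child's seat with child-scale motion must
    # produce identity errors somewhere across seeds.
    tl = default_timeline(0.05)
    model = dataclasses.replace(
        MotionModel(),
        distractor_stations=[MotionModel().home_position],
        distractor_excursion_scale=60.0,
        distractor_step_scale=18.0,
        distractor_absent_bout_s=2.0,
    )
    params = FilterParams.for_video(DEFAULT_META, init_position=model.home_position)
    rates = []
    for seed in range(5):
        scene = generate_scene(1, tl, model, 10.0, seed)
        _, record = filter_stream(scene.frames, params)
        rates.append(mismatch_rate(record, scene.truth, n_audit=10_000, seed=seed))
    assert max(rates) > 0.0


def test_mismatch_rate_is_deterministic_and_bounded():
    positions = [[(100, 100)], [(101, 101)], [(102, 102)]]
    params = FilterParams(gate_radius=50, init_position=(100, 100))
    _, record = filter_stream(frames_from_positions(positions), params)
    truth = [["child"], ["distractor_0"], ["child"]]
    r1 = mismatch_rate(record, truth, n_audit=2, seed=123)
    r2 = mismatch_rate(record, truth, n_audit=2, seed=123)
    assert r1 == r2 and 0.0 <= r1 <= 1.0
    # n_audit beyond the number of selections audits everything.
    assert mismatch_rate(record, truth, n_audit=100, seed=0) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        mismatch_rate(record, truth, n_audit=0)
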