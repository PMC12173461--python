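"""Behavioral quantification: laps, freezing, metrics, shock response."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vrcfc.behavior import (
    BehaviorSession,
    SessionValidationError,
    detect_freezing,
    discrimination_delta,
    freezing_epochs,
    segment_laps,
    session_metrics,
    shock_response,
)
from vrcfc.simulate.behavior import (
    BehaviorSimParams,
    freeze_fraction_to_rates,
    simulate_session,
)

from conftest import make_ramp_session


# ---------------------------------------------------------------------------
# session validation
# ---------------------------------------------------------------------------

def test_minimal_session_is_valid():
    ses = BehaviorSession(
        frame_time=np.array([0.0, 1 / 30, 2 / 30]),
        position=np.array([0.0, 5.0, 10.0]),
        velocity=np.array([150.0, 150.0, 150.0]),
    )
    assert ses.n_frames == 3
    assert len(ses.events) == 0
    assert ses.frame_rate == pytest.approx(30.0)


def test_non_monotone_time_names_offending_frame():
    t = np.arange(20) / 30.0
    t[10] = t[9] - 0.01
    with pytest.raises(SessionValidationError, match="frame 10"):
        BehaviorSession(frame_time=t, position=np.zeros(20),
                        velocity=np.zeros(20))


def test_position_outside_track_rejected():
    with pytest.raises(SessionValidationError, match="position"):
        BehaviorSession(
            frame_time=np.array([0.0, 0.1]),
            position=np.array([0.0, 250.0]),
            velocity=np.zeros(2),
        )


# ---------------------------------------------------------------------------
# lap segmentation
# ---------------------------------------------------------------------------

def test_three_ramps_give_three_laps():
    ses = make_ramp_session(n_laps=3)
    laps = segment_laps(ses)
    assert laps.n_laps == 3
    assert list(laps.laps["is_first_lap"]) == [True, False, False]
    # lap duration excludes the teleport pause
    assert laps.laps["duration_s"].iloc[0] == pytest.approx(89 / 30.0)
    # pause frames belong to no lap
    assert (laps.frame_lap == -1).sum() == 3 * 45


def test_no_position_change_gives_empty_lap_table():
    ses = BehaviorSession(
        frame_time=np.arange(100) / 30.0,
        position=np.full(100, 50.0),
        velocity=np.zeros(100),
    )
    laps = segment_laps(ses)
    assert laps.n_laps == 0
    assert laps.incomplete is not None


def test_incomplete_final_traversal_not_a_lap():
    ses = make_ramp_session(n_laps=2)
    # append a half traversal
    half = np.linspace(0, 90, 40)
    pos = np.concatenate([ses.position, half])
    vel = np.concatenate([ses.velocity, np.full(40, 60.0)])
    t = np.arange(pos.size) / 30.0
    ses2 = BehaviorSession(frame_time=t, position=pos, velocity=vel)
    laps = segment_laps(ses2)
    assert laps.n_laps == 2
    assert laps.incomplete is not None
    assert laps.incomplete["max_position"] == pytest.approx(90.0)


def test_training_criterion_laps_per_minute():
    # 31 completed laps in a 10-minute session -> 3.1 laps/min, meeting
    # the >3 laps-per-minute training criterion
    frames_per_lap = int(600 * 30 / 31) - 45
    ses = make_ramp_session(n_laps=31, frames_per_lap=frames_per_lap)
    laps = segment_laps(ses)
    mask = detect_freezing(ses)
    m = session_metrics(ses, laps, mask)
    assert m.n_laps == 31
    assert m.laps_per_minute == pytest.approx(31 / (ses.duration / 60.0))
    assert m.laps_per_minute > 3.0


def _brute_force_lap_count(pos, track_length=200.0, tol=0.5):
    """Single-pass scan: count first end-reach per traversal, reset on
    teleport (large negative jump)."""
    count = 0
    reached = False
    for i in range(len(pos)):
        if i and pos[i] - pos[i - 1] < -track_length / 2:
            reached = False
        if not reached and pos[i] >= track_length - tol:
            count += 1
            reached = True
    return count


@pytest.mark.parametrize("seed", range(5))
def test_lap_count_matches_brute_force_on_random_sessions(seed):
    params = BehaviorSimParams(session_duration=120.0, seed=seed)
    ses, _ = simulate_session(params)
    laps = segment_laps(ses)
    assert laps.n_laps == _brute_force_lap_count(ses.position, ses.track_length)


def test_lap_count_invariant_to_time_rescaling():
    ses = make_ramp_session(n_laps=4)
    scaled = BehaviorSession(
        frame_time=ses.frame_time * 2.0,
        position=ses.position,
        velocity=ses.velocity / 2.0,
        frame_rate=15.0,
    )
    laps, laps2 = segment_laps(ses), segment_laps(scaled)
    assert laps.n_laps == laps2.n_laps
    assert np.allclose(
        laps2.laps["duration_s"], 2.0 * laps.laps["duration_s"]
    )


# ---------------------------------------------------------------------------
# freezing detection and epochs
# ---------------------------------------------------------------------------

def test_all_zero_velocity_is_all_freezing():
    ses = BehaviorSession(
        frame_time=np.arange(10) / 30.0,
        position=np.zeros(10), velocity=np.zeros(10),
    )
    assert detect_freezing(ses).all()


def test_backward_movement_is_not_freezing():
    ses = BehaviorSession(
        frame_time=np.arange(5) / 30.0,
        position=np.full(5, 10.0),
        velocity=np.array([0.0, 0.2, 0.0, -3.0, 0.0]),
    )
    assert detect_freezing(ses, epsilon=0.0).tolist() == [
        True, False, True, False, True,
    ]


def test_negative_epsilon_rejected():
    ses = make_ramp_session(1)
    with pytest.raises(ValueError):
        detect_freezing(ses, epsilon=-0.1)


@given(
    v=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=200),
    eps=st.floats(0, 0.5),
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_freezing_mask_equals_elementwise_oracle(v, eps):
    v = np.asarray(v)
    ses = BehaviorSession(
        frame_time=np.arange(v.size) / 30.0,
        position=np.zeros(v.size), velocity=v,
    )
    mask = detect_freezing(ses, eps)
    oracle = np.array([abs(x) <= eps for x in v])
    assert np.array_equal(mask, oracle)


def test_epoch_boundary_is_strict_at_one_second():
    # 30 true frames at 30 Hz is exactly 1.0 s -> not an epoch;
    # 31 frames (1.033 s) is
    assert freezing_epochs(np.ones(30, bool), 30.0, 1.0) == []
    eps = freezing_epochs(np.ones(31, bool), 30.0, 1.0)
    assert len(eps) == 1
    assert eps[0].duration == pytest.approx(31 / 30.0)


def test_all_false_mask_gives_no_epochs():
    assert freezing_epochs(np.zeros(100, bool), 30.0, 1.0) == []


def _rle_epoch_oracle(mask, frame_rate, min_duration):
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        if not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return [
        (s, e) for s, e in runs if (e - s + 1) / frame_rate > min_duration
    ]


@given(mask=st.lists(st.booleans(), min_size=0, max_size=300))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_epochs_match_rle_oracle(mask):
    mask = np.array(mask, dtype=bool)
    got = [(e.start_frame, e.end_frame)
           for e in freezing_epochs(mask, 30.0, 0.2)]
    assert got == _rle_epoch_oracle(mask, 30.0, 0.2)


@given(mask=st.lists(st.booleans(), min_size=1, max_size=100),
       pad=st.integers(0, 20))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_epochs_invariant_to_false_padding(mask, pad):
    mask = np.array(mask, dtype=bool)
    padded = np.r_[np.zeros(pad, bool), mask, np.zeros(pad, bool)]
    base = [(e.start_frame, e.end_frame, e.duration)
            for e in freezing_epochs(mask, 30.0, 0.1)]
    shifted = [(e.start_frame - pad, e.end_frame - pad, e.duration)
               for e in freezing_epochs(padded, 30.0, 0.1)]
    assert base == shifted


# ---------------------------------------------------------------------------
# session metrics
# ---------------------------------------------------------------------------

def test_freezing_pct_formula():
    # one lap of 300 frames with 30 freezing frames -> 10%
    vel = np.full(300, 20.0)
    vel[100:130] = 0.0
    pos = np.clip(np.cumsum(vel) / 30.0 * (200.0 / (np.sum(vel) / 30.0)), 0, 200)
    pos[-1] = 200.0
    ses = BehaviorSession(
        frame_time=np.arange(300) / 30.0, position=pos, velocity=vel
    )
    laps = segment_laps(ses)
    assert laps.n_laps == 1
    m = session_metrics(ses, laps, detect_freezing(ses))
    assert m.first_lap_freezing_pct == pytest.approx(10.0)
    # single-lap session: averages equal first-lap values
    assert m.avg_freezing_pct == m.first_lap_freezing_pct
    assert m.avg_lap_time == m.first_lap_time


def test_zero_laps_flagged_undefined_not_zero():
    ses = BehaviorSession(
        frame_time=np.arange(50) / 30.0,
        position=np.full(50, 10.0), velocity=np.zeros(50),
    )
    m = session_metrics(ses, segment_laps(ses), detect_freezing(ses))
    assert not m.defined
    assert np.isnan(m.avg_freezing_pct)


def test_metrics_recover_simulator_ground_truth():
    p_rf, p_fr = freeze_fraction_to_rates(0.25)
    params = BehaviorSimParams(
        session_duration=600.0, p_run_to_freeze=p_rf,
        p_freeze_to_run=p_fr, seed=42,
    )
    ses, gt = simulate_session(params)
    m = session_metrics(ses, segment_laps(ses), detect_freezing(ses))
    assert m.total_freezing_pct == pytest.approx(
        100.0 * gt.freezing_fraction, abs=1.0
    )


def test_lap_freezing_frames_bounded_by_mask_total():
    ses, _ = simulate_session(BehaviorSimParams(session_duration=120.0, seed=3))
    mask = detect_freezing(ses)
    m = session_metrics(ses, segment_laps(ses), mask)
    if m.defined:
        assert m.per_lap["freezing_frames"].sum() <= mask.sum()


# ---------------------------------------------------------------------------
# discrimination delta and shock response
# ---------------------------------------------------------------------------

def _metrics_with(avg):
    from vrcfc.behavior import SessionMetrics

    return SessionMetrics(avg, avg, avg, 10.0, 10.0, 5, 2.0, True)


@pytest.mark.parametrize(
    "a,b,expected",
    [(21.15, 20.54, 0.61), (10.0, 10.0, 0.0), (3.0, 7.5, -4.5)],
)
def test_discrimination_delta_is_signed_difference(a, b, expected):
    assert discrimination_delta(
        _metrics_with(a), _metrics_with(b)
    ) == pytest.approx(expected)


def test_discrimination_delta_propagates_undefined():
    from vrcfc.behavior import SessionMetrics

    undef = SessionMetrics(*([np.nan] * 5), 0, np.nan, False)
    assert np.isnan(discrimination_delta(_metrics_with(5.0), undef))


def test_constant_velocity_session_not_shock_responsive():
    ses = BehaviorSession(
        frame_time=np.arange(900) / 30.0,
        position=np.zeros(900),
        velocity=np.full(900, 10.0),
        events=pd.DataFrame({"frame": [450], "kind": ["shock"]}),
    )
    resp = shock_response(ses, window=5.0)
    assert resp.per_shock["diff"].abs().max() == pytest.approx(0.0)
    assert not resp.responsive


def test_six_shocks_at_one_minute_spacing_all_recorded():
    # the conditioning protocol: six 1 s shocks at 60 s intervals after
    # a 10-minute exploration block
    shock_times = tuple(600.0 + 60.0 * k for k in range(6))
    params = BehaviorSimParams(
        session_duration=1020.0, shock_times=shock_times, seed=0,
    )
    ses, _ = simulate_session(params)
    resp = shock_response(ses, window=5.0)
    assert len(resp.per_shock) == 6
    assert resp.n_excluded == 0
    assert resp.responsive


def test_shock_near_session_edge_excluded_with_count():
    params = BehaviorSimParams(
        session_duration=60.0, shock_times=(1.0, 30.0), seed=0,
    )
    ses, _ = simulate_session(params)
    resp = shock_response(ses, window=5.0)
    assert resp.n_excluded == 1
    assert len(resp.per_shock) == 1


def test_shock_sprint_amplitude_recovered_within_20pct():
    amp = 20.0
    params = BehaviorSimParams(
        session_duration=600.0,
        shock_times=tuple(60.0 + 60.0 * k for k in range(6)),
        shock_sprint_amplitude=amp,
        shock_sprint_decay=2.0,
        seed=11,
    )
    ses, _ = simulate_session(params)
    resp = shock_response(ses, window=5.0)
    # mean of the decaying sprint over the 5 s post window
    expected = amp * 2.0 / 5.0 * (1 - np.exp(-5.0 / 2.0))
    assert resp.per_shock["diff"].mean() == pytest.approx(
        expected, rel=0.2
    )
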