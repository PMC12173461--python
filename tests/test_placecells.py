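"""Spatial binning, transient detection and field criteria/parameters."""

import numpy as np
import pandas as pd
import pytest

from vrcfc.behavior import BehaviorSession, segment_laps
from vrcfc.placecells import (
    CalciumTraceSet,
    bin_activity,
    bootstrap_field_test,
    candidate_fields,
    detect_place_fields,
    detect_transients,
    field_criteria,
    field_parameters,
    place_cell_fraction,
    position_bins,
)

from conftest import make_ramp_session


def _traces(session, dff):
    return CalciumTraceSet(dff, np.arange(dff.shape[0]), session)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_bin_index_convention():
    # half-open 5 cm bins, last bin closed at the track end
    pos = np.array([0.0, 4.999, 5.0, 7.5, 199.9, 200.0])
    assert position_bins(pos, 200.0, 40).tolist() == [0, 0, 1, 1, 39, 39]


def test_constant_dff_fills_every_observed_bin_with_constant():
    ses = make_ramp_session(n_laps=4)
    laps = segment_laps(ses)
    dff = np.full((2, ses.n_frames), 3.5)
    sam = bin_activity(_traces(ses, dff), laps)
    observed = np.isfinite(sam.map)
    assert observed.any()
    assert np.allclose(sam.map[observed], 3.5)
    # occupancy counts every speed-included frame exactly once per lap
    included = (laps.frame_lap >= 0) & (np.abs(ses.velocity) >= 1.0)
    assert sam.occupancy.sum() == included.sum()


def test_bin_activity_matches_brute_force_loop():
    rng = np.random.default_rng(0)
    ses = make_ramp_session(n_laps=3, frames_per_lap=120)
    # jitter velocities so some frames fall below the speed threshold
    vel = ses.velocity.copy()
    vel[rng.random(vel.size) < 0.2] = 0.5
    ses = BehaviorSession(
        frame_time=ses.frame_time, position=ses.position, velocity=vel,
        frame_rate=30.0,
    )
    laps = segment_laps(ses)
    dff = rng.normal(size=(3, ses.n_frames))
    sam = bin_activity(_traces(ses, dff), laps, n_bins=40)
    bins = position_bins(ses.position, 200.0, 40)
    for c in range(3):
        for l in range(laps.n_laps):
            for b in range(40):
                sel = (
                    (laps.frame_lap == l)
                    & (bins == b)
                    & (np.abs(ses.velocity) >= 1.0)
                )
                if sel.any():
                    assert sam.map[c, l, b] == pytest.approx(
                        dff[c, sel].mean()
                    )
                else:
                    assert np.isnan(sam.map[c, l, b])


def test_binning_ignores_immobile_frame_values():
    ses = make_ramp_session(n_laps=3)
    laps = segment_laps(ses)
    rng = np.random.default_rng(1)
    dff = rng.normal(size=(2, ses.n_frames))
    sam1 = bin_activity(_traces(ses, dff), laps)
    immobile = np.abs(ses.velocity) < 1.0
    dff2 = dff.copy()
    dff2[:, immobile] = rng.normal(scale=100.0, size=(2, immobile.sum()))
    sam2 = bin_activity(_traces(ses, dff2), laps)
    assert np.array_equal(sam1.map, sam2.map, equal_nan=True)


def test_misaligned_traces_rejected():
    ses = make_ramp_session(1)
    with pytest.raises(ValueError, match="frames"):
        _traces(ses, np.zeros((2, ses.n_frames + 1)))


# ---------------------------------------------------------------------------
# transients
# ---------------------------------------------------------------------------

def _inject(n_frames, onsets, amplitude=1.0, tau=0.5, fr=30.0):
    x = np.zeros(n_frames)
    for t0 in onsets:
        t = np.arange(n_frames - t0)
        x[t0:] += amplitude * np.exp(-t / (tau * fr))
    return x


def test_single_noiseless_transient_detected_at_injection_frame():
    ses = make_ramp_session(n_laps=2)
    x = _inject(ses.n_frames, [100])
    events = detect_transients(_traces(ses, x[None, :]))
    assert len(events) == 1
    assert events["onset"].iloc[0] == 100
    assert events["peak_dff"].iloc[0] == pytest.approx(1.0)


def test_flat_trace_has_no_events():
    ses = make_ramp_session(1)
    events = detect_transients(_traces(ses, np.zeros((1, ses.n_frames))))
    assert len(events) == 0


def test_false_event_rate_on_pure_noise_below_2_percent_per_second():
    rng = np.random.default_rng(2)
    ses = make_ramp_session(n_laps=10, frames_per_lap=300)
    dff = rng.normal(0.0, 0.2, size=(20, ses.n_frames))
    events = detect_transients(_traces(ses, dff), k_sigma=2.0,
                               min_duration=0.5)
    seconds = 20 * ses.n_frames / 30.0
    assert len(events) / seconds < 0.02


def test_onset_recovery_at_snr_4():
    rng = np.random.default_rng(3)
    ses = make_ramp_session(n_laps=10, frames_per_lap=300)
    true_onsets = np.arange(100, ses.n_frames - 200, 400)
    hits = 0
    n_cells = 20
    for c in range(n_cells):
        x = _inject(ses.n_frames, true_onsets, amplitude=0.8)
        x += rng.normal(0.0, 0.2, x.size)  # SNR 4
        events = detect_transients(_traces(ses, x[None, :]))
        got = events["onset"].to_numpy()
        for t0 in true_onsets:
            if got.size and np.min(np.abs(got - t0)) <= 2:
                hits += 1
    assert hits / (n_cells * true_onsets.size) >= 0.95


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------

def test_flat_profile_has_no_candidates():
    assert candidate_fields(np.full(40, 1.0)) == []


def _gaussian_profile(center_cm, sigma_cm, peak=3.0, base=1.0):
    centers = (np.arange(40) + 0.5) * 5.0
    return base + (peak - base) * np.exp(
        -((centers - center_cm) ** 2) / (2 * sigma_cm**2)
    )


def test_single_bump_gives_one_candidate_containing_peak():
    profile = _gaussian_profile(100.0, 10.0)
    cands = candidate_fields(profile)
    assert len(cands) == 1
    s, e = cands[0]
    assert s <= int(np.argmax(profile)) < e


def test_two_bumps_give_two_disjoint_candidates():
    profile = np.maximum(
        _gaussian_profile(50.0, 7.0), _gaussian_profile(150.0, 7.0)
    )
    cands = candidate_fields(profile)
    assert len(cands) == 2
    assert cands[0][1] <= cands[1][0]


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def _lap_maps_from_profile(profile, n_laps=20, noise=0.0, rng=None):
    rng = np.random.default_rng(rng)
    maps = np.tile(profile, (n_laps, 1))
    if noise:
        maps = maps + rng.normal(0.0, noise, maps.shape)
    return maps


def test_reliability_exactly_30pct_is_rejected():
    profile = _gaussian_profile(100.0, 10.0)
    cand = candidate_fields(profile)[0]
    n_laps = 20
    # onsets inside the field on exactly 6/20 = 30% of laps
    mid = (cand[0] + cand[1]) // 2
    onsets = np.array([[l, mid] for l in range(6)])
    decision = field_criteria(
        cand, profile, _lap_maps_from_profile(profile, n_laps),
        onsets, n_laps, n_shuffles=100, rng=0,
    )
    assert not decision.accepted
    assert decision.reason == "criterion2_reliability"
    assert decision.reliability == pytest.approx(0.30)


def test_profile_peaking_at_track_start_rejected_by_rising_phase():
    centers = (np.arange(40) + 0.5) * 5.0
    profile = 3.0 * np.exp(-centers / 40.0) + 1.0  # max at bin 0, decreasing
    cand = candidate_fields(profile)[0]
    assert cand[0] == 0
    n_laps = 20
    onsets = np.array([[l, 1] for l in range(n_laps)])
    decision = field_criteria(
        cand, profile, _lap_maps_from_profile(profile, n_laps),
        onsets, n_laps, n_shuffles=100, rng=0,
    )
    assert not decision.accepted
    assert decision.reason == "criterion3_rising_phase"


def test_reliable_significant_field_accepted():
    profile = _gaussian_profile(100.0, 10.0)
    cand = candidate_fields(profile)[0]
    n_laps = 20
    mid = (cand[0] + cand[1]) // 2
    onsets = np.array([[l, mid] for l in range(16)])  # 80% of laps
    decision = field_criteria(
        cand, profile,
        _lap_maps_from_profile(profile, n_laps, noise=0.2, rng=5),
        onsets, n_laps, n_shuffles=200, rng=0,
    )
    assert decision.accepted
    assert decision.reason is None
    assert decision.boot_p < 0.05


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_perfect_field_reaches_minimum_attainable_p():
    profile = _gaussian_profile(100.0, 10.0)
    maps = _lap_maps_from_profile(profile, n_laps=15)
    cand = candidate_fields(profile)[0]
    res = bootstrap_field_test(maps, cand, n_shuffles=500, rng=0)
    assert res.p == pytest.approx(1.0 / 501.0)


def test_bootstrap_reproducible_from_seed():
    rng_maps = np.random.default_rng(4)
    maps = rng_maps.normal(size=(20, 40))
    a = bootstrap_field_test(maps, (10, 16), n_shuffles=200, rng=42)
    b = bootstrap_field_test(maps, (10, 16), n_shuffles=200, rng=42)
    assert a.p == b.p


def test_candidate_spanning_all_bins_rejected():
    maps = np.ones((10, 40))
    with pytest.raises(ValueError, match="all bins"):
        bootstrap_field_test(maps, (0, 40), n_shuffles=100, rng=0)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def test_symmetric_triangle_com_at_center():
    centers = (np.arange(40) + 0.5) * 5.0
    profile = np.maximum(0.0, 2.0 - np.abs(centers - 100.0) / 20.0)
    cands = candidate_fields(profile)
    cand = max(cands, key=lambda se: se[1] - se[0])
    com, width, out_in, _ = field_parameters(cand, profile, 5.0)
    assert com == pytest.approx(100.0, abs=1e-6)
    assert width >= 5.0


def test_zero_outside_activity_gives_zero_out_in_ratio():
    profile = np.zeros(40)
    profile[18:22] = 2.0
    com, width, out_in, mean_in = field_parameters((18, 22), profile, 5.0)
    assert out_in == 0.0
    assert mean_in == pytest.approx(2.0)


def test_width_floor_is_one_bin():
    profile = np.zeros(40)
    profile[20] = 5.0
    _, width, _, _ = field_parameters((20, 21), profile, 5.0)
    assert width >= 5.0


# ---------------------------------------------------------------------------
# end-to-end detection properties
# ---------------------------------------------------------------------------

def test_detection_equivariant_to_multiplicative_rescaling(imaging_session,
                                                           imaging_laps):
    # criteria 2-4 are rank/ratio-based; criterion 1 is an absolute
    # ΔF/F offset, so rescaling the traces together with that offset
    # must reproduce the identical field table
    from vrcfc.simulate.calcium import CalciumSimParams, simulate_traces

    session, _ = imaging_session
    params = CalciumSimParams(n_cells=20, frac_place_cells=0.5, seed=6)
    traces, _ = simulate_traces(session, params, laps=imaging_laps)
    scaled = CalciumTraceSet(traces.dff * 7.0, traces.cell_ids, session)
    det1 = detect_place_fields(traces, imaging_laps, n_shuffles=200, seed=9)
    det2 = detect_place_fields(scaled, imaging_laps, min_dff=0.7,
                               n_shuffles=200, seed=9)
    cols = ["cell_id", "bin_start", "bin_stop"]
    pd.testing.assert_frame_equal(det1.fields[cols], det2.fields[cols])
    assert np.allclose(det1.fields["com"], det2.fields["com"])
    assert np.allclose(det1.fields["width"], det2.fields["width"])


def test_place_cell_fraction_extremes(imaging_session, imaging_laps):
    from vrcfc.placecells import PlaceFieldResult

    empty = PlaceFieldResult(
        pd.DataFrame(columns=["cell_id"]), pd.DataFrame(), 50
    )
    assert place_cell_fraction(empty) == 0.0
    full = PlaceFieldResult(
        pd.DataFrame({"cell_id": np.arange(50)}), pd.DataFrame(), 50
    )
    assert place_cell_fraction(full) == 100.0
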