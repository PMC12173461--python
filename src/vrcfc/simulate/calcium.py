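"""Synthetic ΔF/F traces with ground-truth spatial tuning.

Place cells carry a Gaussian spatial gate: on each lap, with
probability ``reliability``, a calcium transient (instantaneous rise to
``amplitude``, exponential decay ``decay_tau`` — GCaMP6f-like
asymmetry) is triggered at a position drawn from the cell's tuning
curve as the mouse crosses it.  Non-place cells emit randomly timed
transients at the same per-lap event rate, so detection cannot separate
the two groups by activity rate alone.  Gaussian noise is added last.

Because the indicator kernel is causal, fluorescence mass trails the
triggering position by roughly run-speed x tau; the ground truth
therefore records both the latent tuning center and the center of mass
/ width that the noise-free binned profile actually has (the quantity
a map-based pipeline can recover without deconvolution).

A paired-session generator copies the tuning into a second session,
reassigns a ``remap_fraction`` subset of place cells to new uniform
centers and rescales all widths by ``width_scale_session2``, modelling
across-day remapping and field narrowing with a known cell-identity
map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ..behavior import BehaviorSession, LapTable, segment_laps
from ..placecells import (
    CalciumTraceSet,
    bin_activity,
    candidate_fields,
    field_parameters,
    position_bins,
)
from .behavior import BehaviorSimParams, simulate_session

__all__ = [
    "CalciumSimParams",
    "GroundTruthTuning",
    "simulate_traces",
    "TwoSessionSim",
    "simulate_two_sessions",
]


@dataclass
class CalciumSimParams:
    """Tuning and kinetics of a simulated cell population.

    ``amplitude / noise_sd`` is the transient SNR (default 5).
    """

    n_cells: int = 100
    frac_place_cells: float = 0.4
    field_sigma: float = 10.0  # cm
    amplitude: float = 1.0  # ΔF/F
    reliability: float = 0.8  # per-lap activation probability
    decay_tau: float = 0.5  # s
    noise_sd: float = 0.2  # ΔF/F
    center_range: tuple[float, float] = (0.0, 200.0)
    n_bins: int = 40
    speed_threshold: float = 1.0  # cm/s
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.frac_place_cells <= 1.0:
            raise ValueError("frac_place_cells must be in [0, 1]")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must be in [0, 1]")
        if self.field_sigma <= 0 or self.decay_tau <= 0:
            raise ValueError("field_sigma and decay_tau must be > 0")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValueError("noise_sd and amplitude must be >= 0")


@dataclass
class GroundTruthTuning:
    """Latent tuning of every simulated cell.

    ``cells`` columns: ``cell, is_place_cell, center, sigma,
    com_noise_free, width_noise_free`` (NaN for non-place cells).
    ``activation`` is the (cells x laps) boolean matrix of per-lap
    activation outcomes.
    """

    cells: pd.DataFrame
    activation: np.ndarray


def _noise_free_field_summary(
    clean: np.ndarray,
    session: BehaviorSession,
    laps: LapTable,
    params: CalciumSimParams,
    centers: np.ndarray,
    is_place: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """COM and width of the noise-free binned profile of each place cell."""
    traces = CalciumTraceSet(clean, np.arange(clean.shape[0]), session)
    sam = bin_activity(traces, laps, params.n_bins, params.speed_threshold)
    profiles = sam.mean_profiles()
    com = np.full(clean.shape[0], np.nan)
    width = np.full(clean.shape[0], np.nan)
    for c in np.nonzero(is_place)[0]:
        profile = profiles[c]
        if not np.any(np.isfinite(profile)):
            continue
        cands = candidate_fields(profile)
        if not cands:
            continue
        center_bin = int(
            position_bins(np.array([centers[c]]), session.track_length,
                          params.n_bins)[0]
        )
        # the candidate containing the tuning center, else the strongest
        chosen = None
        for cand in cands:
            if cand[0] <= center_bin < cand[1]:
                chosen = cand
                break
        if chosen is None:
            chosen = max(
                cands, key=lambda se: np.nanmean(profile[se[0]:se[1]])
            )
        com[c], width[c], _, _ = field_parameters(
            chosen, profile, sam.bin_width
        )
    return com, width


def simulate_traces(
    session: BehaviorSession,
    params: CalciumSimParams,
    rng: np.random.Generator | None = None,
    laps: LapTable | None = None,
    tuning: pd.DataFrame | None = None,
) -> tuple[CalciumTraceSet, GroundTruthTuning]:
    """Simulate a ΔF/F trace set aligned to ``session``.

    ``tuning`` optionally fixes per-cell ``is_place_cell, center,
    sigma`` (used by the paired-session generator); otherwise place
    cells are assigned uniform random centers.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if laps is None:
        laps = segment_laps(session)
    if laps.n_laps < 5:
        raise ValueError("behavior must contain >= 5 laps for reliability")
    n, n_laps = params.n_cells, laps.n_laps
    fr = session.frame_rate

    if tuning is None:
        n_place = int(round(params.frac_place_cells * n))
        is_place = np.zeros(n, dtype=bool)
        is_place[rng.permutation(n)[:n_place]] = True
        lo, hi = params.center_range
        centers = np.where(is_place, rng.uniform(lo, hi, n), np.nan)
        sigmas = np.where(is_place, params.field_sigma, np.nan)
    else:
        is_place = tuning["is_place_cell"].to_numpy(bool)
        centers = tuning["center"].to_numpy(float)
        sigmas = tuning["sigma"].to_numpy(float)

    activation = rng.random((n, n_laps)) < params.reliability
    impulses = np.zeros((n, session.n_frames))
    lap_bounds = list(
        zip(laps.laps["start_frame"].to_numpy(), laps.laps["end_frame"].to_numpy())
    )
    pos = session.position
    running = np.abs(session.velocity) >= params.speed_threshold
    for c in np.nonzero(is_place)[0]:
        for l, (s, e) in enumerate(lap_bounds):
            if not activation[c, l]:
                continue
            x_trig = rng.normal(centers[c], sigmas[c])
            x_trig = float(np.clip(x_trig, 0.5, session.track_length - 0.5))
            seg = pos[s : e + 1]
            hits = np.nonzero(seg >= x_trig)[0]
            if hits.size == 0:
                continue
            impulses[c, s + hits[0]] += params.amplitude
    # non-place cells: Poisson-timed transients at the matched rate
    pool = np.nonzero((laps.frame_lap >= 0) & running)[0]
    for c in np.nonzero(~is_place)[0]:
        n_events = int(rng.binomial(n_laps, params.reliability))
        if n_events and pool.size:
            frames = rng.choice(pool, size=n_events, replace=False)
            np.add.at(impulses[c], frames, params.amplitude)

    a = float(np.exp(-1.0 / (fr * params.decay_tau)))
    clean = lfilter([1.0], [1.0, -a], impulses, axis=1)
    dff = clean + rng.normal(0.0, params.noise_sd, clean.shape) \
        if params.noise_sd > 0 else clean.copy()

    com_nf, width_nf = _noise_free_field_summary(
        clean, session, laps, params, centers, is_place
    )
    cells = pd.DataFrame(
        {
            "cell": np.arange(n),
            "is_place_cell": is_place,
            "center": centers,
            "sigma": sigmas,
            "com_noise_free": com_nf,
            "width_noise_free": width_nf,
        }
    )
    traces = CalciumTraceSet(dff, np.arange(n), session)
    return traces, GroundTruthTuning(cells, activation)


@dataclass
class TwoSessionSim:
    """Paired-session simulation with a ground-truth cell-identity map."""

    traces_a: CalciumTraceSet
    tuning_a: GroundTruthTuning
    traces_b: CalciumTraceSet
    tuning_b: GroundTruthTuning
    match: pd.DataFrame  # columns cell_id_a, cell_id_b
    laps_a: LapTable
    laps_b: LapTable


DEFAULT_IMAGING_BEHAVIOR = BehaviorSimParams(
    session_duration=420.0,  # ~25-28 laps at well-trained running speed
    p_run_to_freeze=0.001,
    backward_prob=0.005,
)


def simulate_two_sessions(
    params: CalciumSimParams,
    remap_fraction: float,
    width_scale_session2: float = 1.0,
    seed: int | None = None,
    sessions: tuple[BehaviorSession, BehaviorSession] | None = None,
) -> TwoSessionSim:
    """Simulate the same cell population across two sessions.

    Session 2 copies session 1's tuning except that a
    ``remap_fraction`` subset of place cells receives new uniform
    centers, and all field widths are multiplied by
    ``width_scale_session2`` (< 1 models field narrowing).
    """
    if not 0.0 <= remap_fraction <= 1.0:
        raise ValueError("remap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if sessions is None:
        ses_a, _ = simulate_session(
            DEFAULT_IMAGING_BEHAVIOR, rng=rng, context_id="day0",
            session_label="before_cfc",
        )
        ses_b, _ = simulate_session(
            DEFAULT_IMAGING_BEHAVIOR, rng=rng, context_id="day1",
            session_label="recall_day_1",
        )
    else:
        ses_a, ses_b = sessions
    laps_a, laps_b = segment_laps(ses_a), segment_laps(ses_b)
    traces_a, tuning_a = simulate_traces(ses_a, params, rng=rng, laps=laps_a)

    cells_b = tuning_a.cells[["cell", "is_place_cell", "center", "sigma"]].copy()
    place_idx = np.nonzero(cells_b["is_place_cell"].to_numpy())[0]
    n_remap = int(round(remap_fraction * place_idx.size))
    remapped = rng.permutation(place_idx)[:n_remap]
    lo, hi = params.center_range
    new_centers = cells_b["center"].to_numpy(float).copy()
    new_centers[remapped] = rng.uniform(lo, hi, n_remap)
    cells_b["center"] = new_centers
    cells_b["sigma"] = cells_b["sigma"] * width_scale_session2
    params_b = replace(params, field_sigma=params.field_sigma * width_scale_session2)
    traces_b, tuning_b = simulate_traces(
        ses_b, params_b, rng=rng, laps=laps_b, tuning=cells_b
    )
    tuning_b.cells["remapped"] = False
    tuning_b.cells.loc[remapped, "remapped"] = True
    match = pd.DataFrame(
        {"cell_id_a": np.arange(params.n_cells),
         "cell_id_b": np.arange(params.n_cells)}
    )
    return TwoSessionSim(
        traces_a, tuning_a, traces_b, tuning_b, match, laps_a, laps_b
    )
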