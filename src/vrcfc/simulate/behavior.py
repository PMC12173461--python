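"""Ground-truth-labelled behavior simulator for head-fixed VR sessions.

The generator is deliberately minimal: a two-state (run/freeze) Markov
chain drives the treadmill velocity, with two deterministic overlays —
an exponentially decaying sprint after each tail shock and the imposed
1.5 s teleport pause at the end of every lap.  This keeps analytic
expectations available for tests: the stationary freezing probability
of the chain is ``p_rf / (p_rf + p_fr)`` and the expected freeze-bout
duration is ``dt / p_fr``.

Cohorts mirror the three experimental designs: a familiar-vs-novel
discrimination (paradigm 1, 10 min pre-conditioning exposures, six 1 s
shocks at 60 s intervals, 5 min recall sessions), two novel contexts
with an extra habituation day (paradigm 2), and the same with shocks
packed at ~22.5 s intervals and the tail-coat worn during recall
(paradigm 3).  Context order alternates with mouse parity
(counterbalancing); mouse-level and session-level Gaussian variation in
the freezing set-point make the cohorts suitable for power analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ..behavior import (
    BehaviorSession,
    detect_freezing,
    segment_laps,
    session_metrics,
)
from ._kernels import (
    STATE_FREEZE,
    STATE_PAUSE,
    integrate_session,
)

__all__ = [
    "BehaviorSimParams",
    "GroundTruthBehavior",
    "simulate_session",
    "BehaviorSimCohortParams",
    "CohortSession",
    "simulate_cohort",
    "cohort_freezing_table",
    "freeze_fraction_to_rates",
]


@dataclass
class BehaviorSimParams:
    """Parameters of one simulated session.

    Transition probabilities are per frame; ``freeze_fraction_to_rates``
    converts a target stationary freezing fraction and mean bout length
    into ``(p_run_to_freeze, p_freeze_to_run)``.
    """

    frame_rate: float = 30.0  # Hz
    track_length: float = 200.0  # cm
    session_duration: float = 300.0  # s
    run_speed_mean: float = 15.0  # cm/s
    run_speed_sd: float = 5.0  # cm/s
    p_run_to_freeze: float = 0.003  # per frame
    p_freeze_to_run: float = 1.0 / 60.0  # per frame (mean bout 2 s at 30 Hz)
    backward_prob: float = 0.01  # per running frame
    teleport_pause: float = 1.5  # s
    shock_times: tuple[float, ...] = ()  # s from session start
    shock_sprint_amplitude: float = 20.0  # cm/s
    shock_sprint_decay: float = 2.0  # s
    shock_amplitude_ma: float = 1.0  # metadata only (not modelled)
    seed: int | None = None

    def validate(self) -> None:
        for name in ("p_run_to_freeze", "p_freeze_to_run", "backward_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.run_speed_mean < 0 or self.run_speed_sd < 0:
            raise ValueError("speeds must be >= 0")
        if self.frame_rate <= 0 or self.session_duration <= 0:
            raise ValueError("frame_rate and session_duration must be > 0")


@dataclass
class GroundTruthBehavior:
    """Simulator-side latent variables for recovery tests."""

    state: np.ndarray  # per-frame code: 0 run, 1 freeze, 2 sprint, 3 pause
    freezing_fraction: float  # freeze frames / non-pause frames
    lap_starts: np.ndarray
    lap_ends: np.ndarray  # inclusive lap-end frames (track end reached)

    @property
    def n_laps(self) -> int:
        return int(self.lap_starts.size)


def freeze_fraction_to_rates(
    fraction: float,
    mean_bout_s: float = 2.0,
    frame_rate: float = 30.0,
) -> tuple[float, float]:
    """Per-frame transition rates with a given stationary freeze fraction.

    ``p_freeze_to_run = 1 / (mean_bout_s * frame_rate)`` fixes the bout
    length; ``p_run_to_freeze`` follows from the stationary balance
    ``fraction = p_rf / (p_rf + p_fr)``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    p_fr = 1.0 / (mean_bout_s * frame_rate)
    p_rf = p_fr * fraction / (1.0 - fraction)
    return float(min(p_rf, 1.0)), float(p_fr)


def _shock_boost(params: BehaviorSimParams, t: np.ndarray) -> np.ndarray:
    boost = np.zeros_like(t)
    for ts in params.shock_times:
        after = t >= ts
        boost[after] += params.shock_sprint_amplitude * np.exp(
            -(t[after] - ts) / params.shock_sprint_decay
        )
    return boost


def simulate_session(
    params: BehaviorSimParams,
    rng: np.random.Generator | None = None,
    context_id: str = "sim",
    session_label: str = "recall_day_1",
) -> tuple[BehaviorSession, GroundTruthBehavior]:
    """Simulate one session; fully reproducible from ``params.seed``."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.session_duration * params.frame_rate))
    dt = 1.0 / params.frame_rate
    t = np.arange(n) * dt
    u_state = rng.random(n)
    speed_draw = rng.normal(params.run_speed_mean, params.run_speed_sd, n)
    u_back = rng.random(n)
    boost = _shock_boost(params, t)
    pause_frames = int(round(params.teleport_pause * params.frame_rate))
    state, vel, pos = integrate_session(
        dt,
        params.track_length,
        params.p_run_to_freeze,
        params.p_freeze_to_run,
        params.backward_prob,
        pause_frames,
        1.0,
        u_state,
        speed_draw,
        u_back,
        boost,
    )
    # events: reward at each lap-end frame, teleport on the last pause
    # frame (the next frame restarts from 0), shocks at their frames
    at_end = pos >= params.track_length
    end_frames = np.nonzero(at_end & ~np.r_[False, at_end[:-1]])[0]
    pause_end = np.nonzero(at_end & ~np.r_[at_end[1:], True])[0]
    ev_rows = [
        *({"frame": int(f), "kind": "reward"} for f in end_frames),
        *({"frame": int(f), "kind": "teleport"} for f in pause_end if f < n - 1),
        *(
            {"frame": int(round(ts * params.frame_rate)), "kind": "shock"}
            for ts in params.shock_times
            if round(ts * params.frame_rate) < n
        ),
    ]
    events = pd.DataFrame(ev_rows, columns=["frame", "kind"]).sort_values(
        "frame", kind="stable", ignore_index=True
    )
    session = BehaviorSession(
        frame_time=t,
        position=pos,
        velocity=vel,
        context_id=context_id,
        session_label=session_label,
        events=events,
        frame_rate=params.frame_rate,
        track_length=params.track_length,
        meta={"shock_amplitude_ma": params.shock_amplitude_ma,
              "n_shocks": len(params.shock_times)},
    )
    non_pause = state != STATE_PAUSE
    frozen = state == STATE_FREEZE
    frac = float(frozen.sum() / non_pause.sum()) if non_pause.any() else 0.0
    # true lap boundaries: traversal start = first non-pause frame after
    # the previous pause run (or frame 0); end = lap-end frame
    starts = []
    prev = 0
    for f in end_frames:
        starts.append(prev)
        later = pause_end[pause_end >= f]
        prev = int(later[0]) + 1 if later.size else n
    gt = GroundTruthBehavior(
        state=state,
        freezing_fraction=frac,
        lap_starts=np.asarray(starts, dtype=int),
        lap_ends=end_frames.astype(int),
    )
    return session, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

PARADIGM_SHOCKS = {
    1: {"n_shocks": 6, "isi": 60.0, "amplitude_ma": 1.0},
    2: {"n_shocks": 6, "isi": 60.0, "amplitude_ma": 1.0},
    3: {"n_shocks": 6, "isi": 22.5, "amplitude_ma": 0.6},
}


@dataclass
class BehaviorSimCohortParams:
    """Study-level conditions for a simulated cohort.

    Defaults follow the study conditions of the designs being emulated:
    10 min pre-conditioning exposures, 5 min recall sessions, six 1 s
    shocks, recall-day freezing set-points of ~16% (neutral) vs
    16% + ``effect`` (shock-paired), with mouse-level (shared across
    contexts, cancelled by pairing) and session-level (independent)
    Gaussian variation of the set-point.
    """

    baseline_freezing_pct: float = 16.0
    effect: float = 8.0  # freezing-% increase in the CFC context on recall day 1
    effect_decay: float = 0.4  # geometric decay of the effect across recall days
    mouse_sd: float = 5.0
    session_sd: float = 4.0
    exposure_duration: float = 600.0  # s, habituation / before-CFC sessions
    recall_duration: float = 300.0  # s
    n_recall_days: int = 1
    mean_bout_s: float = 2.0
    base: BehaviorSimParams = field(default_factory=BehaviorSimParams)


@dataclass
class CohortSession:
    mouse: int
    day: int  # -1 habituation, 0 conditioning day, 1.. recall days
    context_role: str  # "neutral" or "cfc"
    session_label: str
    tailcoat: bool
    order: int  # presentation order within the day (counterbalanced)
    session: BehaviorSession
    ground_truth: GroundTruthBehavior


def _schedule(paradigm: int, n_recall_days: int) -> list[tuple[int, str, str]]:
    """(day, context_role, session_label) sequence for one mouse."""
    if paradigm not in (1, 2, 3):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    days: list[tuple[int, str, str]] = []
    if paradigm in (2, 3):
        days += [(-1, "neutral", "habituation"), (-1, "cfc", "habituation")]
    days += [
        (0, "neutral", "before_cfc"),
        (0, "cfc", "before_cfc"),
        (0, "cfc", "during_cfc"),
    ]
    for d in range(1, n_recall_days + 1):
        days += [(d, "neutral", f"recall_day_{d}"), (d, "cfc", f"recall_day_{d}")]
    return days


def simulate_cohort(
    paradigm: int,
    n_mice: int,
    effect: float | None = None,
    seed: int | None = None,
    params: BehaviorSimCohortParams | None = None,
) -> list[CohortSession]:
    """Simulate the full session sequence of one paradigm for a cohort.

    The shock-paired context's recall-day freezing set-point is elevated
    by ``effect`` percentage points (decaying geometrically on later
    recall days); context presentation order alternates with mouse index
    parity.  Paradigms 2 and 3 include the extra habituation day;
    paradigm 3 keeps the tail-coat on during recall and packs the six
    shocks at ~22.5 s intervals.
    """
    if paradigm not in PARADIGM_SHOCKS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if n_mice < 2:
        raise ValueError("n_mice must be >= 2")
    p = params or BehaviorSimCohortParams()
    if effect is not None:
        p = replace(p, effect=effect)
    rng = np.random.default_rng(seed)
    shock_cfg = PARADIGM_SHOCKS[paradigm]
    out: list[CohortSession] = []
    for mouse in range(n_mice):
        mouse_offset = rng.normal(0.0, p.mouse_sd)
        for day, role, label in _schedule(paradigm, p.n_recall_days):
            target = p.baseline_freezing_pct + mouse_offset
            if role == "cfc" and day >= 1:
                target += p.effect * p.effect_decay ** (day - 1)
            target += rng.normal(0.0, p.session_sd)
            target = float(np.clip(target, 1.0, 90.0))
            p_rf, p_fr = freeze_fraction_to_rates(
                target / 100.0, p.mean_bout_s, p.base.frame_rate
            )
            if label == "during_cfc":
                isi = shock_cfg["isi"]
                n_shocks = shock_cfg["n_shocks"]
                first = p.exposure_duration  # shocks follow 10 min exploration
                shock_times = tuple(first + k * isi for k in range(n_shocks))
                duration = first + n_shocks * isi + 60.0
            else:
                shock_times = ()
                duration = (
                    p.recall_duration if day >= 1 else p.exposure_duration
                )
            sp = replace(
                p.base,
                session_duration=duration,
                p_run_to_freeze=p_rf,
                p_freeze_to_run=p_fr,
                shock_times=shock_times,
                shock_amplitude_ma=shock_cfg["amplitude_ma"],
            )
            # counterbalancing: odd mice see the CFC context first
            order = int((role == "cfc") == (mouse % 2 == 0))
            tailcoat = (day <= 0) or (paradigm == 3)
            session, gt = simulate_session(
                sp, rng=rng,
                context_id="familiar" if (paradigm == 1 and role == "neutral")
                else f"{role}_vr",
                session_label=label,
            )
            session.meta.update(
                mouse=mouse, day=day, context_role=role,
                tailcoat=tailcoat, true_freezing_pct=target,
            )
            out.append(
                CohortSession(mouse, day, role, label, tailcoat, order, session, gt)
            )
    return out


def cohort_freezing_table(
    cohort: Sequence[CohortSession],
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Long-format freezing table from a simulated cohort.

    One row per mouse x context x day x metric with the measured
    freezing percentage (``metric`` in ``{first_lap, average}``), the
    layout consumed by the extinction mixed model and the paired tests.
    Conditioning sessions (``during_cfc``) are excluded; day 0 rows are
    the pre-conditioning baseline.
    """
    rows = []
    for cs in cohort:
        if cs.session_label == "during_cfc":
            continue
        laps = segment_laps(cs.session)
        mask = detect_freezing(cs.session, epsilon)
        m = session_metrics(cs.session, laps, mask)
        if not m.defined:
            continue
        day_label = "Day0" if cs.day == 0 else (
            "Habituation" if cs.day < 0 else f"Recall{cs.day}"
        )
        for metric, value in (
            ("first_lap", m.first_lap_freezing_pct),
            ("average", m.avg_freezing_pct),
        ):
            rows.append(
                {
                    "mouse_id": cs.mouse,
                    "vr_context": cs.context_role,
                    "day": day_label,
                    "metric": metric,
                    "freezing_pct": value,
                    "n_laps": m.n_laps,
                    "avg_lap_time": m.avg_lap_time,
                    "first_lap_time": m.first_lap_time,
                }
            )
    return pd.DataFrame(rows)
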