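"""Behavioral quantification for head-fixed VR sessions.

A session is a per-frame record of a mouse running on a cylindrical
treadmill through a 2 m virtual linear track.  Reaching the end of the
track triggers a brief teleport pause after which the mouse restarts at
0 cm; one complete 0->200 cm traversal is a lap.  Fear is read out as
freezing: frames whose instantaneous treadmill velocity is (within a
configurable tolerance of) 0 cm/s, aggregated into per-lap freezing
percentages and freezing epochs (uninterrupted freezing longer than a
minimum duration, 1 s by default).

Conventions
-----------
* velocity is signed; negative values are backward movement and are
  *not* freezing (freezing requires ``|v| <= epsilon``).
* lap duration excludes the end-of-lap teleport pause: a lap ends at
  the frame where the track end is reached, and the next lap starts on
  the first frame after the pause.  Pause frames therefore never enter
  per-lap freezing denominators.
* the first lap of a session is the first *completed* traversal; a
  traversal still in progress when the session ends is reported
  separately, never as a lap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionValidationError",
    "BehaviorSession",
    "LapTable",
    "FreezingEpoch",
    "SessionMetrics",
    "ShockResponse",
    "segment_laps",
    "detect_freezing",
    "freezing_epochs",
    "session_metrics",
    "discrimination_delta",
    "shock_response",
]

EVENT_KINDS = ("reward", "shock", "lick", "teleport")

DEFAULT_TRACK_LENGTH = 200.0  # cm
DEFAULT_FRAME_RATE = 30.0  # Hz


class SessionValidationError(ValueError):
    """Raised when a behavior session violates a structural invariant."""


@dataclass
class BehaviorSession:
    """Per-frame behavioral time series for one mouse/session/context.

    Parameters
    ----------
    frame_time
        Frame timestamps in seconds, strictly increasing.
    position
        Track position in cm, within ``[0, track_length]``.
    velocity
        Signed instantaneous velocity in cm/s (negative = backward).
    context_id
        Label of the VR context (e.g. ``"familiar"``, ``"cfc"``).
    session_label
        One of ``habituation``, ``before_cfc``, ``during_cfc`` or
        ``recall_day_<k>``.
    events
        DataFrame with integer column ``frame`` and string column
        ``kind`` (one of ``reward``, ``shock``, ``lick``, ``teleport``).
    frame_rate
        Sampling rate in Hz; inferred from timestamps when omitted.
    """

    frame_time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    context_id: str = "unknown"
    session_label: str = "recall_day_1"
    events: pd.DataFrame | None = None
    frame_rate: float | None = None
    track_length: float = DEFAULT_TRACK_LENGTH
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_time = np.asarray(self.frame_time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.events is None:
            self.events = pd.DataFrame({"frame": pd.Series([], dtype=int),
                                        "kind": pd.Series([], dtype=str)})
        self.validate()
        if self.frame_rate is None:
            dt = np.median(np.diff(self.frame_time)) if self.n_frames > 1 else None
            self.frame_rate = 1.0 / dt if dt else DEFAULT_FRAME_RATE

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        n = self.frame_time.size
        if self.position.size != n or self.velocity.size != n:
            raise SessionValidationError(
                "frame_time, position and velocity must have equal length"
            )
        if n > 1:
            bad = np.nonzero(np.diff(self.frame_time) <= 0)[0]
            if bad.size:
                raise SessionValidationError(
                    f"frame_time not strictly increasing at frame {bad[0] + 1}"
                )
        if n:
            out = np.nonzero(
                (self.position < -1e-9) | (self.position > self.track_length + 1e-9)
            )[0]
            if out.size:
                raise SessionValidationError(
                    f"position outside [0, {self.track_length}] at frame {out[0]}"
                )
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise SessionValidationError("frame_rate must be > 0")
        bad_kinds = set(self.events["kind"]) - set(EVENT_KINDS)
        if bad_kinds:
            raise SessionValidationError(f"unknown event kinds: {sorted(bad_kinds)}")
        tele = self.events.loc[self.events["kind"] == "teleport", "frame"].to_numpy(int)
        tele = tele[tele < n - 1]
        if tele.size and np.any(self.position[tele + 1] > 0.1 * self.track_length):
            bad = tele[self.position[tele + 1] > 0.1 * self.track_length][0]
            raise SessionValidationError(
                f"teleport at frame {bad} not followed by a position near 0"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frame_time.size)

    @property
    def duration(self) -> float:
        """Session duration in seconds (inclusive of the last frame)."""
        if self.n_frames == 0:
            return 0.0
        span = float(self.frame_time[-1] - self.frame_time[0])
        return span + 1.0 / self.frame_rate

    def event_frames(self, kind: str) -> np.ndarray:
        return self.events.loc[self.events["kind"] == kind, "frame"].to_numpy(int)


@dataclass
class FreezingEpoch:
    """A maximal run of freezing frames longer than the minimum duration."""

    start_frame: int
    end_frame: int  # inclusive
    duration: float  # seconds


@dataclass
class LapTable:
    """Lap boundaries and per-lap metrics for one session.

    ``laps`` has one row per completed 0->track_end traversal with columns
    ``lap_index, start_frame, end_frame, start_s, end_s, duration_s,
    n_frames, is_first_lap`` (frames are inclusive on both ends and
    exclude the teleport pause).  ``frame_lap`` maps every session frame
    to its lap index, with -1 for frames outside any completed lap
    (teleport pauses, the incomplete final traversal).
    """

    laps: pd.DataFrame
    frame_lap: np.ndarray
    incomplete: dict | None = None

    @property
    def n_laps(self) -> int:
        return len(self.laps)

    def __len__(self) -> int:
        return len(self.laps)


def _lap_end_candidates(session: BehaviorSession, complete_tol: float) -> np.ndarray:
    """Frames at which the track end is reached (one per traversal)."""
    pos = session.position
    at_end = pos >= session.track_length - complete_tol
    # first frame of each run of at-end frames
    starts = np.nonzero(at_end & ~np.r_[False, at_end[:-1]])[0]
    return starts


def segment_laps(
    session: BehaviorSession,
    complete_tol: float = 0.5,
) -> LapTable:
    """Segment a session into completed laps.

    A lap is a completed traversal from the track start to within
    ``complete_tol`` cm of the track end.  The lap ends on the frame the
    end is reached; frames between that frame and the post-teleport
    restart (position back near 0) are the imposed pause and belong to
    no lap.  A final traversal that never reaches the end is returned in
    ``LapTable.incomplete``.
    """
    n = session.n_frames
    frame_lap = np.full(n, -1, dtype=int)
    rows: list[dict] = []
    incomplete: dict | None = None
    if n == 0:
        return LapTable(_empty_lap_frame(), frame_lap, None)

    pos = session.position
    t = session.frame_time
    ends = _lap_end_candidates(session, complete_tol)
    # position resets (teleports) appear as large negative jumps
    resets = np.nonzero(np.diff(pos) < -session.track_length / 2)[0]

    start = 0
    lap_index = 0
    for end in ends:
        if end < start:  # still inside the previous pause run
            continue
        # pause lasts until the position has reset to the track start
        later_resets = resets[resets >= end]
        nxt = int(later_resets[0]) + 1 if later_resets.size else n
        rows.append(
            {
                "lap_index": lap_index,
                "start_frame": start,
                "end_frame": int(end),
                "start_s": float(t[start]),
                "end_s": float(t[end]),
                "duration_s": float(t[end] - t[start]),
                "n_frames": int(end - start + 1),
                "is_first_lap": lap_index == 0,
            }
        )
        frame_lap[start : end + 1] = lap_index
        lap_index += 1
        start = nxt
    if start < n and (not ends.size or start > ends[-1]):
        incomplete = {
            "start_frame": int(start),
            "n_frames": int(n - start),
            "duration_s": float(t[-1] - t[start]),
            "max_position": float(np.max(pos[start:])),
        }
    laps = pd.DataFrame(rows) if rows else _empty_lap_frame()
    return LapTable(laps, frame_lap, incomplete)


def _empty_lap_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lap_index": pd.Series([], dtype=int),
            "start_frame": pd.Series([], dtype=int),
            "end_frame": pd.Series([], dtype=int),
            "start_s": pd.Series([], dtype=float),
            "end_s": pd.Series([], dtype=float),
            "duration_s": pd.Series([], dtype=float),
            "n_frames": pd.Series([], dtype=int),
            "is_first_lap": pd.Series([], dtype=bool),
        }
    )


def detect_freezing(session: BehaviorSession, epsilon: float = 0.0) -> np.ndarray:
    """Per-frame freezing mask: ``|velocity| <= epsilon``.

    The faithful definition of freezing is instantaneous velocity of
    exactly 0 cm/s (``epsilon=0``); a small positive tolerance (a
    recommended 0.05 cm/s) absorbs encoder quantization noise in real
    logs.  Backward movement is never freezing.  Teleport-pause frames
    satisfy the velocity criterion but are excluded from per-lap metrics
    because laps never contain them.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return np.abs(session.velocity) <= epsilon


def freezing_epochs(
    mask: np.ndarray,
    frame_rate: float,
    min_duration: float = 1.0,
) -> list[FreezingEpoch]:
    """Maximal runs of freezing frames strictly longer than ``min_duration``.

    Duration of a run of ``k`` frames is ``k / frame_rate``; the
    threshold is strict, so at 30 Hz a run of exactly 30 frames (1.0 s)
    is not an epoch while 31 frames is.
    """
    if min_duration <= 0:
        raise ValueError("min_duration must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.r_[False, mask, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]  # exclusive
    out = []
    for s, e in zip(starts, stops):
        dur = (e - s) / frame_rate
        if dur > min_duration:
            out.append(FreezingEpoch(int(s), int(e - 1), float(dur)))
    return out


@dataclass
class SessionMetrics:
    """Session-level behavioral summary.

    ``avg_freezing_pct`` is the unweighted mean of per-lap freezing
    percentages (freezing frames in a lap / total frames in that lap x
    100).  Because freezing lengthens the laps that contain it, this
    per-lap average sits a few points below the frame-level freezing
    fraction; ``total_freezing_pct`` (all freezing frames in laps /
    all lap frames) is the frame-weighted companion that converges to
    the underlying per-frame freeze probability.  With zero completed
    laps all metrics are NaN and ``defined`` is False rather than
    reporting spurious zeros.
    """

    avg_freezing_pct: float
    total_freezing_pct: float
    first_lap_freezing_pct: float
    avg_lap_time: float
    first_lap_time: float
    n_laps: int
    laps_per_minute: float
    defined: bool
    per_lap: pd.DataFrame | None = None


def session_metrics(
    session: BehaviorSession,
    laps: LapTable,
    mask: np.ndarray,
) -> SessionMetrics:
    """Per-lap and session-averaged freezing and lap-time metrics."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != session.n_frames:
        raise ValueError("mask length must equal session frame count")
    minutes = session.duration / 60.0
    if laps.n_laps == 0:
        return SessionMetrics(
            np.nan, np.nan, np.nan, np.nan, np.nan, 0,
            0.0 if minutes > 0 else np.nan, defined=False,
        )
    per_lap = laps.laps.copy()
    freezing_frames = np.array(
        [int(mask[s : e + 1].sum())
         for s, e in zip(per_lap["start_frame"], per_lap["end_frame"])]
    )
    per_lap["freezing_frames"] = freezing_frames
    per_lap["freezing_pct"] = 100.0 * freezing_frames / per_lap["n_frames"]
    first = per_lap.iloc[0]
    return SessionMetrics(
        avg_freezing_pct=float(per_lap["freezing_pct"].mean()),
        total_freezing_pct=float(
            100.0 * freezing_frames.sum() / per_lap["n_frames"].sum()
        ),
        first_lap_freezing_pct=float(first["freezing_pct"]),
        avg_lap_time=float(per_lap["duration_s"].mean()),
        first_lap_time=float(first["duration_s"]),
        n_laps=laps.n_laps,
        laps_per_minute=float(laps.n_laps / minutes) if minutes > 0 else np.nan,
        defined=True,
        per_lap=per_lap,
    )


def discrimination_delta(
    metrics_cfc: SessionMetrics,
    metrics_neutral: SessionMetrics,
    metric: str = "avg_freezing_pct",
) -> float:
    """Shock-paired minus neutral context value of ``metric``.

    Positive values indicate correct contextual discrimination (more
    freezing in the shock-paired context).  Undefined inputs propagate
    as NaN.
    """
    if not (metrics_cfc.defined and metrics_neutral.defined):
        return float("nan")
    return float(getattr(metrics_cfc, metric) - getattr(metrics_neutral, metric))


@dataclass
class ShockResponse:
    """Per-shock running-speed change around each shock."""

    per_shock: pd.DataFrame  # shock_frame, pre_speed, post_speed, diff
    responsive: bool
    n_excluded: int


def shock_response(
    session: BehaviorSession,
    window: float = 5.0,
    majority: float = 2.0 / 3.0,
) -> ShockResponse:
    """Mean absolute running speed before vs after each shock.

    For every shock with a full ``window`` seconds of data on both
    sides, reports mean ``|velocity|`` in the pre- and post-window and
    their difference, skipping the imposed end-of-lap teleport-pause
    frames (position held at the track end), which are not behavior.
    The session is flagged ``responsive`` when the post-shock speed
    exceeds the pre-shock speed for at least ``majority`` of the
    evaluable shocks (a QC check that the shock hardware provoked the
    expected escape response).
    """
    shocks = session.event_frames("shock")
    if shocks.size == 0:
        raise ValueError("session contains no shock events")
    w = int(round(window * session.frame_rate))
    speed = np.abs(session.velocity)
    behaving = session.position < session.track_length  # excludes pause
    rows = []
    excluded = 0

    def _mean(sl: slice) -> float:
        vals = speed[sl][behaving[sl]]
        return float(vals.mean()) if vals.size else float("nan")

    for f in shocks:
        if f - w < 0 or f + w >= session.n_frames:
            excluded += 1
            continue
        pre = _mean(slice(f - w, f))
        post = _mean(slice(f + 1, f + 1 + w))
        rows.append({"shock_frame": int(f), "pre_speed": pre,
                     "post_speed": post, "diff": post - pre})
    per_shock = pd.DataFrame(
        rows, columns=["shock_frame", "pre_speed", "post_speed", "diff"]
    )
    if len(per_shock):
        responsive = (per_shock["diff"] > 0).mean() >= majority
    else:
        responsive = False
    return ShockResponse(per_shock, bool(responsive), excluded)
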