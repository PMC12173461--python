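"""Shared fixtures: small synthetic sessions and trace sets.

Everything is generated at test time from fixed seeds; expensive
objects are module/session scoped so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vrcfc.behavior import BehaviorSession, segment_laps
from vrcfc.simulate.behavior import BehaviorSimParams, simulate_session


def make_ramp_session(
    n_laps: int = 3,
    frames_per_lap: int = 90,
    pause_frames: int = 45,
    frame_rate: float = 30.0,
    track_length: float = 200.0,
    velocity: float | None = None,
) -> BehaviorSession:
    """Deterministic sawtooth session: linear 0->200 ramps with pauses."""
    pos_parts, vel_parts = [], []
    v = velocity if velocity is not None else track_length / (
        frames_per_lap / frame_rate
    )
    ramp = np.linspace(0.0, track_length, frames_per_lap)
    for _ in range(n_laps):
        pos_parts.append(ramp)
        vel_parts.append(np.full(frames_per_lap, v))
        pos_parts.append(np.full(pause_frames, track_length))
        vel_parts.append(np.zeros(pause_frames))
    pos = np.concatenate(pos_parts)
    vel = np.concatenate(vel_parts)
    t = np.arange(pos.size) / frame_rate
    return BehaviorSession(
        frame_time=t, position=pos, velocity=vel,
        context_id="ramp", frame_rate=frame_rate, track_length=track_length,
    )


@pytest.fixture(scope="session")
def imaging_session():
    """A low-freezing running session with ~27 laps (for imaging tests)."""
    params = BehaviorSimParams(
        session_duration=420.0, p_run_to_freeze=0.001, backward_prob=0.005,
    )
    session, gt = simulate_session(params, rng=np.random.default_rng(7))
    return session, gt


@pytest.fixture(scope="session")
def imaging_laps(imaging_session):
    session, _ = imaging_session
    return segment_laps(session)
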