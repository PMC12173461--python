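"""Sequential frame-loop kernels for the behavior simulator.

Position integration and the run/freeze Markov chain are inherently
sequential, so the per-frame loop is compiled with numba; all random
draws are made up front with a numpy Generator so that reproducibility
is owned entirely by the caller's seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# latent state codes (shared with simulate.behavior)
STATE_RUN = 0
STATE_FREEZE = 1
STATE_SPRINT = 2
STATE_PAUSE = 3


@njit(cache=False)
def integrate_session(
    dt: float,
    track_length: float,
    p_run_to_freeze: float,
    p_freeze_to_run: float,
    backward_prob: float,
    pause_frames: int,
    sprint_label_thresh: float,
    u_state: np.ndarray,
    speed_draw: np.ndarray,
    u_back: np.ndarray,
    boost: np.ndarray,
):
    """Run the two-state chain and integrate position over one session.

    Returns ``(state, velocity, position)``.  The frame on which the
    integrated position reaches the track end is clamped to
    ``track_length`` (the lap-end frame); the following ``pause_frames``
    frames hold position at the track end with velocity 0 (the imposed
    teleport pause) and the next frame restarts from 0.  ``boost`` is an
    additive speed transient (shock-evoked sprint); frames where it
    exceeds ``sprint_label_thresh`` are labelled sprint in the latent
    state even if the chain is frozen.
    """
    n = u_state.shape[0]
    state = np.empty(n, dtype=np.int8)
    vel = np.zeros(n)
    pos = np.zeros(n)
    s = STATE_RUN
    pause_left = 0
    x = 0.0
    for t in range(n):
        if pause_left > 0:
            state[t] = STATE_PAUSE
            vel[t] = 0.0
            pos[t] = track_length
            pause_left -= 1
            if pause_left == 0:
                x = 0.0
            continue
        if s == STATE_RUN:
            if u_state[t] < p_run_to_freeze:
                s = STATE_FREEZE
        else:
            if u_state[t] < p_freeze_to_run:
                s = STATE_RUN
        v = 0.0
        if s == STATE_RUN:
            v = speed_draw[t]
            if v < 0.0:
                v = 0.0
            if u_back[t] < backward_prob:
                v = -v
        v = v + boost[t]
        x = x + v * dt
        if x < 0.0:
            x = 0.0
        if x >= track_length:
            pos[t] = track_length
            if pause_frames > 0:
                pause_left = pause_frames
                x = track_length
            else:
                x = 0.0
        else:
            pos[t] = x
        vel[t] = v
        if boost[t] > sprint_label_thresh:
            state[t] = STATE_SPRINT
        else:
            state[t] = s
    return state, vel, pos
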