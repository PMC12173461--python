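"""Reading and writing sessions, traces and result tables.

Behavior sessions travel as delimited text with one row per frame and
canonical columns ``time_s, position_cm, velocity_cms, context`` plus
optional 0/1 event channels (``reward, shock, lick, teleport``); a
column-mapping config (YAML ``canonical: actual`` pairs) adapts foreign
headers.  An HDF5 container with one group per session holds the same
arrays.  ΔF/F matrices are stored as HDF5 datasets (cells x frames)
with a cell-id sidecar, or as wide CSV with one row per cell.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import (
    EVENT_KINDS,
    BehaviorSession,
    LapTable,
    SessionMetrics,
    SessionValidationError,
)
from .placecells import CalciumTraceSet

__all__ = [
    "SchemaError",
    "DEFAULT_SCHEMA",
    "load_schema",
    "read_session",
    "write_session",
    "read_session_h5",
    "write_session_h5",
    "load_traces",
    "save_traces",
    "read_match_map",
    "write_lap_table",
    "write_session_metrics",
]

REQUIRED = ("time", "position", "velocity", "context")
DEFAULT_SCHEMA = {
    "time": "time_s",
    "position": "position_cm",
    "velocity": "velocity_cms",
    "context": "context",
    **{k: k for k in EVENT_KINDS},
}


class SchemaError(ValueError):
    """A required column is missing after applying the column mapping."""


def load_schema(path: str | Path) -> dict:
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    return {**DEFAULT_SCHEMA, **schema}


def read_session(
    path: str | Path,
    schema: dict | None = None,
    session_label: str = "recall_day_1",
    frame_rate: float | None = None,
    track_length: float = 200.0,
    sep: str | None = None,
) -> BehaviorSession:
    """Read a per-frame behavior log from delimited text.

    ``schema`` maps canonical names (``time, position, velocity,
    context`` and the event kinds) to the file's column headers; event
    channels are optional 0/1 columns and default empty.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [k for k in REQUIRED if schema[k] not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing} "
            f"(mapped to {[schema[k] for k in missing]}) in {path}"
        )
    ev_rows = []
    for kind in EVENT_KINDS:
        col = schema.get(kind)
        if col in df.columns:
            frames = np.nonzero(df[col].to_numpy() > 0)[0]
            ev_rows += [{"frame": int(f), "kind": kind} for f in frames]
    events = pd.DataFrame(ev_rows, columns=["frame", "kind"]).sort_values(
        "frame", kind="stable", ignore_index=True
    )
    context = df[schema["context"]].iloc[0] if len(df) else "unknown"
    return BehaviorSession(
        frame_time=df[schema["time"]].to_numpy(float),
        position=df[schema["position"]].to_numpy(float),
        velocity=df[schema["velocity"]].to_numpy(float),
        context_id=str(context),
        session_label=session_label,
        events=events,
        frame_rate=frame_rate,
        track_length=track_length,
    )


def write_session(session: BehaviorSession, path: str | Path) -> None:
    """Write a session to CSV in the canonical column layout."""
    df = pd.DataFrame(
        {
            "time_s": session.frame_time,
            "position_cm": session.position,
            "velocity_cms": session.velocity,
            "context": session.context_id,
        }
    )
    for kind in EVENT_KINDS:
        channel = np.zeros(session.n_frames, dtype=int)
        channel[session.event_frames(kind)] = 1
        df[kind] = channel
    df.to_csv(path, index=False)


def write_session_h5(
    session: BehaviorSession, path: str | Path, group: str = "session"
) -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for name in ("frame_time", "position", "velocity"):
            g.create_dataset(name, data=getattr(session, name))
        for kind in EVENT_KINDS:
            g.create_dataset(f"events/{kind}", data=session.event_frames(kind))
        g.attrs["context_id"] = session.context_id
        g.attrs["session_label"] = session.session_label
        g.attrs["frame_rate"] = session.frame_rate
        g.attrs["track_length"] = session.track_length


def read_session_h5(path: str | Path, group: str = "session") -> BehaviorSession:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        ev_rows = []
        for kind in EVENT_KINDS:
            for f in np.asarray(g[f"events/{kind}"]):
                ev_rows.append({"frame": int(f), "kind": kind})
        events = pd.DataFrame(ev_rows, columns=["frame", "kind"]).sort_values(
            "frame", kind="stable", ignore_index=True
        )
        return BehaviorSession(
            frame_time=np.asarray(g["frame_time"]),
            position=np.asarray(g["position"]),
            velocity=np.asarray(g["velocity"]),
            context_id=str(g.attrs["context_id"]),
            session_label=str(g.attrs["session_label"]),
            events=events,
            frame_rate=float(g.attrs["frame_rate"]),
            track_length=float(g.attrs["track_length"]),
        )


def save_traces(traces: CalciumTraceSet, path: str | Path) -> None:
    """Save a ΔF/F matrix as HDF5 (datasets ``dff`` and ``cell_ids``)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("dff", data=traces.dff)
        fh.create_dataset("cell_ids", data=np.asarray(traces.cell_ids, dtype="S"))


def load_traces(path: str | Path, session: BehaviorSession) -> CalciumTraceSet:
    """Load ΔF/F from HDF5 or wide CSV (one row per cell) and align it."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            dff = np.asarray(fh["dff"], dtype=float)
            cell_ids = np.asarray(fh["cell_ids"]).astype(str)
    else:
        df = pd.read_csv(path)
        id_col = df.columns[0]
        cell_ids = df[id_col].to_numpy(str)
        dff = df.drop(columns=[id_col]).to_numpy(float)
    return CalciumTraceSet(dff, cell_ids, session)


def read_match_map(path: str | Path) -> pd.DataFrame:
    """Two-column CSV of matched cell ids across sessions."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError("match map needs two columns (cell_id_a, cell_id_b)")
    df = df.iloc[:, :2]
    df.columns = ["cell_id_a", "cell_id_b"]
    if df["cell_id_a"].duplicated().any() or df["cell_id_b"].duplicated().any():
        raise SessionValidationError("match map must be one-to-one")
    return df


def write_lap_table(metrics: SessionMetrics, path: str | Path) -> None:
    """Per-lap CSV: lap_index, start_s, end_s, duration_s, freezing_pct."""
    cols = ["lap_index", "start_s", "end_s", "duration_s", "freezing_pct"]
    table = metrics.per_lap[cols] if metrics.per_lap is not None else pd.DataFrame(
        columns=cols
    )
    table.to_csv(path, index=False)


def write_session_metrics(metrics: SessionMetrics, path: str | Path) -> None:
    record = {
        k: getattr(metrics, k)
        for k in (
            "avg_freezing_pct", "first_lap_freezing_pct", "avg_lap_time",
            "first_lap_time", "n_laps", "laps_per_minute", "defined",
        )
    }
    record = {
        k: (None if isinstance(v, float) and not np.isfinite(v) else v)
        for k, v in record.items()
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
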