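"""Reading, writing and synchronisation of the two input streams.

Activity CSV: ``timestamp, act_x, act_y`` — one row per 5-minute bin.
Observation CSV: ``session_id, timestamp, state`` — behaviour-change events
(state onsets) grouped into focal-follow sessions; an optional last row per
session with state ``end`` marks the session end (otherwise the last event
time is used, so no bins after the last event can be labelled).

``synchronize_labels`` projects the observed piecewise-constant behaviour
onto the activity bins: a bin is labelled with the behaviour occupying at
least ``dominance_threshold`` of its 5 minutes; mixed bins, bins partially
outside a session and bins before the first event of a session are excluded.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BIN_DELTA,
    ActivitySeries,
    BehaviourClass,
    LabeledDataset,
    ObservationLog,
    ObservationSession,
    PosteriorSequence,
    StatePath,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_activity_csv",
    "read_observation_log",
    "synchronize_labels",
    "write_state_sequence",
    "read_state_sequence",
]

_SESSION_END = "end"


def read_activity_csv(path, individual_id: str | None = None) -> ActivitySeries:
    """Read and validate an activity CSV into an :class:`ActivitySeries`.

    Gaps (consecutive rows more than 5 minutes apart) are legal and recorded
    as block boundaries.  Duplicate or non-increasing timestamps and counts
    outside [0, 255] are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("timestamp", "act_x", "act_y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise ValueError(
            f"{path}: malformed timestamp {df['timestamp'].iloc[row]!r} at row {row}"
        )
    if ts.duplicated().any():
        row = int(ts.duplicated().idxmax())
        raise ValueError(f"{path}: duplicate timestamp at row {row}")
    counts = df[["act_x", "act_y"]].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError(f"{path}: activity counts must be numeric")
    order = np.argsort(ts.to_numpy(), kind="stable")
    return ActivitySeries(
        individual_id=individual_id or path.stem,
        timestamps=pd.DatetimeIndex(ts.to_numpy()[order]),
        counts=counts[order],
    )


def read_observation_log(path) -> ObservationLog:
    """Read a behaviour-change event CSV into an :class:`ObservationLog`."""
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        return ObservationLog(sessions=[])
    for col in ("session_id", "timestamp", "state"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise ValueError(
            f"{path}: malformed timestamp {df['timestamp'].iloc[row]!r} at row {row}"
        )
    df = df.assign(timestamp=ts)
    sessions = []
    for sid, grp in df.groupby("session_id", sort=False):
        times = grp["timestamp"].tolist()
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"{path}: events out of order in session {sid!r}")
        states = [str(s).strip().lower() for s in grp["state"]]
        end_ts = times[-1]
        events = []
        for i, (t, s) in enumerate(zip(times, states)):
            if s == _SESSION_END:
                if i != len(states) - 1:
                    raise ValueError(
                        f"{path}: session {sid!r} has events after its 'end' marker"
                    )
                end_ts = t
            else:
                events.append((t, BehaviourClass.from_name(s)))
        if not events:
            raise ValueError(f"{path}: session {sid!r} contains no behaviour events")
        sessions.append(
            ObservationSession(
                session_id=str(sid), start_ts=times[0], end_ts=end_ts, events=events
            )
        )
    return ObservationLog(sessions=sessions)


def _bin_label(intervals, bin_start, bin_end, threshold: float):
    """Behaviour occupying >= threshold of [bin_start, bin_end), or None."""
    minutes = np.zeros(3)
    for lo, hi, state in intervals:
        overlap = min(hi, bin_end) - max(lo, bin_start)
        if overlap > pd.Timedelta(0):
            minutes[int(state) - 1] += overlap / pd.Timedelta(minutes=1)
    total = (bin_end - bin_start) / pd.Timedelta(minutes=1)
    frac = minutes / total
    best = int(np.argmax(frac))  # ties resolve to the lowest class code
    if frac[best] >= threshold - 1e-12:
        return BehaviourClass(best + 1)
    return None


def synchronize_labels(
    activity: ActivitySeries,
    log: ObservationLog,
    dominance_threshold: float = 1.0,
) -> LabeledDataset:
    """Project field observations onto activity bins to build the labelled set.

    A bin ``[t, t+5)`` is considered only if it lies fully inside a session's
    span; it receives the behaviour covering at least ``dominance_threshold``
    of the bin, and is excluded otherwise (mixed-behaviour bins).  An empty
    result is legal.
    """
    if not 0 < dominance_threshold <= 1:
        raise ValueError("dominance_threshold must be in (0, 1]")
    rows = []
    for sess in log:
        intervals = sess.state_intervals()
        inside = (activity.timestamps >= sess.start_ts) & (
            activity.timestamps + BIN_DELTA <= sess.end_ts
        )
        for i in np.flatnonzero(inside):
            t = activity.timestamps[i]
            label = _bin_label(intervals, t, t + BIN_DELTA, dominance_threshold)
            if label is not None:
                rows.append(
                    (
                        t,
                        activity.counts[i, 0],
                        activity.counts[i, 1],
                        int(label),
                        sess.session_id,
                    )
                )
    table = pd.DataFrame(
        rows, columns=["timestamp", "act_x", "act_y", "label", "session_id"]
    )
    return LabeledDataset(table, dominance_threshold)


def write_state_sequence(
    path, states: StatePath, posteriors: PosteriorSequence | None = None
) -> None:
    """Write a decoded state sequence (and optional posteriors) to CSV.

    Columns: ``timestamp, state[, P_feeding, P_mobile, P_stationary]``.
    States round-trip exactly; probabilities at 1e-9 precision.
    """
    df = states.to_frame().drop(columns="block")
    if posteriors is not None:
        if len(posteriors) != len(states):
            raise ValueError(
                f"states ({len(states)}) and posteriors ({len(posteriors)}) "
                "length mismatch"
            )
        for j, name in enumerate(("P_feeding", "P_mobile", "P_stationary")):
            df[name] = np.round(posteriors.values[:, j], 9)
    df.to_csv(path, index=False)


def read_state_sequence(path) -> StatePath:
    """Read back a CSV written by :func:`write_state_sequence`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    states = [int(BehaviourClass.from_name(s)) for s in df["state"]]
    return StatePath(pd.DatetimeIndex(df["timestamp"]), np.asarray(states))
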