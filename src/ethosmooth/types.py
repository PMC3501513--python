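"""Core domain containers for the activity-classification pipeline.

The pipeline works on 5-minute bins of bi-axial collar activity counts
(integers in [0, 255] per channel).  Bins are half-open ``[t, t + 5 min)``
and identified by their start time; all timestamps are local time.
Recording gaps split a series into independent contiguous *blocks* —
temporal smoothing and bout extraction never cross a block boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

BIN_MINUTES = 5
BIN_DELTA = pd.Timedelta(minutes=BIN_MINUTES)

__all__ = [
    "BIN_MINUTES",
    "BIN_DELTA",
    "BehaviourClass",
    "CLASS_NAMES",
    "ActivitySeries",
    "ObservationSession",
    "ObservationLog",
    "LabeledDataset",
    "PosteriorSequence",
    "LikelihoodSequence",
    "StatePath",
    "derive_blocks",
]


class BehaviourClass(enum.IntEnum):
    """The three-state ethogram, with fixed canonical codes."""

    FEEDING = 1
    MOBILE = 2
    STATIONARY = 3

    @classmethod
    def from_name(cls, name: str) -> "BehaviourClass":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            allowed = ", ".join(c.name.lower() for c in cls)
            raise ValueError(
                f"unknown behaviour state {name!r}; allowed values: {allowed}"
            ) from None

    @property
    def label(self) -> str:
        return self.name.lower()


CLASS_NAMES = tuple(c.label for c in BehaviourClass)  # ("feeding", "mobile", "stationary")
N_CLASSES = len(BehaviourClass)


def derive_blocks(timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Assign a block id to each bin: a new block starts wherever consecutive
    bins are not exactly 5 minutes apart."""
    if len(timestamps) == 0:
        return np.zeros(0, dtype=np.int64)
    gaps = np.ones(len(timestamps), dtype=bool)
    gaps[1:] = (timestamps[1:] - timestamps[:-1]) != BIN_DELTA
    return np.cumsum(gaps) - 1


def _as_index(timestamps) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(timestamps)
    if len(idx) > 1:
        diffs = idx[1:] - idx[:-1]
        if (diffs <= pd.Timedelta(0)).any():
            pos = int(np.argmax(diffs <= pd.Timedelta(0)))
            raise ValueError(
                f"timestamps must be strictly increasing; violation after row {pos}"
            )
    return idx


@dataclass
class ActivitySeries:
    """Timestamped 5-minute bins of paired integer activity counts.

    Parameters
    ----------
    individual_id : str
        Animal / deployment identifier.
    timestamps : DatetimeIndex
        Bin start times (local), strictly increasing.
    counts : (n, 2) int array
        Per-bin activity counts, each channel in [0, 255].
    """

    individual_id: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    blocks: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = _as_index(self.timestamps)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must be an (n, 2) array")
        if counts.shape[0] != len(self.timestamps):
            raise ValueError("counts and timestamps length mismatch")
        if counts.size and (np.any(counts < 0) or np.any(counts > 255)):
            bad = int(np.argmax(np.any((counts < 0) | (counts > 255), axis=1)))
            raise ValueError(
                f"activity counts must lie in [0, 255]; row {bad} has {counts[bad]}"
            )
        self.counts = counts.astype(np.int64)
        if self.blocks is None:
            self.blocks = derive_blocks(self.timestamps)
        else:
            self.blocks = np.asarray(self.blocks, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_blocks(self) -> int:
        return int(self.blocks.max()) + 1 if len(self) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "act_x": self.counts[:, 0],
                "act_y": self.counts[:, 1],
                "block": self.blocks,
            }
        )


@dataclass
class ObservationSession:
    """One continuous focal follow: ordered behaviour-change events inside
    ``[start_ts, end_ts]``.  Each event marks the onset of its state."""

    session_id: str
    start_ts: pd.Timestamp
    end_ts: pd.Timestamp
    events: list  # list[(Timestamp, BehaviourClass)]

    def __post_init__(self) -> None:
        self.start_ts = pd.Timestamp(self.start_ts)
        self.end_ts = pd.Timestamp(self.end_ts)
        if self.end_ts <= self.start_ts:
            raise ValueError(f"session {self.session_id}: end_ts must be after start_ts")
        times = [pd.Timestamp(t) for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"session {self.session_id}: events out of order")
        for t in times:
            if t < self.start_ts or t > self.end_ts:
                raise ValueError(
                    f"session {self.session_id}: event at {t} outside session span"
                )
        self.events = [(pd.Timestamp(t), BehaviourClass(s)) for t, s in self.events]

    def state_intervals(self) -> list:
        """Piecewise-constant state function as ``[(lo, hi, state), ...]``.

        Time before the first event is unobserved and yields no interval.
        """
        out = []
        for i, (t, s) in enumerate(self.events):
            hi = self.events[i + 1][0] if i + 1 < len(self.events) else self.end_ts
            if hi > t:
                out.append((t, hi, s))
        return out


@dataclass
class ObservationLog:
    """Field observation sessions for one individual, ordered by start time."""

    sessions: list

    def __post_init__(self) -> None:
        self.sessions = sorted(self.sessions, key=lambda s: s.start_ts)
        for a, b in zip(self.sessions, self.sessions[1:]):
            if b.start_ts < a.end_ts:
                raise ValueError(
                    f"sessions {a.session_id!r} and {b.session_id!r} overlap"
                )

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self) -> Iterator[ObservationSession]:
        return iter(self.sessions)


@dataclass
class LabeledDataset:
    """Activity bins carrying a single behaviour label, grouped into sessions.

    The table has columns ``timestamp, act_x, act_y, label, session_id``;
    ``label`` holds integer behaviour codes.  Sessions are the original field
    follows and serve as cross-validation units; excluded (mixed) bins may
    split a session's bins into several contiguous runs.
    """

    table: pd.DataFrame
    dominance_threshold: float = 1.0

    def __post_init__(self) -> None:
        required = {"timestamp", "act_x", "act_y", "label", "session_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"labeled table missing columns: {sorted(missing)}")
        if not 0 < self.dominance_threshold <= 1:
            raise ValueError("dominance_threshold must be in (0, 1]")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def session_ids(self) -> list:
        return list(dict.fromkeys(self.table["session_id"]))

    @property
    def X(self) -> np.ndarray:
        return self.table[["act_x", "act_y"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=np.int64)

    def class_counts(self) -> dict:
        counts = self.table["label"].value_counts()
        return {c: int(counts.get(int(c), 0)) for c in BehaviourClass}

    def session(self, session_id) -> "LabeledDataset":
        sub = self.table[self.table["session_id"] == session_id]
        return LabeledDataset(sub.copy(), self.dominance_threshold)

    def drop_session(self, session_id) -> "LabeledDataset":
        sub = self.table[self.table["session_id"] != session_id]
        return LabeledDataset(sub.copy(), self.dominance_threshold)


@dataclass
class _AlignedTriples:
    """Shared behaviour of per-bin (feeding, mobile, stationary) triples."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    blocks: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CLASSES:
            raise ValueError("values must be an (n, 3) array")
        if self.values.shape[0] != len(self.timestamps):
            raise ValueError("values and timestamps length mismatch")
        if self.blocks is None:
            self.blocks = derive_blocks(self.timestamps)
        else:
            self.blocks = np.asarray(self.blocks, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.timestamps)

    def iter_blocks(self) -> Iterator[np.ndarray]:
        """Yield index arrays for each contiguous block, in time order."""
        for b in np.unique(self.blocks):
            yield np.flatnonzero(self.blocks == b)


class PosteriorSequence(_AlignedTriples):
    """Per-bin normalised class posteriors ``(P_feed, P_mob, P_stat)``.

    Each row is nonnegative and sums to one (within 1e-12).
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self) and (
            np.any(self.values < -1e-12)
            or np.any(np.abs(self.values.sum(axis=1) - 1.0) > 1e-9)
        ):
            raise ValueError("posterior rows must be nonnegative and sum to 1")


class LikelihoodSequence(_AlignedTriples):
    """Per-bin relative observation likelihoods, normalised to sum to one.

    Only ratios matter for decoding; the per-bin evidence constant P(o_t)
    is dropped, which offsets log-evidence by a data-dependent constant
    identical across transition-parameter settings.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self) and np.any(self.values < -1e-12):
            raise ValueError("likelihoods must be nonnegative")


@dataclass
class StatePath:
    """A decoded (or simulated ground-truth) behaviour sequence."""

    timestamps: pd.DatetimeIndex
    states: np.ndarray
    blocks: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (len(self.timestamps),):
            raise ValueError("states and timestamps length mismatch")
        valid = {int(c) for c in BehaviourClass}
        if len(self) and not set(np.unique(self.states)).issubset(valid):
            raise ValueError("states must be behaviour codes 1, 2 or 3")
        if self.blocks is None:
            self.blocks = derive_blocks(self.timestamps)
        else:
            self.blocks = np.asarray(self.blocks, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.timestamps)

    def iter_blocks(self) -> Iterator[np.ndarray]:
        for b in np.unique(self.blocks):
            yield np.flatnonzero(self.blocks == b)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "state": [BehaviourClass(s).label for s in self.states],
                "block": self.blocks,
            }
        )
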