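"""Behavioural summaries of decoded state sequences.

Bouts are maximal runs of one behaviour within a contiguous recording
block (recording gaps always break a bout).  Two interval notions are
exposed: end-to-start *pauses* between successive bouts (for interval
histograms) and start-to-start *recurrence* intervals (for the event rate
per day — an animal feeding every second day has rate 0.5).  Hour-of-day
profiles use local time; wet season is November through March, dry season
April through October.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BIN_MINUTES, BehaviourClass, StatePath

__all__ = [
    "Bout",
    "HourlyProfile",
    "IntervalHistogram",
    "extract_bouts",
    "hourly_profile",
    "inter_event_intervals",
    "interval_histogram",
    "event_rate_per_day",
    "assign_season",
    "seasonal_partition",
]

WET_MONTHS = frozenset({11, 12, 1, 2, 3})


@dataclass(frozen=True)
class Bout:
    """A maximal run of one behaviour; duration is a multiple of 5 minutes."""

    behaviour: BehaviourClass
    start_ts: pd.Timestamp
    end_ts: pd.Timestamp

    @property
    def duration_minutes(self) -> float:
        return (self.end_ts - self.start_ts) / pd.Timedelta(minutes=1)

    @property
    def n_bins(self) -> int:
        return round(self.duration_minutes / BIN_MINUTES)


def extract_bouts(states: StatePath, target: BehaviourClass) -> list:
    """Maximal runs of ``target`` within each contiguous block, in time order."""
    bouts = []
    for idx in states.iter_blocks():
        s = states.states[idx]
        hit = s == int(target)
        if not hit.any():
            continue
        edges = np.diff(hit.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if hit[0]:
            starts.insert(0, 0)
        if hit[-1]:
            ends.append(len(s))
        for a, b in zip(starts, ends):
            bouts.append(
                Bout(
                    behaviour=BehaviourClass(target),
                    start_ts=states.timestamps[idx[a]],
                    end_ts=states.timestamps[idx[b - 1]]
                    + pd.Timedelta(minutes=BIN_MINUTES),
                )
            )
    return bouts


@dataclass
class HourlyProfile:
    """Distribution of decoded states per local hour of day.

    ``fractions`` is 24x3 (feeding, mobile, stationary); rows with
    ``counts == 0`` have no data and hold NaN.
    """

    fractions: np.ndarray
    counts: np.ndarray

    @property
    def missing_hours(self) -> np.ndarray:
        return np.flatnonzero(self.counts == 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hour": np.arange(24),
                "frac_feeding": self.fractions[:, 0],
                "frac_mobile": self.fractions[:, 1],
                "frac_stationary": self.fractions[:, 2],
                "n": self.counts,
            }
        )


def hourly_profile(states: StatePath) -> HourlyProfile:
    """Per-hour class distribution among bins whose start hour is h."""
    if len(states) == 0:
        raise ValueError("empty state path")
    hours = states.timestamps.hour.to_numpy()
    counts = np.zeros(24, dtype=np.int64)
    frac = np.full((24, 3), np.nan)
    for h in range(24):
        sel = states.states[hours == h]
        counts[h] = len(sel)
        if len(sel):
            frac[h] = [np.mean(sel == int(c)) for c in BehaviourClass]
    return HourlyProfile(fractions=frac, counts=counts)


def inter_event_intervals(bouts: list) -> list:
    """End-to-start pauses between successive bouts, as Timedeltas.

    Fewer than two bouts yield an empty list.
    """
    bouts = sorted(bouts, key=lambda b: b.start_ts)
    return [b.start_ts - a.end_ts for a, b in zip(bouts, bouts[1:])]


@dataclass
class IntervalHistogram:
    """Histogram of durations with a fixed bin width."""

    bin_width: pd.Timedelta
    edges: np.ndarray  # in units of bin_width
    counts: np.ndarray
    intervals: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lo": self.edges[:-1], "hi": self.edges[1:], "count": self.counts}
        )


def interval_histogram(intervals: list, bin_width: pd.Timedelta) -> IntervalHistogram:
    """Bin a list of Timedeltas into fixed-width bins starting at zero."""
    vals = np.array([iv / bin_width for iv in intervals], dtype=float)
    n_bins = max(1, int(np.ceil(vals.max())) if len(vals) else 1)
    counts, edges = np.histogram(vals, bins=n_bins, range=(0, n_bins))
    return IntervalHistogram(
        bin_width=bin_width, edges=edges, counts=counts, intervals=list(intervals)
    )


def event_rate_per_day(bouts: list, interval: str = "start_to_start") -> float:
    """Average number of events per day.

    The reciprocal of the mean inter-event interval in days; by default
    start-to-start recurrence intervals (an event every second day gives
    0.5).  ``interval='end_to_start'`` uses pauses instead.
    """
    bouts = sorted(bouts, key=lambda b: b.start_ts)
    if len(bouts) < 2:
        raise ValueError("event rate needs at least 2 bouts")
    if interval == "start_to_start":
        deltas = [b.start_ts - a.start_ts for a, b in zip(bouts, bouts[1:])]
    elif interval == "end_to_start":
        deltas = inter_event_intervals(bouts)
    else:
        raise ValueError("interval must be 'start_to_start' or 'end_to_start'")
    mean_days = np.mean([d / pd.Timedelta(days=1) for d in deltas])
    if mean_days <= 0:
        raise ValueError("mean inter-event interval is not positive")
    return float(1.0 / mean_days)


def assign_season(ts) -> str:
    """'wet' for November-March, 'dry' for April-October (local time)."""
    return "wet" if pd.Timestamp(ts).month in WET_MONTHS else "dry"


def seasonal_partition(states: StatePath) -> tuple:
    """Split a path into (wet, dry) sub-paths by each bin's start timestamp.

    Every bin lands in exactly one partition; block structure is re-derived
    inside each partition, so bouts crossing a season boundary are split.
    """
    if len(states) == 0:
        raise ValueError("empty state path")
    months = states.timestamps.month.to_numpy()
    wet_mask = np.isin(months, list(WET_MONTHS))
    parts = []
    for mask in (wet_mask, ~wet_mask):
        parts.append(
            StatePath(
                timestamps=states.timestamps[mask], states=states.states[mask]
            )
        )
    return tuple(parts)
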