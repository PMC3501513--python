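"""Synthetic study generator: ground-truth behaviour chains, 0-255 bi-axial
activity emissions and focal-follow observation sessions.

The generator mirrors the statistical structure the pipeline assumes: a
first-order Markov behaviour chain with per-class stay probabilities,
class-conditional bivariate-normal activity emissions rounded and clipped to
the 0-255 integer grid (stationary low, feeding intermediate, mobile high —
partially overlapping clusters), and non-overlapping observation sessions of
one to three hours whose behaviour-change events are written from the
ground-truth path.  A single master seed is split into named substreams
(states, emissions, sessions) so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hmm import build_transition_matrix
from .types import (
    BIN_DELTA,
    ActivitySeries,
    BehaviourClass,
    ObservationLog,
    ObservationSession,
    StatePath,
)

__all__ = [
    "EmissionSpec",
    "GeneratorConfig",
    "SyntheticStudy",
    "simulate_states",
    "emit_activity",
    "sample_sessions",
    "generate_study",
]

# substream order under the master seed; keep stable across releases
_STREAMS = ("states", "emissions", "sessions")


def _substream(seed: int, name: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(name)])


@dataclass(frozen=True)
class EmissionSpec:
    """Class-conditional bivariate emission distributions on the count scale.

    Defaults place stationary low, feeding intermediate and mobile high,
    with a common diagonal covariance of 225 (sd 15 counts) per channel —
    well-separated but adjacent clusters.
    """

    means: dict = field(
        default_factory=lambda: {
            BehaviourClass.FEEDING: (80.0, 70.0),
            BehaviourClass.MOBILE: (180.0, 160.0),
            BehaviourClass.STATIONARY: (20.0, 15.0),
        }
    )
    covs: dict = field(
        default_factory=lambda: {
            c: ((225.0, 0.0), (0.0, 225.0)) for c in BehaviourClass
        }
    )

    def __post_init__(self) -> None:
        for c in BehaviourClass:
            mu = np.asarray(self.means[c], float)
            if mu.shape != (2,) or np.any(mu < 0) or np.any(mu > 255):
                raise ValueError(f"mean for {c.label} must be a 2-vector in [0, 255]")
            cov = np.asarray(self.covs[c], float)
            if cov.shape != (2, 2) or np.any(np.linalg.eigvalsh(cov) < -1e-9):
                raise ValueError(f"covariance for {c.label} must be 2x2 PSD")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic deployment.

    Sessions are 12-36 bins (one to three hours, matching the field minimum
    of one hour per follow) and aligned to bin boundaries by default, which
    guarantees each labelled bin holds a single behaviour.
    """

    n_bins: int = 20_000
    stay: tuple = (0.8, 0.9, 0.9)
    emissions: EmissionSpec = field(default_factory=EmissionSpec)
    n_sessions: int = 4
    session_min_len: int = 12
    session_max_len: int = 36
    align_sessions: bool = True
    dwell_mode: str = "geometric"
    start_time: str = "2010-06-01 00:00"
    individual_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not 1 <= self.session_min_len <= self.session_max_len:
            raise ValueError("invalid session length range")
        if self.session_min_len < 12:
            raise ValueError("sessions must be at least 12 bins (one hour)")
        if self.dwell_mode not in ("geometric", "fixed"):
            raise ValueError("dwell_mode must be 'geometric' or 'fixed'")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class SyntheticStudy:
    """Aligned activity series, observation log and ground-truth path."""

    activity: ActivitySeries
    log: ObservationLog
    truth: StatePath
    config: GeneratorConfig


def _timestamps(config: GeneratorConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.start_time)
    return pd.DatetimeIndex([start + i * BIN_DELTA for i in range(config.n_bins)])


def simulate_states(
    stay: tuple, n_bins: int, seed: int = 0, start_time: str = "2010-06-01 00:00"
) -> StatePath:
    """First-order Markov behaviour chain; initial state drawn uniformly."""
    rng = _substream(seed, "states")
    T = build_transition_matrix(tuple(stay))
    cum = np.cumsum(T, axis=1)
    states = np.empty(n_bins, dtype=np.int64)
    u = rng.random(n_bins)
    states[0] = rng.integers(3)
    for t in range(1, n_bins):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    start = pd.Timestamp(start_time)
    ts = pd.DatetimeIndex([start + i * BIN_DELTA for i in range(n_bins)])
    return StatePath(timestamps=ts, states=states + 1)


def _simulate_fixed_dwell(
    stay: tuple, n_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Deterministic dwell lengths (mean of the geometric, 1/(1-stay) bins);
    exercises model mismatch against the geometric decoder assumption."""
    dwell = [max(1, round(1.0 / (1.0 - p))) if p < 1 else n_bins for p in stay]
    out = np.empty(n_bins, dtype=np.int64)
    state = int(rng.integers(3))
    t = 0
    while t < n_bins:
        run = min(dwell[state], n_bins - t)
        out[t : t + run] = state
        t += run
        state = [j for j in range(3) if j != state][int(rng.integers(2))]
    return out + 1


def emit_activity(
    truth: StatePath, spec: EmissionSpec | None = None, seed: int = 0,
    individual_id: str = "synthetic",
) -> ActivitySeries:
    """Draw per-bin activity counts from the class-conditional distributions,
    rounded to integers and clipped to [0, 255]."""
    spec = spec or EmissionSpec()
    rng = _substream(seed, "emissions")
    n = len(truth)
    raw = np.empty((n, 2))
    normals = rng.standard_normal((n, 2))
    for c in BehaviourClass:
        sel = truth.states == int(c)
        if not sel.any():
            continue
        chol = np.linalg.cholesky(
            np.asarray(spec.covs[c], float) + 1e-12 * np.eye(2)
        )
        raw[sel] = np.asarray(spec.means[c], float) + normals[sel] @ chol.T
    counts = np.clip(np.rint(raw), 0, 255).astype(np.int64)
    return ActivitySeries(
        individual_id=individual_id, timestamps=truth.timestamps, counts=counts
    )


def sample_sessions(
    truth: StatePath,
    count: int,
    min_len: int = 12,
    max_len: int = 36,
    seed: int = 0,
    align: bool = True,
) -> ObservationLog:
    """Place non-overlapping observation windows and transcribe the truth.

    Windows are aligned to bin boundaries (``align=True``); lengths are
    uniform in ``[min_len, max_len]`` bins.  Events record each state onset
    inside the window; an 'end' marker closes the session at the window end.
    """
    rng = _substream(seed, "sessions")
    n = len(truth)
    if count < 1:
        raise ValueError("count must be >= 1")
    lengths = rng.integers(min_len, max_len + 1, size=count)
    free = n - int(lengths.sum())
    if free < 0:
        raise ValueError(
            f"cannot place {count} sessions of total {lengths.sum()} bins "
            f"in {n} bins"
        )
    gaps = rng.multinomial(free, np.full(count + 1, 1.0 / (count + 1)))
    sessions = []
    pos = 0
    for k in range(count):
        pos += int(gaps[k])
        start_idx, end_idx = pos, pos + int(lengths[k])
        start_ts = truth.timestamps[start_idx]
        end_ts = truth.timestamps[end_idx - 1] + BIN_DELTA
        if not align:
            # push the session edges inside the first/last bin so those bins
            # are only partially covered (stress-tests the synchroniser)
            offset = pd.Timedelta(minutes=float(rng.uniform(0.5, 4.0)))
            start_ts = start_ts + offset
            end_ts = end_ts - offset
        events = [(start_ts, BehaviourClass(truth.states[start_idx]))]
        for i in range(start_idx + 1, end_idx):
            if truth.states[i] != truth.states[i - 1]:
                events.append((truth.timestamps[i], BehaviourClass(truth.states[i])))
        sessions.append(
            ObservationSession(
                session_id=f"s{k:02d}", start_ts=start_ts, end_ts=end_ts,
                events=events,
            )
        )
        pos = end_idx
    return ObservationLog(sessions=sessions)


def generate_study(config: GeneratorConfig | None = None, **overrides) -> SyntheticStudy:
    """Compose states -> emissions -> sessions under one master seed."""
    config = (config or GeneratorConfig()).replace(**overrides)
    if config.dwell_mode == "fixed":
        rng = _substream(config.seed, "states")
        states = _simulate_fixed_dwell(config.stay, config.n_bins, rng)
        truth = StatePath(timestamps=_timestamps(config), states=states)
    else:
        truth = simulate_states(
            config.stay, config.n_bins, seed=config.seed,
            start_time=config.start_time,
        )
    activity = emit_activity(
        truth, config.emissions, seed=config.seed,
        individual_id=config.individual_id,
    )
    log = sample_sessions(
        truth,
        config.n_sessions,
        config.session_min_len,
        config.session_max_len,
        seed=config.seed,
        align=config.align_sessions,
    )
    return SyntheticStudy(activity=activity, log=log, truth=truth, config=config)
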