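"""Shared fixtures and brute-force HMM oracles."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

from ethosmooth.types import (
    BIN_DELTA,
    ActivitySeries,
    LabeledDataset,
    LikelihoodSequence,
    StatePath,
)

T0 = pd.Timestamp("2010-06-01 00:00")


def bin_times(n: int, start: pd.Timestamp = T0) -> pd.DatetimeIndex:
    return pd.DatetimeIndex([start + i * BIN_DELTA for i in range(n)])


# --- brute-force oracles (independent of the log-space implementations) ---


def brute_force_paths(L: np.ndarray, T: np.ndarray, pi: np.ndarray):
    """Score every 3^N path directly in probability space.

    Returns (best_path, best_score, total_probability); the first maximum in
    lexicographic path order is kept.
    """
    n = len(L)
    best_path, best_score, total = None, -1.0, 0.0
    for path in product(range(3), repeat=n):
        p = pi[path[0]] * L[0, path[0]]
        for t in range(1, n):
            p *= T[path[t - 1], path[t]] * L[t, path[t]]
        total += p
        if p > best_score:
            best_path, best_score = path, p
    return np.array(best_path) + 1, best_score, total


def path_log_score(states: np.ndarray, L: np.ndarray, T: np.ndarray, pi: np.ndarray):
    """Log probability of one concrete path (zero-indexed internally)."""
    s = np.asarray(states) - 1
    with np.errstate(divide="ignore"):
        logp = np.log(pi[s[0]]) + np.log(L[0, s[0]])
        for t in range(1, len(s)):
            logp += np.log(T[s[t - 1], s[t]]) + np.log(L[t, s[t]])
    return logp


def random_hmm_instance(rng: np.random.Generator, n_max: int = 8):
    """A random valid (likelihoods, transition matrix, initial) triple."""
    n = int(rng.integers(1, n_max + 1))
    L = rng.random((n, 3)) + 1e-3
    L /= L.sum(axis=1, keepdims=True)
    T = rng.random((3, 3)) + 1e-3
    T /= T.sum(axis=1, keepdims=True)
    pi = rng.random(3) + 1e-3
    pi /= pi.sum()
    return L, T, pi


def as_likelihood_sequence(L: np.ndarray) -> LikelihoodSequence:
    return LikelihoodSequence(bin_times(len(L)), L)


# --- synthetic labelled data --------------------------------------------

CLUSTER_MEANS = {1: (80.0, 70.0), 2: (180.0, 160.0), 3: (20.0, 15.0)}


def make_labeled(
    rng: np.random.Generator,
    n_sessions: int = 4,
    bins_per_session: int = 24,
    sd: float = 5.0,
    labels=None,
) -> LabeledDataset:
    """Well-separated labelled sessions with contiguous 8-bin class runs."""
    rows = []
    for s in range(n_sessions):
        base = T0 + pd.Timedelta(days=s)
        for i in range(bins_per_session):
            label = labels[s][i] if labels is not None else [1, 2, 3][(i // 8) % 3]
            mu = CLUSTER_MEANS[label]
            xy = np.clip(np.rint(rng.normal(mu, sd)), 0, 255)
            rows.append((base + i * BIN_DELTA, xy[0], xy[1], label, f"s{s}"))
    return LabeledDataset(
        pd.DataFrame(rows, columns=["timestamp", "act_x", "act_y", "label", "session_id"])
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120)


@pytest.fixture
def separable_labeled(rng) -> LabeledDataset:
    return make_labeled(rng)


@pytest.fixture
def separable_activity(separable_labeled) -> ActivitySeries:
    t = separable_labeled.table
    return ActivitySeries(
        "fixture", pd.DatetimeIndex(t["timestamp"]), t[["act_x", "act_y"]].to_numpy()
    )


def make_path(states, start: pd.Timestamp = T0) -> StatePath:
    states = np.asarray(states)
    return StatePath(bin_times(len(states), start), states)
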