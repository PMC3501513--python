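"""Three-state hidden Markov smoothing of the SVM posteriors.

The transition model has one free parameter per state — the *stay*
probability T[i][i] — with the remaining mass split equally between the two
alternative behaviours.  Under a first-order chain a stay probability p
implies a geometric dwell with mean 5/(1-p) minutes.  Defaults are
stay_feed = 0.8 and stay_mob = stay_stat = 0.9: feeding bouts are expected
to be shorter than mobile or stationary spells.

SVM posteriors P(S_i | o_t) are converted to observation likelihoods
P(o_t | S_i) via Bayes' rule with configurable (default uniform) state
priors; the per-bin constant P(o_t) is dropped, which leaves Viterbi
decoding and across-parameter evidence comparisons unchanged.  Decoding and
evidence run in log space per contiguous recording block, restarting the
initial distribution at each gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BehaviourClass,
    LikelihoodSequence,
    PosteriorSequence,
    StatePath,
)

__all__ = [
    "HMMParams",
    "EvidenceCurve",
    "build_transition_matrix",
    "posteriors_to_likelihoods",
    "viterbi_decode",
    "log_evidence",
    "evidence_sweep",
]

UNIFORM = np.full(3, 1.0 / 3.0)


@dataclass(frozen=True)
class HMMParams:
    """Stay probabilities and initial distribution of the 3-state chain."""

    stay_feed: float = 0.8
    stay_mob: float = 0.9
    stay_stat: float = 0.9
    initial: np.ndarray = field(default_factory=lambda: UNIFORM.copy())

    def __post_init__(self) -> None:
        for name in ("stay_feed", "stay_mob", "stay_stat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        pi = np.asarray(self.initial, float)
        if pi.shape != (3,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must be a length-3 simplex vector")
        object.__setattr__(self, "initial", pi)

    @property
    def stays(self) -> tuple:
        return (self.stay_feed, self.stay_mob, self.stay_stat)

    def mean_dwell_minutes(self) -> tuple:
        """Geometric mean dwell per state, 5/(1-stay) minutes (inf if stay=1)."""
        return tuple(
            np.inf if p == 1.0 else 5.0 / (1.0 - p) for p in self.stays
        )


def build_transition_matrix(params: HMMParams | tuple) -> np.ndarray:
    """Row-stochastic 3x3 transition matrix from stay probabilities.

    ``T[i][i] = stay_i`` and ``T[i][j] = (1 - stay_i)/2`` for ``j != i`` —
    both alternatives are equally likely, keeping the model at three
    parameters.
    """
    if not isinstance(params, HMMParams):
        params = HMMParams(*params)
    T = np.empty((3, 3))
    for i, stay in enumerate(params.stays):
        T[i] = (1.0 - stay) / 2.0
        T[i, i] = stay
    return T


def posteriors_to_likelihoods(
    post: PosteriorSequence, state_priors=None
) -> LikelihoodSequence:
    """Convert posteriors to relative observation likelihoods via Bayes' rule.

    ``L_i ∝ P(S_i | o) / P(S_i)``, renormalised per bin.  With the default
    uniform priors this is the identity on the posterior triples.
    """
    priors = UNIFORM if state_priors is None else np.asarray(state_priors, float)
    if priors.shape != (3,) or abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError("state_priors must be a length-3 simplex vector")
    if np.any(priors <= 0):
        raise ValueError("state priors must be strictly positive")
    lik = post.values / priors
    lik = lik / lik.sum(axis=1, keepdims=True)
    return LikelihoodSequence(
        timestamps=post.timestamps, values=lik, blocks=post.blocks
    )


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _viterbi_block(logL: np.ndarray, logT: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    n = len(logL)
    delta = logpi + logL[0]
    psi = np.zeros((n, 3), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + logT  # cand[i, j]
        psi[t] = np.argmax(cand, axis=0)  # first max -> lowest state index
        delta = cand[psi[t], np.arange(3)] + logL[t]
        if np.all(np.isinf(delta)):
            raise ValueError(f"zero-probability dead end at step {t} of block")
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path + 1  # behaviour codes


def viterbi_decode(
    lik: LikelihoodSequence, T: np.ndarray, initial=None
) -> StatePath:
    """Most probable state path, decoded independently per contiguous block.

    Maximises ``pi(q_1) L(q_1) prod T(q_{t-1}, q_t) L(q_t)`` in log space.
    Ties break towards the lowest behaviour code
    (feeding < mobile < stationary), so decoding is deterministic.
    """
    pi = UNIFORM if initial is None else np.asarray(initial, float)
    logT, logpi, logL = _log(np.asarray(T, float)), _log(pi), _log(lik.values)
    states = np.empty(len(lik), dtype=np.int64)
    for idx in lik.iter_blocks():
        states[idx] = _viterbi_block(logL[idx], logT, logpi)
    return StatePath(timestamps=lik.timestamps, states=states, blocks=lik.blocks)


def log_evidence(lik: LikelihoodSequence, T: np.ndarray, initial=None) -> float:
    """Log marginal probability of the observation sequence under the chain.

    Scaled forward recursion (per-step normalisation with an accumulated log
    scale) for numerical stability; a multi-block input returns the sum of
    per-block log-evidences, the initial distribution restarting at each
    block.  Because likelihoods are per-bin normalised, this is offset from
    the true log evidence by a constant shared across transition settings.
    """
    pi = UNIFORM if initial is None else np.asarray(initial, float)
    T = np.asarray(T, float)
    total = 0.0
    for idx in lik.iter_blocks():
        L = lik.values[idx]
        alpha = pi * L[0]
        scale = alpha.sum()
        if scale == 0.0:
            raise ValueError("zero-probability dead end at block start")
        alpha /= scale
        logev = np.log(scale)
        for t in range(1, len(L)):
            alpha = (alpha @ T) * L[t]
            scale = alpha.sum()
            if scale == 0.0:
                raise ValueError(f"zero-probability dead end at step {t} of block")
            alpha /= scale
            logev += np.log(scale)
        total += logev
    return float(total)


@dataclass
class EvidenceCurve:
    """Summed held-out log evidence as a function of the feeding stay probability."""

    grid: np.ndarray
    log_evidence: np.ndarray  # summed over sessions, per grid value
    per_session: np.ndarray  # (n_grid, n_sessions)
    session_ids: list

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.log_evidence))])


def evidence_sweep(
    data,
    kernel=None,
    grid=None,
    fixed: tuple = (0.9, 0.9),
    state_priors=None,
    initial=None,
    seed: int = 0,
) -> EvidenceCurve:
    """Leave-one-session-out evidence profile over the feeding stay probability.

    For each held-out session, an SVM is trained on the remaining sessions
    and the held-out posteriors converted to likelihoods once; the log
    evidence of the held-out session's contiguous labelled runs is then
    evaluated for every grid value of ``stay_feed`` (mobile and stationary
    stays held at ``fixed``), and summed over sessions.
    """
    from .svm import predict_posterior_sequence, train_one_vs_rest
    from .types import ActivitySeries

    grid = np.arange(0.0, 0.96, 0.05) if grid is None else np.asarray(grid, float)
    if np.any(grid < 0) or np.any(grid >= 1):
        raise ValueError("grid values must lie in [0, 1)")
    sessions = data.session_ids
    if len(sessions) < 2:
        raise ValueError("evidence sweep needs at least 2 observation sessions")
    held_liks = []
    for sid in sessions:
        train, test = data.drop_session(sid), data.session(sid)
        model = train_one_vs_rest(train, kernel, seed=seed)
        act = ActivitySeries(
            individual_id=str(sid),
            timestamps=pd.DatetimeIndex(test.table["timestamp"]),
            counts=test.X,
        )
        post = predict_posterior_sequence(model, act)
        held_liks.append(posteriors_to_likelihoods(post, state_priors))
    per_session = np.empty((len(grid), len(sessions)))
    for gi, stay_feed in enumerate(grid):
        T = build_transition_matrix((stay_feed, *fixed))
        for si, lik in enumerate(held_liks):
            per_session[gi, si] = log_evidence(lik, T, initial)
    return EvidenceCurve(
        grid=grid,
        log_evidence=per_session.sum(axis=1),
        per_session=per_session,
        session_ids=list(sessions),
    )
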