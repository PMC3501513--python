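"""Leave-one-session-out cross-validation and classification metrics.

Each field-observation session is held out in turn: the one-vs-rest SVMs
are retrained on the remaining sessions (the full pipeline, including the
logistic/fusion stage, is refit per fold) and predictions for the held-out
session's labelled bins are compared against the field labels.  In
``svm_hmm`` mode the held-out posteriors are first smoothed by Viterbi
decoding over the session's contiguous labelled runs; by default only the
session's own bins provide temporal context (no neighbouring unlabelled
data), which can be relaxed by passing the full activity series.

Fold counts are pooled into a single confusion matrix before metrics are
derived, which keeps every metric well defined even when an individual fold
lacks a class; a per-fold-mean aggregation is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import (
    HMMParams,
    build_transition_matrix,
    posteriors_to_likelihoods,
    viterbi_decode,
)
from .svm import KernelSpec, predict_posterior_sequence, train_one_vs_rest
from .types import (
    ActivitySeries,
    BehaviourClass,
    LabeledDataset,
)

__all__ = [
    "ConfusionMatrix",
    "CVReport",
    "leave_one_session_out",
    "summarize_confusion",
    "missed_event_probability",
]


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError("confusion matrix must be 3x3 with nonnegative counts")
        self.counts = c.astype(np.int64)

    def add(self, true: np.ndarray, pred: np.ndarray) -> None:
        for t, p in zip(np.asarray(true), np.asarray(pred)):
            self.counts[int(t) - 1, int(p) - 1] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [c.label for c in BehaviourClass]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class CVReport:
    """Cross-validation metric suite.

    per_class_accuracy is recall (diagonal over row sum); the false-positive
    rate of class X is the fraction of X-predictions that are not truly X
    (column sum minus diagonal, over column sum) — NaN when X is never
    predicted.
    """

    overall_accuracy: float
    per_class_accuracy: dict
    per_class_false_positive: dict
    per_class_counts: dict
    total_labeled: int
    mode: str
    confusion: ConfusionMatrix
    fold_errors: dict = field(default_factory=dict)
    aggregate: str = "pooled"
    per_fold_accuracy: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Leave-one-session-out cross-validation ({self.mode}, {self.aggregate})",
            f"  Labelled data points: {self.total_labeled}",
            f"  Percent correct (overall):   {100 * self.overall_accuracy:6.2f}%",
        ]
        for c in BehaviourClass:
            lines.append(
                f"  Percent correct ({c.label + ')':<12} "
                f"{100 * self.per_class_accuracy[c]:6.2f}%"
            )
        for c in BehaviourClass:
            fp = self.per_class_false_positive[c]
            fp_s = "   n/a" if np.isnan(fp) else f"{100 * fp:6.2f}%"
            lines.append(f"  False positives ({c.label + ')':<12} {fp_s}")
        for c in BehaviourClass:
            lines.append(
                f"  {(c.label.capitalize() + ' data points:'):<29}"
                f"{self.per_class_counts[c]}"
            )
        if self.fold_errors:
            lines.append(f"  Folds skipped with errors: {len(self.fold_errors)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "aggregate": self.aggregate,
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": {
                c.label: self.per_class_accuracy[c] for c in BehaviourClass
            },
            "per_class_false_positive": {
                c.label: self.per_class_false_positive[c] for c in BehaviourClass
            },
            "per_class_counts": {
                c.label: self.per_class_counts[c] for c in BehaviourClass
            },
            "total_labeled": self.total_labeled,
            "confusion": self.confusion.counts.tolist(),
            "fold_errors": {str(k): str(v) for k, v in self.fold_errors.items()},
        }


def summarize_confusion(
    cm: ConfusionMatrix, mode: str = "svm_only", **kwargs
) -> CVReport:
    """Derive the metric suite from pooled confusion counts."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    diag = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
        fp = np.where(col > 0, (col - diag) / np.where(col > 0, col, 1), np.nan)
    report = CVReport(
        overall_accuracy=float(diag.sum() / total),
        per_class_accuracy={c: float(recall[i]) for i, c in enumerate(BehaviourClass)},
        per_class_false_positive={
            c: float(fp[i]) for i, c in enumerate(BehaviourClass)
        },
        per_class_counts={c: int(row[i]) for i, c in enumerate(BehaviourClass)},
        total_labeled=int(total),
        mode=mode,
        confusion=cm,
        **kwargs,
    )
    # algebraic identity: overall accuracy is the count-weighted recall mean
    weighted = sum(
        report.per_class_accuracy[c] * report.per_class_counts[c]
        for c in BehaviourClass
        if report.per_class_counts[c] > 0
    )
    assert abs(weighted / total - report.overall_accuracy) < 1e-12
    return report


def _session_bins(
    test: LabeledDataset, context_activity: ActivitySeries | None
):
    """Bins over which the held-out session is predicted.

    Returns (ActivitySeries, labeled_mask, labels).  Without context the
    session's own labelled bins form the series (excluded bins split it into
    contiguous runs); with context every collar bin spanning the session's
    labelled range is used and evaluated only at labelled bins.
    """
    ts = pd.DatetimeIndex(test.table["timestamp"])
    if context_activity is None:
        act = ActivitySeries("held-out", ts, test.X)
        return act, np.ones(len(ts), bool), test.y
    lo, hi = ts.min(), ts.max()
    sel = (context_activity.timestamps >= lo) & (context_activity.timestamps <= hi)
    idx = np.flatnonzero(sel)
    act = ActivitySeries(
        "held-out",
        context_activity.timestamps[idx],
        context_activity.counts[idx],
    )
    pos = {t: i for i, t in enumerate(act.timestamps)}
    mask = np.zeros(len(act), bool)
    labels = np.zeros(len(act), dtype=np.int64)
    for t, lab in zip(ts, test.y):
        mask[pos[t]] = True
        labels[pos[t]] = lab
    return act, mask, labels[mask]


def leave_one_session_out(
    data: LabeledDataset,
    kernel: KernelSpec | None = None,
    hmm: HMMParams | None = None,
    mode: str = "svm_hmm",
    aggregate: str = "pooled",
    context_activity: ActivitySeries | None = None,
    state_priors=None,
    seed: int = 0,
) -> tuple:
    """Run leave-one-session-out cross-validation.

    Returns ``(ConfusionMatrix, CVReport)``.  A fold whose training split
    lacks a class is skipped and recorded in ``report.fold_errors``.
    """
    if mode not in ("svm_only", "svm_hmm"):
        raise ValueError("mode must be 'svm_only' or 'svm_hmm'")
    if aggregate not in ("pooled", "per_fold_mean"):
        raise ValueError("aggregate must be 'pooled' or 'per_fold_mean'")
    hmm = hmm or HMMParams()
    sessions = data.session_ids
    if len(sessions) < 2:
        raise ValueError("cross-validation needs at least 2 observation sessions")
    T = build_transition_matrix(hmm)
    pooled = ConfusionMatrix()
    fold_errors: dict = {}
    per_fold_accuracy: dict = {}
    for sid in sessions:
        train = data.drop_session(sid)
        test = data.session(sid)
        try:
            model = train_one_vs_rest(train, kernel, seed=seed)
        except ValueError as exc:
            fold_errors[sid] = exc
            continue
        act, mask, labels = _session_bins(test, context_activity)
        post = predict_posterior_sequence(model, act)
        if mode == "svm_hmm":
            lik = posteriors_to_likelihoods(post, state_priors)
            pred = viterbi_decode(lik, T, hmm.initial).states[mask]
        else:
            pred = np.argmax(post.values, axis=1)[mask] + 1
        pooled.add(labels, pred)
        per_fold_accuracy[sid] = float(np.mean(pred == labels))
    if pooled.total == 0:
        raise ValueError(
            "no fold completed; errors: "
            + "; ".join(f"{k}: {v}" for k, v in fold_errors.items())
        )
    report = summarize_confusion(
        pooled,
        mode=mode,
        fold_errors=fold_errors,
        aggregate=aggregate,
        per_fold_accuracy=per_fold_accuracy,
    )
    if aggregate == "per_fold_mean":
        report.overall_accuracy = float(
            np.mean(list(per_fold_accuracy.values()))
        )
    return pooled, report


def missed_event_probability(per_point_error: float, n_points: int) -> float:
    """Probability that an n-bin behavioural event is missed entirely.

    With independent per-bin errors, a run of n bins is missed only if every
    bin is misclassified: ``per_point_error ** n_points``.  E.g. a one-hour
    feeding event spans 12 five-minute bins.
    """
    if not 0.0 <= per_point_error <= 1.0:
        raise ValueError("per_point_error must lie in [0, 1]")
    if n_points < 1:
        raise ValueError("n_points must be a positive integer")
    return float(per_point_error**n_points)
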