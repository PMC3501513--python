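"""One-vs-rest Gaussian-kernel SVMs and posterior fusion.

Three binary maximum-margin classifiers are trained, one per behaviour
class (positives: that class; negatives: the other two pooled).  Signed
decision values pass through the logistic function to give per-class
probabilities p_f, p_m, p_s, which are fused under the constraint that only
one behaviour is present at a time:

    raw_f = p_f (1 - p_m)(1 - p_s),   (and cyclically for m, s)

then normalised to sum to one per bin.  The Gaussian kernel is
``k(x, x') = exp(-||x - x'||^2 / (2 b^2))`` with bandwidth ``b``; inputs are
standardised per channel with training statistics before kernel evaluation,
since raw 0-255 counts would otherwise dominate the bandwidth choice.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist
from scipy.special import expit
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from .types import (
    ActivitySeries,
    BehaviourClass,
    LabeledDataset,
    PosteriorSequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "OvRModel",
    "median_bandwidth",
    "train_one_vs_rest",
    "logistic_map",
    "fuse_posteriors",
    "predict_posterior_sequence",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian-kernel hyper-parameters.

    bandwidth
        Kernel width ``b`` in standardised input units; ``None`` means
        "resolve with the median heuristic at training time".
    regularization
        Soft-margin penalty C.
    """

    bandwidth: float | None = None
    regularization: float = 1.0

    def __post_init__(self) -> None:
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")

    @property
    def gamma(self) -> float:
        if self.bandwidth is None:
            raise ValueError("bandwidth not resolved")
        return 1.0 / (2.0 * self.bandwidth**2)


def median_bandwidth(points, size_cap: int = 2000, seed: int = 0) -> float:
    """Median pairwise Euclidean distance over distinct index pairs.

    Above ``size_cap`` points a seeded subsample is used.  Raises if the
    median distance is zero (e.g. all points identical), in which case an
    explicit bandwidth must be supplied.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 points")
    if len(pts) > size_cap:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size_cap, replace=False)]
    med = float(np.median(pdist(pts)))
    if med <= 0:
        raise ValueError(
            "median pairwise distance is zero (points coincide); "
            "supply an explicit bandwidth"
        )
    return med


def logistic_map(decision_value):
    """Logistic link 1 / (1 + exp(-t)) applied to a decision value."""
    return expit(decision_value)


def fuse_posteriors(p_feed, p_mob, p_stat):
    """Fuse three per-class probabilities into a normalised posterior triple.

    Accepts scalars or equal-length arrays; returns an array of shape
    ``(..., 3)``.  If all three raw products vanish (each class both asserted
    and contradicted with certainty), the posterior falls back to uniform and
    a warning is logged — downstream smoothing then relies on the transition
    model alone for such bins.
    """
    p = np.stack(
        [np.asarray(p_feed, float), np.asarray(p_mob, float), np.asarray(p_stat, float)],
        axis=-1,
    )
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("class probabilities must lie in [0, 1]")
    q = 1.0 - p
    raw = np.stack(
        [
            p[..., 0] * q[..., 1] * q[..., 2],
            p[..., 1] * q[..., 0] * q[..., 2],
            p[..., 2] * q[..., 0] * q[..., 1],
        ],
        axis=-1,
    )
    total = raw.sum(axis=-1, keepdims=True)
    degenerate = total[..., 0] == 0.0
    if np.any(degenerate):
        n_bad = int(np.count_nonzero(degenerate))
        logger.warning(
            "fuse_posteriors: %d bin(s) with all-zero fused mass; using uniform", n_bad
        )
        raw = np.where(degenerate[..., None], 1.0 / 3.0, raw)
        total = np.where(degenerate[..., None], 1.0, total)
    return raw / total


@dataclass
class _BinarySVM:
    """A trained binary classifier reduced to its kernel expansion.

    Decision values are recomputed from the stored support vectors and dual
    coefficients so a JSON round-trip reproduces in-memory decisions exactly.
    """

    support_vectors: np.ndarray  # (m, 2), standardised units
    dual_coef: np.ndarray  # (m,)
    intercept: float
    gamma: float

    def decision(self, Z: np.ndarray) -> np.ndarray:
        K = rbf_kernel(Z, self.support_vectors, gamma=self.gamma)
        return K @ self.dual_coef + self.intercept


@dataclass
class OvRModel:
    """Three one-vs-rest decision functions plus training metadata.

    Decision values are positive on the class side of each boundary.
    Standardisation constants come from the training data only.
    """

    classifiers: dict  # BehaviourClass -> _BinarySVM
    mean: np.ndarray  # (2,) per-channel training mean
    std: np.ndarray  # (2,) per-channel training std
    kernel: KernelSpec
    class_counts: dict = field(default_factory=dict)
    platt: dict | None = None  # BehaviourClass -> (slope a, offset b), optional

    def standardize(self, X) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.std

    def decision_values(self, X) -> np.ndarray:
        """Signed decision values, shape (n, 3) ordered feeding/mobile/stationary."""
        Z = self.standardize(X)
        return np.column_stack(
            [self.classifiers[c].decision(Z) for c in BehaviourClass]
        )

    def class_probabilities(self, X) -> np.ndarray:
        """Per-class logistic probabilities p_f, p_m, p_s, shape (n, 3)."""
        d = self.decision_values(X)
        if self.platt is not None:
            for j, c in enumerate(BehaviourClass):
                a, b = self.platt[c]
                d[:, j] = a * d[:, j] + b
        return logistic_map(d)

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kernel": {
                "bandwidth": self.kernel.bandwidth,
                "regularization": self.kernel.regularization,
            },
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "class_counts": {c.label: int(n) for c, n in self.class_counts.items()},
            "platt": None
            if self.platt is None
            else {c.label: list(map(float, ab)) for c, ab in self.platt.items()},
            "classifiers": {
                c.label: {
                    "support_vectors": clf.support_vectors.tolist(),
                    "dual_coef": clf.dual_coef.tolist(),
                    "intercept": clf.intercept,
                    "gamma": clf.gamma,
                }
                for c, clf in self.classifiers.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OvRModel":
        classifiers = {
            BehaviourClass.from_name(name): _BinarySVM(
                support_vectors=np.asarray(spec["support_vectors"], float),
                dual_coef=np.asarray(spec["dual_coef"], float),
                intercept=float(spec["intercept"]),
                gamma=float(spec["gamma"]),
            )
            for name, spec in d["classifiers"].items()
        }
        platt = d.get("platt")
        return cls(
            classifiers=classifiers,
            mean=np.asarray(d["mean"], float),
            std=np.asarray(d["std"], float),
            kernel=KernelSpec(**d["kernel"]),
            class_counts={
                BehaviourClass.from_name(k): v
                for k, v in d.get("class_counts", {}).items()
            },
            platt=None
            if platt is None
            else {BehaviourClass.from_name(k): tuple(v) for k, v in platt.items()},
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "OvRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _fit_platt(decision: np.ndarray, target: np.ndarray) -> tuple:
    """Two-parameter logistic calibration (slope, offset) by Newton iteration."""
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1e6, solver="lbfgs")
    lr.fit(decision.reshape(-1, 1), target)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def train_one_vs_rest(
    data: LabeledDataset,
    kernel: KernelSpec | None = None,
    class_weighting: bool = False,
    platt_calibration: bool = False,
    seed: int = 0,
) -> OvRModel:
    """Train the three one-vs-rest Gaussian-kernel SVMs.

    Parameters
    ----------
    data
        Labelled bins; every behaviour class must be present.
    kernel
        Hyper-parameters; an unresolved bandwidth is set by the median
        heuristic on the standardised training inputs.
    class_weighting
        If true, inverse-frequency class weights counteract the typically
        stationary-heavy label distribution (off by default).
    platt_calibration
        If true, fit a two-parameter logistic calibration per class on the
        training decision values instead of the unit-slope link.
    """
    kernel = kernel or KernelSpec()
    counts = data.class_counts()
    for c, n in counts.items():
        if n == 0:
            raise ValueError(f"class {c.label!r} absent from training data")
    X, y = data.X, data.y
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Z = (X - mean) / std
    if kernel.bandwidth is None:
        kernel = KernelSpec(median_bandwidth(Z, seed=seed), kernel.regularization)
    classifiers = {}
    for c in BehaviourClass:
        target = np.where(y == int(c), 1, -1)
        svc = SVC(
            kernel="rbf",
            gamma=kernel.gamma,
            C=kernel.regularization,
            class_weight="balanced" if class_weighting else None,
            # tight tolerance keeps decision values independent of row order;
            # the iteration cap bounds runtime on heavily overlapping classes
            tol=1e-8,
            max_iter=1_000_000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svc.fit(Z, target)
        # sklearn orients decision_function positive towards classes_[1] == +1
        classifiers[c] = _BinarySVM(
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_[0].copy(),
            intercept=float(svc.intercept_[0]),
            gamma=kernel.gamma,
        )
    model = OvRModel(
        classifiers=classifiers,
        mean=mean,
        std=std,
        kernel=kernel,
        class_counts=counts,
    )
    if platt_calibration:
        d = model.decision_values(X)
        model.platt = {
            c: _fit_platt(d[:, j], (y == int(c)).astype(int))
            for j, c in enumerate(BehaviourClass)
        }
    return model


def predict_posterior_sequence(
    model: OvRModel, activity: ActivitySeries
) -> PosteriorSequence:
    """Apply the trained model to every bin of an activity series.

    Per bin: decision values -> logistic link -> fusion -> normalised
    posterior triple.  Deterministic given the model; block structure is
    inherited from the activity series.
    """
    if len(activity) == 0:
        raise ValueError("activity series is empty")
    p = model.class_probabilities(activity.counts)
    post = fuse_posteriors(p[:, 0], p[:, 1], p[:, 2])
    return PosteriorSequence(
        timestamps=activity.timestamps, values=post, blocks=activity.blocks
    )
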