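"""Model / Results front-end tying the pipeline stages together.

:class:`BehaviourModel` is constructed from a labelled dataset (and,
optionally, the full activity series of the deployment); ``fit()`` trains
the one-vs-rest SVMs and returns a :class:`BehaviourModelResults`, from
which posteriors, smoothed state paths, cross-validation reports, evidence
sweeps and behavioural summaries are obtained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as _io
from .evaluate import CVReport, leave_one_session_out
from .hmm import (
    EvidenceCurve,
    HMMParams,
    build_transition_matrix,
    evidence_sweep,
    posteriors_to_likelihoods,
    viterbi_decode,
)
from .svm import (
    KernelSpec,
    OvRModel,
    predict_posterior_sequence,
    train_one_vs_rest,
)
from .types import (
    ActivitySeries,
    BehaviourClass,
    LabeledDataset,
    PosteriorSequence,
    StatePath,
)

__all__ = ["BehaviourModel", "BehaviourModelResults"]


class BehaviourModel:
    """Three-state behaviour classifier for 5-minute activity counts.

    Parameters
    ----------
    labeled
        Field-labelled activity bins grouped into observation sessions.
    activity
        Optional full activity series of the deployment; used as the
        default input for decoding after fitting.
    kernel
        Gaussian-kernel hyper-parameters (bandwidth resolved by the median
        heuristic when unset).
    hmm
        Transition-model parameters for smoothing (defaults: stay
        probabilities 0.8 feeding / 0.9 mobile / 0.9 stationary, uniform
        initial distribution).
    state_priors
        Priors used in the Bayes inversion of posteriors to likelihoods
        (default uniform).
    """

    def __init__(
        self,
        labeled: LabeledDataset,
        activity: ActivitySeries | None = None,
        kernel: KernelSpec | None = None,
        hmm: HMMParams | None = None,
        state_priors=None,
    ) -> None:
        if len(labeled) == 0:
            raise ValueError("labelled dataset is empty")
        self.labeled = labeled
        self.activity = activity
        self.kernel = kernel or KernelSpec()
        self.hmm = hmm or HMMParams()
        self.state_priors = state_priors

    @classmethod
    def from_csv(
        cls,
        activity_csv,
        observation_csv,
        dominance_threshold: float = 1.0,
        **kwargs,
    ) -> "BehaviourModel":
        """Build a model straight from the two input CSV streams."""
        activity = _io.read_activity_csv(activity_csv)
        log = _io.read_observation_log(observation_csv)
        labeled = _io.synchronize_labels(activity, log, dominance_threshold)
        return cls(labeled, activity=activity, **kwargs)

    @classmethod
    def from_study(cls, study, dominance_threshold: float = 1.0, **kwargs):
        """Build a model from a :class:`~ethosmooth.simulate.SyntheticStudy`."""
        labeled = _io.synchronize_labels(
            study.activity, study.log, dominance_threshold
        )
        return cls(labeled, activity=study.activity, **kwargs)

    def fit(
        self,
        class_weighting: bool = False,
        platt_calibration: bool = False,
        seed: int = 0,
    ) -> "BehaviourModelResults":
        """Train the one-vs-rest SVMs on all labelled data."""
        ovr = train_one_vs_rest(
            self.labeled,
            self.kernel,
            class_weighting=class_weighting,
            platt_calibration=platt_calibration,
            seed=seed,
        )
        return BehaviourModelResults(model=self, ovr=ovr)


@dataclass
class BehaviourModelResults:
    """Fitted classifier plus everything derived from it."""

    model: BehaviourModel
    ovr: OvRModel

    # -- prediction -------------------------------------------------------
    def predict_posteriors(
        self, activity: ActivitySeries | None = None
    ) -> PosteriorSequence:
        """Per-bin fused class posteriors for an activity series."""
        activity = activity if activity is not None else self.model.activity
        if activity is None:
            raise ValueError("no activity series supplied or stored on the model")
        return predict_posterior_sequence(self.ovr, activity)

    def decode(
        self, activity: ActivitySeries | None = None, smooth: bool = True
    ) -> StatePath:
        """Behaviour sequence for an activity series.

        ``smooth=True`` runs Viterbi decoding per contiguous block;
        ``smooth=False`` returns the per-bin posterior argmax.
        """
        post = self.predict_posteriors(activity)
        if not smooth:
            states = np.argmax(post.values, axis=1) + 1
            return StatePath(post.timestamps, states, blocks=post.blocks)
        lik = posteriors_to_likelihoods(post, self.model.state_priors)
        T = build_transition_matrix(self.model.hmm)
        return viterbi_decode(lik, T, self.model.hmm.initial)

    # -- evaluation -------------------------------------------------------
    def cross_validate(self, mode: str = "svm_hmm", **kwargs) -> CVReport:
        """Leave-one-session-out cross-validation of the full pipeline."""
        _, report = leave_one_session_out(
            self.model.labeled,
            kernel=self.model.kernel,
            hmm=self.model.hmm,
            mode=mode,
            state_priors=self.model.state_priors,
            **kwargs,
        )
        return report

    def evidence_sweep(self, grid=None, **kwargs) -> EvidenceCurve:
        """Held-out log-evidence profile over the feeding stay probability."""
        return evidence_sweep(
            self.model.labeled,
            kernel=self.model.kernel,
            grid=grid,
            fixed=(self.model.hmm.stay_mob, self.model.hmm.stay_stat),
            state_priors=self.model.state_priors,
            initial=self.model.hmm.initial,
            **kwargs,
        )

    # -- reporting --------------------------------------------------------
    def training_accuracy(self) -> float:
        """Posterior-argmax accuracy on the training set (optimistic)."""
        p = self.ovr.class_probabilities(self.model.labeled.X)
        pred = np.argmax(p, axis=1) + 1
        return float(np.mean(pred == self.model.labeled.y))

    def summary(self) -> str:
        m = self.model
        k = self.ovr.kernel
        dwell = m.hmm.mean_dwell_minutes()
        counts = m.labeled.class_counts()
        lines = [
            "Behavioural state model (one-vs-rest SVM + HMM smoothing)",
            "=" * 58,
            f"Labelled data points:        {len(m.labeled)}",
            f"Observation sessions:        {len(m.labeled.session_ids)}",
        ]
        for c in BehaviourClass:
            lines.append(f"  {c.label + ' points:':<26} {counts[c]}")
        lines += [
            f"Kernel bandwidth (std units): {k.bandwidth:.4f}",
            f"Regularization C:            {k.regularization:g}",
            "Stay probabilities:          "
            f"feeding {m.hmm.stay_feed:.2f}, mobile {m.hmm.stay_mob:.2f}, "
            f"stationary {m.hmm.stay_stat:.2f}",
            "Implied mean dwell (min):    "
            + ", ".join("inf" if not np.isfinite(d) else f"{d:.0f}" for d in dwell),
            f"Training-set accuracy:       {100 * self.training_accuracy():.2f}%",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Persist the fitted classifier and smoothing parameters as JSON."""
        payload = self.ovr.to_dict()
        payload["hmm"] = {
            "stay_feed": self.model.hmm.stay_feed,
            "stay_mob": self.model.hmm.stay_mob,
            "stay_stat": self.model.hmm.stay_stat,
            "initial": self.model.hmm.initial.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path, labeled: LabeledDataset | None = None):
        """Reload a persisted results object.

        Without the original labelled data the returned object supports
        prediction and decoding, but not refitting or cross-validation.
        """
        payload = json.loads(Path(path).read_text())
        ovr = OvRModel.from_dict(payload)
        h = payload.get("hmm", {})
        hmm = HMMParams(
            stay_feed=h.get("stay_feed", 0.8),
            stay_mob=h.get("stay_mob", 0.9),
            stay_stat=h.get("stay_stat", 0.9),
            initial=np.asarray(h.get("initial", [1 / 3] * 3)),
        )
        if labeled is None:
            model = BehaviourModel.__new__(BehaviourModel)
            model.labeled = None  # type: ignore[assignment]
            model.activity = None
            model.kernel = ovr.kernel
            model.hmm = hmm
            model.state_priors = None
        else:
            model = BehaviourModel(labeled, kernel=ovr.kernel, hmm=hmm)
        return cls(model=model, ovr=ovr)
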