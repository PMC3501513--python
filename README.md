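# ethosmooth

Behavioural state classification from collar accelerometer activity counts.

Biologging collars for terrestrial carnivores commonly aggregate bi-axial
accelerometer readings into one integer pair per 5-minute bin, each channel
in [0, 255]. Direct field observation of the same animals is expensive and
sparse — a researcher can follow a collared animal for an hour or a few at a
time, noting the exact moment each behaviour change occurs. `ethosmooth`
turns that combination into a continuous behavioural record: it calibrates a
classifier on the few observed hours and applies it to the months-long
activity stream, labelling every 5-minute bin as **feeding**, **mobile** or
**stationary**. From the decoded sequence it derives the quantities
behavioural ecologists ask for: hourly activity profiles, feeding bout
lengths, intervals between feeding events, feeding rates per day, and
wet/dry-season splits.

## Method

Let `x_i ∈ {0,…,255}²` be the activity pair of bin `i`. Three one-vs-rest
soft-margin SVMs with a Gaussian kernel
`k(x, x′) = exp(−‖x−x′‖² / 2b²)` are trained, one per behaviour class
(inputs standardised per channel; bandwidth `b` from the median pairwise
distance heuristic; `C = 1`). Each signed decision value `t_c(x)` passes
through the logistic link `σ(t) = 1/(1+e^{−t})` to give per-class
probabilities `p_f, p_m, p_s`, which are fused under the constraint that
exactly one behaviour is present at a time,

    P_f ∝ p_f (1−p_m)(1−p_s),   P_m ∝ p_m (1−p_f)(1−p_s),   P_s ∝ p_s (1−p_f)(1−p_m),

and normalised to sum to one per bin.

Because the SVM ignores temporal context, the posterior sequence is smoothed
with a 3-state hidden Markov model. The transition matrix has one free
parameter per state — the *stay* probability — with the remaining mass split
equally between the two alternatives; defaults are stay(feeding) = 0.8 and
stay(mobile) = stay(stationary) = 0.9. Posteriors become observation
likelihoods via Bayes' rule with uniform state priors, and the most probable
state path is decoded per contiguous recording block with the Viterbi
algorithm in log space. Model checking uses the log evidence (scaled forward
recursion) of held-out observation sessions as a function of the feeding
stay probability; evaluation uses leave-one-session-out cross-validation,
each field session held out in turn.

A synthetic-study generator (first-order Markov behaviour chain,
class-conditional bivariate-normal emissions on the integer grid,
non-overlapping 1–3-hour observation sessions) provides ground truth for
testing and parameter-recovery experiments.

## Worked example

```python
import numpy as np
import ethosmooth as es

study = es.generate_study(es.GeneratorConfig(seed=1))   # 20,000 bins, 4 follows
model = es.BehaviourModel.from_study(study)
res = model.fit(seed=1)
print(res.summary())
```

```
Behavioural state model (one-vs-rest SVM + HMM smoothing)
==========================================================
Labelled data points:        64
Observation sessions:        4
  feeding points:            10
  mobile points:             22
  stationary points:         32
Kernel bandwidth (std units): 1.4315
Regularization C:            1
Stay probabilities:          feeding 0.80, mobile 0.90, stationary 0.90
Implied mean dwell (min):    25, 50, 50
Training-set accuracy:       100.00%
```

Sixty-four labelled bins — about five hours of direct observation — suffice
to calibrate the classifier for this synthetic deployment. Cross-validation
holds out each follow in turn:

```python
print(res.cross_validate(mode="svm_hmm", seed=1).summary())
```

```
Leave-one-session-out cross-validation (svm_hmm, pooled)
  Labelled data points: 64
  Percent correct (overall):    98.44%
  Percent correct (feeding)     100.00%
  Percent correct (mobile)      100.00%
  Percent correct (stationary)   96.88%
  ...
```

Decoding the full deployment and summarising feeding behaviour:

```python
path = res.decode()                                   # all 20,000 bins
bouts = es.extract_bouts(path, es.BehaviourClass.FEEDING)
np.mean(path.states == study.truth.states)            # 0.971
len(bouts)                                            # 510
np.mean([b.duration_minutes for b in bouts])          # 36.1 min
es.event_rate_per_day(bouts)                          # 7.34
```

97.1% of the 20,000 bins match the simulated ground truth; the decoded
feeding bouts average 36 minutes. (The synthetic chain feeds far more often
than a real carnivore would — it has no diel structure; the rate is the
reciprocal mean start-to-start interval in days.)

The same pipeline is scriptable from the shell:

```bash
ethosmooth simulate --seed 1 --out-dir study/
ethosmooth sync --activity study/activity.csv --obs study/observations.csv --out labeled.csv
ethosmooth train --labeled labeled.csv --out model.json
ethosmooth classify --model model.json --activity study/activity.csv --out posteriors.csv
ethosmooth smooth --posteriors posteriors.csv --out states.csv
ethosmooth summarize --states states.csv --out-dir summaries/ --season-split
ethosmooth evaluate --labeled labeled.csv --mode svm_hmm --out report.json
ethosmooth sweep --labeled labeled.csv --out curve.csv
```

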