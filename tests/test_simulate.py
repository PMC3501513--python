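"""Synthetic-study generator: chains, emissions, sessions, reproducibility."""

import numpy as np
import pytest

from ethosmooth import (
    EmissionSpec,
    GeneratorConfig,
    emit_activity,
    generate_study,
    sample_sessions,
    simulate_states,
    synchronize_labels,
)
from ethosmooth.hmm import build_transition_matrix
from ethosmooth.types import BehaviourClass

from .conftest import make_path


class TestSimulateStates:
    def test_absorbing_stays_are_constant(self):
        path = simulate_states((1, 1, 1), 200, seed=3)
        assert len(np.unique(path.states)) == 1

    def test_zero_stay_never_self_transitions(self):
        path = simulate_states((0, 0, 0), 1000, seed=3)
        assert np.all(path.states[1:] != path.states[:-1])

    def test_empirical_stay_frequencies(self):
        path = simulate_states((0.8, 0.9, 0.9), 50_000, seed=7)
        s = path.states
        for code, stay in zip((1, 2, 3), (0.8, 0.9, 0.9)):
            here = s[:-1] == code
            observed = np.mean(s[1:][here] == code)
            assert observed == pytest.approx(stay, abs=0.01)

    def test_empirical_transition_matrix_converges(self):
        stay = (0.8, 0.9, 0.9)
        path = simulate_states(stay, 50_000, seed=11)
        s = path.states - 1
        counts = np.zeros((3, 3))
        np.add.at(counts, (s[:-1], s[1:]), 1)
        empirical = counts / counts.sum(axis=1, keepdims=True)
        assert np.allclose(empirical, build_transition_matrix(stay), atol=0.01)


class TestEmitActivity:
    def test_zero_covariance_is_deterministic(self):
        spec = EmissionSpec(
            covs={c: ((0.0, 0.0), (0.0, 0.0)) for c in BehaviourClass}
        )
        truth = make_path([3] * 50)
        act = emit_activity(truth, spec, seed=1)
        assert (act.counts == [20, 15]).all()

    def test_draws_clipped_to_byte_range(self):
        spec = EmissionSpec(
            means={
                BehaviourClass.FEEDING: (250.0, 5.0),
                BehaviourClass.MOBILE: (250.0, 5.0),
                BehaviourClass.STATIONARY: (250.0, 5.0),
            }
        )
        act = emit_activity(make_path([1] * 5000), spec, seed=2)
        assert act.counts.max() <= 255 and act.counts.min() >= 0
        assert (act.counts[:, 0] == 255).any()  # upper clip active
        assert (act.counts[:, 1] == 0).any()  # lower clip active

    def test_sample_means_converge(self):
        spec = EmissionSpec(
            means={c: (50.0, 40.0) for c in BehaviourClass},
            covs={c: ((100.0, 0.0), (0.0, 100.0)) for c in BehaviourClass},
        )
        act = emit_activity(make_path([3] * 20_000), spec, seed=3)
        assert np.allclose(act.counts.mean(axis=0), [50, 40], atol=1.0)

    def test_out_of_range_mean_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 255\]"):
            EmissionSpec(means={
                BehaviourClass.FEEDING: (300.0, 300.0),
                BehaviourClass.MOBILE: (180.0, 160.0),
                BehaviourClass.STATIONARY: (20.0, 15.0),
            })


class TestSampleSessions:
    def test_exact_fit_single_session(self):
        truth = make_path([3] * 100)
        log = sample_sessions(truth, 1, min_len=12, max_len=12, seed=0)
        (sess,) = log.sessions
        assert sess.end_ts - sess.start_ts == np.timedelta64(60, "m")

    def test_sessions_never_overlap(self):
        truth = make_path([3] * 400)
        for seed in range(100):
            log = sample_sessions(truth, 5, seed=seed)
            spans = sorted((s.start_ts, s.end_ts) for s in log.sessions)
            assert all(b[0] >= a[1] for a, b in zip(spans, spans[1:]))

    def test_infeasible_placement_rejected(self):
        truth = make_path([3] * 30)
        with pytest.raises(ValueError, match="cannot place"):
            sample_sessions(truth, 4, min_len=12, max_len=12, seed=0)

    def test_events_transcribe_truth_onsets(self):
        truth = make_path([3] * 6 + [1] * 6 + [2] * 6)
        log = sample_sessions(truth, 1, min_len=18, max_len=18, seed=1)
        states = [s for _, s in log.sessions[0].events]
        assert states == [
            BehaviourClass.STATIONARY,
            BehaviourClass.FEEDING,
            BehaviourClass.MOBILE,
        ]


class TestGenerateStudy:
    def test_same_seed_bit_identical(self):
        a = generate_study(GeneratorConfig(n_bins=3000, seed=9))
        b = generate_study(GeneratorConfig(n_bins=3000, seed=9))
        assert np.array_equal(a.truth.states, b.truth.states)
        assert np.array_equal(a.activity.counts, b.activity.counts)
        assert [s.session_id for s in a.log] == [s.session_id for s in b.log]
        assert all(
            x.start_ts == y.start_ts for x, y in zip(a.log, b.log)
        )

    def test_different_seed_differs(self):
        a = generate_study(GeneratorConfig(n_bins=3000, seed=9))
        c = generate_study(GeneratorConfig(n_bins=3000, seed=10))
        assert not np.array_equal(a.activity.counts, c.activity.counts)

    def test_labels_recover_truth_when_aligned(self):
        study = generate_study(GeneratorConfig(n_bins=4000, n_sessions=5, seed=2))
        lab = synchronize_labels(study.activity, study.log, 1.0)
        truth = dict(zip(study.truth.timestamps, study.truth.states))
        assert len(lab) >= 5 * 12
        assert all(truth[t] == l for t, l in zip(lab.table.timestamp, lab.table.label))

    def test_unaligned_sessions_drop_edge_bins(self):
        aligned = generate_study(GeneratorConfig(n_bins=4000, n_sessions=5, seed=2))
        shifted = generate_study(
            GeneratorConfig(n_bins=4000, n_sessions=5, seed=2, align_sessions=False)
        )
        la = synchronize_labels(aligned.activity, aligned.log)
        ls = synchronize_labels(shifted.activity, shifted.log)
        assert len(ls) < len(la)

    def test_fixed_dwell_mode_has_deterministic_bout_lengths(self):
        study = generate_study(
            GeneratorConfig(n_bins=2000, dwell_mode="fixed", seed=4)
        )
        from ethosmooth import extract_bouts

        bouts = extract_bouts(study.truth, BehaviourClass.FEEDING)
        interior = [b for b in bouts[1:-1]]
        # stay 0.8 -> every interior feeding dwell exactly 5 bins (25 min)
        assert {b.duration_minutes for b in interior} == {25.0}

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="one hour"):
            GeneratorConfig(session_min_len=6)
        with pytest.raises(ValueError, match="dwell_mode"):
            GeneratorConfig(dwell_mode="weibull")
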