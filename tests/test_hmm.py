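"""Transition model, Bayes inversion, Viterbi decoding and evidence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethosmooth import (
    HMMParams,
    build_transition_matrix,
    evidence_sweep,
    log_evidence,
    posteriors_to_likelihoods,
    viterbi_decode,
)
from ethosmooth.types import LikelihoodSequence, PosteriorSequence

from .conftest import (
    as_likelihood_sequence,
    bin_times,
    brute_force_paths,
    make_labeled,
    path_log_score,
    random_hmm_instance,
)

stay = st.floats(0.0, 1.0, allow_nan=False)


class TestTransitionMatrix:
    def test_default_parameterisation(self):
        T = build_transition_matrix((0.8, 0.9, 0.9))
        expect = np.array(
            [[0.8, 0.1, 0.1], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]]
        )
        assert np.allclose(T, expect, atol=1e-15)

    def test_absorbing_and_reflecting_rows(self):
        assert np.array_equal(build_transition_matrix((1, 1, 1)), np.eye(3))
        T = build_transition_matrix((0, 0.5, 1))
        assert np.allclose(
            T, [[0, 0.5, 0.5], [0.25, 0.5, 0.25], [0, 0, 1]], atol=1e-15
        )

    def test_out_of_range_stay_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix((1.2, 0.5, 0.5))

    @given(stay, stay, stay)
    @settings(deadline=None)
    def test_rows_sum_to_one(self, a, b, c):
        T = build_transition_matrix((a, b, c))
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(T >= 0)
        assert T[0, 1] == T[0, 2]  # equal split to the two alternatives


class TestBayesInversion:
    def test_uniform_prior_is_identity(self):
        post = PosteriorSequence(bin_times(1), [[0.8, 0.1, 0.1]])
        lik = posteriors_to_likelihoods(post)
        assert np.allclose(lik.values, [[0.8, 0.1, 0.1]], atol=1e-15)

    def test_prior_matching_posterior_gives_uniform(self):
        post = PosteriorSequence(bin_times(1), [[0.5, 0.25, 0.25]])
        lik = posteriors_to_likelihoods(post, (0.5, 0.25, 0.25))
        assert np.allclose(lik.values, [[1 / 3] * 3], atol=1e-15)

    def test_zero_prior_rejected(self):
        post = PosteriorSequence(bin_times(1), [[0.5, 0.25, 0.25]])
        with pytest.raises(ValueError, match="positive"):
            posteriors_to_likelihoods(post, (1.0, 0.0, 0.0))

    def test_rows_renormalised(self, rng):
        vals = rng.dirichlet(np.ones(3), size=50)
        post = PosteriorSequence(bin_times(50), vals)
        lik = posteriors_to_likelihoods(post, (0.2, 0.3, 0.5))
        assert np.allclose(lik.values.sum(axis=1), 1.0, atol=1e-12)


class TestViterbi:
    def test_one_hot_likelihoods_follow_observations(self):
        L = np.tile([0.0, 1.0, 0.0], (3, 1))
        path = viterbi_decode(
            as_likelihood_sequence(L), build_transition_matrix((0.5, 0.5, 0.5))
        )
        assert path.states.tolist() == [2, 2, 2]

    def test_isolated_spike_smoothed_to_surrounding_state(self):
        # single confident feeding bin inside a stationary run is removed
        L = np.array(
            [
                [0.05, 0.05, 0.9],
                [0.05, 0.05, 0.9],
                [0.9, 0.05, 0.05],
                [0.05, 0.05, 0.9],
                [0.05, 0.05, 0.9],
            ]
        )
        T = build_transition_matrix((0.8, 0.9, 0.9))
        lik = as_likelihood_sequence(L)
        path = viterbi_decode(lik, T)
        assert path.states.tolist() == [3, 3, 3, 3, 3]
        # agreement with exhaustive 3^5 search
        best, _, _ = brute_force_paths(L, T, np.full(3, 1 / 3))
        assert path.states.tolist() == best.tolist()

    def test_spike_survives_without_smoothing_incentive(self):
        L = np.array([[0.05, 0.05, 0.9], [0.9, 0.05, 0.05], [0.05, 0.05, 0.9]])
        path = viterbi_decode(
            as_likelihood_sequence(L), build_transition_matrix((0.4, 0.4, 0.4))
        )
        assert path.states.tolist() == [3, 1, 3]

    def test_matches_exhaustive_maximum_on_random_instances(self, rng):
        for _ in range(100):
            L, T, pi = random_hmm_instance(rng)
            path = viterbi_decode(as_likelihood_sequence(L), T, pi)
            _, best_score, _ = brute_force_paths(L, T, pi)
            got = path_log_score(path.states, L, T, pi)
            assert got == pytest.approx(np.log(best_score), rel=1e-9)

    def test_deterministic_tie_break_prefers_lowest_state(self):
        # fully symmetric instance: every path ties; feeding (code 1) wins
        L = np.full((4, 3), 1 / 3)
        T = build_transition_matrix((1 / 3, 1 / 3, 1 / 3))
        path = viterbi_decode(as_likelihood_sequence(L), T)
        assert path.states.tolist() == [1, 1, 1, 1]

    def test_blocks_decoded_independently(self):
        # two one-bin blocks separated by a gap: no transition cost between
        ts = bin_times(1).append(bin_times(1, bin_times(3)[2]))
        L = np.array([[0.9, 0.05, 0.05], [0.05, 0.05, 0.9]])
        lik = LikelihoodSequence(ts, L)
        assert lik.blocks.tolist() == [0, 1]
        path = viterbi_decode(lik, build_transition_matrix((0.99, 0.99, 0.99)))
        assert path.states.tolist() == [1, 3]

    def test_dead_end_raises(self):
        L = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        T = np.eye(3)  # cannot leave feeding, but bin 2 demands mobile
        with pytest.raises(ValueError, match="dead end"):
            viterbi_decode(as_likelihood_sequence(L), T)

    def test_empty_input_gives_empty_path(self):
        lik = LikelihoodSequence(bin_times(0), np.zeros((0, 3)))
        path = viterbi_decode(lik, build_transition_matrix((0.8, 0.9, 0.9)))
        assert len(path) == 0


class TestLogEvidence:
    def test_single_uniform_bin_closed_form(self):
        lik = as_likelihood_sequence(np.full((1, 3), 1 / 3))
        T = build_transition_matrix((0.8, 0.9, 0.9))
        assert log_evidence(lik, T) == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_matches_exhaustive_sum_on_random_instances(self, rng):
        for _ in range(100):
            L, T, pi = random_hmm_instance(rng)
            _, _, total = brute_force_paths(L, T, pi)
            assert log_evidence(as_likelihood_sequence(L), T, pi) == pytest.approx(
                np.log(total), rel=1e-9
            )

    def test_bounded_above_by_zero(self, rng):
        for _ in range(20):
            L, T, pi = random_hmm_instance(rng)
            assert log_evidence(as_likelihood_sequence(L), T, pi) <= 0.0

    def test_multi_block_sums_block_evidences(self):
        L = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3]])
        T = build_transition_matrix((0.8, 0.9, 0.9))
        ts = bin_times(1).append(bin_times(1, bin_times(3)[2]))
        both = LikelihoodSequence(ts, L)
        single = [as_likelihood_sequence(L[[i]]) for i in range(2)]
        assert log_evidence(both, T) == pytest.approx(
            sum(log_evidence(s, T) for s in single), rel=1e-12
        )


class TestEvidenceSweep:
    def test_grid_of_length_one(self, rng):
        data = make_labeled(rng, n_sessions=2)
        curve = evidence_sweep(data, grid=[0.8])
        assert len(curve.grid) == 1
        assert curve.argmax == 0.8
        assert curve.per_session.shape == (1, 2)

    def test_single_session_rejected(self, rng):
        data = make_labeled(rng, n_sessions=1)
        with pytest.raises(ValueError, match="2 observation sessions"):
            evidence_sweep(data)

    def test_hmm_params_validation(self):
        with pytest.raises(ValueError):
            HMMParams(stay_feed=1.5)
        with pytest.raises(ValueError):
            HMMParams(initial=np.array([0.5, 0.5, 0.5]))
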