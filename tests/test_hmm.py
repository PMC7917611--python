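"""HMM inference and EM training against independent oracles.

Short-sequence quantities are checked against exhaustive path enumeration;
the Gaussian forward pass is additionally cross-checked against hmmlearn,
which plays no role in the implementation itself.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitphase import (
    DiscreteEmission,
    GaussianEmission,
    GmmEmission,
    HmmModel,
    circular_left_right_topology,
    estimate_cycle_length,
    fit_baum_welch,
    forward_backward,
    initial_model,
    jitter_model,
    loglikelihood,
    simulate,
    supervised_initial_model,
    viterbi,
)
from gaitphase.hmm import align_states_by_means

from conftest import brute_force_logliks, random_model

FAMILIES = ("discrete", "gaussian", "gmm")


class TestTopology:
    def test_wrap_mask_has_2n_transitions(self):
        mask = circular_left_right_topology(4, allow_wrap=True)
        assert mask.sum() == 8
        assert mask[3, 0]

    def test_no_wrap_two_states(self):
        mask = circular_left_right_topology(2, allow_wrap=False)
        assert np.array_equal(mask, [[True, True], [False, True]])

    def test_rejects_single_state(self):
        with pytest.raises(ValueError):
            circular_left_right_topology(1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_forward_and_viterbi_match_enumeration(self, family, rng):
        for rep in range(5):
            model = random_model(rng, family)
            obs, _ = simulate(model, 6, seed=rep)
            bf_ll, bf_best = brute_force_logliks(model, obs)
            assert loglikelihood(model, obs) == pytest.approx(bf_ll, abs=1e-9)
            post = forward_backward(model, obs)
            assert post.log_likelihood == pytest.approx(bf_ll, abs=1e-9)
            _, best = viterbi(model, obs)
            assert best == pytest.approx(bf_best, abs=1e-9)

    def test_forward_matches_hmmlearn(self, rng):
        from hmmlearn.hmm import GaussianHMM

        model = random_model(rng, "gaussian", dim=2)
        obs, _ = simulate(model, 200, seed=0)
        ref = GaussianHMM(n_components=4, covariance_type="full", init_params="")
        ref.startprob_ = model.pi
        ref.transmat_ = model.transitions
        ref.means_ = model.emission.means
        ref.covars_ = model.emission.covs
        assert loglikelihood(model, obs) == pytest.approx(ref.score(obs), abs=1e-8)


class TestPosteriorInvariants:
    @given(seed=st.integers(0, 200))
    @settings(max_examples=30, deadline=None)
    def test_gamma_xi_eta_normalisation(self, seed):
        r = np.random.default_rng(seed)
        family = FAMILIES[seed % 3]
        model = random_model(r, family)
        obs, _ = simulate(model, 25, seed=seed)
        post = forward_backward(model, obs)
        assert np.allclose(post.gamma.sum(axis=1), 1, atol=1e-8)
        assert np.allclose(post.xi.sum(axis=(1, 2)), 1, atol=1e-8)
        if family == "gmm":
            assert np.allclose(post.eta.sum(axis=2), post.gamma, atol=1e-8)
        # xi marginal consistency: sum_j xi[t] = gamma[t]
        assert np.allclose(post.xi.sum(axis=2), post.gamma[:-1], atol=1e-6)

    def test_single_observation(self, rng):
        model = random_model(rng, "gaussian")
        post = forward_backward(model, np.zeros((1, 2)))
        dens = np.exp(model.emission.log_density(np.zeros((1, 2))))[0]
        expected = model.pi * dens / (model.pi @ dens)
        assert np.allclose(post.gamma[0], expected)
        assert post.xi.shape == (0, 4, 4)

    def test_zero_likelihood_raises_informative_error(self):
        # a symbol no state can emit zeroes the total likelihood
        em = DiscreteEmission(np.array([[1.0, 0.0], [1.0, 0.0]]))
        model = HmmModel([0.5, 0.5], np.full((2, 2), 0.5), em)
        with pytest.raises(FloatingPointError, match="variance floor|underflow"):
            forward_backward(model, np.array([0, 1, 0]))

    def test_non_finite_observation_rejected(self, rng):
        model = random_model(rng, "gaussian")
        with pytest.raises(ValueError, match="non-finite"):
            forward_backward(model, np.array([[np.nan, 0.0]]))


class TestViterbi:
    def test_well_separated_emissions_follow_generation(self):
        em = GaussianEmission(np.array([[-10.0], [10.0]]), np.full(2, 0.1))
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = HmmModel([0.5, 0.5], A, em)
        obs, states = simulate(model, 100, seed=3)
        path, _ = viterbi(model, obs)
        assert np.array_equal(path, states)

    def test_tie_breaks_to_lower_state(self):
        # two identical states: every path has equal probability
        em = GaussianEmission(np.zeros((2, 1)), np.ones(2))
        model = HmmModel([0.5, 0.5], np.full((2, 2), 0.5), em)
        path, _ = viterbi(model, np.zeros((5, 1)))
        assert np.array_equal(path, np.zeros(5, dtype=int))


class TestSimulate:
    def test_point_mass_start(self, rng):
        model = random_model(rng, "gaussian")
        model.pi = np.array([1.0, 0.0, 0.0, 0.0])
        for seed in range(10):
            _, states = simulate(model, 5, seed=seed)
            assert states[0] == 0

    def test_transitions_respect_wrap_mask(self):
        mask = circular_left_right_topology(4, allow_wrap=True)
        A = np.where(mask, 0.5, 0.0)
        em = GaussianEmission(np.zeros((4, 1)), np.ones(4))
        model = HmmModel([1, 0, 0, 0], A, em, mask)
        _, states = simulate(model, 2000, seed=1)
        steps = set(zip(states[:-1], states[1:]))
        assert steps <= {(i, i) for i in range(4)} | {(i, i + 1) for i in range(3)} | {(3, 0)}

    def test_empirical_transition_frequencies(self, rng):
        model = random_model(rng, "discrete", n_states=3)
        _, states = simulate(model, 100_000, seed=7)
        counts = np.zeros((3, 3))
        np.add.at(counts, (states[:-1], states[1:]), 1)
        freq = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(freq - model.transitions).max() < 0.01

    def test_reproducible(self, rng):
        model = random_model(rng, "gmm")
        a = simulate(model, 50, seed=9)
        b = simulate(model, 50, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestBaumWelch:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_loglik_trace_non_decreasing(self, family, rng):
        model = random_model(rng, family)
        obs, _ = simulate(model, 120, seed=0)
        init = jitter_model(model, seed=1)
        _, trace = fit_baum_welch(init, [obs], tol=1e-9, max_iter=30)
        assert np.all(np.diff(trace) > -1e-8)

    def test_one_step_from_truth_does_not_decrease(self, rng):
        model = random_model(rng, "gaussian")
        obs, _ = simulate(model, 200, seed=2)
        _, trace = fit_baum_welch(model, [obs], tol=0.0, max_iter=2)
        assert trace[1] >= trace[0] - 1e-8

    def test_transition_mask_and_row_sums_preserved(self):
        mask = circular_left_right_topology(4)
        A = np.where(mask, 0.5, 0.0)
        em = GaussianEmission(np.arange(4.0)[:, None] * 3, np.ones(4))
        model = HmmModel([1, 0, 0, 0], A, em, mask)
        obs, _ = simulate(model, 300, seed=4)
        fitted, _ = fit_baum_welch(jitter_model(model, 5), [obs], max_iter=10)
        assert np.all(fitted.transitions[~mask] == 0)
        assert np.allclose(fitted.transitions.sum(axis=1), 1, atol=1e-10)

    def test_gmm_weights_stay_normalised(self, rng):
        model = random_model(rng, "gmm", dim=1)
        obs, _ = simulate(model, 200, seed=6)
        fitted, _ = fit_baum_welch(jitter_model(model, 7), [obs], max_iter=10)
        assert np.allclose(fitted.emission.weights.sum(axis=1), 1, atol=1e-10)

    def test_single_component_gmm_tracks_gaussian_fit(self, rng):
        """A 1-component mixture is the Gaussian family in disguise."""
        truth = random_model(rng, "gaussian", dim=1)
        obs, _ = simulate(truth, 150, seed=8)
        g_init = jitter_model(truth, seed=9, transition_mix=0.3)
        m_init = HmmModel(
            g_init.pi.copy(),
            g_init.transitions.copy(),
            GmmEmission(
                np.ones((4, 1)),
                g_init.emission.means[:, None, :],
                np.stack([np.diag(c)[None, :] for c in g_init.emission.covs]),
            ),
            g_init.topology_mask.copy(),
        )
        _, tr_g = fit_baum_welch(g_init, [obs], tol=1e-9, max_iter=15)
        _, tr_m = fit_baum_welch(m_init, [obs], tol=1e-9, max_iter=15)
        assert np.allclose(tr_g, tr_m, atol=1e-6)

    def test_multi_sequence_pooling_beats_single_subset(self, rng):
        model = random_model(rng, "gaussian", dim=1)
        seqs = [simulate(model, 80, seed=s)[0] for s in range(4)]
        fitted, trace = fit_baum_welch(jitter_model(model, 3), seqs, max_iter=20)
        total = sum(loglikelihood(fitted, s) for s in seqs)
        assert total == pytest.approx(trace[-1], rel=1e-6, abs=1.0)

    def test_needs_sequences(self, rng):
        with pytest.raises(ValueError):
            fit_baum_welch(random_model(rng), [])


class TestInitialisation:
    def test_cycle_length_estimate(self):
        x = np.tile(np.r_[np.zeros(8), np.ones(8)], 12)
        assert estimate_cycle_length(x) == 16

    def test_uniform_segmentation_orders_states_in_time(self):
        x = np.r_[np.zeros(50), np.full(50, 10.0)][:, None]
        model = initial_model([x], n_states=2, emission="gaussian")
        assert model.emission.means[0, 0] < model.emission.means[1, 0]
        assert model.pi[0] == 1.0

    def test_supervised_bootstrap_matches_label_moments(self, rng):
        x = rng.normal(size=(200, 1))
        labels = np.tile([1, 1, 2, 2, 3, 3, 4, 4], 25)
        x[labels == 2] += 10
        model = supervised_initial_model([x], [labels])
        assert model.emission.means[1, 0] == pytest.approx(x[labels == 2].mean(), abs=1e-9)
        assert np.all(model.transitions[~model.topology_mask] == 0)

    def test_alignment_recovers_permutation(self, rng):
        model = random_model(rng, "gaussian")
        perm = np.array([2, 0, 3, 1])
        shuffled = HmmModel(
            model.pi[perm],
            model.transitions[np.ix_(perm, perm)],
            GaussianEmission(model.emission.means[perm], model.emission.covs[perm]),
        )
        back = align_states_by_means(shuffled, model)
        assert np.allclose(shuffled.emission.means[back], model.emission.means)


class TestSerialisation:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_json_round_trip_exact(self, family, rng, tmp_path):
        model = random_model(rng, family)
        path = tmp_path / "model.json"
        model.save(path)
        back = HmmModel.load(path)
        assert np.array_equal(back.pi, model.pi)
        assert np.array_equal(back.transitions, model.transitions)
        obs, _ = simulate(model, 20, seed=0)
        assert loglikelihood(back, obs) == loglikelihood(model, obs)
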