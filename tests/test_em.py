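"""EM machinery: E-step, mean parameters, gradients, baselines, and fitting."""

import numpy as np
import pytest

from condmix.countdist import Truncation
from condmix.mixture import (
    MixtureNatural,
    WeightsRates,
    natural_from_weights_rates,
    observable_log_pmf,
    index_log_probabilities,
    joint_log_pmf,
    sample,
)
from condmix.conditional import ConditionalMixture, VonMisesMap, DiscreteMap
from condmix.em import (
    TrainingSchedule,
    e_step,
    mean_parameters,
    m_step_gradients,
    complete_log_likelihood,
    fit_independent_baseline,
    initialize_cm,
    fit_em,
    log_likelihood,
    _pack,
    _minimal_blocks,
    _unpack_into_cm,
)
from condmix.synthetic import (
    RandomCmRecipe,
    random_ground_truth_cm,
    generate_dataset,
    _discretize,
)

from conftest import enumerated_joint


def _constant_cm(mix: MixtureNatural, family: str) -> ConditionalMixture:
    smap = DiscreteMap(mix.theta_n, np.zeros((mix.n_neurons, 0)), [0.0])
    return ConditionalMixture("discrete", family, stimulus_map=smap,
                              theta_k=mix.theta_k, theta_nk=mix.theta_nk,
                              theta_star=mix.theta_star)


class TestSchedule:
    def test_learning_rate_interpolation(self):
        s = TrainingSchedule(em_iters=5, lr_start=0.002, lr_end=0.0005)
        assert s.learning_rate(0) == pytest.approx(0.002)
        assert s.learning_rate(4) == pytest.approx(0.0005)
        mid = s.learning_rate(2)
        assert mid == pytest.approx(np.sqrt(0.002 * 0.0005))

    def test_defaults_match_reference_procedure(self):
        s = TrainingSchedule()
        assert (s.em_iters, s.ascent_steps) == (500, 100)
        assert (s.lr_start, s.lr_end, s.cb_warm_fraction) == (0.002, 0.0005, 0.8)


class TestEStep:
    def test_single_component(self, tiny_dataset, tiny_truth_cm):
        counts, stim = tiny_dataset
        base = ConditionalMixture("von_mises", "ip",
                                  stimulus_map=tiny_truth_cm.stimulus_map)
        resp = e_step(base, counts, stim)
        assert resp.shape == (len(stim), 1)
        assert np.allclose(resp, 1.0)

    def test_separated_components_saturate(self):
        nat = natural_from_weights_rates(
            WeightsRates([0.5, 0.5], [[0.5, 0.5], [20.0, 20.0]]))
        cm = _constant_cm(nat, "ip")
        counts = np.array([[22, 19], [0, 1]])
        resp = e_step(cm, counts, np.zeros(2))
        assert resp[0, 1] > 0.999
        assert resp[1, 0] > 0.999

    def test_matches_bayes_rule(self, small_cb):
        cm = _constant_cm(small_cb, "cb")
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 8, size=(12, 3))
        resp = e_step(cm, counts, np.zeros(12))
        for i, n in enumerate(counts):
            joint = np.array([joint_log_pmf(small_cb, n, k) for k in range(4)])
            bayes = np.exp(joint - np.logaddexp.reduce(joint))
            assert np.allclose(resp[i], bayes, atol=1e-10)


class TestMeanParameters:
    def test_single_component_ip(self, tiny_truth_cm):
        base = ConditionalMixture("von_mises", "ip",
                                  stimulus_map=tiny_truth_cm.stimulus_map)
        mp = mean_parameters(base, 30.0)
        assert np.allclose(mp.eta_n, np.exp(base.baseline_params(30.0)), atol=1e-12)
        assert mp.eta_k.size == 0

    def test_matches_enumeration(self, small_cb):
        grid, probs = enumerated_joint(small_cb, 22)
        mp = mean_parameters(small_cb, with_star=True)
        p_n = probs.sum(axis=1)
        assert np.allclose(mp.eta_n, p_n @ grid, atol=1e-6)
        from scipy.special import gammaln
        assert np.allclose(mp.eta_star, p_n @ gammaln(grid + 1.0), atol=1e-6)
        assert np.allclose(mp.eta_k, probs.sum(axis=0)[1:], atol=1e-6)
        for k in range(1, 4):
            target = probs[:, k] @ grid          # E[n 1(k)] per neuron
            assert np.allclose(mp.eta_nk[:, k - 1], target, atol=1e-6)

    def test_eta_k_equals_index_probabilities(self, small_cb):
        mp = mean_parameters(small_cb)
        ref = np.exp(index_log_probabilities(small_cb))[1:]
        assert np.allclose(mp.eta_k, ref, atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("family", ["ip", "cb"])
    @pytest.mark.parametrize("variant", ["von_mises", "discrete"])
    def test_finite_differences(self, family, variant):
        cm = random_ground_truth_cm(
            RandomCmRecipe(n_neurons=3, n_components=2, family=family), 3)
        levels = [0.0, 45.0, 90.0, 135.0]
        if variant == "discrete":
            cm = _discretize(cm, levels)
        counts, stim = generate_dataset(cm, levels, 15, 5)
        resp = e_step(cm, counts, stim)
        train_star = family == "cb"
        grads = m_step_gradients(cm, counts, stim, resp)
        assert ("theta_star" in grads) == train_star
        vec = _pack(_minimal_blocks(cm, train_star))
        gvec = _pack([(n, grads[n]) for n, _ in _minimal_blocks(cm, train_star)])
        eps = 1e-5
        fd = np.zeros_like(vec)
        for j in range(len(vec)):
            up, down = vec.copy(), vec.copy()
            up[j] += eps
            down[j] -= eps
            fd[j] = (complete_log_likelihood(_unpack_into_cm(up, cm, train_star),
                                             counts, stim, resp)
                     - complete_log_likelihood(_unpack_into_cm(down, cm, train_star),
                                               counts, stim, resp)) / (2 * eps)
        rel = np.abs(fd - gvec) / np.maximum(1.0, np.abs(gvec))
        assert rel.max() < 1e-5

    def test_maximal_routes_per_condition(self, small_cb):
        levels = [0.0, 90.0]
        table = [small_cb, MixtureNatural(small_cb.theta_n + 0.2, small_cb.theta_k,
                                          small_cb.theta_nk, small_cb.theta_star)]
        cm = ConditionalMixture("maximal", "cb", table=table, stimulus_levels=levels)
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 6, size=(20, 3))
        stim = np.array([0.0] * 10 + [90.0] * 10)
        resp = e_step(cm, counts, stim)
        grads = m_step_gradients(cm, counts, stim, resp)
        assert set(grads) == {0.0, 90.0}
        # each condition's gradients equal a stand-alone fit on its trials
        solo = _constant_cm(small_cb, "cb")
        ref = m_step_gradients(solo, counts[:10], np.zeros(10), resp[:10])
        assert np.allclose(grads[0.0]["theta_n"], ref["theta_n0"])
        assert np.allclose(grads[0.0]["theta_nk"], ref["theta_nk"])

    def test_vanishes_at_stationary_point(self):
        # dK=1 discrete model whose rates equal the empirical means
        counts = np.array([[2], [4], [3], [3]])
        stim = np.zeros(4)
        base = fit_independent_baseline(counts, stim, "discrete")
        resp = e_step(base, counts, stim)
        grads = m_step_gradients(base, counts, stim, resp)
        assert np.abs(grads["theta_n0"]).max() < 1e-9


class TestBaselines:
    def test_poisson_ml_single_neuron(self):
        counts = np.array([[2], [4]])
        base = fit_independent_baseline(counts, np.zeros(2), "discrete")
        assert base.stimulus_map.theta_n0[0] == pytest.approx(np.log(3.0))

    def test_discrete_fit_reproduces_condition_means(self, tiny_dataset):
        counts, stim = tiny_dataset
        base = fit_independent_baseline(counts, stim, "discrete")
        for x in np.unique(stim):
            rates = np.exp(base.baseline_params(x))
            assert np.allclose(rates, counts[stim == x].mean(axis=0), atol=1e-10)

    def test_zero_count_neuron_floored(self):
        counts = np.column_stack([np.zeros(10, dtype=int),
                                  np.ones(10, dtype=int)])
        base = fit_independent_baseline(counts, np.zeros(10), "discrete")
        assert np.exp(base.stimulus_map.theta_n0[0]) == pytest.approx(0.1 / 10)

    def test_von_mises_consistency(self):
        # ML fit on data from a von Mises neuron recovers the map
        truth = ConditionalMixture("von_mises", "ip", stimulus_map=VonMisesMap(
            np.array([1.0, 0.4]), np.array([[0.8, -0.3], [0.2, 0.9]])))
        grid = np.linspace(0, 180, 12, endpoint=False)
        counts, stim = generate_dataset(truth, grid, 400, 9)
        fit = fit_independent_baseline(counts, stim, "von_mises")
        assert np.allclose(fit.stimulus_map.theta_n0,
                           truth.stimulus_map.theta_n0, atol=0.05)
        assert np.allclose(fit.stimulus_map.theta_nx,
                           truth.stimulus_map.theta_nx, atol=0.05)


class TestInitialization:
    def test_deterministic(self, tiny_dataset):
        counts, stim = tiny_dataset
        a = initialize_cm(counts, stim, "von_mises", 3, seed=5)
        b = initialize_cm(counts, stim, "von_mises", 3, seed=5)
        assert np.array_equal(a.theta_nk, b.theta_nk)
        assert np.array_equal(a.theta_k, b.theta_k)

    def test_single_component_returns_baseline(self, tiny_dataset):
        counts, stim = tiny_dataset
        init = initialize_cm(counts, stim, "von_mises", 1, seed=5)
        base = fit_independent_baseline(counts, stim, "von_mises")
        assert np.allclose(init.stimulus_map.theta_n0, base.stimulus_map.theta_n0)

    def test_sinusoidal_modulations(self, tiny_dataset):
        counts, stim = tiny_dataset
        init = initialize_cm(counts, stim, "von_mises", 4, seed=5)
        assert np.all(np.abs(init.theta_nk) <= 0.2 + 1e-12)
        # distinct phases: every pair of modulation columns differs
        cols = init.theta_nk.T
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                assert not np.allclose(cols[a], cols[b], atol=1e-6)

    def test_discrete_uniform_small(self, tiny_dataset):
        counts, stim = tiny_dataset
        init = initialize_cm(counts, stim, "discrete", 3, seed=5)
        assert np.all(np.abs(init.theta_nk) <= 1e-4)


class TestFitEm:
    def test_monotone_log_likelihood(self, tiny_dataset):
        counts, stim = tiny_dataset
        _, trace = fit_em(counts, stim, "von_mises", "ip", 2,
                          TrainingSchedule(em_iters=10, ascent_steps=50), seed=3)
        assert np.all(np.diff(trace) > -1e-6 * len(stim))

    def test_cb_warm_start_continuity(self, tiny_dataset):
        counts, stim = tiny_dataset
        _, trace = fit_em(counts, stim, "von_mises", "cb", 2,
                          TrainingSchedule(em_iters=10, ascent_steps=50), seed=3)
        # attaching theta_star = -1 leaves the density unchanged, so the
        # trace stays monotone across the IP -> CB switch
        assert len(trace) == 10
        assert np.all(np.diff(trace) > -1e-6 * len(stim))

    def test_dk1_matches_convex_baseline(self, tiny_dataset):
        counts, stim = tiny_dataset
        base = fit_independent_baseline(counts, stim, "von_mises")
        ll_base = log_likelihood(base, counts, stim)
        _, trace = fit_em(counts, stim, "von_mises", "ip", 1,
                          TrainingSchedule(em_iters=5, ascent_steps=50), seed=3)
        assert trace[-1] == pytest.approx(ll_base, abs=1e-4)

    def test_maximal_fit_matches_per_condition_mixtures(self, tiny_dataset):
        counts, stim = tiny_dataset
        sched = TrainingSchedule(em_iters=5, ascent_steps=30)
        cm, trace = fit_em(counts, stim, "maximal", "ip", 2, sched, seed=3)
        assert cm.variant == "maximal"
        assert len(trace) == 5
        assert log_likelihood(cm, counts, stim) == pytest.approx(trace[-1])

    def test_moment_recovery_up_to_permutation(self):
        # fitting to ample data from a known IP-CM recovers per-stimulus
        # means and covariances (component labels may permute)
        truth = random_ground_truth_cm(
            RandomCmRecipe(n_neurons=5, n_components=3, family="ip"), 13)
        grid = np.linspace(0, 180, 8, endpoint=False)
        counts, stim = generate_dataset(truth, grid, 1250, 14)
        cm, _ = fit_em(counts, stim, "von_mises", "ip", 3,
                       TrainingSchedule(em_iters=60), seed=15)
        from condmix.mixture import moments
        for x in (0.0, 67.5, 112.5):
            mt = moments(truth.mixture_at(x))
            mf = moments(cm.mixture_at(x))
            assert np.allclose(mf.mean, mt.mean, rtol=0.1, atol=0.15)
            scale = np.sqrt(np.outer(np.diag(mt.covariance), np.diag(mt.covariance)))
            assert np.max(np.abs(mf.covariance - mt.covariance) / scale) < 0.25


class TestLogLikelihood:
    def test_empty_dataset(self, tiny_truth_cm):
        assert log_likelihood(tiny_truth_cm, np.zeros((0, 3), dtype=int),
                              np.zeros(0)) == 0.0

    def test_single_trial_equals_observable(self, tiny_truth_cm):
        n = np.array([[1, 2, 0]])
        ref = observable_log_pmf(tiny_truth_cm.mixture_at(30.0), n[0])
        assert log_likelihood(tiny_truth_cm, n, np.array([30.0])) == pytest.approx(ref)

    def test_matches_enumeration_weighting(self, small_cb):
        cm = _constant_cm(small_cb, "cb")
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 6, size=(7, 3))
        total, per = log_likelihood(cm, counts, np.zeros(7), per_trial=True)
        ref = [observable_log_pmf(small_cb, n) for n in counts]
        assert np.allclose(per, ref, atol=1e-10)
        assert total == pytest.approx(float(np.sum(ref)))

    def test_aborts_on_nonfinite(self, tiny_dataset):
        counts, stim = tiny_dataset
        bad = ConditionalMixture(
            "von_mises", "ip",
            stimulus_map=VonMisesMap(np.full(3, 800.0), np.zeros((3, 2))))
        with pytest.raises((RuntimeError, ValueError, OverflowError)):
            fit_em(counts, stim, "von_mises", "ip", 1,
                   TrainingSchedule(em_iters=2, ascent_steps=5), seed=0, init=bad)
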