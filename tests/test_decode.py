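"""Bayesian decoding, Fisher information, decoder baselines, cross-validation."""

import itertools

import numpy as np
import pytest

from condmix.mixture import observable_log_pmf, weights_rates_from_natural
from condmix.conditional import ConditionalMixture, VonMisesMap
from condmix.countdist import poisson_log_pmf
from condmix.em import fit_independent_baseline, fit_em, TrainingSchedule
from condmix.decode import (
    estimate_prior,
    bayes_posterior,
    BayesDecoder,
    mean_log_posterior,
    fisher_information,
    linear_fisher_information,
    mean_derivative,
    subpopulation_lfi,
    CategoricalDecoder,
    fit_categorical_decoder,
    decoder_param_count,
    crossval,
    fold_summary,
    crossval_information_gain,
    crossval_log_posterior,
)
from condmix.synthetic import (
    RandomCmRecipe,
    random_ground_truth_cm,
    generate_dataset,
    _discretize,
)


@pytest.fixture(scope="module")
def decoding_setup():
    """Discrete ground truth, a dataset, and the empirical prior."""
    truth = random_ground_truth_cm(
        RandomCmRecipe(n_neurons=4, n_components=3, family="ip"), 31)
    levels = [0.0, 45.0, 90.0, 135.0]
    cm = _discretize(truth, levels)
    counts, stim = generate_dataset(cm, levels, 60, 32)
    lv, prior = estimate_prior(stim)
    return cm, counts, stim, lv, prior


class TestPrior:
    def test_balanced_design_uniform(self):
        lv, prior = estimate_prior(np.repeat([0.0, 45.0, 90.0], 7))
        assert np.allclose(prior, 1 / 3)
        assert prior.sum() == 1.0

    def test_frequency_ratio(self):
        _, prior = estimate_prior(np.array([0] * 10 + [1] * 30))
        assert np.allclose(prior, [0.25, 0.75])

    def test_unseen_level_gets_zero(self):
        lv, prior = estimate_prior(np.array([0, 0, 1]), levels=[0, 1, 2])
        assert prior[2] == 0.0
        assert prior.sum() == pytest.approx(1.0)


class TestBayesPosterior:
    def test_uniform_when_likelihoods_equal(self, decoding_setup):
        cm, *_ = decoding_setup
        flat = ConditionalMixture(
            "discrete", "ip",
            stimulus_map=type(cm.stimulus_map)(
                cm.stimulus_map.theta_n0,
                np.zeros_like(cm.stimulus_map.theta_nx),
                cm.stimulus_map.stimulus_levels))
        post = bayes_posterior(flat, [1, 0, 2, 1], np.full(4, 0.25))
        assert np.allclose(np.exp(post), 0.25)

    def test_one_hot_prior_dominates(self, decoding_setup):
        cm, counts, *_ = decoding_setup
        post = bayes_posterior(cm, counts[0], [0.0, 1.0, 0.0, 0.0])
        assert np.exp(post[1]) == pytest.approx(1.0)

    def test_matches_brute_force_weights_rates(self, decoding_setup):
        cm, counts, stim, lv, prior = decoding_setup
        n = counts[3]
        unnorm = []
        for j, x in enumerate(lv):
            wr = weights_rates_from_natural(cm.mixture_at(x))
            like = sum(w * np.exp(poisson_log_pmf(n, np.log(r)).sum())
                       for w, r in zip(wr.weights, wr.rates))
            unnorm.append(like * prior[j])
        ref = np.log(np.array(unnorm) / np.sum(unnorm))
        assert np.allclose(bayes_posterior(cm, n, prior), ref, atol=1e-10)

    def test_rejects_non_simplex_prior(self, decoding_setup):
        cm, counts, *_ = decoding_setup
        with pytest.raises(ValueError):
            bayes_posterior(cm, counts[0], [0.5, 0.2, 0.2, 0.2])


class TestMeanLogPosterior:
    def test_ignorant_decoder_nine_conditions(self):
        class Uniform:
            levels = np.arange(9)

            def log_posteriors(self, counts):
                return np.full((len(counts), 9), -np.log(9.0))

        mlp, _ = mean_log_posterior(Uniform(), np.zeros((5, 2), dtype=int),
                                    np.array([0, 3, 5, 7, 8]))
        assert mlp == pytest.approx(np.log(1 / 9))

    def test_hand_computed_toy(self):
        class Fixed:
            levels = np.array([0, 1])

            def log_posteriors(self, counts):
                return np.log(np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]]))

        mlp, raw = mean_log_posterior(Fixed(), np.zeros((3, 1), dtype=int),
                                      np.array([0, 1, 1]))
        assert mlp == pytest.approx(np.mean(np.log([0.9, 0.8, 0.5])))
        assert np.allclose(raw, np.log([0.9, 0.8, 0.5]))

    def test_floor_keeps_values_finite(self):
        class Zero:
            levels = np.array([0, 1])

            def log_posteriors(self, counts):
                return np.array([[-np.inf, 0.0]])

        mlp, raw = mean_log_posterior(Zero(), np.zeros((1, 1), dtype=int),
                                      np.array([0]))
        assert np.isfinite(mlp)
        assert raw[0] == -np.inf


class TestFisherInformation:
    def test_independent_poisson_closed_form(self):
        smap = VonMisesMap(np.array([0.5, 1.0]),
                           np.array([[0.7, 0.2], [-0.4, 0.6]]))
        cm = ConditionalMixture("von_mises", "ip", stimulus_map=smap)
        for x in (10.0, 88.0):
            mu = np.exp(smap(x))
            dmu = mu * smap.derivative(x)
            assert fisher_information(cm, x) == pytest.approx(
                np.sum(dmu**2 / mu), rel=1e-10)

    def test_flat_tuning_zero(self):
        cm = ConditionalMixture("von_mises", "ip", stimulus_map=VonMisesMap(
            np.array([1.0]), np.zeros((1, 2))))
        assert fisher_information(cm, 45.0) == pytest.approx(0.0, abs=1e-12)

    def test_covariance_form_equals_lfi(self, tiny_truth_cm):
        for x in (25.0, 140.0):
            a = fisher_information(tiny_truth_cm, x)
            b = linear_fisher_information(tiny_truth_cm, x)
            assert abs(a / b - 1) < 1e-6

    def test_matches_definitional_enumeration(self):
        cm = random_ground_truth_cm(RandomCmRecipe(n_neurons=2, n_components=3), 7)
        grid = np.array(list(itertools.product(range(60), repeat=2)))
        for x in (10.0, 77.5):
            h = 0.05
            lp0 = observable_log_pmf(cm.mixture_at(x), grid)
            dlogp = (observable_log_pmf(cm.mixture_at(x + h), grid)
                     - observable_log_pmf(cm.mixture_at(x - h), grid)) / np.deg2rad(2 * h)
            fi_def = float(np.exp(lp0) @ dlogp**2)
            assert fisher_information(cm, x) == pytest.approx(fi_def, rel=1e-4)

    def test_subpopulation_lfi_full_set_matches(self, tiny_truth_cm):
        full = linear_fisher_information(tiny_truth_cm, 60.0)
        sub = subpopulation_lfi(tiny_truth_cm, 60.0, np.arange(3))
        assert sub == pytest.approx(full, rel=1e-10)

    def test_requires_smooth_map(self, decoding_setup):
        cm, *_ = decoding_setup
        with pytest.raises(ValueError):
            fisher_information(cm, 0.0)


class TestDirectDecoders:
    def test_param_counts(self):
        assert decoder_param_count(43, 9) == 352
        assert decoder_param_count(70, 9) == 568
        assert decoder_param_count(43, 9, (700, 700)) == 527_108
        assert decoder_param_count(70, 9, (600, 600)) == 408_008

    def test_separable_toy_approaches_certainty(self):
        rng = np.random.default_rng(3)
        c0 = rng.poisson([1.0, 10.0], (300, 2))
        c1 = rng.poisson([10.0, 1.0], (300, 2))
        counts = np.vstack([c0, c1])
        stim = np.array([0] * 300 + [1] * 300)
        dec = fit_categorical_decoder(counts, stim, seed=5,
                                      learning_rate=0.01, max_epochs=500)
        mlp, _ = mean_log_posterior(dec, counts, stim)
        assert mlp > -0.1

    def test_posteriors_normalize_and_params_count(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 5, (80, 3))
        stim = rng.integers(0, 3, 80)
        dec = fit_categorical_decoder(counts, stim, hidden=(6, 6), seed=1,
                                      max_epochs=5)
        assert dec.param_count == decoder_param_count(3, 3, (6, 6))
        post = dec.log_posteriors(counts)
        assert np.allclose(np.exp(post).sum(axis=1), 1.0)

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 5, (60, 2))
        stim = rng.integers(0, 2, 60)
        a = fit_categorical_decoder(counts, stim, seed=4, max_epochs=10)
        b = fit_categorical_decoder(counts, stim, seed=4, max_epochs=10)
        for (wa, ba), (wb, bb) in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb) and np.array_equal(ba, bb)


class TestCrossval:
    def test_folds_partition_and_stratify(self, decoding_setup):
        _, counts, stim, lv, _ = decoding_setup
        from condmix.decode import _stratified_folds
        folds = _stratified_folds(stim, 10, seed=2)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(len(stim)))
        for f in folds:
            _, per = np.unique(stim[f], return_counts=True)
            assert per.max() - per.min() <= 1

    def test_metric_aggregation_two_folds(self):
        import pandas as pd
        df = pd.DataFrame({"fold": [0, 1], "n_test": [5, 5],
                           "metric": [1.0, 3.0]})
        out = fold_summary(df)
        assert out.loc["metric", "mean"] == pytest.approx(2.0)
        assert out.loc["metric", "se"] == pytest.approx(
            np.std([1.0, 3.0], ddof=1) / np.sqrt(2))

    def test_baseline_against_itself_gains_zero(self, decoding_setup):
        _, counts, stim, *_ = decoding_setup
        def fit_model(tc, ts, s):
            return fit_independent_baseline(tc, ts, "von_mises")
        df = crossval_information_gain(counts, stim, fit_model, folds=4, seed=0)
        assert np.allclose(df["information_gain"], 0.0, atol=1e-12)

    def test_correlated_truth_beats_baseline(self, decoding_setup):
        cm, counts, stim, *_ = decoding_setup
        # the generating model itself decodes no worse than the independent
        # baseline, and carries positive held-out information gain
        def fit_truth(tc, ts, s):
            return cm
        df = crossval_information_gain(counts, stim, fit_truth, folds=4, seed=1)
        assert fold_summary(df).loc["information_gain", "mean"] > 0

    def test_cm_decoder_beats_independent_on_correlated_data(self):
        # strong gain modulations -> strong noise correlations, which the
        # independent decoder cannot exploit
        truth = random_ground_truth_cm(
            RandomCmRecipe(n_neurons=6, n_components=3, family="ip",
                           modulation_mean=1.0, modulation_sd=0.2), 41)
        levels = [0.0, 45.0, 90.0, 135.0]
        cm = _discretize(truth, levels)
        counts, stim = generate_dataset(cm, levels, 60, 42)
        lv, prior = estimate_prior(stim)

        def fit_cm_decoder(tc, ts, s):
            return BayesDecoder(cm, lv, prior)

        def fit_ip_decoder(tc, ts, s):
            base = fit_independent_baseline(tc, ts, "discrete")
            return BayesDecoder(base, lv, prior)

        a = fold_summary(crossval_log_posterior(counts, stim, fit_cm_decoder,
                                                folds=4, seed=3))
        b = fold_summary(crossval_log_posterior(counts, stim, fit_ip_decoder,
                                                folds=4, seed=3))
        assert (a.loc["mean_log_posterior", "mean"]
                >= b.loc["mean_log_posterior", "mean"] - 1e-6)
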