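"""Measurement-model assembly, HDI computation and the Gibbs sampler."""

import numpy as np
import pytest

import priorcfa as pc
from priorcfa.model import (
    BayesianCFA,
    MeasurementModel,
    ModelSpecificationError,
    assemble_model,
    fit_gibbs,
    hdi,
)

from conftest import all_missing_frame


class TestHDI:
    def test_standard_normal_matches_equal_tailed(self):
        draws = np.random.default_rng(1).standard_normal(1_000_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_constant_draws_zero_width(self):
        assert hdi(np.full(100, 3.5), 0.95) == (3.5, 3.5)

    def test_exponential_hdi_starts_at_minimum(self):
        draws = np.random.default_rng(2).standard_exponential(1_000_000)
        lo, _ = hdi(draws, 0.90)
        assert lo <= draws.min() + 0.01

    def test_agrees_with_arviz_on_skewed_sample(self):
        import arviz as az

        draws = np.random.default_rng(3).gamma(2.0, size=20_000)
        lo, hi = hdi(draws, 0.9)
        ref = az.hdi(draws, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    @pytest.mark.parametrize("bad", [
        ([1.0], 0.95), ([1.0, np.nan], 0.95), ([1.0, 2.0], 1.5),
        ([1.0, 2.0], 0.0),
    ])
    def test_invalid_inputs(self, bad):
        draws, mass = bad
        with pytest.raises(ValueError):
            hdi(np.asarray(draws), mass)


class TestMeasurementModel:
    def test_assembles_with_consistent_priors(self, small_cls, small_model):
        assert small_model.n_factors == 2
        assert small_model.item_ids == [1, 2, 3, 4, 5, 6]

    def test_prior_classification_mismatch_raises(self, small_cls,
                                                  published_priors):
        with pytest.raises(ModelSpecificationError):
            assemble_model(small_cls, published_priors)

    def test_identification_mode_sets_latent_scale(self, small_model):
        assert small_model.latent_sd == 1.0
        faithful = MeasurementModel(small_model.loading_pattern,
                                    small_model.priors, "vague_latent")
        assert faithful.latent_sd == 100.0

    def test_unknown_mode_rejected(self, small_model):
        with pytest.raises(ValueError):
            MeasurementModel(small_model.loading_pattern,
                             small_model.priors, "nonsense")


def _tiny_model():
    cls = pc.ItemClassification({1: "SAT", 2: "SAT"})
    votes = pc.vote_matrix_from_dicts(
        {1: {"SAT": 15, "OUT": 7}, 2: {"SAT": 12, "OUT": 10}}, 22)
    return cls, assemble_model(cls, pc.build_prior_set(cls, votes))


class TestFitGibbs:
    def test_single_indicator_factor_rejected(self):
        cls = pc.ItemClassification({1: "SAT", 2: "SAT", 3: "OUT"})
        votes = pc.vote_matrix_from_dicts(
            {i: {cls.assignments[i]: 15, "MOB": 7} for i in (1, 2, 3)}, 22)
        model = assemble_model(cls, pc.build_prior_set(cls, votes))
        with pytest.raises(ModelSpecificationError, match="single indicator"):
            fit_gibbs(model, all_missing_frame([1, 2, 3]), chains=1,
                      iterations=10, burn_in=0, seed=1)

    def test_empty_data_rejected(self, small_model):
        X = all_missing_frame(small_model.item_ids, n=0)
        with pytest.raises(ValueError, match="empty data"):
            fit_gibbs(small_model, X, chains=1, iterations=10, burn_in=0,
                      seed=1)

    def test_out_of_range_likert_values_rejected(self, small_model):
        X = all_missing_frame(small_model.item_ids, n=2)
        X.iloc[0, 0] = 6.0
        with pytest.raises(ValueError, match="1..5"):
            fit_gibbs(small_model, X, chains=1, iterations=10, burn_in=0,
                      seed=1)

    def test_seed_required(self, small_model):
        with pytest.raises(ValueError, match="seed"):
            fit_gibbs(small_model, all_missing_frame(small_model.item_ids),
                      chains=1, iterations=10, burn_in=0, seed=None)

    def test_identical_seed_gives_identical_draws(self, small_model,
                                                  small_data):
        kw = dict(chains=2, iterations=200, burn_in=100, seed=99)
        a = fit_gibbs(small_model, small_data, **kw)
        b = fit_gibbs(small_model, small_data, **kw)
        assert np.array_equal(a.loadings, b.loadings)
        assert np.array_equal(a.error_variances, b.error_variances)
        assert np.array_equal(a.latent, b.latent)
        c = fit_gibbs(small_model, small_data, chains=2, iterations=200,
                      burn_in=100, seed=100)
        assert not np.array_equal(a.loadings, c.loadings)

    def test_error_variance_draws_positive(self, small_model, small_data):
        s = fit_gibbs(small_model, small_data, chains=2, iterations=300,
                      burn_in=100, seed=5)
        assert np.all(s.error_variances > 0)

    def test_prior_recovery_with_all_missing_data(self):
        # no observed cells: every full conditional is the prior, so the
        # posterior must reproduce it within Monte-Carlo error
        _, model = _tiny_model()
        X = all_missing_frame(model.item_ids)
        s = fit_gibbs(model, X, chains=2, iterations=4000, burn_in=1000,
                      seed=0)
        for role, arr in (("loading", s.loadings),
                          ("intercept", s.intercepts)):
            for idx, j in enumerate(s.item_ids):
                d = arr[:, :, idx].ravel()
                prior = model.prior(role, j)
                mcse = d.std(ddof=1) / np.sqrt(d.size)
                assert abs(d.mean() - prior.mean) <= 2 * mcse
                assert d.std(ddof=1) == pytest.approx(prior.sd, rel=0.1)

    def test_parameter_recovery_bias_shrinks_with_n(self, small_cls,
                                                    small_model):
        true = {j: small_model.prior("loading", j).mean
                for j in small_model.item_ids}
        bias = []
        for n in (50, 200, 800):
            data = pc.simulate_responses(small_cls, pc.ResponseSimConfig(
                n_respondents=n, true_loadings=true, seed=31))
            s = fit_gibbs(small_model, data, chains=2, iterations=1000,
                          burn_in=400, seed=17, save_latent=False)
            post = s.loadings.mean(axis=(0, 1))
            bias.append(np.mean(np.abs(
                post - [true[j] for j in s.item_ids])))
        assert bias[0] > bias[2]

    def test_summary_contract(self, small_model, small_data):
        s = fit_gibbs(small_model, small_data, chains=2, iterations=400,
                      burn_in=100, seed=5, save_latent=False)
        summ = s.summary()
        assert len(summ) == 3 * len(s.item_ids)
        d = s.parameter_draws("loading[1]").ravel()
        row = summ.loc["loading[1]"]
        assert row["mean"] == pytest.approx(d.mean())
        assert row["hdi_low"] < row["mean"] < row["hdi_high"]
        mass = np.mean((d >= row["hdi_low"]) & (d <= row["hdi_high"]))
        assert mass >= 0.95 - 1.0 / d.size


class TestGridOracle:
    """Gibbs posterior vs. dense grid integration on a pinned tiny model.

    The oracle (see conftest) evaluates the exact 2-d loading posterior of
    a one-factor, two-item, five-respondent model on a dense grid via the
    closed-form marginal likelihood, independently of the sampler.
    """

    def test_total_variation_below_tolerance(self):
        from conftest import gibbs_vs_grid_total_variation

        assert gibbs_vs_grid_total_variation(seed=5) < 0.05


class TestBayesianCFAEstimator:
    def test_sklearn_params_roundtrip(self, small_model):
        from sklearn.base import clone

        est = BayesianCFA(loading_pattern=small_model.loading_pattern,
                          priors=small_model.priors, chains=2, n_iter=50,
                          burn_in=10, random_state=3)
        cloned = clone(est)
        assert cloned.get_params()["chains"] == 2
        est.set_params(chains=3)
        assert est.chains == 3

    def test_fit_exposes_fitted_attributes(self, small_model, small_data):
        est = BayesianCFA(loading_pattern=small_model.loading_pattern,
                          priors=small_model.priors, chains=2, n_iter=300,
                          burn_in=100, random_state=3).fit(small_data)
        assert est.summary_.shape[0] == 18
        assert est.n_respondents_ == len(small_data)
        scores = est.transform()
        assert scores.shape == (len(small_data), 2)

    def test_unfitted_transform_raises(self, small_model):
        from sklearn.exceptions import NotFittedError

        est = BayesianCFA(loading_pattern=small_model.loading_pattern,
                          priors=small_model.priors)
        with pytest.raises(NotFittedError):
            est.transform()

    def test_vague_latent_mode_identifies_loading_scale_product(
            self, small_cls, small_model, small_data):
        # with a vague latent prior only lambda * eta is identified: the
        # product's posterior mean must agree across identification modes
        std = BayesianCFA(loading_pattern=small_model.loading_pattern,
                          priors=small_model.priors, chains=2, n_iter=1500,
                          burn_in=700, random_state=3).fit(small_data)
        faith = BayesianCFA(loading_pattern=small_model.loading_pattern,
                            priors=small_model.priors,
                            identification="vague_latent", chains=2,
                            n_iter=1500, burn_in=700,
                            random_state=3).fit(small_data)
        prod_std = (std.samples_.loadings[:, :, 0, None]
                    * std.samples_.latent[:, :, :, 0]).mean(axis=(0, 1))
        prod_faith = (faith.samples_.loadings[:, :, 0, None]
                      * faith.samples_.latent[:, :, :, 0]).mean(axis=(0, 1))
        rms = np.sqrt(np.mean((prod_std - prod_faith) ** 2))
        assert rms < 0.15
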