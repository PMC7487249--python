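"""Model fitting API, AIC, likelihood-ratio tests, bootstrap intervals."""

import numpy as np
import pytest

import polygrowth as pg
from polygrowth.inference import (
    NESTED_PAIRS,
    FitResult,
    NotNestedError,
    significance_stars,
)
from polygrowth.likelihood import ModelSpec


def make_fit(name: str, nll: float) -> FitResult:
    """Bookkeeping-only FitResult (parameters irrelevant for AIC/LRT math)."""
    spec = ModelSpec.from_name(name)
    theta = pg.GrowthParams(k=0.05, b=1.3, l=0.0 if name[0] == "A" else 0.5)
    dist = (pg.Lognormal(3.0, 0.2) if name[1] == "L"
            else pg.GenGamma(20.0, 2.0, 5.0))
    k = spec.n_params
    return FitResult(spec=spec, theta=theta, dist=dist, nll=nll,
                     k_params=k, aic=pg.aic(nll, k))


class TestAic:
    @pytest.mark.parametrize("nll, k, expected", [
        (327.0, 4, 662.0),
        (317.6, 5, 645.2),
        (0.0, 1, 2.0),
    ])
    def test_values(self, nll, k, expected):
        assert pg.aic(nll, k) == pytest.approx(expected)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            pg.aic(10.0, 0)


class TestLikelihoodRatioTest:
    def test_statistic_from_published_nlls(self):
        r = pg.likelihood_ratio_test(make_fit("AL", 810.1), make_fit("AG", 795.7))
        assert r.chi2 == pytest.approx(28.8, abs=1e-9)
        assert r.df == 1
        assert r.p < 0.001
        assert significance_stars(r.p) == "***"

    def test_identical_models_give_p_one(self):
        r = pg.likelihood_ratio_test(make_fit("AL", 500.0), make_fit("PL", 500.0))
        assert r.chi2 == 0.0
        assert r.p == pytest.approx(1.0)

    def test_nonnested_pair_refused(self):
        with pytest.raises(NotNestedError):
            pg.likelihood_ratio_test(make_fit("AG", 500.0), make_fit("PL", 490.0))
        with pytest.raises(NotNestedError):
            pg.likelihood_ratio_test(make_fit("PG", 490.0), make_fit("AL", 500.0))

    def test_degrees_of_freedom_rules(self):
        assert NESTED_PAIRS[("AL", "AG")] == 1
        assert NESTED_PAIRS[("AL", "PL")] == 1
        assert NESTED_PAIRS[("AG", "PG")] == 1
        assert NESTED_PAIRS[("PL", "PG")] == 1
        assert NESTED_PAIRS[("AL", "PG")] == 2
        r = pg.likelihood_ratio_test(make_fit("AL", 810.1), make_fit("PG", 794.8))
        assert r.df == 2


class TestFitModel:
    def test_recovers_al_truth_roughly(self, larch_al, fast_pso):
        data = pg.generate(larch_al, 2000, 13)
        fit = pg.fit_model(data, ModelSpec.from_name("AL"), fast_pso)
        p = fit.params_dict()
        assert p["k"] == pytest.approx(0.0471, rel=0.10)
        assert p["b"] == pytest.approx(1.35, rel=0.10)
        assert p["mu"] == pytest.approx(3.26, rel=0.10)
        assert p["sigma"] == pytest.approx(0.161, rel=0.10)

    def test_deterministic_refit(self, larch_al, fast_pso):
        data = pg.generate(larch_al, 100, 14)
        f1 = pg.fit_model(data, ModelSpec.from_name("AL"), fast_pso)
        f2 = pg.fit_model(data, ModelSpec.from_name("AL"), fast_pso)
        assert f1.nll == f2.nll
        assert f1.params_dict() == f2.params_dict()

    def test_aic_identity(self, larch_al, fast_pso):
        data = pg.generate(larch_al, 100, 15)
        fit = pg.fit_model(data, ModelSpec.from_name("AL"), fast_pso)
        assert fit.aic == pytest.approx(2 * fit.nll + 2 * fit.k_params)
        assert fit.k_params == 4

    def test_too_few_observations(self, larch_al, fast_pso):
        data = pg.generate(larch_al, 4, 16)
        with pytest.raises(ValueError):
            pg.fit_model(data, ModelSpec.from_name("AL"), fast_pso)

    def test_nested_fit_improves_nll(self, larch_al, tiny_pso):
        """Fuller models reach at least the reduced model's likelihood.

        The generalized gamma only approaches the lognormal in the psi ->
        infinity limit, which the bounded search box truncates, so the
        comparison across distribution families carries a small slack.
        """
        for s in range(6):
            data = pg.generate(larch_al, 120, 400 + s)
            fit_al = pg.fit_model(data, ModelSpec.from_name("AL"), tiny_pso)
            fit_pl = pg.fit_model(data, ModelSpec.from_name("PL"), tiny_pso,
                                  init_theta=fit_al.theta)
            fit_pg = pg.fit_model(data, ModelSpec.from_name("PG"), tiny_pso,
                                  init_theta=fit_pl.theta)
            assert fit_pl.nll <= fit_al.nll + 1e-4
            assert fit_pg.nll <= fit_al.nll + 0.5


class TestBootstrap:
    def test_percentile_intervals_cover_point(self, larch_al, fast_pso):
        data = pg.generate(larch_al, 120, 23)
        res = pg.bootstrap_ci(data, ModelSpec.from_name("AL"), B=40, seed=4,
                              settings=fast_pso)
        assert res.B == 40
        assert len(res.estimates) == 40 - res.n_failures
        for name in ("k", "b", "mu", "sigma"):
            lo, hi = res.ci[name]
            assert lo <= hi
        # point estimate inside (or at worst on) its own interval
        assert res.ci["mu"][0] <= res.point["mu"] <= res.ci["mu"][1]

    def test_deterministic(self, larch_al, fast_pso):
        data = pg.generate(larch_al, 80, 24)
        r1 = pg.bootstrap_ci(data, ModelSpec.from_name("AL"), B=10, seed=5,
                             settings=fast_pso)
        r2 = pg.bootstrap_ci(data, ModelSpec.from_name("AL"), B=10, seed=5,
                             settings=fast_pso)
        assert r1.ci == r2.ci

    def test_intervals_shrink_with_sample_size(self, larch_al, fast_pso):
        widths = {}
        for n in (100, 400):
            data = pg.generate(larch_al, n, 25)
            res = pg.bootstrap_ci(data, ModelSpec.from_name("AL"), B=60,
                                  seed=6, settings=fast_pso)
            widths[n] = res.ci["mu"][1] - res.ci["mu"][0]
        assert widths[400] < widths[100]

    def test_degenerate_data_structured_failure(self, fast_pso):
        ages = np.full(8, 50.0)
        sizes = np.full(8, 20.0)
        data = pg.ObservationSet(ages=ages, sizes=sizes)
        with pytest.raises(pg.FitFailureError):
            pg.bootstrap_ci(data, ModelSpec.from_name("AL"), B=5, seed=7,
                            settings=fast_pso)

    def test_invalid_B(self, larch_al, fast_pso):
        data = pg.generate(larch_al, 50, 26)
        with pytest.raises(ValueError):
            pg.bootstrap_ci(data, ModelSpec.from_name("AL"), B=1, seed=1,
                            settings=fast_pso)


class TestPercentileCurves:
    def test_median_curve_anamorphic(self):
        theta = pg.GrowthParams(k=0.0463, b=1.76)
        dist = pg.Lognormal(mu=3.06, sigma=0.194)
        ages = np.linspace(11, 110, 12)
        curves = pg.percentile_curves((theta, dist), (0.5,), ages)
        expected = np.exp(3.06) * (1 - np.exp(-theta.k * ages)) ** theta.b
        np.testing.assert_allclose(curves[0.5].to_numpy(), expected, rtol=1e-10)

    def test_quantile_ordering(self, cypress_pg):
        ages = np.linspace(11, 110, 15)
        curves = pg.percentile_curves((cypress_pg.theta, cypress_pg.dist),
                                      (0.025, 0.5, 0.975), ages)
        assert np.all(curves[0.025] < curves[0.5])
        assert np.all(curves[0.5] < curves[0.975])

    def test_matches_quantile_evaluate_composition(self, cypress_pg):
        theta, dist = cypress_pg.theta, cypress_pg.dist
        ages = np.linspace(11, 110, 8)
        curves = pg.percentile_curves((theta, dist), (0.025, 0.5, 0.975), ages)
        for q in (0.025, 0.5, 0.975):
            A_q = dist.quantile(q)
            expected = [pg.evaluate(theta, A_q, float(t)) for t in ages]
            np.testing.assert_allclose(curves[q].to_numpy(), expected, rtol=1e-12)
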