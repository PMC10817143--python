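"""BCCG distribution, backfitting fit, centile evaluation, diagnostics."""

import numpy as np
import pytest
from scipy import optimize, stats

from gwgcharts.centiles import (BCCGCentileModel, bccg_cdf, bccg_logpdf,
                                bccg_quantile, bccg_rvs, compare_models,
                                evaluate_centiles, fit_bccg,
                                pool_centile_models, quantile_diagnostics)


class TestDistribution:
    def test_nu_one_is_scaled_normal(self):
        # with nu = 1, Y ~ Normal(mu, mu sigma)
        y = np.linspace(5, 15, 30)
        got = bccg_logpdf(y, 10.0, 0.2, 1.0)
        want = stats.norm.logpdf(y, 10.0, 2.0)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_median_is_mu(self):
        for nu in (-1.0, 0.0, 0.5, 2.0):
            assert bccg_quantile(0.5, 8.0, 0.15, nu) == pytest.approx(8.0)

    def test_quantile_linear_in_zp_at_nu_one(self):
        mu, sigma = 12.0, 0.1
        for p in (0.03, 0.25, 0.9):
            zp = stats.norm.ppf(p)
            assert bccg_quantile(p, mu, sigma, 1.0) == pytest.approx(
                mu * (1 + sigma * zp), abs=1e-9)

    def test_cdf_quantile_round_trip(self):
        for nu in (-0.8, 0.0, 1.3):
            for p in (0.05, 0.5, 0.95):
                y = bccg_quantile(p, 9.0, 0.12, nu)
                assert bccg_cdf(y, 9.0, 0.12, nu) == pytest.approx(p, abs=1e-10)

    def test_logpdf_integrates_to_one(self):
        from scipy.integrate import quad
        val, _ = quad(lambda y: np.exp(bccg_logpdf(y, 10.0, 0.1, 0.5)),
                      1e-6, 50.0)
        assert val == pytest.approx(1.0, abs=1e-4)


@pytest.fixture(scope="module")
def constant_truth_sample():
    rng = np.random.default_rng(13)
    t = rng.uniform(5, 40, 2000)
    y = rng.normal(10.0, 2.0, 2000)          # BCCG(mu=10, sigma=0.2, nu=1)
    return t, y


class TestFit:
    def test_constant_fit_recovers_normal_truth(self, constant_truth_sample):
        t, y = constant_truth_sample
        model = BCCGCentileModel(mu_basis="constant", mu_df=1,
                                 sigma_basis="constant", sigma_df=1,
                                 shift=0.0).fit(t, y)
        mu, sigma, nu = model.parameters(np.array([20.0]))
        se_mu = 2.0 / np.sqrt(len(y))
        assert abs(mu[0] - 10.0) < 3 * se_mu + 0.05
        assert abs(sigma[0] - 0.2) < 0.02

    def test_fixed_nu_matches_direct_optimizer_oracle(self,
                                                      constant_truth_sample):
        t, y = constant_truth_sample
        model = BCCGCentileModel(mu_basis="constant", mu_df=1,
                                 sigma_basis="constant", sigma_df=1,
                                 shift=0.0, fix_nu=1.0).fit(t, y)

        def neg2ll(params):
            mu, sigma = np.exp(params)
            return -2 * np.sum(bccg_logpdf(y, mu, sigma, 1.0))

        res = optimize.minimize(neg2ll, [np.log(10.0), np.log(0.2)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert model.deviance_ == pytest.approx(res.fun, abs=1e-4)

    def test_deviance_never_increases(self, constant_truth_sample):
        t, y = constant_truth_sample
        model = BCCGCentileModel(mu_basis="bspline", mu_df=4,
                                 shift=0.0).fit(t, y)
        path = np.array(model.deviance_path_)
        assert np.all(np.diff(path) <= 1e-9)

    def test_refit_determinism(self, constant_truth_sample):
        t, y = constant_truth_sample
        d1 = BCCGCentileModel(shift=0.0).fit(t, y).deviance_
        d2 = BCCGCentileModel(shift=0.0).fit(t, y).deviance_
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="50 observations"):
            BCCGCentileModel().fit([1.0] * 10, [1.0] * 10)
        rng = np.random.default_rng(0)
        t = rng.uniform(5, 40, 100)
        with pytest.raises(ValueError, match="support shift"):
            BCCGCentileModel(shift=0.0).fit(t, rng.normal(-5, 1, 100))


@pytest.fixture(scope="module")
def fitted(constant_truth_sample):
    t, y = constant_truth_sample
    return BCCGCentileModel(mu_basis="linear", mu_df=2, shift=0.0).fit(t, y)


class TestCentiles:
    def test_median_equals_mu(self, fitted):
        grid = np.linspace(6, 39, 12)
        np.testing.assert_allclose(fitted.centile(grid, 0.5),
                                   fitted.predict(grid), atol=1e-9)

    def test_non_crossing(self, fitted):
        grid = np.linspace(6, 39, 40)
        ps = (0.03, 0.1, 0.25, 0.5, 0.75, 0.9, 0.97)
        curves = np.array([fitted.centile(grid, p) for p in ps])
        assert np.all(np.diff(curves, axis=0) > 0)

    def test_closed_form_at_nu_one(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(5, 40, 800)
        y = rng.normal(10, 2, 800)
        m = BCCGCentileModel(mu_basis="constant", mu_df=1,
                             sigma_basis="constant", sigma_df=1,
                             shift=0.0, fix_nu=1.0).fit(t, y)
        mu, sigma, _ = m.parameters(np.array([20.0]))
        for p in (0.1, 0.9):
            want = mu[0] * (1 + sigma[0] * stats.norm.ppf(p))
            assert m.centile(np.array([20.0]), p)[0] == pytest.approx(
                want, abs=1e-9)

    def test_centile_bounds_enforced(self, fitted):
        with pytest.raises(ValueError):
            fitted.centile(np.array([20.0]), 0.0)
        with pytest.raises(ValueError):
            evaluate_centiles(fitted, [20.0], centiles=(1.5,))

    def test_table_layout(self, fitted):
        table = evaluate_centiles(fitted, np.arange(6, 40),
                                  centiles=(0.1, 0.5, 0.9))
        assert list(table.columns) == ["ga_weeks", "P10", "P50", "P90"]
        assert (table["P10"] < table["P50"]).all()


class TestDiagnostics:
    def test_self_consistency_coverage(self):
        """Data drawn from the fitted model's own family: empirical centile
        coverage within binomial 99% bands, residuals ~ N(0, 1)."""
        rng = np.random.default_rng(29)
        n = 5000
        t = rng.uniform(5, 40, n)
        mu_true = 8.0 + 0.25 * t
        y = bccg_rvs(mu_true, 0.15, 0.7, n, rng)
        model = BCCGCentileModel(mu_basis="linear", mu_df=2,
                                 sigma_basis="constant", sigma_df=1,
                                 shift=0.0).fit(t, y)
        diag = quantile_diagnostics(model, t, y,
                                    centiles=(0.03, 0.10, 0.50, 0.90, 0.97))
        for p, cov in diag.coverage.items():
            lo = stats.binom.ppf(0.005, n, p) / n
            hi = stats.binom.ppf(0.995, n, p) / n
            assert lo <= cov <= hi, (p, cov)
        assert abs(diag.residuals.mean()) < 3 / np.sqrt(n) + 0.01
        assert abs(diag.homoscedasticity_corr) < 0.05

    def test_coverage_monotone(self, constant_truth_sample):
        t, y = constant_truth_sample
        model = BCCGCentileModel(mu_basis="constant", mu_df=1,
                                 shift=0.0).fit(t, y)
        diag = quantile_diagnostics(model, t, y)
        cov = [diag.coverage[p] for p in sorted(diag.coverage)]
        assert cov == sorted(cov)

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError):
            quantile_diagnostics(BCCGCentileModel(), [1.0], [1.0])


@pytest.fixture(scope="module")
def two_fits(constant_truth_sample):
    t, y = constant_truth_sample
    small = BCCGCentileModel(mu_basis="constant", mu_df=1,
                             sigma_basis="constant", sigma_df=1,
                             shift=0.0).fit(t, y)
    big = BCCGCentileModel(mu_basis="bspline", mu_df=6,
                           sigma_basis="constant", sigma_df=1,
                           shift=0.0).fit(t, y)
    return small, big


class TestComparison:
    def test_gaic2_is_aic(self, two_fits):
        for m in two_fits:
            assert m.gaic(2.0) == pytest.approx(m.aic_)

    def test_overfit_ranked_below_truth(self, two_fits):
        small, big = two_fits
        ranking = compare_models([big, small], k=3.0)
        assert ranking.iloc[0]["edf"] == small.edf_

    def test_tie_broken_by_edf(self, constant_truth_sample):
        t, y = constant_truth_sample
        a = BCCGCentileModel(mu_basis="constant", mu_df=1, shift=0.0).fit(t, y)
        b = BCCGCentileModel(mu_basis="constant", mu_df=1, shift=0.0).fit(t, y)
        ranking = compare_models([a, b], k=2.0)
        assert list(ranking["rank"]) == [1, 2]

    def test_different_data_rejected(self, constant_truth_sample):
        t, y = constant_truth_sample
        a = BCCGCentileModel(mu_basis="constant", shift=0.0,
                             mu_df=1).fit(t, y)
        b = BCCGCentileModel(mu_basis="constant", shift=0.0,
                             mu_df=1).fit(t[:1000], y[:1000])
        with pytest.raises(ValueError, match="different data"):
            compare_models([a, b])


class TestPooling:
    def test_pooled_curves_average_identical_models(self, constant_truth_sample):
        t, y = constant_truth_sample
        m = BCCGCentileModel(mu_basis="linear", mu_df=2, shift=0.0).fit(t, y)
        grid = np.linspace(6, 39, 10)
        single = evaluate_centiles(m, grid, centiles=(0.1, 0.5, 0.9))
        pooled = pool_centile_models([m, m, m], grid, centiles=(0.1, 0.5, 0.9))
        np.testing.assert_allclose(pooled["P50"], single["P50"], atol=1e-12)

    def test_shift_mismatch_rejected(self, constant_truth_sample):
        t, y = constant_truth_sample
        y2 = np.abs(y) + 1
        a = BCCGCentileModel(shift=0.0, mu_basis="constant", mu_df=1).fit(t, y2)
        b = BCCGCentileModel(shift=5.0, mu_basis="constant", mu_df=1).fit(t, y2)
        with pytest.raises(ValueError, match="shift"):
            pool_centile_models([a, b], np.array([20.0]))
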