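"""Beta-binomial likelihood, design matrices, fitting and selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist
from scipy.stats import binom

import callsplit as cs
from callsplit.bbgam import (TABLE_CANDIDATES, BBParams, BetaBinomialGAM,
                             BetaBinomialGAMResults, FitControl,
                             ModelStructure, aicc, bb_logpmf, bb_mean_var,
                             bootstrap_refit, build_design,
                             fit_occurrence_model, select_model)
from conftest import make_constant_acoustic


def quadrature_logpmf(k, n, mu, sigma):
    """Independent oracle: integrate Binomial(k; n, p) * Beta(p; a, b)."""
    a, b = mu / sigma, (1 - mu) / sigma
    val, _ = quad(lambda p: binom.pmf(k, n, p) * beta_dist.pdf(p, a, b),
                  0, 1, epsabs=1e-13, epsrel=1e-12, limit=200)
    return np.log(val)


class TestLogPmf:
    def test_bernoulli_case_reduces_to_mu(self):
        # n = 1: the beta mixing integrates out exactly
        for sigma in (0.01, 0.5, 3.0):
            assert bb_logpmf(1, 1, BBParams(0.3, sigma)) == pytest.approx(
                np.log(0.3), abs=1e-9)

    def test_binomial_limit(self):
        expected = np.log(binom.pmf(2, 5, 0.4))  # C(5,2) 0.4^2 0.6^3 = 0.3456
        assert bb_logpmf(2, 5, mu=0.4, sigma=1e-10) == pytest.approx(
            expected, abs=1e-4)
        assert bb_logpmf(2, 5, mu=0.4, sigma=0.0) == pytest.approx(
            expected, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        assert bb_logpmf(3, 10, mu=0.25, sigma=0.5) == pytest.approx(
            quadrature_logpmf(3, 10, 0.25, 0.5), abs=1e-8)

    @pytest.mark.parametrize("mu", [0.05, 0.5, 0.95])
    @pytest.mark.parametrize("sigma", [0.01, 0.5, 2.0])
    def test_pmf_normalizes(self, mu, sigma):
        for n in (1, 7, 50):
            total = np.exp(bb_logpmf(np.arange(n + 1), n,
                                     mu=mu, sigma=sigma)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("mu,sigma,n", [
        (0.05, 0.01, 20), (0.5, 0.5, 30), (0.95, 2.0, 15), (0.3, 0.1, 50)])
    def test_moments_match_closed_form(self, mu, sigma, n):
        k = np.arange(n + 1)
        pmf = np.exp(bb_logpmf(k, n, mu=mu, sigma=sigma))
        mean, var = bb_mean_var(n, BBParams(mu, sigma))
        assert (k * pmf).sum() == pytest.approx(mean, abs=1e-8)
        assert ((k - mean) ** 2 * pmf).sum() == pytest.approx(var, abs=1e-8)

    def test_variance_collapses_to_binomial_as_sigma_vanishes(self):
        n, mu = 30, 0.3
        _, var = bb_mean_var(n, BBParams(mu, 1e-12))
        assert var == pytest.approx(n * mu * (1 - mu), rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bb_logpmf(6, 5, mu=0.4, sigma=0.1)
        with pytest.raises(ValueError):
            bb_logpmf(-1, 5, mu=0.4, sigma=0.1)
        with pytest.raises(ValueError):
            BBParams(1.2, 0.5)
        with pytest.raises(ValueError):
            BBParams(0.5, -0.1)


class TestDesign:
    @pytest.mark.parametrize("mu_terms,sigma_terms,cols_mu,cols_sigma", [
        ("additive", "additive", 20, 20),
        ("additive", "linear", 20, 14),
        ("additive", "constant", 20, 1),
        ("linear", "linear", 14, 14),
        ("constant", "constant", 1, 1),
    ])
    def test_column_counts(self, mu_terms, sigma_terms, cols_mu, cols_sigma):
        data = make_constant_acoustic(n_rows=60, seed=1)
        # ensure all 12 months appear so the factor has 11 contrasts
        data.loc[:11, "month"] = np.arange(1, 13)
        X_mu, X_sigma, _ = build_design(
            data, ModelStructure("beta_binomial", mu_terms, sigma_terms))
        assert X_mu.shape[1] == cols_mu
        assert X_sigma.shape[1] == cols_sigma

    def test_binomial_has_no_sigma_design(self):
        data = make_constant_acoustic(n_rows=40, seed=2)
        data.loc[:11, "month"] = np.arange(1, 13)
        X_mu, X_sigma, _ = build_design(
            data, ModelStructure("binomial", "additive", "none"))
        assert X_mu.shape[1] == 20 and X_sigma is None

    def test_candidate_df_accounting(self):
        """The six candidate structures use 40/34/21/28/20/14 coefficients."""
        data = make_constant_acoustic(n_rows=80, seed=3)
        data.loc[:11, "month"] = np.arange(1, 13)
        dfs = []
        for cand in TABLE_CANDIDATES:
            X_mu, X_sigma, _ = build_design(data, cand)
            dfs.append(X_mu.shape[1]
                       + (0 if X_sigma is None else X_sigma.shape[1]))
        assert dfs == [40, 34, 21, 28, 20, 14]

    def test_too_few_distinct_values_names_covariate(self):
        data = make_constant_acoustic(n_rows=40, seed=4)
        data["lat"] = 30.0
        with pytest.raises(ValueError, match="lat"):
            build_design(data, ModelStructure())

    def test_structure_validation(self):
        with pytest.raises(ValueError):
            ModelStructure("binomial", "additive", "additive")
        with pytest.raises(ValueError):
            ModelStructure(spline_df=2)


class TestAicc:
    def test_closed_forms(self):
        assert aicc(-100, 5, 30) == pytest.approx(212.5)
        assert aicc(0, 1, 10) == pytest.approx(2.5)

    def test_reduces_to_aic_for_huge_samples(self):
        assert aicc(-100, 5, 10 ** 9) == pytest.approx(210.0, abs=1e-6)

    def test_undefined_below_minimum_sample(self):
        with pytest.raises(ValueError):
            aicc(-100, 5, 6)


class TestFit:
    def test_intercept_only_recovers_truth(self):
        """90%-style check: estimates near truth across several seeds."""
        mu_t, sig_t = 0.2, 0.3
        hits_mu = hits_sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            data = make_constant_acoustic(mu_t, sig_t, n_rows=100, seed=seed)
            res = fit_occurrence_model(
                data, ModelStructure("beta_binomial", "constant", "constant"),
                FitControl(seed=seed))
            assert res.converged
            mu_hat = 1 / (1 + np.exp(-res.beta_mu[0]))
            sig_hat = np.exp(res.beta_sigma[0])
            hits_mu += abs(mu_hat - mu_t) < 0.03
            hits_sig += abs(sig_hat - sig_t) < 0.15
        assert hits_mu >= 8 and hits_sig >= 8

    def test_all_zero_counts_flagged_not_raised(self):
        data = make_constant_acoustic(n_rows=50, seed=5)
        data["k_hours"] = 0
        with pytest.warns(UserWarning, match="boundary"):
            res = fit_occurrence_model(
                data, ModelStructure("beta_binomial", "constant", "constant"))
        assert not res.converged

    def test_monotone_truth_recovered(self):
        rng = np.random.default_rng(6)
        n_rows, n = 150, 720
        lon = rng.uniform(150, 250, n_rows)
        mu = 1 / (1 + np.exp(-(-2.0 + 0.02 * (lon - 200))))
        p = rng.beta(mu / 0.3, (1 - mu) / 0.3)
        data = pd.DataFrame({
            "station_id": [f"s{i}" for i in range(n_rows)],
            "lon_east": lon, "lat": rng.uniform(22, 60, n_rows),
            "month": rng.integers(1, 13, n_rows), "n_hours": n,
            "k_hours": rng.binomial(n, p), "call_type": "east"})
        res = fit_occurrence_model(data)
        assert res.converged
        assert res.predict_mu(240.0, 40.0, 6) > res.predict_mu(150.0, 40.0, 6)

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError):
            BetaBinomialGAM(pd.DataFrame(columns=["k_hours", "n_hours"]))
        data = make_constant_acoustic(n_rows=30, seed=7)
        mixed = pd.concat([data, data.assign(call_type="west")])
        with pytest.raises(ValueError, match="call type"):
            BetaBinomialGAM(mixed)
        bad = data.copy()
        bad.loc[0, "k_hours"] = bad.loc[0, "n_hours"] + 1
        with pytest.raises(ValueError):
            BetaBinomialGAM(bad)

    def test_loglik_nesting_property(self):
        """Richer structures cannot fit worse at the maximum likelihood."""
        data = make_constant_acoustic(0.25, 0.4, n_rows=90, seed=8)
        data.loc[:11, "month"] = np.arange(1, 13)
        ll = {}
        for cand in TABLE_CANDIDATES:
            ll[(cand.family, cand.mu_terms, cand.sigma_terms)] = \
                fit_occurrence_model(data, cand, FitControl(seed=1)).loglik
        bb = "beta_binomial"
        assert ll[(bb, "additive", "additive")] >= \
            ll[(bb, "additive", "linear")] - 1e-6
        assert ll[(bb, "additive", "linear")] >= \
            ll[(bb, "additive", "constant")] - 1e-6
        assert ll[(bb, "additive", "linear")] >= \
            ll[(bb, "linear", "linear")] - 1e-6
        assert ll[("binomial", "additive", "none")] >= \
            ll[("binomial", "linear", "none")] - 1e-6


class TestPredict:
    def test_intercept_zero_gives_half(self):
        data = make_constant_acoustic(n_rows=40, seed=9)
        res = fit_occurrence_model(
            data, ModelStructure("beta_binomial", "constant", "constant"))
        res.beta_mu = np.zeros_like(res.beta_mu)
        assert res.predict_mu(200.0, 40.0, 6) == pytest.approx(0.5)

    def test_prediction_matches_fitted_values(self, small_world,
                                              light_structure, base_fits):
        fe, _ = base_fits
        east = small_world["east"]
        pred = fe.predict_mu(east["lon_east"].to_numpy(),
                             east["lat"].to_numpy(),
                             east["month"].to_numpy())
        assert np.allclose(pred, fe.fittedvalues, atol=1e-12)

    def test_month_out_of_range_rejected(self, base_fits):
        with pytest.raises(ValueError):
            base_fits[0].predict_mu(200.0, 40.0, 13)

    def test_extrapolation_flagged(self, base_fits):
        _, flag = base_fits[0].predict_mu(100.0, 40.0, 6,
                                          return_extrapolation=True)
        assert flag
        _, flag = base_fits[0].predict_mu(200.0, 40.0, 6,
                                          return_extrapolation=True)
        assert not flag

    def test_json_round_trip(self, base_fits, tmp_path):
        fe, _ = base_fits
        path = tmp_path / "fit.json"
        fe.to_json(path)
        back = BetaBinomialGAMResults.from_json(path)
        grid = [(150.0, 30.0, 2), (200.0, 45.0, 7), (255.0, 58.0, 11)]
        for lon, lat, m in grid:
            assert back.predict_mu(lon, lat, m) == pytest.approx(
                fe.predict_mu(lon, lat, m), abs=1e-12)
        assert back.aicc == pytest.approx(fe.aicc)


class TestSelection:
    def test_single_candidate_has_zero_delta(self):
        data = make_constant_acoustic(n_rows=60, seed=10)
        table = select_model(
            data, [ModelStructure("beta_binomial", "constant", "constant")])
        assert table["delta_aicc"].tolist() == [0.0]

    def test_binomial_data_shows_no_large_gap(self):
        """With sigma = 0 the over-dispersion terms buy nothing beyond the
        parameter penalty."""
        data = make_constant_acoustic(0.2, 0.0, n_rows=120, seed=11)
        cands = [ModelStructure("binomial", "linear", "none"),
                 ModelStructure("beta_binomial", "linear", "constant")]
        table = select_model(data, cands, FitControl(seed=2))
        gap = abs(table["aicc"].iloc[0] - table["aicc"].iloc[1])
        assert gap < 2 * 2 + 1  # about one parameter's AICc penalty


class TestBootstrap:
    def test_unique_row_fraction(self):
        """With-replacement resampling keeps ~63.2% unique rows on average."""
        rng_rows = 100
        fractions = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, rng_rows, rng_rows)
            fractions.append(np.unique(idx).size / rng_rows)
        assert np.mean(fractions) == pytest.approx(1 - np.exp(-1), abs=0.01)

    def test_refit_resamples_and_flags(self, small_world, light_structure):
        res = bootstrap_refit(small_world["east"], light_structure, 3)
        assert isinstance(res.converged, bool)

    def test_single_row_table_flagged_degenerate(self, light_structure):
        data = make_constant_acoustic(n_rows=1, seed=12)
        res = bootstrap_refit(data, light_structure, 0)
        assert not res.converged
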