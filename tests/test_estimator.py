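"""Panel estimator: oracle equivalences (LSDV, HC1, pooled OLS), exact
identities, diagnostics behaviour and income clustering."""

import numpy as np
import pandas as pd
import pytest

from cigtaxsim import (PanelDGPParams, assign_income_clusters, estimate_by_group,
                       fit_fe_2sls, fit_re_gls, generate_panel, hausman_test,
                       weak_id_F, within_transform)
from cigtaxsim.estimator import (RankError, _cluster_meat, _cr1_factor,
                                 _fe_ols_conventional, _prepare)


# ---------------------------------------------------------------------------
# income clustering

class TestIncomeClusters:
    def test_thresholds_and_boundaries(self):
        gni = {"A": 500, "B": 999.99, "C": 1000, "D": 2500, "E": 3500,
               "F": 4000, "G": 5999, "H": 6000, "I": 9000}
        by_group = {c.group_id: c.members for c in assign_income_clusters(gni)}
        assert set(by_group[1]) == {"A", "B"}
        assert set(by_group[2]) == {"C"}
        assert set(by_group[3]) == {"D"}
        assert set(by_group[4]) == {"E"}
        assert set(by_group[5]) == {"F", "G"}
        assert set(by_group[6]) == {"H", "I"}

    def test_partition_is_exhaustive_and_disjoint(self):
        gni = {f"C{i}": g for i, g in enumerate(np.geomspace(100, 50000, 40))}
        clusters = assign_income_clusters(gni)
        members = [c for cl in clusters for c in cl.members]
        assert sorted(members) == sorted(gni)

    def test_missing_gni_names_country(self):
        with pytest.raises(ValueError, match="Bhutan"):
            assign_income_clusters({"A": 500, "Bhutan": float("nan")})


# ---------------------------------------------------------------------------
# within transform

class TestWithinTransform:
    def test_two_observations(self):
        df = pd.DataFrame({"country": ["A", "A"], "v": [3.0, 5.0]})
        out = within_transform(df, ["v"])
        assert list(out["v"]) == [-1.0, 1.0]

    def test_constant_variable_becomes_zero(self):
        df = pd.DataFrame({"country": ["A"] * 4, "v": [7.0] * 4})
        assert within_transform(df, ["v"])["v"].abs().max() == 0.0

    def test_country_means_are_zero(self, tiny_panel):
        df = tiny_panel.assign(lp=np.log(tiny_panel.price))
        out = within_transform(df, ["lp", "fctc"])
        assert out.groupby("country")[["lp", "fctc"]].mean().abs().max().max() < 1e-10

    def test_demeaned_fctc_no_longer_binary(self, tiny_panel):
        out = within_transform(tiny_panel.astype({"fctc": float}), ["fctc"])
        assert not out["fctc"].isin([0.0, 1.0]).all()

    def test_single_observation_country_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"country": ["A", "A", "B"], "v": [1.0, 2.0, 3.0]})
        with caplog.at_level("WARNING"):
            out = within_transform(df, ["v"])
        assert set(out["country"]) == {"A"}
        assert "B" in caplog.text


# ---------------------------------------------------------------------------
# fixed-effects 2SLS

class TestFE2SLS:
    def test_within_ols_equals_lsdv_oracle(self, tiny_panel):
        """Within-FE slopes must equal least-squares-dummy-variable slopes."""
        import statsmodels.api as sm
        fit = fit_fe_2sls(tiny_panel, iv=False, compute_diagnostics=False)
        df = tiny_panel
        X = pd.concat([
            pd.DataFrame({"ln_price": np.log(df.price), "ln_gni": np.log(df.gni),
                          "fctc": df.fctc.astype(float)}),
            pd.get_dummies(df.country, dtype=float),
        ], axis=1)
        ols = sm.OLS(np.log(df.consumption), X).fit()
        assert np.allclose(fit.slopes, ols.params[:3], atol=1e-8)
        for c in ("A", "B", "C"):
            assert abs(fit.intercepts[c] - ols.params[c]) < 1e-8

    def test_2sls_with_instrument_equal_regressor_is_ols(self, default_panel):
        a = fit_fe_2sls(default_panel, iv=True, instruments=("ln_price",),
                        compute_diagnostics=False)
        b = fit_fe_2sls(default_panel, iv=False, compute_diagnostics=False)
        assert np.abs(a.slopes - b.slopes).max() < 1e-10

    def test_noise_free_panel_identified_exactly(self, noise_free_panel):
        fit = fit_fe_2sls(noise_free_panel, compute_diagnostics=False)
        assert np.allclose(fit.slopes, [-1.304, 0.769, -0.103], atol=1e-8)

    def test_elasticity_invariant_to_price_rescaling(self, default_panel):
        a = fit_fe_2sls(default_panel, compute_diagnostics=False)
        scaled = default_panel.assign(price=default_panel.price * 1000.0)
        b = fit_fe_2sls(scaled, compute_diagnostics=False)
        assert abs(a.beta_price - b.beta_price) < 1e-10
        assert abs(a.se[0] - b.se[0]) < 1e-10

    def test_vcov_symmetric_psd_and_se_consistent(self, default_panel):
        fit = fit_fe_2sls(default_panel, compute_diagnostics=False)
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert (np.linalg.eigvalsh(fit.vcov) > -1e-12).all()
        assert np.allclose(fit.se, np.sqrt(np.diag(fit.vcov)))
        assert fit.n_obs == 22 * 16  # one year lost to the lag

    def test_singleton_clusters_reduce_to_hc1(self, default_panel):
        """With each observation its own cluster the CR1 sandwich equals the
        HC1 heteroskedasticity-robust covariance (statsmodels oracle)."""
        import statsmodels.api as sm
        df = _prepare(default_panel, require_lags=False)
        y = (df.ln_c - df.groupby("country").ln_c.transform("mean")).to_numpy()
        X = (df[["ln_price", "ln_gni", "fctc"]]
             - df.groupby("country")[["ln_price", "ln_gni", "fctc"]].transform("mean")).to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        N, k = X.shape
        bread = np.linalg.inv(X.T @ X)
        ours = _cr1_factor(N, N, k) * bread @ _cluster_meat(X, resid, np.arange(N)) @ bread
        hc1 = sm.OLS(y, X).fit(cov_type="HC1").cov_params()
        assert np.abs(ours - np.asarray(hc1)).max() < 1e-8

    def test_bias_shrinks_with_noise(self):
        def mean_abs_bias(sd):
            errs = [abs(fit_fe_2sls(generate_panel(PanelDGPParams(seed=s, error_sd=sd)),
                                    compute_diagnostics=False).beta_price + 1.304)
                    for s in range(15)]
            return np.mean(errs)
        assert mean_abs_bias(0.01) < mean_abs_bias(0.3)

    def test_rank_error_on_collinear_design(self, default_panel):
        flat = default_panel.assign(price=2.0)
        with pytest.raises(RankError, match="ln_price"):
            fit_fe_2sls(flat, compute_diagnostics=False)

    def test_requires_two_countries(self, default_panel):
        one = default_panel[default_panel.country == "C01"]
        with pytest.raises(ValueError, match="2 countries"):
            fit_fe_2sls(one, compute_diagnostics=False)

    def test_non_positive_values_rejected(self, tiny_panel):
        bad = tiny_panel.copy()
        bad.loc[0, "consumption"] = 0.0
        with pytest.raises(ValueError, match="consumption"):
            fit_fe_2sls(bad, compute_diagnostics=False)


# ---------------------------------------------------------------------------
# random effects and Hausman

class TestRandomEffects:
    def test_shared_intercept_no_noise_equals_pooled_and_fe(self):
        panel = generate_panel(PanelDGPParams(seed=7, alpha_sd=0.0, error_sd=0.0))
        re = fit_re_gls(panel)
        fe = fit_fe_2sls(panel, iv=False, compute_diagnostics=False)
        df = _prepare(panel, require_lags=False)
        Xp = np.column_stack([df.ln_price, df.ln_gni, df.fctc, np.ones(len(df))])
        pooled = np.linalg.lstsq(Xp, df.ln_c.to_numpy(), rcond=None)[0]
        assert np.abs(re["beta"][:3] - fe.slopes).max() < 1e-8
        assert np.abs(re["beta"][:3] - pooled[:3]).max() < 1e-8

    def test_large_between_variance_drives_theta_to_one(self):
        panel = generate_panel(PanelDGPParams(seed=5, alpha_sd=5.0, error_sd=0.1))
        re = fit_re_gls(panel)
        fe = fit_fe_2sls(panel, iv=False, compute_diagnostics=False)
        assert re["theta"].mean() > 0.95
        assert np.abs(re["beta"][:3] - fe.slopes).max() < 0.02

    def test_deterministic(self):
        panel = generate_panel(PanelDGPParams(seed=13))
        a, b = fit_re_gls(panel), fit_re_gls(panel)
        assert np.array_equal(a["beta"], b["beta"])

    def test_negative_variance_component_truncated(self, caplog):
        # within variance dominates: intercepts identical, heavy noise
        panel = generate_panel(PanelDGPParams(seed=2, alpha_sd=0.0, error_sd=1.0,
                                              error_cluster_rho=0.0, n_countries=30))
        with caplog.at_level("WARNING"):
            re = fit_re_gls(panel)
        assert re["s2_u"] >= 0.0


class TestHausman:
    def test_identical_fits_give_zero_statistic(self):
        b = np.array([1.0, 2.0, 3.0])
        v1 = np.diag([2.0, 2.0, 2.0])
        v2 = np.diag([1.0, 1.0, 1.0])
        res = hausman_test(b, v1, b, v2)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 3

    def test_indefinite_difference_flagged_not_hidden(self):
        b1, b2 = np.array([1.0, 2.0]), np.array([1.1, 2.1])
        res = hausman_test(b1, np.diag([1.0, 1.0]), b2, np.diag([2.0, 0.5]))
        assert res.indefinite
        assert np.isfinite(res.statistic) and res.statistic >= 0

    def test_detects_intercepts_correlated_with_price(self):
        """Rejection is frequent under the endogenous-intercept alternative
        and rare under the exogenous null (small-replicate smoke version of
        the full size/power study)."""
        def reject_rate(corr, n, sd):
            rej = 0
            for s in range(n):
                p = generate_panel(PanelDGPParams(seed=1000 + s, error_sd=sd,
                                                  alpha_price_corr=corr))
                rej += fit_fe_2sls(p, iv=False).hausman_p < 0.05
            return rej / n
        assert reject_rate(0.8, 25, 0.15) > 0.6
        assert reject_rate(0.0, 25, 0.15) < 0.3


# ---------------------------------------------------------------------------
# weak identification

class TestWeakID:
    def test_irrelevant_instruments_give_small_F(self):
        """With serially uncorrelated prices the lagged instruments carry no
        information about current price and F falls below 10."""
        small = 0
        for s in range(10):
            p = generate_panel(PanelDGPParams(seed=500 + s, price_rho=0.0))
            small += weak_id_F(p) < 10
        assert small >= 8

    def test_persistent_prices_give_large_F(self):
        for s in range(5):
            p = generate_panel(PanelDGPParams(seed=600 + s, price_rho=0.9))
            assert weak_id_F(p) > 10

    def test_perfect_instrument_capped(self, default_panel):
        assert weak_id_F(default_panel, instruments=("ln_price",)) == 1e6


# ---------------------------------------------------------------------------
# per-group driver

def test_estimate_by_group_runs_on_full_panel(default_panel):
    import time
    t0 = time.time()
    fits = estimate_by_group(default_panel)
    assert time.time() - t0 < 5.0
    assert sum(f.n_countries for f in fits) <= 22
    for f in fits:
        assert f.n_countries >= 2
        assert np.isfinite(f.beta_price)
        assert f.hausman_df == 3
        d = f.to_dict()
        assert set(d["countries"]) == set(f.countries)
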