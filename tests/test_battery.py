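"""The moderated regression battery and its summary decompositions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import salnet
from salnet.battery import (
    COVARIATE_SETS,
    MODEL_TERMS,
    fit_battery_model,
    impute_metrics_time1,
    run_battery,
    standardize,
    stratified_correlation,
    two_group_f,
)
from salnet.synthetic import PhenotypeSettings


def _scaled_table(n=200, seed=0):
    """A table whose continuous columns are already sample-standardized."""
    rng = np.random.default_rng(seed)
    z = lambda x: (x - x.mean()) / x.std(ddof=1)  # noqa: E731
    cols = {
        "sex": (rng.random(n) < 0.6).astype(int),
        "violence": z(rng.normal(size=n)),
        "expansion": z(rng.normal(size=n)),
        "connectivity": z(rng.normal(size=n)),
        "depression": z(rng.normal(size=n)),
        "age": z(rng.normal(size=n)),
        "black": (rng.random(n) < 0.4).astype(int),
        "white": (rng.random(n) < 0.4).astype(int),
        "hispanic": (rng.random(n) < 0.3).astype(int),
        "bmi_pct": z(rng.normal(size=n)),
        "puberty": z(rng.normal(size=n)),
        "ipr": z(rng.normal(size=n)),
        "depression_t1": z(rng.normal(size=n)),
        "expansion_t1": z(rng.normal(size=n)),
        "connectivity_t1": z(rng.normal(size=n)),
        "violence_t1": z(rng.normal(size=n)),
    }
    return pd.DataFrame(cols)


class TestStandardize:
    def test_non_indicators_zero_mean_unit_variance(self):
        table = salnet.simulate_phenotypes(150, seed=1)
        out = standardize(table)
        for col in ("violence", "depression", "age", "ipr"):
            assert abs(out[col].mean()) < 1e-12
            assert out[col].var(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_indicators_untouched(self):
        table = salnet.simulate_phenotypes(150, seed=2)
        out = standardize(table)
        for col in ("sex", "black", "white", "hispanic"):
            pd.testing.assert_series_equal(out[col], table[col])

    def test_idempotent_on_scaled_columns(self):
        table = _scaled_table()
        once = standardize(table)
        twice = standardize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_variance_column_named_in_error(self):
        table = salnet.simulate_phenotypes(50, seed=3)
        table["ipr"] = 1.0
        with pytest.raises(ValueError, match="ipr"):
            standardize(table)


class TestFitBatteryModel:
    @pytest.mark.parametrize("k", list(MODEL_TERMS))
    def test_noiseless_tables_interpolated_exactly(self, k):
        """Each model's coefficients are recovered to 1e-10 when the outcome
        is built exactly from that model's regressors."""
        table = _scaled_table(seed=10 + k)
        outcome, terms = MODEL_TERMS[k]
        truth = {"const": 0.3}
        rng = np.random.default_rng(k)
        cols = [np.ones(len(table))]
        for i, t in enumerate(terms):
            truth[t] = 0.5 + 0.1 * i
            if ":" in t:
                a, b = t.split(":")
                cols.append(table[a] * table[b])
            else:
                cols.append(table[t])
        table[outcome] = sum(w * c for w, c in zip(truth.values(), cols))
        fit = fit_battery_model(k, table, covariate_set="none", standardized=False)
        for term, value in truth.items():
            assert fit.params[term] == pytest.approx(value, abs=1e-10)

    def test_model2_df_at_cohort_size(self):
        table = salnet.simulate_phenotypes(220, seed=5)
        fit = fit_battery_model(2, table)
        assert fit.df_resid == 220 - 4
        assert fit.n_obs == 220

    @pytest.mark.parametrize("k", list(MODEL_TERMS))
    @pytest.mark.parametrize("cs", COVARIATE_SETS)
    def test_df_bookkeeping_exact(self, k, cs):
        table = salnet.simulate_phenotypes(150, seed=6)
        fit = fit_battery_model(k, table, covariate_set=cs)
        assert fit.df_resid == fit.n_obs - len(fit.params)

    def test_scaling_equivariance(self):
        """Standardized estimates are invariant to affine rescaling of raw
        non-indicator inputs."""
        table = salnet.simulate_phenotypes(180, seed=7)
        rescaled = table.copy()
        rescaled["violence"] = rescaled["violence"] * 7.0 + 3.0
        rescaled["depression"] = rescaled["depression"] / 5.0 - 11.0
        a = fit_battery_model(2, table)
        b = fit_battery_model(2, rescaled)
        pd.testing.assert_series_equal(a.params, b.params, atol=1e-10, rtol=0)

    def test_interaction_recovery_monte_carlo(self):
        """Mean OLS estimate of the sex-by-violence interaction over
        replicates at the cohort size matches the generating value within 3
        Monte-Carlo SEs (oracle: direct normal-equations solve)."""
        reps, n, truth = 300, 220, 0.337
        est, oracle_est = [], []
        for r in range(reps):
            table = salnet.simulate_phenotypes(n, seed=10_000 + r)
            fit = fit_battery_model(2, table)
            est.append(fit.params["sex:violence"])
            # independent oracle: explicit normal equations on the same
            # standardized columns
            std = standardize(table[["sex", "violence", "depression"]])
            X = np.column_stack([
                np.ones(n), std["sex"], std["violence"], std["sex"] * std["violence"],
            ])
            y = std["depression"].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            oracle_est.append(beta[3])
        est, oracle_est = np.array(est), np.array(oracle_est)
        np.testing.assert_allclose(est, oracle_est, atol=1e-10)
        se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - truth) < 3 * se

    def test_rank_deficiency_reported(self):
        table = _scaled_table()
        table["violence"] = table["sex"].astype(float)
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_battery_model(2, table)

    def test_missing_column_reported(self):
        table = _scaled_table().drop(columns=["connectivity"])
        with pytest.raises(ValueError, match="connectivity"):
            fit_battery_model(6, table)


class TestStratifiedCorrelation:
    def test_t_from_r_identity_at_cohort_sizes(self):
        """r = 0.264 in a 141-subject stratum gives t = 3.227 on 139 df."""
        rng = np.random.default_rng(8)
        # construct a female stratum with exactly the target correlation
        n = 141
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # residualize e on x
        r_target = 0.264
        y = r_target * (x - x.mean()) / x.std() + np.sqrt(1 - r_target**2) * (
            e - e.mean()
        ) / e.std()
        table = pd.DataFrame({"sex": 1, "violence": x, "depression": y})
        r, t, df, p = stratified_correlation(table, "violence", "depression", 1)
        assert r == pytest.approx(0.264, abs=1e-12)
        assert t == pytest.approx(3.227, abs=1e-3)
        assert df == 139
        assert p == pytest.approx(0.0016, abs=2e-4)

    def test_perfect_linearity(self):
        x = np.linspace(0, 1, 30)
        table = pd.DataFrame({"sex": 0, "violence": x, "depression": 2 * x})
        r, t, df, p = stratified_correlation(table, "violence", "depression", 0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_t_p_value_agrees_with_permutation_null(self):
        """On a 12-point sample the parametric p matches a permutation
        Monte-Carlo p within simulation error."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(size=12)
        table = pd.DataFrame({"sex": 1, "violence": x, "depression": y})
        r, t, df, p = stratified_correlation(table, "violence", "depression", 1)
        n_perm = 20_000
        perm_r = np.empty(n_perm)
        for i in range(n_perm):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (np.sum(np.abs(perm_r) >= abs(r)) + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < max(4 * se, 0.02)

    def test_small_stratum_rejected(self):
        table = pd.DataFrame({"sex": [1, 1], "violence": [0, 1], "depression": [1, 2]})
        with pytest.raises(ValueError):
            stratified_correlation(table, "violence", "depression", 1)


class TestTwoGroupF:
    def test_cohort_summary_example(self):
        """Group summaries (141, 1.16, 2.37) vs (79, 2.95, 5.05) give
        F(1, 218) near 12.7."""
        F, df1, df2 = two_group_f(141, 1.16, 2.37, 79, 2.95, 5.05)
        assert (df1, df2) == (1, 218)
        assert F == pytest.approx(12.74, abs=0.01)

    def test_equal_means_give_zero(self):
        F, _, _ = two_group_f(10, 1.0, 1.0, 12, 1.0, 2.0)
        assert F == 0.0

    def test_f_equals_square_of_pooled_t(self):
        """Algebraic identity against a direct pooled-variance t statistic."""
        n1, m1, s1, n2, m2, s2 = 25, 3.0, 1.5, 30, 4.2, 2.0
        F, _, df2 = two_group_f(n1, m1, s1, n2, m2, s2)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df2
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert F == pytest.approx(t**2, rel=1e-12)

    def test_zero_pooled_variance_unequal_means_is_infinite(self):
        F, _, _ = two_group_f(5, 1.0, 0.0, 5, 2.0, 0.0)
        assert np.isinf(F)


class TestImputation:
    def test_no_missing_returns_values_unchanged(self):
        table = salnet.simulate_phenotypes(100, seed=11)
        out = impute_metrics_time1(table)
        for col in ("expansion_t1", "connectivity_t1"):
            pd.testing.assert_series_equal(out[col], table[col])

    def test_exact_linear_function_recovered(self):
        """A time-1 metric that is an exact linear function of time-1
        covariates is imputed back exactly after 20% deletion."""
        rng = np.random.default_rng(12)
        table = salnet.simulate_phenotypes(200, seed=12)
        table["expansion_t1"] = (
            0.02 + 0.005 * table["sex"] + 0.001 * table["ipr"]
            + 0.003 * table["depression_t1"]
        )
        truth = table["expansion_t1"].copy()
        drop = rng.choice(200, size=40, replace=False)
        table.loc[drop, "expansion_t1"] = np.nan
        out = impute_metrics_time1(table)
        np.testing.assert_allclose(out["expansion_t1"], truth, atol=1e-8)
        assert out["expansion_t1_imputed"].sum() == 40

    def test_time2_columns_never_used(self):
        """Perturbing a time-2 column leaves imputed values unchanged."""
        table = salnet.simulate_phenotypes(200, seed=13,
                                           settings=PhenotypeSettings(missing_t1_fraction=0.15))
        a = impute_metrics_time1(table)
        perturbed = table.copy()
        perturbed["depression"] += 100.0
        perturbed["age"] *= -3.0
        perturbed["expansion"] = 0.5
        b = impute_metrics_time1(perturbed)
        np.testing.assert_allclose(a["expansion_t1"], b["expansion_t1"])
        np.testing.assert_allclose(a["connectivity_t1"], b["connectivity_t1"])

    def test_too_few_complete_cases_rejected(self):
        table = salnet.simulate_phenotypes(20, seed=14)
        table.loc[5:, "expansion_t1"] = np.nan
        with pytest.raises(ValueError):
            impute_metrics_time1(table)


class TestRunBattery:
    def test_report_contains_32_fits(self):
        table = salnet.simulate_phenotypes(220, seed=15)
        report = run_battery(table)
        assert len(report.fits) == 32
        combos = {(f.model_index, f.covariate_set) for f in report.fits}
        assert len(combos) == 32

    def test_raw_group_means_reported(self):
        table = salnet.simulate_phenotypes(20_000, seed=16)
        report = run_battery(table)
        assert report.group_means["female"] == pytest.approx(1.16, abs=0.1)
        assert report.group_means["male"] == pytest.approx(2.95, abs=0.25)

    def test_type_i_error_calibrated_under_null(self):
        """With a zero generating interaction, the interaction test rejects
        at close to its nominal 5% level (binomial error bound)."""
        coeffs = salnet.default_phenotype_coeffs()
        coeffs[2]["b3"] = 0.0
        settings = PhenotypeSettings(coeffs=coeffs)
        reps, n = 1000, 220
        hits = 0
        for r in range(reps):
            table = salnet.simulate_phenotypes(n, settings, seed=40_000 + r)
            fit = fit_battery_model(2, table)
            hits += fit.pvalues["sex:violence"] < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se

    def test_summary_mentions_focal_interaction(self):
        table = salnet.simulate_phenotypes(220, seed=17)
        text = run_battery(table).summary()
        assert "beta3(2)" in text
        assert "32 model fits" in text

    def test_imputation_applied_before_fitting(self):
        settings = PhenotypeSettings(missing_t1_fraction=0.1)
        table = salnet.simulate_phenotypes(220, settings, seed=18)
        report = run_battery(table)
        assert report.n_subjects == 220
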