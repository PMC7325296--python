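"""Wagstaff decomposition: adding-up identity, audits, recovery."""

import numpy as np
import pandas as pd
import pytest

from tehb import (covariate_concentration_indices, decompose,
                  expand_covariates, fit_outcome_model, fractional_rank,
                  table3_check)
from tehb.decompose import significance_stars


def equally_spaced_ranks(n: int) -> np.ndarray:
    return np.arange(1, n + 1) / n


class TestCovariateIndices:
    def test_indicator_held_by_top_half(self):
        n = 10_000
        r = equally_spaced_ranks(n)
        df = pd.DataFrame({"x": (r > 0.5).astype(float)})
        c = covariate_concentration_indices(df, ["x"], r)["x"]
        assert c == pytest.approx(0.5, abs=1e-3)

    def test_rank_against_itself(self):
        n = 10_000
        r = equally_spaced_ranks(n)
        df = pd.DataFrame({"x": r})
        c = covariate_concentration_indices(df, ["x"], r)["x"]
        assert c == pytest.approx(1 / 3, abs=1e-3)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(8)
        n = 20_000
        df = pd.DataFrame({"x": rng.normal(5.0, 1.0, n)})
        c = covariate_concentration_indices(
            df, ["x"], equally_spaced_ranks(n))["x"]
        assert abs(c) < 0.02

    def test_zero_mean_covariate_flagged(self, caplog):
        df = pd.DataFrame({"x": [-1.0, 1.0, -1.0, 1.0]})
        with caplog.at_level("WARNING"):
            c = covariate_concentration_indices(
                df, ["x"], equally_spaced_ranks(4))["x"]
        assert np.isnan(c)
        assert "zero mean" in caplog.text


class TestOutcomeModel:
    def test_noise_free_linear_outcome_has_zero_residuals(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=200),
                           "x2": rng.integers(0, 2, 200).astype(float)})
        df["tehb"] = 2.0 + 1.5 * df["x1"] - 0.5 * df["x2"]
        fit = fit_outcome_model(df, ["x1", "x2"])
        assert np.max(np.abs(df["tehb"] - fit.fittedvalues)) < 1e-10

    def test_rank_deficient_design_lists_collinear_columns(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=50)})
        df["x2"] = 2.0 * df["x1"] + 1.0
        df["tehb"] = df["x1"]
        with pytest.raises(ValueError, match=r"x2"):
            fit_outcome_model(df, ["x1", "x2"])

    def test_elasticities_recover_truth_on_known_linear_model(self):
        rng = np.random.default_rng(12)
        n = 50_000
        w = rng.normal(size=n)
        df = pd.DataFrame({
            "x1": rng.normal(2.0, 1.0, n) + 0.5 * w,
            "x2": (rng.random(n) < 0.3 + 0.1 * (w > 0)).astype(float),
        })
        df["tehb"] = 6.0 + 1.5 * df["x1"] - 2.0 * df["x2"] + rng.normal(0, 1, n)
        rank = fractional_rank(w)
        table = decompose(df, ["x1", "x2"], rank)
        mu = df["tehb"].mean()
        truth = {"x1": 1.5 * df["x1"].mean() / mu,
                 "x2": -2.0 * df["x2"].mean() / mu}
        for row in table.rows:
            rel_err = abs(row.elasticity - truth[row.variable]) / abs(
                truth[row.variable])
            assert rel_err < 0.05, row.variable


class TestDecomposition:
    def test_self_decomposition(self):
        rng = np.random.default_rng(5)
        y = rng.exponential(3.0, 300)
        df = pd.DataFrame({"x": y, "tehb": y})
        rank = fractional_rank(rng.normal(size=300))
        table = decompose(df, ["x"], rank)
        row = table.rows[0]
        assert row.beta == pytest.approx(1.0, abs=1e-10)
        assert row.elasticity == pytest.approx(1.0, abs=1e-10)
        assert row.abs_contribution == pytest.approx(table.total_c, abs=1e-10)
        assert table.residual == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_covariate_with_zero_beta_contributes_nothing(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(size=400)
        x2 = rng.normal(size=400)
        # orthogonalize x2 against [1, x1] so its OLS beta is exactly 0
        X = np.column_stack([np.ones(400), x1])
        x2 = x2 - X @ np.linalg.lstsq(X, x2, rcond=None)[0] + 1.0
        df = pd.DataFrame({"x1": x1 + 5.0, "x2": x2, "tehb": 3.0 + 2.0 * x1})
        table = decompose(df, ["x1", "x2"], fractional_rank(rng.normal(size=400)))
        x2_row = [r for r in table.rows if r.variable == "x2"][0]
        assert abs(x2_row.beta) < 1e-10
        assert abs(x2_row.abs_contribution) < 1e-10

    def test_adding_up_identity_on_pipeline_sample(self, scored_sample):
        expanded, covariates, groups = expand_covariates(scored_sample)
        table = decompose(expanded, covariates,
                          expanded["frac_rank"].to_numpy(), groups=groups)
        gap = table.sum_contributions + table.residual - table.total_c
        assert abs(gap) < 1e-10
        assert table.sum_rel_pct + table.residual_rel_pct == pytest.approx(
            100.0, abs=1e-6)
        for row in table.rows:
            assert row.abs_contribution == pytest.approx(
                row.elasticity * row.c_k, abs=1e-12)
            assert row.rel_contribution_pct == pytest.approx(
                100 * row.abs_contribution / table.total_c, abs=1e-9)

    def test_wealth_quintile_betas_negative_and_dominant(self, scored_sample):
        expanded, covariates, groups = expand_covariates(scored_sample)
        table = decompose(expanded, covariates,
                          expanded["frac_rank"].to_numpy(), groups=groups)
        rows = {r.variable: r for r in table.rows}
        for q in ("quintile_2", "quintile_3", "quintile_4", "quintile_5"):
            assert rows[q].beta < 0, q
        # richer-quintile coefficients grow in magnitude
        assert rows["quintile_5"].beta < rows["quintile_2"].beta
        wealth_share = sum(rows[q].rel_contribution_pct
                           for q in ("quintile_2", "quintile_3",
                                     "quintile_4", "quintile_5"))
        others = [abs(r.rel_contribution_pct) for v, r in rows.items()
                  if not v.startswith("quintile_")]
        assert wealth_share > max(others)

    def test_reference_category_switch_preserves_total_and_residual(
            self, scored_sample):
        expanded, covariates, groups = expand_covariates(scored_sample)
        rank = expanded["frac_rank"].to_numpy()
        a = decompose(expanded, covariates, rank, groups=groups)
        # re-reference HDI to 'high': indicators for low and middle instead
        alt = expanded.copy()
        alt["hdi_low"] = (alt["hdi_category"] == "low").astype(int)
        cov_alt = [c if c != "hdi_high" else "hdi_low" for c in covariates]
        b = decompose(alt, cov_alt, rank, groups=groups)
        assert a.total_c == pytest.approx(b.total_c, abs=1e-12)
        assert a.residual == pytest.approx(b.residual, abs=1e-10)


class TestTable3Check:
    @pytest.mark.parametrize("elasticity, c_k, expected_abs", [
        (1.023, 0.004, 0.004),
        (0.117, 0.055, 0.006),
        (0.040, -0.193, -0.008),
    ])
    def test_absolute_contribution_cells(self, elasticity, c_k, expected_abs):
        abs_c, _ = table3_check(elasticity, c_k, -0.142)
        assert round(abs_c, 3) == expected_abs

    def test_relative_contribution_cell(self):
        _, rel = table3_check(-0.113, 0.053, -0.142)
        assert rel == pytest.approx(4.2, abs=0.11)

    def test_zero_index_covariate(self):
        assert table3_check(5.0, 0.0, -0.142) == (0.0, 0.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            table3_check(1.0, 1.0, 0.0)


def test_significance_star_thresholds():
    assert significance_stars(0.005) == "***"
    assert significance_stars(0.03) == "**"
    assert significance_stars(0.07) == "*"
    assert significance_stars(0.2) == ""
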