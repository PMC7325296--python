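"""Concentration index and curve: exact examples, equivalences, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tehb import (concentration_curve, concentration_index, fractional_rank,
                  normalized_indices, subgroup_concentration)

RANKS4 = np.array([0.25, 0.5, 0.75, 1.0])


@st.composite
def dataset(draw):
    """Non-degenerate outcome/score pairs, with ties in both."""
    n = draw(st.integers(min_value=3, max_value=40))
    y = draw(st.lists(st.integers(min_value=0, max_value=50),
                      min_size=n, max_size=n))
    scores = draw(st.lists(st.integers(min_value=0, max_value=10),
                           min_size=n, max_size=n))
    if sum(y) == 0:
        y[0] = 1
    if len(set(scores)) == 1:
        scores[0] += 1
    return np.array(y, float), np.array(scores, float)


class TestConcentrationIndex:
    def test_hand_example(self):
        res = concentration_index([1, 2, 3, 4], RANKS4)
        assert res.c_hat == pytest.approx(0.25, abs=1e-12)
        assert res.mu == 2.5

    def test_antisymmetric_under_rank_reversal(self):
        res = concentration_index([1, 2, 3, 4], RANKS4[::-1].copy())
        assert res.c_hat == pytest.approx(-0.25, abs=1e-12)

    def test_constant_outcome_has_zero_index(self):
        res = concentration_index([3.0] * 5, fractional_rank(np.arange(5)))
        assert res.c_hat == pytest.approx(0.0, abs=1e-9)
        assert res.ci_low <= 1e-9 and res.ci_high >= -1e-9

    @given(dataset())
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_regression_slope_equals_covariance_formula(self, data):
        y, scores = data
        res = concentration_index(y, fractional_rank(scores))
        assert abs(res.c_hat - res.c_cov) < 1e-10

    @given(dataset(), st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_scale_invariance(self, data, k):
        y, scores = data
        r = fractional_rank(scores)
        a = concentration_index(y, r).c_hat
        b = concentration_index(k * y, r).c_hat
        assert a == pytest.approx(b, abs=1e-9)

    @given(dataset())
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_bounded_for_nonnegative_outcomes(self, data):
        y, scores = data
        res = concentration_index(y, fractional_rank(scores))
        assert -1.0 - 1e-9 <= res.c_hat <= 1.0 + 1e-9
        assert res.ci_low <= res.c_hat <= res.ci_high

    def test_translation_shrinks_magnitude(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        base = concentration_index(y, RANKS4).c_hat
        shifted = concentration_index(y + 10.0, RANKS4).c_hat
        assert abs(shifted) < abs(base)
        assert np.sign(shifted) == np.sign(base)

    def test_errors(self):
        with pytest.raises(ValueError, match="mean"):
            concentration_index([0.0, 0.0, 0.0], RANKS4[:3])
        with pytest.raises(ValueError, match="rank"):
            concentration_index([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="3 observations"):
            concentration_index([1.0, 2.0], [0.5, 1.0])

    def test_robust_and_serial_options_agree_on_point_estimate(self):
        rng = np.random.default_rng(4)
        y = rng.exponential(2.0, 200)
        r = fractional_rank(rng.normal(size=200))
        hc = concentration_index(y, r)
        hac = concentration_index(y, r, cov_type="HAC",
                                  cov_kwds={"maxlags": 3})
        assert hc.c_hat == pytest.approx(hac.c_hat, abs=1e-12)
        assert hac.se > 0


class TestConcentrationCurve:
    def test_constant_outcome_is_diagonal(self):
        cur = concentration_curve([2.0] * 8, fractional_rank(np.arange(8)))
        np.testing.assert_allclose(cur.L, cur.p, atol=1e-12)

    def test_extreme_pro_poor(self):
        cur = concentration_curve([1, 0, 0, 0], RANKS4)
        np.testing.assert_allclose(cur.p, [0, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(cur.L, [0, 1.0, 1.0, 1.0, 1.0])

    def test_ties_pool_into_single_step(self):
        cur = concentration_curve([1, 2, 3], [0.5, 0.5, 1.0])
        np.testing.assert_allclose(cur.p, [0, 2 / 3, 1.0])
        np.testing.assert_allclose(cur.L, [0, 0.5, 1.0])

    def test_endpoints_and_monotonicity(self, scored_sample):
        cur = concentration_curve(scored_sample["tehb"],
                                  scored_sample["frac_rank"])
        assert cur.p[0] == 0 and cur.L[0] == 0
        assert cur.p[-1] == pytest.approx(1.0, abs=1e-12)
        assert cur.L[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(cur.p) >= 0) and np.all(np.diff(cur.L) >= 0)

    def test_pro_poor_curve_lies_above_diagonal(self, scored_sample):
        cur = concentration_curve(scored_sample["tehb"],
                                  scored_sample["frac_rank"])
        interior = (cur.p > 0) & (cur.p < 1)
        assert np.all(cur.L[interior] >= cur.p[interior])

    def test_errors(self):
        with pytest.raises(ValueError, match="positive"):
            concentration_curve([0.0, 0.0], [0.5, 1.0])
        with pytest.raises(ValueError, match="non-negative"):
            concentration_curve([1.0, -1.0], [0.5, 1.0])


class TestSubgroups:
    def test_identical_subgroups_match_pooled(self):
        y = np.array([1.0, 4.0, 2.0, 7.0, 5.0])
        s = np.array([0.3, 1.2, -0.5, 2.0, 0.9])
        df = pd.DataFrame({
            "tehb": np.concatenate([y, y]),
            "wealth_score": np.concatenate([s, s]),
            "g": ["a"] * 5 + ["b"] * 5,
        })
        pooled, ga, gb = subgroup_concentration(df, "g")
        assert ga.c_hat == pytest.approx(pooled.c_hat, abs=1e-12)
        assert gb.c_hat == pytest.approx(pooled.c_hat, abs=1e-12)

    def test_constant_outcome_subgroup_has_zero_index(self):
        df = pd.DataFrame({
            "tehb": [2.0, 2.0, 2.0, 1.0, 5.0, 3.0],
            "wealth_score": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            "g": ["flat"] * 3 + ["vary"] * 3,
        })
        results = {r.subgroup_label: r for r in subgroup_concentration(df, "g")}
        assert results["g=flat"].c_hat == pytest.approx(0.0, abs=1e-12)

    def test_small_subgroup_skipped_with_warning(self, caplog):
        df = pd.DataFrame({
            "tehb": [1.0, 2.0, 3.0, 4.0, 9.0],
            "wealth_score": [1.0, 2.0, 3.0, 4.0, 5.0],
            "g": ["big"] * 4 + ["tiny"],
        })
        with caplog.at_level("WARNING"):
            results = subgroup_concentration(df, "g")
        assert {r.subgroup_label for r in results} == {"national", "g=big"}
        assert "tiny" in caplog.text

    def test_urban_gradient_scale_orders_subgroup_indices(self,
                                                          default_config):
        from tehb import generate_households, prepare_analysis_sample
        from tehb import fit_wealth_index, score_and_classify
        cfg = default_config.replace(n_households=20_000, seed=13,
                                     tehb_urban_slope_scale=1.6)
        sample, _ = prepare_analysis_sample(generate_households(cfg))
        ind = [c for c in sample.columns if c.startswith("asset_")]
        scored = score_and_classify(sample, fit_wealth_index(sample, ind))
        res = {r.subgroup_label: r
               for r in subgroup_concentration(scored, "urban")}
        assert abs(res["urban=1"].c_hat) > abs(res["urban=0"].c_hat)


def test_normalized_indices_for_bounded_outcome():
    res = concentration_index([1, 2, 3, 4], RANKS4)
    out = normalized_indices(res, lower=0.0, upper=100.0)
    assert out["plain"] == res.c_hat
    assert out["erreygers"] == pytest.approx(4 * 2.5 * 0.25 / 100)
    assert out["wagstaff"] == pytest.approx(0.25 * 2.5 * 100 / (97.5 * 2.5))
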