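"""Equity tests, determinant models, VIFs and percent conversions."""

import numpy as np
import pandas as pd
import pytest

from thaali.inference import (
    determinant_design,
    fit_determinants,
    format_pct,
    pct_from_log,
    test_equity,
    vif,
)


def _covariates(n, rng, constant=False):
    if constant:
        return pd.DataFrame({"asset_score": np.ones(n), "empowerment": np.ones(n)})
    return pd.DataFrame(
        {
            "earnings_parity": rng.random(n) < 0.25,
            "gravidity": np.where(rng.random(n) < 0.7, "1+", "0"),
            "empowerment": rng.integers(0, 11, n).astype(float),
            "asset_score": rng.normal(0, 1, n),
            "hh_kcal_per_1000": rng.normal(2.4, 0.4, n),
            "husband_overseas": rng.random(n) < 0.2,
            "caste_group": rng.choice(
                ["disadvantaged", "middle", "least_disadvantaged"], n
            ),
            "season": rng.choice(["pre_monsoon", "monsoon"], n),
        }
    )


class TestEquityTest:
    def test_all_zero_ratios_give_zero_estimate_and_p_one(self):
        res = test_equity(np.zeros(40), np.repeat(np.arange(8), 5))
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            test_equity(np.random.default_rng(0).normal(size=20), np.zeros(20))

    def test_estimate_near_truth_with_cluster_noise(self, rng):
        n_cl, per = 20, 8
        cl = np.repeat(np.arange(n_cl), per)
        y = -0.2 + rng.normal(0, 0.05, n_cl)[cl] + rng.normal(0, 0.3, n_cl * per)
        res = test_equity(y, cl)
        assert res.ci_low < -0.2 < res.ci_high
        assert res.n == n_cl * per

    def test_missing_values_dropped(self, rng):
        y = rng.normal(size=30)
        y[::3] = np.nan
        res = test_equity(y, np.repeat(np.arange(6), 5))
        assert res.n == 20


class TestDeterminants:
    def test_constant_covariates_rejected_for_rank(self, rng):
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            fit_determinants(y, _covariates(30, rng, constant=True),
                             np.repeat(np.arange(6), 5))

    def test_reference_levels_absent_from_terms(self, rng):
        n = 120
        cov = _covariates(n, rng)
        y = rng.normal(size=n)
        model = fit_determinants(y, cov, np.repeat(np.arange(12), 10))
        terms = set(model.table.index)
        assert "Intercept" in terms
        assert "caste_middle" in terms and "caste_least_disadvantaged" in terms
        assert "earnings_same_or_more" in terms
        assert not any("disadvantaged" == t for t in terms)
        assert (model.vifs >= 1.0).all()

    def test_single_constant_design_degenerates_to_equity_intercept(self, rng):
        n = 80
        cl = np.repeat(np.arange(8), 10)
        y = rng.normal(-0.3, 0.2, size=n)
        eq = test_equity(y, cl)
        det = fit_determinants(y, pd.DataFrame(index=range(n)), cl)
        assert det.table.loc["Intercept", "estimate"] == pytest.approx(
            eq.estimate, abs=1e-8
        )

    def test_known_effect_recovered_single_fit(self, rng):
        n = 400
        cov = _covariates(n, rng)
        x = cov["earnings_parity"].to_numpy(dtype=float)
        y = -0.2 + 0.27 * x + rng.normal(0, 0.2, n)
        model = fit_determinants(y, cov, np.repeat(np.arange(20), 20))
        est = model.table.loc["earnings_same_or_more"]
        assert est["ci_low"] < 0.27 < est["ci_high"]

    def test_quadratic_wealth_term_added(self, rng):
        n = 120
        cov = _covariates(n, rng)
        model = fit_determinants(
            rng.normal(size=n), cov, np.repeat(np.arange(12), 10),
            quadratic_wealth=True,
        )
        assert "asset_score_sq" in model.table.index


class TestVif:
    def test_orthogonal_covariates_give_unit_vifs(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        out = vif(pd.DataFrame({"a": x1, "b": x2}))
        assert np.allclose(out, 1.0)

    def test_duplicated_covariate_rejected(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": x, "b": x}))

    def test_known_correlation_gives_closed_form_vif(self, rng):
        # construct exact sample correlation 0.6 via orthonormalised basis
        n = 200
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)  # orthogonalise
        z2 /= z2.std()
        x2 = 0.6 * z1 + 0.8 * z2
        out = vif(pd.DataFrame({"a": z1, "b": x2}))
        assert out["a"] == pytest.approx(1.5625, abs=1e-9)
        assert out["b"] == pytest.approx(1.5625, abs=1e-9)


class TestPercentConversion:
    @pytest.mark.parametrize(
        "coeff,expected",
        [
            (0.27, "31% higher"),
            (0.29, "34% higher"),
            (-0.20, "18% lower"),
            (-0.28, "24% lower"),
            (-0.47, "38% lower"),
            (-0.15, "14% lower"),
            (-0.54, "42% lower"),
            (0.0, "0% higher"),
        ],
    )
    def test_display_strings(self, coeff, expected):
        assert format_pct(coeff) == expected

    @pytest.mark.parametrize("coeff", [0.27, 0.47, 1.3, 0.05])
    def test_reciprocal_consistency_before_rounding(self, coeff):
        up, d_up = pct_from_log(coeff)
        down, d_down = pct_from_log(-coeff)
        assert d_up == "higher" and d_down == "lower"
        assert (1 + up / 100) * (1 - down / 100) == pytest.approx(1.0, abs=1e-12)

    def test_design_encoding_columns(self, rng):
        X = determinant_design(_covariates(50, rng))
        assert list(X.columns) == [
            "earnings_same_or_more", "gravidity_1plus", "empowerment",
            "asset_score", "hh_kcal_per_1000", "husband_overseas",
            "caste_middle", "caste_least_disadvantaged", "season_monsoon",
        ]
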