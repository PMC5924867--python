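"""Cluster-adjusted equity tests and determinant models for log ratios.

Perfect intra-household equity corresponds to a log allocation ratio of
zero, so the equity test asks whether the mean log ratio differs from
zero while allowing for correlation within sampling clusters: a linear
mixed model with a cluster random intercept and no covariates.

Determinant models regress a log ratio on all hypothesised household
covariates simultaneously (again with a cluster random intercept);
collinearity among covariates is screened with variance inflation
factors.  Estimation is by maximum likelihood with Wald intervals, and
the significance threshold is 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "EquityTestResult",
    "DeterminantsModel",
    "test_equity",
    "fit_determinants",
    "determinant_design",
    "vif",
    "pct_from_log",
    "format_pct",
]

#: Covariate coding used throughout: reference levels first.
REFERENCE_LEVELS = {
    "earnings_parity": False,   # "earns less than the spouse"
    "gravidity": "0",
    "husband_overseas": False,
    "caste_group": "disadvantaged",  # Dalit or Muslim
    "season": "pre_monsoon",
}


@dataclass
class EquityTestResult:
    """Intercept-only cluster random-effects test of a log ratio."""

    pair: str
    outcome: str
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class DeterminantsModel:
    """Multivariable mixed-effects determinant model for one log ratio."""

    pair: str
    outcome: str
    n: int
    table: pd.DataFrame  # index: term; columns: estimate, ci_low, ci_high, p_value
    vifs: pd.Series
    var_cluster: float
    var_residual: float


@dataclass
class _ClusterFit:
    """Common shape for the cluster random-intercept fit results."""

    params: np.ndarray
    bse: np.ndarray
    var_cluster: float
    scale: float


def _mixed_fit(y: np.ndarray, X: pd.DataFrame, clusters: np.ndarray) -> _ClusterFit:
    """ML cluster random-intercept fit; OLS when the cluster variance
    converges to the zero boundary (where the models coincide)."""
    import warnings
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    groups = pd.Series(clusters).astype(str).to_numpy()
    Xa = np.asarray(X, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.MixedLM(y, Xa, groups=groups).fit(
                reml=False, method=["lbfgs", "powell"]
            )
        k = Xa.shape[1]
        bse = np.asarray(res.bse[:k], dtype=float)
        if not np.all(np.isfinite(bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        cov_re = np.asarray(res.cov_re)
        var_cluster = float(cov_re[0, 0]) if cov_re.size else 0.0
        return _ClusterFit(
            np.asarray(res.params[:k], dtype=float), bse, var_cluster, float(res.scale)
        )
    except (np.linalg.LinAlgError, ValueError):
        ols = sm.OLS(y, Xa).fit()
        return _ClusterFit(
            np.asarray(ols.params, dtype=float),
            np.asarray(ols.bse, dtype=float),
            0.0,
            float(ols.scale),
        )


def test_equity(log_ratios, cluster_ids, pair: str = "", outcome: str = "") -> EquityTestResult:
    """Test whether the mean log ratio differs from zero.

    Fits an intercept-only linear mixed model with a cluster random
    intercept (ML) and returns the Wald interval and P value for the
    intercept.  Missing values are dropped pairwise with their clusters.
    """
    y = pd.Series(np.asarray(log_ratios, dtype=float))
    cl = pd.Series(cluster_ids).astype(str)
    keep = y.notna().to_numpy()
    y, cl = y[keep], cl[keep]
    if y.size == 0:
        raise ValueError("no non-missing log ratios to test")
    if cl.nunique() < 2:
        raise ValueError(f"equity test needs at least 2 clusters, got {cl.nunique()}")
    n = int(y.size)
    if float(np.var(y)) == 0.0:
        est = float(y.iloc[0])
        p = 1.0 if est == 0.0 else 0.0
        return EquityTestResult(pair, outcome, n, est, est, est, p)
    X = pd.DataFrame({"Intercept": np.ones(n)})
    res = _mixed_fit(y.to_numpy(), X, cl.to_numpy())
    est = float(res.params[0])
    se = float(res.bse[0])
    if se == 0.0:
        return EquityTestResult(pair, outcome, n, est, est, est,
                                1.0 if est == 0 else 0.0)
    z = stats.norm.ppf(0.975)
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else (1.0 if est == 0 else 0.0)
    return EquityTestResult(pair, outcome, n, est, est - z * se, est + z * se, float(p))


test_equity.__test__ = False  # not a pytest case despite the field-standard name


def determinant_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Encode household covariates into a numeric design matrix.

    Binary flags become 0/1 against their reference level; caste and
    season become treatment dummies; ``hh_kcal`` is expected already
    rescaled to thousands of kcal.  Continuous columns (empowerment,
    asset_score, hh_kcal_per_1000) pass through unchanged.
    """
    X = pd.DataFrame(index=covariates.index)
    c = covariates
    if "earnings_parity" in c:
        X["earnings_same_or_more"] = c["earnings_parity"].astype(bool).astype(float)
    if "gravidity" in c:
        X["gravidity_1plus"] = (c["gravidity"].astype(str) == "1+").astype(float)
    if "empowerment" in c:
        X["empowerment"] = c["empowerment"].astype(float)
    if "asset_score" in c:
        X["asset_score"] = c["asset_score"].astype(float)
    if "hh_kcal_per_1000" in c:
        X["hh_kcal_per_1000"] = c["hh_kcal_per_1000"].astype(float)
    if "husband_overseas" in c:
        X["husband_overseas"] = c["husband_overseas"].astype(bool).astype(float)
    if "caste_group" in c:
        X["caste_middle"] = (c["caste_group"] == "middle").astype(float)
        X["caste_least_disadvantaged"] = (
            c["caste_group"] == "least_disadvantaged"
        ).astype(float)
    if "season" in c:
        X["season_monsoon"] = (c["season"] == "monsoon").astype(float)
    return X


def fit_determinants(
    log_outcome,
    covariates: pd.DataFrame,
    cluster_ids,
    pair: str = "",
    outcome: str = "",
    quadratic_wealth: bool = False,
) -> DeterminantsModel:
    """Fit the multivariable cluster random-intercept determinant model.

    All covariates enter simultaneously.  ``quadratic_wealth`` adds the
    squared asset score to probe nonlinear wealth effects.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    y = pd.Series(np.asarray(log_outcome, dtype=float)).reset_index(drop=True)
    X = determinant_design(covariates.reset_index(drop=True))
    if quadratic_wealth:
        if "asset_score" not in X:
            raise ValueError("quadratic_wealth requires an asset_score covariate")
        X["asset_score_sq"] = X["asset_score"] ** 2
    cl = pd.Series(cluster_ids).astype(str).reset_index(drop=True)
    keep = y.notna()
    y, X, cl = y[keep], X[keep], cl[keep]
    n = int(y.size)
    if n == 0:
        raise ValueError("no non-missing outcomes to fit")

    Xc = sm.add_constant(X, prepend=True).rename(columns={"const": "Intercept"})
    rank = np.linalg.matrix_rank(np.asarray(Xc, dtype=float))
    if rank < Xc.shape[1]:
        # name offending columns: those whose removal restores full rank
        bad = []
        arr = np.asarray(Xc, dtype=float)
        for j, col in enumerate(Xc.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    res = _mixed_fit(y.to_numpy(), Xc, cl.to_numpy())
    z = stats.norm.ppf(0.975)
    est = res.params
    se = res.bse
    pvals = 2 * stats.norm.sf(np.abs(est / se))
    table = pd.DataFrame(
        {
            "estimate": est,
            "ci_low": est - z * se,
            "ci_high": est + z * se,
            "p_value": pvals,
        },
        index=list(Xc.columns),
    )
    vifs = vif(X) if X.shape[1] >= 2 else pd.Series(1.0, index=X.columns)
    return DeterminantsModel(
        pair, outcome, n, table, vifs, res.var_cluster, res.scale
    )


def vif(covariate_matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: 1/(1 - R^2_j) per covariate.

    Each covariate is regressed (with intercept) on all the others.
    """
    X = pd.DataFrame(covariate_matrix).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 covariates")
    arr = np.asarray(X)
    if np.linalg.matrix_rank(sm.add_constant(arr)) < X.shape[1] + 1:
        raise ValueError("covariate matrix is rank deficient; VIF undefined")
    out = {}
    for j, col in enumerate(X.columns):
        others = sm.add_constant(np.delete(arr, j, axis=1))
        r2 = sm.OLS(arr[:, j], others).fit().rsquared
        if r2 >= 1 - 1e-12:
            raise ValueError(f"covariate {col!r} is perfectly collinear")
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def pct_from_log(coefficient: float) -> tuple[float, str]:
    """Convert a log-ratio coefficient into a percent difference.

    Positive coefficients read "p% higher" with p = 100(exp(c) - 1);
    negative ones read "p% lower" with p = 100(1 - exp(c)).  Returns the
    unrounded percentage and the direction word.
    """
    if not math.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    if coefficient >= 0:
        return 100.0 * (math.expm1(coefficient)), "higher"
    return 100.0 * (1.0 - math.exp(coefficient)), "lower"


def format_pct(coefficient: float) -> str:
    """Display form of :func:`pct_from_log`, e.g. ``'31% higher'``.

    Percentages are rounded half-up at one decimal and then half-up to an
    integer, so a printed coefficient whose percent value lands on x.5
    after the first rounding (e.g. 37.49976 -> 37.5) displays as the next
    integer — consistent with rounding from full-precision coefficients.
    """
    pct, direction = pct_from_log(coefficient)
    one_dp = Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    integer = int(one_dp.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return f"{integer}% {direction}"
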