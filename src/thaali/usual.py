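"""Usual-intake estimation: Box-Cox normalisation and mixed-model BLUPs.

A single 24-h recall is a noisy draw around a person's long-run ("usual")
intake: day-to-day variation is large and intake distributions are
right-skewed.  The estimator here follows the classical two-step recipe:

1. transform per-visit intakes with a Box-Cox power transform whose
   exponent is chosen by profile maximum likelihood;
2. on the transformed scale, fit a linear mixed model with random
   intercepts for cluster and for individual (nested in cluster) and
   fixed effects for survey strata, and read each person's usual intake
   off the best linear unbiased predictors (BLUPs), back-transformed.

Models are fitted separately per nutrient and per member role, because
requirement groups (and hence intake distributions) differ by role.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "BoxCoxFit",
    "UsualIntakeModel",
    "ModelFitError",
    "fit_boxcox",
    "fit_usual_model",
    "predict_usual",
    "estimate_usual_intakes",
]


class ModelFitError(RuntimeError):
    """Raised when a usual-intake model cannot be fitted."""


@dataclass
class BoxCoxFit:
    """A fitted Box-Cox transform y = ((x + shift)^lambda - 1) / lambda.

    ``shift`` keeps the transform defined when zero intakes occur: it is
    zero when all observed values are positive, otherwise half the
    smallest positive value.
    """

    lmbda: float
    shift: float = 0.0

    def transform(self, x):
        x = np.asarray(x, dtype=float) + self.shift
        if np.any(x <= 0):
            raise ValueError("Box-Cox transform needs positive shifted values")
        if abs(self.lmbda) < 1e-12:
            return np.log(x)
        return (np.power(x, self.lmbda) - 1.0) / self.lmbda

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if abs(self.lmbda) < 1e-12:
            x = np.exp(y)
        else:
            base = self.lmbda * y + 1.0
            base = np.maximum(base, 0.0)  # clamp outside the transform's range
            x = np.power(base, 1.0 / self.lmbda)
        return np.maximum(x - self.shift, 0.0)


def fit_boxcox(values) -> BoxCoxFit:
    """Choose lambda by profile ML on (optionally shifted) intake values."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Box-Cox fit needs at least 3 values, got {x.size}")
    if np.any(x < 0):
        raise ValueError("intakes must be nonnegative")
    if np.all(x == 0):
        raise ValueError("all intakes are zero; nothing to transform")
    if x.min() > 0:
        shift = 0.0
    else:
        shift = float(x[x > 0].min()) / 2.0
    if np.ptp(x) == 0:
        # constant positive data: any lambda fits; use log for stability
        return BoxCoxFit(0.0, shift)
    _, lmbda = stats.boxcox(x + shift)
    return BoxCoxFit(float(lmbda), shift)


@dataclass
class UsualIntakeModel:
    """Mixed-model fit for one nutrient and one member role."""

    nutrient: str
    role: str
    boxcox: BoxCoxFit
    intercept: float
    stratum_effects: dict[str, float]  # per stratum, reference = 0
    var_cluster: float
    var_individual: float
    var_residual: float
    cluster_blups: dict[str, float]
    individual_blups: dict[str, float]
    member_meta: pd.DataFrame = field(repr=False, default=None)
    # member_meta: index member_id, columns cluster_id, stratum

    def linear_predictor(self, member_id: str) -> float:
        if member_id not in self.member_meta.index:
            raise KeyError(f"member {member_id!r} not in fitted model")
        cluster = self.member_meta.loc[member_id, "cluster_id"]
        stratum = self.member_meta.loc[member_id, "stratum"]
        return (
            self.intercept
            + self.stratum_effects.get(str(stratum), 0.0)
            + self.cluster_blups.get(str(cluster), 0.0)
            + self.individual_blups.get(str(member_id), 0.0)
        )


_VC_RE = re.compile(r"member\[C\(member_id\)\[(.+)\]\]")


def _degenerate_fit(df: pd.DataFrame, nutrient: str, role: str, boxcox: BoxCoxFit) -> UsualIntakeModel:
    # no within-member variance: residual variance is zero and BLUPs are
    # unshrunken; decompose member means into grand mean + cluster + individual
    means = df.groupby(["cluster_id", "member_id"], observed=True)["y"].mean().reset_index()
    strata = df.groupby("member_id", observed=True)["stratum"].first()
    intercept = float(means["y"].mean())
    cl_mean = means.groupby("cluster_id", observed=True)["y"].mean()
    cluster_blups = {str(c): float(v - intercept) for c, v in cl_mean.items()}
    indiv = {
        str(r.member_id): float(r.y - intercept - cluster_blups[str(r.cluster_id)])
        for r in means.itertuples(index=False)
    }
    var_cluster = float(np.var(list(cluster_blups.values()))) if len(cluster_blups) > 1 else 0.0
    var_indiv = float(np.var(list(indiv.values()))) if len(indiv) > 1 else 0.0
    meta = means.set_index("member_id")[["cluster_id"]]
    meta["stratum"] = strata
    return UsualIntakeModel(
        nutrient, role, boxcox, intercept, {},
        var_cluster, var_indiv, 0.0, cluster_blups, indiv, meta,
    )


def fit_usual_model(
    data: pd.DataFrame,
    boxcox: BoxCoxFit,
    nutrient: str = "",
    role: str = "",
) -> UsualIntakeModel:
    """Fit the cluster/individual random-intercept model on transformed intakes.

    ``data`` needs columns ``y`` (Box-Cox-transformed per-visit intake),
    ``member_id``, ``cluster_id`` and ``stratum``.  Individuals are nested
    within clusters; strata enter as fixed effects when more than one
    stratum is present.  Estimation is by REML; if the full model is
    singular the cluster variance component is dropped first.
    """
    required = {"y", "member_id", "cluster_id", "stratum"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns {sorted(missing)}")
    df = data.reset_index(drop=True).copy()
    df["member_id"] = df["member_id"].astype(str)
    df["cluster_id"] = df["cluster_id"].astype(str)
    df["stratum"] = df["stratum"].astype(str)
    n_clusters = df["cluster_id"].nunique()
    if n_clusters < 2:
        raise ModelFitError(
            f"{nutrient}/{role}: need at least 2 clusters, got {n_clusters}"
        )

    within = df.groupby("member_id", observed=True)["y"].var(ddof=0).fillna(0.0)
    total_var = float(df["y"].var(ddof=0))
    if within.max() <= max(1e-12, 1e-10 * max(total_var, 1.0)):
        return _degenerate_fit(df, nutrient, role, boxcox)

    n_strata = df["stratum"].nunique()
    fixed = "y ~ 1" if n_strata == 1 else "y ~ C(stratum)"

    def _do_fit(with_cluster: bool):
        kwargs = dict(
            groups="cluster_id",
            vc_formula={"member": "0 + C(member_id)"},
        )
        if with_cluster:
            kwargs["re_formula"] = "1"
        else:
            kwargs["re_formula"] = "0"
        model = smf.mixedlm(fixed, df, **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            return model.fit(reml=True, method=["lbfgs", "powell"])

    with_cluster = True
    try:
        res = _do_fit(True)
        if not np.all(np.isfinite(res.params)):
            raise np.linalg.LinAlgError("non-finite parameters")
    except (np.linalg.LinAlgError, ValueError):
        try:
            res = _do_fit(False)
            with_cluster = False
        except (np.linalg.LinAlgError, ValueError) as err:
            raise ModelFitError(f"{nutrient}/{role}: singular mixed-model fit") from err

    params = res.params
    intercept = float(params["Intercept"])
    stratum_effects: dict[str, float] = {}
    if n_strata > 1:
        for s in sorted(df["stratum"].unique()):
            key = f"C(stratum)[T.{s}]"
            if key in params.index:
                stratum_effects[s] = float(params[key])

    var_cluster = float(res.cov_re.iloc[0, 0]) if with_cluster and res.cov_re.size else 0.0
    var_individual = float(res.vcomp[0]) if res.vcomp.size else 0.0
    var_residual = float(res.scale)

    cluster_blups: dict[str, float] = {}
    individual_blups: dict[str, float] = {}
    for cluster, re_vals in res.random_effects.items():
        for name, val in re_vals.items():
            m = _VC_RE.fullmatch(name)
            if m:
                individual_blups[m.group(1)] = float(val)
            elif with_cluster:
                cluster_blups[str(cluster)] = float(val)

    meta = (
        df.groupby("member_id", observed=True)
        .agg(cluster_id=("cluster_id", "first"), stratum=("stratum", "first"))
    )
    return UsualIntakeModel(
        nutrient, role, boxcox, intercept, stratum_effects,
        var_cluster, var_individual, var_residual,
        cluster_blups, individual_blups, meta,
    )


def predict_usual(model: UsualIntakeModel, member_id: str) -> float:
    """Back-transformed usual intake for one member (original units)."""
    y = model.linear_predictor(str(member_id))
    return float(model.boxcox.inverse(y))


def estimate_usual_intakes(
    raw: pd.DataFrame, nutrient: str = "", role: str = ""
) -> tuple[UsualIntakeModel, pd.Series]:
    """Convenience: Box-Cox fit + mixed model + per-member usual intakes.

    ``raw`` needs columns ``value`` (per-visit intake, original units),
    ``member_id``, ``cluster_id``, ``stratum``.
    """
    bc = fit_boxcox(raw["value"].to_numpy())
    df = raw.copy()
    df["y"] = bc.transform(df["value"].to_numpy())
    model = fit_usual_model(df, bc, nutrient=nutrient, role=role)
    usual = pd.Series(
        {mid: predict_usual(model, mid) for mid in model.member_meta.index},
        name=nutrient,
    )
    return model, usual
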