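"""Box-Cox fitting, the nested mixed model and BLUP-based usual intakes."""

import numpy as np
import pandas as pd
import pytest

from thaali.usual import (
    BoxCoxFit,
    ModelFitError,
    estimate_usual_intakes,
    fit_boxcox,
    fit_usual_model,
    predict_usual,
)


def _nested_data(rng, n_clusters=20, n_per_cluster=8, n_visits=3,
                 mean=7.0, sd_cluster=0.1, sd_individual=0.2, sd_day=0.25,
                 n_strata=1):
    """Transformed-scale intakes with known variance components."""
    rows = []
    mid = 0
    for c in range(n_clusters):
        uc = rng.normal(0, sd_cluster)
        stratum = f"S{(c % n_strata) + 1}"
        for _ in range(n_per_cluster):
            mid += 1
            ui = rng.normal(0, sd_individual)
            for _v in range(n_visits):
                rows.append(
                    {
                        "member_id": f"M{mid:03d}",
                        "cluster_id": f"C{c:02d}",
                        "stratum": stratum,
                        "y": mean + uc + ui + rng.normal(0, sd_day),
                    }
                )
    return pd.DataFrame(rows)


class TestBoxCox:
    def test_lognormal_sample_gives_lambda_near_zero(self, rng):
        x = np.exp(rng.normal(1.0, 0.5, size=500))
        fit = fit_boxcox(x)
        assert -0.2 <= fit.lmbda <= 0.2
        assert fit.shift == 0.0

    def test_normal_positive_sample_gives_lambda_near_one(self, rng):
        x = rng.normal(100.0, 5.0, size=500)
        fit = fit_boxcox(x)
        assert 0.5 <= fit.lmbda <= 1.6

    def test_zeros_trigger_half_minimum_shift(self):
        x = np.array([0.0, 0.0, 4.0, 8.0, 2.0, 6.0])
        fit = fit_boxcox(x)
        assert fit.shift == pytest.approx(1.0)  # half the smallest positive

    @pytest.mark.parametrize("lmbda,shift", [(0.0, 0.0), (0.5, 1.0), (-0.3, 0.0), (1.0, 2.5)])
    def test_transform_inverse_round_trip(self, lmbda, shift, rng):
        fit = BoxCoxFit(lmbda, shift)
        x = rng.uniform(0.5, 200.0, size=50)
        back = fit.inverse(fit.transform(x))
        assert np.allclose(back, x, atol=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_boxcox([1.0, 2.0])
        with pytest.raises(ValueError):
            fit_boxcox([0.0, 0.0, 0.0])


class TestMixedModel:
    def test_fewer_than_two_clusters_rejected(self, rng):
        df = _nested_data(rng, n_clusters=1)
        with pytest.raises(ModelFitError, match="clusters"):
            fit_usual_model(df, BoxCoxFit(1.0))

    def test_single_stratum_has_no_stratum_coefficients(self, rng):
        df = _nested_data(rng, n_clusters=6, n_per_cluster=4)
        model = fit_usual_model(df, BoxCoxFit(1.0))
        assert model.stratum_effects == {}

    def test_two_strata_yield_one_contrast(self, rng):
        df = _nested_data(rng, n_clusters=6, n_per_cluster=4, n_strata=2)
        model = fit_usual_model(df, BoxCoxFit(1.0))
        assert set(model.stratum_effects) == {"S2"}

    def test_zero_day_noise_recovers_constant_intakes_exactly(self, rng):
        df = _nested_data(rng, n_clusters=5, n_per_cluster=4, sd_day=0.0)
        model = fit_usual_model(df, BoxCoxFit(1.0))
        assert model.var_residual == pytest.approx(0.0, abs=1e-12)
        for mid, grp in df.groupby("member_id"):
            assert model.linear_predictor(mid) == pytest.approx(
                grp["y"].iloc[0], abs=1e-9
            )

    def test_variance_component_recovery(self, rng):
        # mean estimated var_individual over replicates within 30% of 0.04
        estimates = []
        for _ in range(100):
            df = _nested_data(rng, n_clusters=10, n_per_cluster=6)
            model = fit_usual_model(df, BoxCoxFit(1.0))
            estimates.append(model.var_individual)
        assert np.mean(estimates) == pytest.approx(0.04, rel=0.30)

    def test_anova_oracle_for_balanced_design(self, rng):
        # independent oracle: expected-mean-squares estimators on a balanced
        # one-way (member) layout with no cluster effect
        df = _nested_data(rng, n_clusters=10, n_per_cluster=6, sd_cluster=0.0)
        model = fit_usual_model(df, BoxCoxFit(1.0))
        k = 3  # visits per member
        member_means = df.groupby("member_id")["y"].mean()
        mse_within = (
            df.groupby("member_id")["y"].var(ddof=1).mean()
        )
        var_between = member_means.var(ddof=1) - mse_within / k
        assert model.var_residual == pytest.approx(mse_within, rel=0.10)
        assert model.var_individual + model.var_cluster == pytest.approx(
            var_between, rel=0.25, abs=0.01
        )


class TestUsualIntakes:
    def test_usual_intake_increases_with_blup(self, rng):
        df = _nested_data(rng, n_clusters=8, n_per_cluster=5)
        df["value"] = np.exp(df["y"])  # raw intakes, log-normal
        model, usual = estimate_usual_intakes(df[["value", "member_id", "cluster_id", "stratum"]])
        lps = pd.Series(
            {m: model.linear_predictor(m) for m in model.member_meta.index}
        )
        order = lps.sort_values().index
        assert usual[order].is_monotonic_increasing

    def test_shrinkage_reduces_between_member_variance(self, rng):
        df = _nested_data(rng, n_clusters=10, n_per_cluster=6)
        df["value"] = np.exp(df["y"])
        model, usual = estimate_usual_intakes(df[["value", "member_id", "cluster_id", "stratum"]])
        single_day = df.groupby("member_id")["value"].first()
        assert usual.var() < single_day.var()

    def test_member_absent_from_model_raises(self, rng):
        df = _nested_data(rng, n_clusters=4, n_per_cluster=3)
        model = fit_usual_model(df, BoxCoxFit(1.0))
        with pytest.raises(KeyError):
            predict_usual(model, "M999")

    def test_usual_tracks_ground_truth_on_synthetic_energy(self):
        # full-size study: with ~160 members per role the variance
        # components, and hence the BLUP shrinkage, are well estimated
        from thaali.simulate import SimulationConfig, simulate_study

        _, members, fct, visits, truth = simulate_study(SimulationConfig(seed=5))
        from thaali.nutrients import intake_table

        table = intake_table(visits, fct)
        raw = table["energy_kcal"].reset_index().rename(columns={"energy_kcal": "value"})
        meta = truth.members
        raw["cluster_id"] = raw["member_id"].map(meta["cluster_id"])
        raw["role"] = raw["member_id"].map(meta["role"])
        raw["stratum"] = "S1"
        sub = raw[raw["role"] == "household_head"]
        model, usual = estimate_usual_intakes(
            sub[["value", "member_id", "cluster_id", "stratum"]], role="household_head"
        )
        true_usual = meta.loc[usual.index, "true_usual_energy"]
        rel_err = np.abs(usual - true_usual) / true_usual
        assert rel_err.median() < 0.10
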