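"""Energy EARs, probability of adequacy (normal and tabulated iron), MPA."""

import numpy as np
import pytest
from scipy.stats import norm

from thaali.adequacy import (
    IRON_LOGNORMAL_MEDIAN_ABSORBED_MG,
    IRON_LOGNORMAL_SIGMA,
    PREGNANCY_INCREMENT_KCAL,
    IronProbabilityTable,
    RequirementDistribution,
    build_iron_table,
    default_energy_config,
    default_iron_table,
    default_requirements,
    energy_ear,
    mpa,
    pa_iron_tabulated,
    pa_normal,
)
from thaali.nutrients import MICRONUTRIENTS
from thaali.records import MemberRecord


def _member(role="household_head", sex="male", weight=55.0, activity="moderate",
            gest=None):
    return MemberRecord(
        member_id="M", household_id="H", role=role, sex=sex, age=40.0,
        body_weight=weight, activity_level=activity, gestational_age=gest,
    )


class TestEnergyEar:
    def test_pregnancy_adds_exactly_the_increment(self):
        cfg = default_energy_config()
        pregnant = _member(role="pregnant_woman", sex="female", gest=36.0)
        same_but_not = _member(role="mother_in_law", sex="female")
        assert energy_ear(pregnant, cfg) - energy_ear(same_but_not, cfg) == pytest.approx(
            PREGNANCY_INCREMENT_KCAL
        )

    def test_weight_linearity_of_base_requirement(self):
        cfg = default_energy_config()
        light = energy_ear(_member(weight=40.0), cfg)
        heavy = energy_ear(_member(weight=80.0), cfg)
        assert heavy == pytest.approx(2 * light)

    def test_activity_coefficients_are_ordered(self):
        cfg = default_energy_config()
        for sex in ("male", "female"):
            sed, mod, hvy = (
                cfg.kcal_per_kg[(sex, a)] for a in ("sedentary", "moderate", "heavy")
            )
            assert sed < mod < hvy

    def test_missing_coefficient_raises(self):
        cfg = default_energy_config()
        with pytest.raises(KeyError):
            energy_ear(_member(sex="other"), cfg)


class TestPaNormal:
    def test_at_ear_mean_is_exactly_half(self):
        dist = RequirementDistribution("zinc_mg", "pregnant_woman", "normal", 12, 1.5)
        assert pa_normal(12.0, dist) == pytest.approx(0.5, abs=0)

    def test_quantile_values(self):
        dist = RequirementDistribution("vit_c_mg", "pregnant_woman", "normal", 40, 4.0)
        assert pa_normal(40 + 1.96 * 4.0, dist) == pytest.approx(0.975, abs=1e-4)

    def test_pregnant_zinc_example_matches_normal_cdf(self):
        dist = RequirementDistribution("zinc_mg", "pregnant_woman", "normal", 12, 1.5)
        assert pa_normal(11.0, dist) == pytest.approx(norm.cdf(-2.0 / 3.0), abs=1e-12)
        assert pa_normal(11.0, dist) == pytest.approx(0.252, abs=5e-4)

    def test_tabulated_distribution_rejected(self):
        dist = RequirementDistribution("iron_mg", "household_head", "tabulated")
        with pytest.raises(TypeError):
            pa_normal(10.0, dist)

    def test_lowering_ear_never_decreases_pa(self, rng):
        for _ in range(50):
            usual = rng.uniform(0, 50)
            hi = RequirementDistribution("x", "r", "normal", 25, 3.0)
            lo = RequirementDistribution("x", "r", "normal", 20, 3.0)
            assert pa_normal(usual, lo) >= pa_normal(usual, hi)


class TestIronTable:
    def test_boundaries_clamp_to_extreme_intervals(self):
        table = default_iron_table()
        assert pa_iron_tabulated(0.0, table) == table.probabilities[0]
        assert (
            pa_iron_tabulated(table.upper_bounds[-1] * 10, table)
            == table.probabilities[-1]
        )

    def test_probabilities_monotone_in_intake(self):
        table = default_iron_table()
        intakes = np.linspace(0, 60, 200)
        pas = [pa_iron_tabulated(x, table) for x in intakes]
        assert all(b >= a for a, b in zip(pas, pas[1:]))

    def test_frozen_csv_matches_rebuild(self):
        shipped = default_iron_table()
        rebuilt = build_iron_table()
        assert np.allclose(shipped.upper_bounds, rebuilt.upper_bounds, atol=1e-3)
        assert np.allclose(shipped.probabilities, rebuilt.probabilities, atol=1e-4)

    def test_table_agrees_with_monte_carlo_oracle(self, rng):
        # the oracle integrates the generating distribution directly
        table = build_iron_table()
        mu = np.log(IRON_LOGNORMAL_MEDIAN_ABSORBED_MG / table.bioavailability)
        draws = np.exp(rng.normal(mu, IRON_LOGNORMAL_SIGMA, size=200_000))
        for intake in (8.0, 15.0, 22.0, 30.0, 45.0):
            mc = float(np.mean(draws <= intake))
            assert pa_iron_tabulated(intake, table) == pytest.approx(mc, abs=0.02)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            IronProbabilityTable(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            IronProbabilityTable(np.array([1.0, 2.0]), np.array([0.5, 0.4]))


class TestMpa:
    def test_constant_pa_maps_through(self):
        assert mpa({n: 1.0 for n in MICRONUTRIENTS}) == 1.0
        assert mpa({n: 0.5 for n in MICRONUTRIENTS}) == 0.5

    def test_equals_brute_force_mean(self, rng):
        pa = {n: float(rng.uniform()) for n in MICRONUTRIENTS}
        assert mpa(pa) == pytest.approx(sum(pa.values()) / 11)

    def test_missing_and_extra_nutrients_named(self):
        pa = {n: 0.5 for n in MICRONUTRIENTS}
        del pa["iron_mg"]
        with pytest.raises(ValueError, match="iron_mg"):
            mpa(pa)
        pa["iron_mg"] = 0.5
        pa["protein_g"] = 0.5
        with pytest.raises(ValueError, match="protein_g"):
            mpa(pa)

    def test_permutation_invariant(self, rng):
        vals = rng.uniform(size=11)
        a = mpa(dict(zip(MICRONUTRIENTS, vals)))
        b = mpa(dict(zip(MICRONUTRIENTS, vals[::-1])))
        assert a == pytest.approx(b)

    def test_default_requirements_cover_all_roles(self):
        reqs = default_requirements()
        seen = {(r.nutrient, r.role) for r in reqs}
        for role in ("pregnant_woman", "mother_in_law", "household_head"):
            for n in MICRONUTRIENTS:
                assert (n, role) in seen
        tabulated = {r.role for r in reqs if r.kind == "tabulated"}
        assert tabulated == {"mother_in_law", "household_head"}
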