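"""Pairwise allocation ratio arithmetic, reciprocity and exclusion rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thaali.allocation import (
    classify_disparity,
    dd_ratio_terms,
    food_share,
    fs_es,
    mpa_ratio,
    rdear,
)

positive = st.floats(0.01, 1e4, allow_nan=False, allow_infinity=False)


class TestFoodShare:
    def test_equal_intakes_give_unity(self):
        assert food_share(100.0, 100.0) == pytest.approx(1.0)

    def test_zero_on_either_side_is_absent(self):
        assert food_share(50.0, 0.0) is None
        assert food_share(0.0, 50.0) is None

    def test_plain_arithmetic(self):
        assert food_share(60.0, 80.0) == pytest.approx(0.75)

    def test_negative_grams_rejected(self):
        with pytest.raises(ValueError):
            food_share(-1.0, 10.0)


class TestFsEs:
    def test_equal_per_kcal_shares_give_unity(self):
        assert fs_es(100.0, 2000.0, 50.0, 1000.0) == pytest.approx(1.0)
        assert math.log(fs_es(100.0, 2000.0, 50.0, 1000.0)) == pytest.approx(0.0)

    def test_arithmetic(self):
        assert fs_es(100.0, 2000.0, 100.0, 1000.0) == pytest.approx(0.5)

    @given(food=positive, k_a=positive, k_b=positive, scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_in_joint_kcal(self, food, k_a, k_b, scale):
        base = fs_es(food, k_a, food, k_b)
        scaled = fs_es(food, k_a * scale, food, k_b * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_kcal_rejected(self):
        with pytest.raises(ValueError):
            fs_es(10.0, 0.0, 10.0, 1000.0)


class TestRdearAndMpaRatio:
    def test_both_at_own_ear_give_unity(self):
        assert rdear(2000.0, 2000.0, 2500.0, 2500.0) == pytest.approx(1.0)

    def test_80_vs_120_percent(self):
        assert rdear(1600.0, 2000.0, 3000.0, 2500.0) == pytest.approx(2.0 / 3.0)

    def test_role_mpa_ratio_value(self):
        assert mpa_ratio(0.37, 0.57) == pytest.approx(0.649, abs=5e-4)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            mpa_ratio(0.5, 0.0)
        with pytest.raises(ValueError):
            rdear(2000.0, 0.0, 2500.0, 2500.0)

    def test_outlier_flag_below_minus_eight(self):
        ratio = mpa_ratio(1e-5, 0.6)
        assert math.log(ratio) < -8.0


class TestReciprocityAndIdentities:
    @given(
        ga=positive, gb=positive, ka=positive, kb=positive,
        ea=positive, eb=positive, ma=st.floats(0.01, 1), mb=st.floats(0.01, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_pair_reversal_gives_reciprocal(self, ga, gb, ka, kb, ea, eb, ma, mb):
        assert food_share(ga, gb) * food_share(gb, ga) == pytest.approx(1.0, abs=1e-10)
        assert fs_es(ga, ka, gb, kb) * fs_es(gb, kb, ga, ka) == pytest.approx(1.0, abs=1e-10)
        assert rdear(ka, ea, kb, eb) * rdear(kb, eb, ka, ea) == pytest.approx(1.0, abs=1e-10)
        assert mpa_ratio(ma, mb) * mpa_ratio(mb, ma) == pytest.approx(1.0, abs=1e-10)

    @given(ga=positive, gb=positive, ka=positive, kb=positive)
    @settings(max_examples=100, deadline=None)
    def test_fs_es_equals_fs_over_kcal_ratio(self, ga, gb, ka, kb):
        assert fs_es(ga, ka, gb, kb) == pytest.approx(
            food_share(ga, gb) / (ka / kb), rel=1e-12
        )

    def test_identical_diets_give_unit_ratios_everywhere(self, tiny_study):
        import pandas as pd

        from thaali.allocation import household_ratios
        from thaali.nutrients import FOOD_GROUPS

        grams = pd.DataFrame(
            {g: [120.0, 120.0, 120.0] for g in FOOD_GROUPS},
            index=["PW", "MIL", "HH"],
        )
        energy = pd.Series({"PW": 2000.0, "MIL": 2000.0, "HH": 2000.0})
        ears = pd.Series({"PW": 2100.0, "MIL": 2100.0, "HH": 2100.0})
        mpas = pd.Series({"PW": 0.5, "MIL": 0.5, "HH": 0.5})
        scores = pd.Series({"PW": 6, "MIL": 6, "HH": 6})
        out = household_ratios(
            "H1",
            {"pregnant_woman": "PW", "mother_in_law": "MIL", "household_head": "HH"},
            grams, energy, ears, mpas, scores,
        )
        for r in out:
            assert r.rdear == pytest.approx(1.0)
            assert r.mpa_ratio == pytest.approx(1.0)
            assert all(v == pytest.approx(1.0) for v in r.fs.values())
            assert all(v == pytest.approx(0.0, abs=1e-12) for v in r.log_fs_es.values())
            assert not r.excluded_mpa_outlier


class TestDisparityClassification:
    @pytest.mark.parametrize(
        "a,b,flagged",
        [(0.85, 1.20, True), (0.95, 1.20, False), (0.85, 1.05, False),
         (0.90, 1.20, False), (0.85, 1.10, False)],
    )
    def test_threshold_boundaries(self, a, b, flagged):
        assert classify_disparity(a, b) is flagged


class TestDietaryDiversityRatio:
    def test_energy_adjusted_log_subtracts_kcal_ratio(self):
        ratio, log_ratio, adj = dd_ratio_terms(6, 4, 2000.0, 1600.0)
        assert ratio == pytest.approx(1.5)
        assert adj == pytest.approx(math.log(1.5) - math.log(2000.0 / 1600.0))

    def test_zero_score_absent(self):
        assert dd_ratio_terms(0, 4, 2000.0, 1600.0) == (None, None, None)
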