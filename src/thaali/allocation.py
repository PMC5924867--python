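"""Intra-household pairwise allocation statistics.

For each household the three member pairs are compared:

* ``PW:HH`` — pregnant woman vs male household head,
* ``PW:MIL`` — pregnant woman vs mother-in-law,
* ``MIL:HH`` — mother-in-law vs household head.

Food shares (FS) are ratios of food-group gram intakes; food-share-to-
energy shares (FS:ES) divide each member's group intake by their energy
intake first, so they compare diet *composition* rather than quantity.
The relative dietary energy adequacy ratio (RDEAR) compares energy intake
as a fraction of each member's own energy EAR, and the MPA ratio compares
mean probabilities of micronutrient adequacy.  Ratios are analysed on the
log scale; log MPA ratios below -8 are flagged as extreme outliers and
excluded from inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nutrients import FOOD_GROUPS

__all__ = [
    "PAIRS",
    "LOG_MPA_OUTLIER_THRESHOLD",
    "AllocationRatios",
    "food_share",
    "fs_es",
    "rdear",
    "mpa_ratio",
    "dd_ratio_terms",
    "classify_disparity",
    "household_ratios",
]

PAIRS = ("PW:HH", "PW:MIL", "MIL:HH")
_PAIR_ROLES = {
    "PW:HH": ("pregnant_woman", "household_head"),
    "PW:MIL": ("pregnant_woman", "mother_in_law"),
    "MIL:HH": ("mother_in_law", "household_head"),
}

LOG_MPA_OUTLIER_THRESHOLD = -8.0


def food_share(grams_a: float, grams_b: float) -> float | None:
    """Gram-intake ratio a/b for one food group; None unless both ate any."""
    if grams_a < 0 or grams_b < 0:
        raise ValueError("food-group grams cannot be negative")
    if grams_a == 0 or grams_b == 0:
        return None
    return grams_a / grams_b


def fs_es(food_a: float, kcal_a: float, food_b: float, kcal_b: float) -> float:
    """Food-share-to-energy-share: (food_a/kcal_a) / (food_b/kcal_b)."""
    if kcal_a <= 0 or kcal_b <= 0:
        raise ValueError("energy intakes must be positive for FS:ES")
    if food_a <= 0 or food_b <= 0:
        raise ValueError("FS:ES requires both food intakes positive")
    return (food_a / kcal_a) / (food_b / kcal_b)


def rdear(intake_a: float, ear_a: float, intake_b: float, ear_b: float) -> float:
    """Relative dietary energy adequacy ratio (intake_a/EAR_a)/(intake_b/EAR_b)."""
    if ear_a <= 0 or ear_b <= 0:
        raise ValueError("energy EARs must be positive")
    if intake_a <= 0 or intake_b <= 0:
        raise ValueError("energy intakes must be positive")
    return (intake_a / ear_a) / (intake_b / ear_b)


def mpa_ratio(mpa_a: float, mpa_b: float) -> float:
    """Ratio of mean probabilities of adequacy, MPA_a / MPA_b."""
    if mpa_b <= 0:
        raise ValueError("MPA ratio undefined: denominator MPA is zero")
    return mpa_a / mpa_b


def dd_ratio_terms(score_a: int, score_b: int, kcal_a: float, kcal_b: float):
    """Dietary-diversity ratio and its energy-adjusted log version.

    Returns ``(ratio, log_ratio, log_ratio_energy_adjusted)`` where the
    adjusted version subtracts the log energy ratio (the analogue of
    FS:ES for a unitless score).  None entries when either score is zero.
    """
    if kcal_a <= 0 or kcal_b <= 0:
        raise ValueError("energy intakes must be positive")
    if score_a <= 0 or score_b <= 0:
        return None, None, None
    ratio = score_a / score_b
    log_ratio = math.log(ratio)
    return ratio, log_ratio, log_ratio - math.log(kcal_a / kcal_b)


def classify_disparity(
    adequacy_a: float, adequacy_b: float, low: float = 0.90, high: float = 1.10
) -> bool:
    """Flag a household where member a eats under ``low`` x EAR while
    member b eats over ``high`` x EAR."""
    if adequacy_a < 0 or adequacy_b < 0:
        raise ValueError("adequacy fractions cannot be negative")
    return adequacy_a < low and adequacy_b > high


@dataclass
class AllocationRatios:
    """All pairwise ratios for one household and one member pair."""

    household_id: str
    pair: str
    fs: dict[str, float] = field(default_factory=dict)
    fs_es: dict[str, float] = field(default_factory=dict)
    rdear: float | None = None
    mpa_ratio: float | None = None
    dd_ratio: float | None = None
    log_dd_ratio_adj: float | None = None
    excluded_mpa_outlier: bool = False

    @property
    def log_fs(self) -> dict[str, float]:
        return {g: math.log(v) for g, v in self.fs.items()}

    @property
    def log_fs_es(self) -> dict[str, float]:
        return {g: math.log(v) for g, v in self.fs_es.items()}

    @property
    def log_rdear(self) -> float | None:
        return None if self.rdear is None else math.log(self.rdear)

    @property
    def log_mpa_ratio(self) -> float | None:
        return None if self.mpa_ratio is None else math.log(self.mpa_ratio)

    @property
    def log_dd_ratio(self) -> float | None:
        return None if self.dd_ratio is None else math.log(self.dd_ratio)


def household_ratios(
    household_id: str,
    members_by_role: dict[str, str],
    group_grams: pd.DataFrame,
    energy: pd.Series,
    energy_ears: pd.Series,
    mpas: pd.Series | None = None,
    mddw_scores: pd.Series | None = None,
    pairs: tuple[str, ...] = PAIRS,
) -> list[AllocationRatios]:
    """Compute :class:`AllocationRatios` for the requested pairs.

    ``members_by_role`` maps role -> member_id for this household;
    ``group_grams`` is indexed by member_id with one column per food
    group (3-day mean grams); ``energy``/``energy_ears``/``mpas``/
    ``mddw_scores`` are indexed by member_id.
    """
    out = []
    for pair in pairs:
        role_a, role_b = _PAIR_ROLES[pair]
        a, b = members_by_role[role_a], members_by_role[role_b]
        kcal_a, kcal_b = float(energy[a]), float(energy[b])
        res = AllocationRatios(household_id, pair)
        for g in FOOD_GROUPS:
            ga = float(group_grams.loc[a, g]) if g in group_grams.columns else 0.0
            gb = float(group_grams.loc[b, g]) if g in group_grams.columns else 0.0
            share = food_share(ga, gb)
            if share is not None:
                res.fs[g] = share
                res.fs_es[g] = fs_es(ga, kcal_a, gb, kcal_b)
        res.rdear = rdear(kcal_a, float(energy_ears[a]), kcal_b, float(energy_ears[b]))
        if mpas is not None:
            res.mpa_ratio = mpa_ratio(float(mpas[a]), float(mpas[b]))
            log_mpa = res.log_mpa_ratio
            res.excluded_mpa_outlier = (
                log_mpa is not None and log_mpa < LOG_MPA_OUTLIER_THRESHOLD
            )
        if mddw_scores is not None:
            ratio, _, adj = dd_ratio_terms(
                int(mddw_scores[a]), int(mddw_scores[b]), kcal_a, kcal_b
            )
            res.dd_ratio = ratio
            res.log_dd_ratio_adj = adj
        out.append(res)
    return out


def ratios_frame(ratios: list[AllocationRatios]) -> pd.DataFrame:
    """Wide table: one row per household x pair, NaN for absent ratios."""
    rows = []
    for r in ratios:
        row: dict[str, object] = {
            "household_id": r.household_id,
            "pair": r.pair,
            "rdear": r.rdear,
            "log_rdear": r.log_rdear,
            "mpa_ratio": r.mpa_ratio,
            "log_mpa_ratio": r.log_mpa_ratio,
            "dd_ratio": r.dd_ratio,
            "log_dd_ratio": r.log_dd_ratio,
            "log_dd_ratio_adj": r.log_dd_ratio_adj,
            "excluded_mpa_outlier": r.excluded_mpa_outlier,
        }
        for g in FOOD_GROUPS:
            row[f"fs_{g}"] = r.fs.get(g, np.nan)
            row[f"fs_es_{g}"] = r.fs_es.get(g, np.nan)
            row[f"log_fs_{g}"] = r.log_fs.get(g, np.nan)
            row[f"log_fs_es_{g}"] = r.log_fs_es.get(g, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
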