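"""Nutrient engine: portions -> daily intakes, food-group grams, MDD-W.

Intakes are totalled linearly from a food-composition table (FCT) giving
per-100 g values for energy, protein and the 11 micronutrients assessed
by the probability-of-adequacy method.  No nutrient retention factors are
applied; composition values are used as reported.

The minimum dietary diversity score for women (MDD-W) counts how many of
10 defined food groups were consumed in the 24 h covered by the *first*
recall (the reference period for which the indicator was validated); a
score of at least 5 is classified "adequate".  Alcohol is tracked as an
eleventh group for descriptive reporting but never enters the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import RecallVisit

__all__ = [
    "NUTRIENTS",
    "MICRONUTRIENTS",
    "MDDW_GROUPS",
    "FOOD_GROUPS",
    "FoodComposition",
    "IntakeProfile",
    "fct_frame",
    "average_recipes",
    "portions_to_intake",
    "build_profile",
    "build_profiles",
]

#: Column order of every nutrient vector (per 100 g in the FCT, per day in
#: intake totals).
NUTRIENTS = (
    "energy_kcal",
    "protein_g",
    "vit_c_mg",
    "vit_a_re",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_mg",
    "vit_b6_mg",
    "folate_ug",
    "vit_b12_ug",
    "iron_mg",
    "zinc_mg",
    "calcium_mg",
)

#: The 11 micronutrients entering the mean probability of adequacy.
MICRONUTRIENTS = NUTRIENTS[2:]

#: The ten MDD-W food groups, in the conventional order.
MDDW_GROUPS = (
    "grains_roots_tubers",
    "pulses",
    "nuts_seeds",
    "dairy",
    "flesh_foods",
    "eggs",
    "green_leafy_veg",
    "vit_a_fruit_veg",
    "other_veg",
    "other_fruit",
)

#: All tracked groups: the MDD-W ten plus alcohol (reported, never scored).
FOOD_GROUPS = MDDW_GROUPS + ("alcohol",)

MDDW_THRESHOLD = 5


@dataclass
class FoodComposition:
    """Per-100 g composition of one food code."""

    food_code: str
    name: str
    mddw_group: str
    per_100g: dict[str, float]

    def __post_init__(self) -> None:
        if self.mddw_group not in FOOD_GROUPS + ("other",):
            raise ValueError(
                f"food {self.food_code}: unknown group {self.mddw_group!r}"
            )
        missing = [n for n in NUTRIENTS if n not in self.per_100g]
        if missing:
            raise ValueError(f"food {self.food_code}: missing nutrients {missing}")
        bad = [n for n in NUTRIENTS if self.per_100g[n] < 0]
        if bad:
            raise ValueError(f"food {self.food_code}: negative values for {bad}")


def fct_frame(fct: Sequence[FoodComposition] | pd.DataFrame) -> pd.DataFrame:
    """Food-composition table as a DataFrame indexed by food code."""
    if isinstance(fct, pd.DataFrame):
        return fct
    rows = {f.food_code: {"name": f.name, "mddw_group": f.mddw_group, **f.per_100g} for f in fct}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "food_code"
    return df[["name", "mddw_group", *NUTRIENTS]]


def average_recipes(
    observations: Sequence[Mapping[str, float]],
    food_code: str = "dish",
    name: str = "mixed dish",
    mddw_group: str = "other",
) -> FoodComposition:
    """Average several per-100 g composition observations of one dish.

    Mixed dishes (curries, dal preparations, fried snacks) vary between
    households; the study convention is the element-wise arithmetic mean
    over all collected recipe observations.
    """
    if len(observations) == 0:
        raise ValueError("average_recipes requires at least one observation")
    mat = pd.DataFrame(list(observations))[list(NUTRIENTS)]
    mean = mat.mean(axis=0)
    return FoodComposition(food_code, name, mddw_group, mean.to_dict())


def portions_to_intake(
    visit: RecallVisit, fct: Sequence[FoodComposition] | pd.DataFrame
) -> pd.Series:
    """Total nutrient intake for one recall: sum of grams/100 x per-100 g."""
    table = fct_frame(fct)
    total = pd.Series(0.0, index=list(NUTRIENTS))
    for p in visit.portions:
        if p.food_code not in table.index:
            raise KeyError(f"food code {p.food_code!r} not in food composition table")
        total = total + (p.grams / 100.0) * table.loc[p.food_code, list(NUTRIENTS)].astype(float)
    return total


@dataclass
class IntakeProfile:
    """Per-member intake summary over the recall period.

    ``visit_nutrients`` holds one nutrient vector per available visit;
    ``mean_nutrients`` is their arithmetic mean.  ``group_grams`` is the
    mean daily grams per food group over the recall period, and
    ``consumed_any`` flags groups eaten on *any* visit.  The MDD-W score
    uses visit 1 only.
    """

    member_id: str
    visit_nutrients: pd.DataFrame  # index: visit_index, columns: NUTRIENTS
    mean_nutrients: pd.Series
    group_grams: pd.Series  # index: FOOD_GROUPS
    consumed_any: pd.Series  # bool per FOOD_GROUPS
    mddw_score: int
    mddw_adequate: bool


def _group_grams_one_visit(visit: RecallVisit, table: pd.DataFrame) -> pd.Series:
    g = pd.Series(0.0, index=list(FOOD_GROUPS))
    for p in visit.portions:
        if p.food_code not in table.index:
            raise KeyError(f"food code {p.food_code!r} not in food composition table")
        grp = table.loc[p.food_code, "mddw_group"]
        if grp in g.index:
            g[grp] += p.grams
    return g


def build_profile(
    visits: Sequence[RecallVisit], fct: Sequence[FoodComposition] | pd.DataFrame
) -> IntakeProfile:
    """Summarise 1-3 recall visits for one member."""
    if len(visits) == 0:
        raise ValueError("build_profile requires at least one visit")
    member_ids = {v.member_id for v in visits}
    if len(member_ids) != 1:
        raise ValueError(f"visits span multiple members: {sorted(member_ids)}")
    member_id = visits[0].member_id

    table = fct_frame(fct)
    ordered = sorted(visits, key=lambda v: v.visit_index)
    nut = pd.DataFrame(
        {v.visit_index: portions_to_intake(v, table) for v in ordered}
    ).T
    nut.index.name = "visit_index"

    grams = pd.DataFrame(
        {v.visit_index: _group_grams_one_visit(v, table) for v in ordered}
    ).T
    group_grams = grams.mean(axis=0)
    consumed_any = (grams > 0).any(axis=0)

    first = [v for v in ordered if v.visit_index == 1]
    if first:
        g1 = _group_grams_one_visit(first[0], table)
        score = int((g1[list(MDDW_GROUPS)] > 0).sum())
    else:
        score = 0
    return IntakeProfile(
        member_id=member_id,
        visit_nutrients=nut,
        mean_nutrients=nut.mean(axis=0),
        group_grams=group_grams,
        consumed_any=consumed_any,
        mddw_score=score,
        mddw_adequate=score >= MDDW_THRESHOLD,
    )


def visits_to_frame(visits: Iterable[RecallVisit]) -> pd.DataFrame:
    """Flatten visits into a long portion table (one row per portion)."""
    rows = []
    for v in visits:
        for p in v.portions:
            rows.append(
                (v.member_id, v.visit_index, p.food_code, p.grams, p.hour, p.location)
            )
    return pd.DataFrame(
        rows, columns=["member_id", "visit_index", "food_code", "grams", "hour", "location"]
    )


def intake_table(
    visits: Iterable[RecallVisit], fct: Sequence[FoodComposition] | pd.DataFrame
) -> pd.DataFrame:
    """Vectorised per-visit nutrient totals for many members at once.

    Returns a DataFrame indexed by (member_id, visit_index) with one column
    per nutrient.  Equivalent to calling :func:`portions_to_intake` per
    visit; used by the pipeline where thousands of portions are involved.
    """
    table = fct_frame(fct)
    long = visits_to_frame(visits)
    if long.empty:
        return pd.DataFrame(columns=list(NUTRIENTS))
    unknown = set(long["food_code"]) - set(table.index)
    if unknown:
        raise KeyError(f"food codes not in food composition table: {sorted(unknown)}")
    merged = long.merge(
        table[list(NUTRIENTS)], left_on="food_code", right_index=True, how="left"
    )
    contrib = merged[list(NUTRIENTS)].multiply(merged["grams"] / 100.0, axis=0)
    contrib[["member_id", "visit_index"]] = merged[["member_id", "visit_index"]]
    return contrib.groupby(["member_id", "visit_index"]).sum()


def build_profiles(
    visits: Iterable[RecallVisit], fct: Sequence[FoodComposition] | pd.DataFrame
) -> dict[str, IntakeProfile]:
    """Group visits by member and build one profile per member."""
    by_member: dict[str, list[RecallVisit]] = {}
    for v in visits:
        by_member.setdefault(v.member_id, []).append(v)
    table = fct_frame(fct)
    return {mid: build_profile(vs, table) for mid, vs in by_member.items()}
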