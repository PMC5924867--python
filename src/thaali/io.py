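"""CSV interchange for households, members, recall portions and the FCT.

All tables are UTF-8, comma-separated, with a header row.  Schemas:

``households.csv``
    household_id, cluster_id, stratum, earnings_parity, gravidity,
    empowerment, asset_score, husband_overseas, caste_group, season
``members.csv``
    member_id, household_id, role, sex, age, body_weight,
    gestational_age (empty unless pregnant), activity_level,
    illness_any, fasting_any
``recalls.csv``
    one row per portion: member_id, visit_index, proxy_respondent,
    food_code, grams, hour, location
``fct.csv``
    food_code, name, mddw_group, then one column per nutrient (per 100 g)

Booleans are written as ``True``/``False``.  Readers validate field
levels and referential integrity and raise
:class:`~thaali.records.ValidationError` naming the offending row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .nutrients import NUTRIENTS, FoodComposition, fct_frame
from .records import (
    HouseholdRecord,
    MemberRecord,
    PortionRecord,
    RecallVisit,
    ValidationError,
    validate_tables,
)

__all__ = [
    "read_households",
    "read_members",
    "read_recalls",
    "read_fct",
    "read_tables",
    "write_households",
    "write_members",
    "write_recalls",
    "write_fct",
    "write_tables",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _to_bool(value, context: str) -> bool:
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValidationError(f"{context}: cannot parse boolean {value!r}")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_households(path) -> list[HouseholdRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df,
        [
            "household_id", "cluster_id", "stratum", "earnings_parity",
            "gravidity", "empowerment", "asset_score", "husband_overseas",
            "caste_group", "season",
        ],
        path,
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                HouseholdRecord(
                    household_id=row.household_id,
                    cluster_id=row.cluster_id,
                    stratum=row.stratum,
                    earnings_parity=_to_bool(row.earnings_parity, f"{path} row {i}"),
                    gravidity=row.gravidity,
                    empowerment=int(float(row.empowerment)),
                    asset_score=float(row.asset_score),
                    husband_overseas=_to_bool(row.husband_overseas, f"{path} row {i}"),
                    caste_group=row.caste_group,
                    season=row.season,
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path} row {i}: {err}") from err
    return out


def read_members(path) -> list[MemberRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df,
        [
            "member_id", "household_id", "role", "sex", "age", "body_weight",
            "gestational_age", "activity_level", "illness_any", "fasting_any",
        ],
        path,
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ga = row.gestational_age.strip()
            out.append(
                MemberRecord(
                    member_id=row.member_id,
                    household_id=row.household_id,
                    role=row.role,
                    sex=row.sex,
                    age=float(row.age),
                    body_weight=float(row.body_weight),
                    gestational_age=float(ga) if ga else None,
                    activity_level=row.activity_level,
                    illness_any=_to_bool(row.illness_any, f"{path} row {i}"),
                    fasting_any=_to_bool(row.fasting_any, f"{path} row {i}"),
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path} row {i}: {err}") from err
    return out


def read_recalls(path) -> list[RecallVisit]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df,
        ["member_id", "visit_index", "proxy_respondent", "food_code", "grams",
         "hour", "location"],
        path,
    )
    visits: dict[tuple[str, int], RecallVisit] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            key = (row.member_id, int(row.visit_index))
            if key not in visits:
                visits[key] = RecallVisit(
                    member_id=row.member_id,
                    visit_index=int(row.visit_index),
                    proxy_respondent=_to_bool(row.proxy_respondent, f"{path} row {i}"),
                )
            visits[key].portions.append(
                PortionRecord(
                    food_code=row.food_code,
                    grams=float(row.grams),
                    hour=int(float(row.hour)),
                    location=row.location,
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path} row {i}: {err}") from err
    return list(visits.values())


def read_fct(path) -> list[FoodComposition]:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["food_code", "name", "mddw_group", *NUTRIENTS], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            per = {n: float(getattr(row, n)) for n in NUTRIENTS}
            out.append(FoodComposition(row.food_code, row.name, row.mddw_group, per))
        except ValueError as err:
            raise ValidationError(f"{path} row {i}: {err}") from err
    return out


def read_tables(paths: Mapping[str, object]):
    """Read and cross-validate the three survey tables.

    ``paths`` maps ``households``/``members``/``recalls`` to CSV paths.
    Returns the validated record lists.
    """
    for key in ("households", "members", "recalls"):
        if key not in paths:
            raise ValidationError(f"read_tables: missing path for {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"input table not found: {paths[key]}")
    households = read_households(paths["households"])
    members = read_members(paths["members"])
    visits = read_recalls(paths["recalls"])
    validate_tables(households, members, visits)
    return households, members, visits


def write_households(households: Iterable[HouseholdRecord], path) -> None:
    rows = [
        {
            "household_id": h.household_id,
            "cluster_id": h.cluster_id,
            "stratum": h.stratum,
            "earnings_parity": h.earnings_parity,
            "gravidity": h.gravidity,
            "empowerment": h.empowerment,
            "asset_score": repr(h.asset_score),
            "husband_overseas": h.husband_overseas,
            "caste_group": h.caste_group,
            "season": h.season,
        }
        for h in households
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_members(members: Iterable[MemberRecord], path) -> None:
    rows = [
        {
            "member_id": m.member_id,
            "household_id": m.household_id,
            "role": m.role,
            "sex": m.sex,
            "age": repr(m.age),
            "body_weight": repr(m.body_weight),
            "gestational_age": "" if m.gestational_age is None else repr(m.gestational_age),
            "activity_level": m.activity_level,
            "illness_any": m.illness_any,
            "fasting_any": m.fasting_any,
        }
        for m in members
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_recalls(visits: Iterable[RecallVisit], path) -> None:
    rows = []
    for v in visits:
        for p in v.portions:
            rows.append(
                {
                    "member_id": v.member_id,
                    "visit_index": v.visit_index,
                    "proxy_respondent": v.proxy_respondent,
                    "food_code": p.food_code,
                    "grams": repr(p.grams),
                    "hour": p.hour,
                    "location": p.location,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fct(fct, path) -> None:
    fct_frame(fct).reset_index().to_csv(path, index=False)


def write_tables(households, members, visits, out_dir) -> dict[str, Path]:
    """Write the three survey tables into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "households": out / "households.csv",
        "members": out / "members.csv",
        "recalls": out / "recalls.csv",
    }
    write_households(households, paths["households"])
    write_members(members, paths["members"])
    write_recalls(visits, paths["recalls"])
    return paths
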