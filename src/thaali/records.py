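"""Domain records for household dietary-recall studies.

The study design is a fixed triad: each household contributes exactly one
pregnant woman, one mother-in-law and one male household head, sampled
within village-level clusters.  Each member answers up to three 24-hour
dietary recalls on non-consecutive days; every food portion reported is a
:class:`PortionRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ROLES",
    "CASTE_GROUPS",
    "SEASONS",
    "ACTIVITY_LEVELS",
    "ValidationError",
    "HouseholdRecord",
    "MemberRecord",
    "PortionRecord",
    "RecallVisit",
    "validate_tables",
]

ROLES = ("pregnant_woman", "mother_in_law", "household_head")
CASTE_GROUPS = ("disadvantaged", "middle", "least_disadvantaged")
SEASONS = ("pre_monsoon", "monsoon")
ACTIVITY_LEVELS = ("sedentary", "moderate", "heavy")
GRAVIDITY_LEVELS = ("0", "1+")


class ValidationError(ValueError):
    """Raised when an input record violates a structural constraint."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class HouseholdRecord:
    """One joint household and its hypothesised allocation determinants.

    ``earnings_parity`` is True when the pregnant woman earns the same or
    more cash than her spouse; ``gravidity`` distinguishes first pregnancies
    ("0") from women with at least one previous pregnancy ("1+"), a proxy
    for household seniority.  ``asset_score`` is a wealth index (e.g. the
    first principal component of asset indicators) consumed as-is.
    """

    household_id: str
    cluster_id: str
    stratum: str = "S1"
    earnings_parity: bool = False
    gravidity: str = "1+"
    empowerment: int = 5
    asset_score: float = 0.0
    husband_overseas: bool = False
    caste_group: str = "disadvantaged"
    season: str = "pre_monsoon"

    def __post_init__(self) -> None:
        _check(
            0 <= int(self.empowerment) <= 10,
            f"household {self.household_id}: empowerment {self.empowerment} "
            "outside 0-10",
        )
        _check(
            self.gravidity in GRAVIDITY_LEVELS,
            f"household {self.household_id}: unknown gravidity "
            f"{self.gravidity!r}",
        )
        _check(
            self.caste_group in CASTE_GROUPS,
            f"household {self.household_id}: unknown caste_group "
            f"{self.caste_group!r}",
        )
        _check(
            self.season in SEASONS,
            f"household {self.household_id}: unknown season {self.season!r}",
        )


@dataclass
class MemberRecord:
    """One household member in one of the three study roles."""

    member_id: str
    household_id: str
    role: str
    sex: str
    age: float
    body_weight: float
    activity_level: str
    gestational_age: float | None = None
    illness_any: bool = False
    fasting_any: bool = False

    def __post_init__(self) -> None:
        _check(self.role in ROLES, f"member {self.member_id}: unknown role {self.role!r}")
        _check(
            self.activity_level in ACTIVITY_LEVELS,
            f"member {self.member_id}: unknown activity_level "
            f"{self.activity_level!r}",
        )
        _check(
            self.body_weight > 0,
            f"member {self.member_id}: body_weight must be positive",
        )
        if self.role == "pregnant_woman":
            _check(
                self.gestational_age is not None,
                f"member {self.member_id}: pregnant_woman requires "
                "gestational_age",
            )
        else:
            _check(
                self.gestational_age is None,
                f"member {self.member_id}: gestational_age only valid for "
                "pregnant_woman",
            )


@dataclass
class PortionRecord:
    """A single food portion reported on one recall day."""

    food_code: str
    grams: float
    hour: int = 12
    location: str = "home"

    def __post_init__(self) -> None:
        _check(self.grams >= 0, f"portion {self.food_code}: negative grams")
        _check(0 <= self.hour <= 23, f"portion {self.food_code}: hour {self.hour} outside 0-23")
        _check(
            self.location in ("home", "outside"),
            f"portion {self.food_code}: unknown location {self.location!r}",
        )


@dataclass
class RecallVisit:
    """One 24-hour recall (visit 1-3) for one member."""

    member_id: str
    visit_index: int
    portions: list[PortionRecord] = field(default_factory=list)
    proxy_respondent: bool = False

    def __post_init__(self) -> None:
        _check(
            self.visit_index in (1, 2, 3),
            f"visit for {self.member_id}: visit_index {self.visit_index} "
            "outside 1-3",
        )


def validate_tables(
    households: Sequence[HouseholdRecord],
    members: Sequence[MemberRecord],
    visits: Sequence[RecallVisit],
) -> None:
    """Check referential integrity and the fixed-triad design.

    Raises :class:`ValidationError` on duplicate identifiers, dangling
    references, duplicated (member, visit) pairs, or households whose
    member roles deviate from the one-per-role triad.
    """
    hh_ids = [h.household_id for h in households]
    _check(len(hh_ids) == len(set(hh_ids)), "duplicate household_id values")
    hh_set = set(hh_ids)

    member_ids = [m.member_id for m in members]
    _check(len(member_ids) == len(set(member_ids)), "duplicate member_id values")
    member_set = set(member_ids)

    roles_by_hh: dict[str, list[str]] = {}
    for m in members:
        _check(
            m.household_id in hh_set,
            f"member {m.member_id} references unknown household {m.household_id}",
        )
        roles_by_hh.setdefault(m.household_id, []).append(m.role)
    for hid, roles in roles_by_hh.items():
        _check(
            sorted(roles) == sorted(ROLES),
            f"household {hid}: expected exactly one member per role, got {roles}",
        )

    seen: set[tuple[str, int]] = set()
    for v in visits:
        _check(
            v.member_id in member_set,
            f"visit references unknown member {v.member_id}",
        )
        key = (v.member_id, v.visit_index)
        _check(key not in seen, f"duplicate visit {key}")
        seen.add(key)
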