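"""Synthetic study generator with known ground truth.

Emulates a cluster-sampled dietary survey of joint households in the
Nepali Terai: each household contributes a pregnant woman (third
trimester), her mother-in-law and the male household head, and each
member answers three 24-h recalls on non-consecutive days.

The generator works top-down so that downstream estimates are sharply
testable: it first draws each member's *true usual energy intake* as

    energy = energy_EAR(member) x exp(role adequacy mean
                                      + covariate effects
                                      + cluster effect + individual effect)

then draws day-level energies with log-normal within-person noise, and
finally lays out food portions whose grams are scaled so each recall's
summed energy matches its day target exactly.  Because effects are
injected on the log energy-adequacy scale, the configured mean log-RDEAR
per member pair holds by construction regardless of the simulated body
weights, and covariate effects (e.g. earnings parity) appear as additive
shifts on the pregnant woman's log adequacy.  Covariate effects are
centred at their realised sample means so the marginal mean log-RDEAR
equals the configured truth whether or not effects are switched on.

Micronutrient intakes are not separately controlled: they follow from
which foods carry the energy, which is what links the adequacy stage to
realistic food-composition structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adequacy import EnergyRequirementConfig, default_energy_config, energy_ear
from .nutrients import NUTRIENTS, FoodComposition
from .records import HouseholdRecord, MemberRecord, PortionRecord, RecallVisit

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationError",
    "generate_fct",
    "generate_households",
    "generate_recalls",
    "simulate_study",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror the emulated survey: 20 village clusters of 8 joint
    households (160 total), mean log-RDEAR of -0.20 for the pregnant
    woman vs the household head and -0.15 vs the mother-in-law, and an
    earnings-parity effect of +0.27 on the pregnant woman's log energy
    adequacy.  Noise components are log-scale SDs: 0.1 between clusters,
    0.2 between individuals, 0.25 within person between days.
    """

    n_clusters: int = 20
    households_per_cluster: int = 8
    seed: int = 0
    true_log_rdear_mean: dict = field(
        default_factory=lambda: {"PW:HH": -0.20, "PW:MIL": -0.15}
    )
    earnings_effect: float = 0.27
    hh_kcal_effect_on_log_mpa_ratio: float = 0.0
    sd_cluster: float = 0.10
    sd_individual: float = 0.20
    sd_day: float = 0.25
    mean_log_adequacy_head: float = 0.13
    n_strata: int = 2
    covariate_prevalences: dict = field(
        default_factory=lambda: {
            "earnings_parity": 0.25,
            "gravidity_1plus": 0.68,
            "husband_overseas": 0.20,
            "season_monsoon": 0.50,
            "caste_middle": 0.43,
            "caste_least_disadvantaged": 0.21,
        }
    )

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.households_per_cluster < 1:
            raise ValueError("counts must be at least 1")
        for name in ("sd_cluster", "sd_individual", "sd_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for k, p in self.covariate_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence {k} outside [0, 1]")
        for pair in ("PW:HH", "PW:MIL"):
            if pair not in self.true_log_rdear_mean:
                raise ValueError(f"true_log_rdear_mean missing pair {pair}")


@dataclass
class GroundTruth:
    """Realised truth stored alongside every simulated dataset."""

    members: pd.DataFrame    # index member_id: role, household_id, cluster_id,
                             # energy_ear, true_log_adequacy, true_usual_energy
    households: pd.DataFrame  # index household_id: true_log_rdear_pw_hh,
                              # true_log_rdear_pw_mil, true_log_rdear_mil_hh
    config: SimulationConfig

    def true_log_rdear(self, pair: str) -> pd.Series:
        key = {"PW:HH": "true_log_rdear_pw_hh",
               "PW:MIL": "true_log_rdear_pw_mil",
               "MIL:HH": "true_log_rdear_mil_hh"}[pair]
        return self.households[key]


# ---------------------------------------------------------------------------
# food composition

# (name, group, energy, protein, vitC, vitA_RE, thiamin, riboflavin, niacin,
#  B6, folate, B12, iron, zinc, calcium) per 100 g, plus typical portion
# median grams.  Values are plausible FCT magnitudes for Terai foods.
_BASE_FOODS = [
    ("rice_cooked", "grains_roots_tubers", 130, 2.7, 0, 0, 0.02, 0.01, 0.4, 0.09, 4, 0, 0.2, 0.5, 10, 350),
    ("roti_wheat", "grains_roots_tubers", 265, 9.0, 0, 0, 0.30, 0.10, 3.0, 0.16, 30, 0, 2.5, 1.5, 30, 120),
    ("beaten_rice", "grains_roots_tubers", 350, 7.0, 0, 0, 0.20, 0.05, 2.5, 0.10, 10, 0, 2.0, 1.0, 12, 60),
    ("potato_curry", "grains_roots_tubers", 95, 2.0, 10, 2, 0.08, 0.03, 1.1, 0.25, 12, 0, 0.7, 0.4, 12, 120),
    ("dal_lentil", "pulses", 105, 6.5, 1, 1, 0.12, 0.05, 0.6, 0.15, 60, 0, 1.8, 1.0, 20, 130),
    ("chickpea_curry", "pulses", 160, 8.0, 2, 2, 0.15, 0.07, 0.7, 0.20, 90, 0, 2.8, 1.5, 45, 80),
    ("peanut_roasted", "nuts_seeds", 585, 26.0, 0, 0, 0.45, 0.10, 13.0, 0.30, 110, 0, 2.2, 3.3, 55, 25),
    ("sesame_seeds", "nuts_seeds", 570, 17.0, 0, 1, 0.70, 0.25, 4.5, 0.40, 100, 0, 14.5, 7.8, 975, 15),
    ("buffalo_milk", "dairy", 100, 3.8, 2, 50, 0.05, 0.14, 0.1, 0.03, 6, 0.4, 0.1, 0.5, 170, 180),
    ("curd_dahi", "dairy", 65, 3.5, 1, 30, 0.04, 0.16, 0.1, 0.04, 7, 0.4, 0.1, 0.6, 130, 120),
    ("goat_meat_curry", "flesh_foods", 180, 20.0, 0, 10, 0.10, 0.25, 5.5, 0.35, 8, 1.8, 3.0, 4.0, 15, 80),
    ("fish_curry", "flesh_foods", 140, 18.0, 0, 15, 0.05, 0.10, 3.5, 0.30, 10, 2.5, 1.5, 0.8, 60, 70),
    ("chicken_liver", "flesh_foods", 165, 24.0, 25, 3300, 0.30, 2.00, 11.0, 0.85, 580, 17.0, 9.0, 2.7, 10, 50),
    ("egg_boiled", "eggs", 155, 13.0, 0, 160, 0.07, 0.50, 0.1, 0.12, 47, 1.1, 1.8, 1.1, 50, 50),
    ("spinach_saag", "green_leafy_veg", 35, 3.0, 30, 470, 0.08, 0.20, 0.7, 0.20, 150, 0, 3.0, 0.6, 100, 70),
    ("mustard_greens", "green_leafy_veg", 30, 2.7, 60, 300, 0.07, 0.10, 0.6, 0.15, 90, 0, 2.5, 0.4, 110, 70),
    ("mango_ripe", "vit_a_fruit_veg", 65, 0.6, 35, 55, 0.04, 0.05, 0.6, 0.12, 40, 0, 0.2, 0.1, 11, 150),
    ("pumpkin_curry", "vit_a_fruit_veg", 40, 1.0, 10, 250, 0.05, 0.08, 0.5, 0.06, 16, 0, 0.8, 0.3, 20, 100),
    ("carrot", "vit_a_fruit_veg", 40, 0.9, 6, 835, 0.07, 0.06, 1.0, 0.14, 19, 0, 0.3, 0.2, 33, 60),
    ("pointed_gourd_curry", "other_veg", 45, 2.0, 25, 25, 0.05, 0.06, 0.5, 0.04, 15, 0, 1.7, 0.5, 30, 110),
    ("onion_raw", "other_veg", 40, 1.1, 7, 0, 0.05, 0.03, 0.1, 0.12, 19, 0, 0.2, 0.2, 23, 30),
    ("cauliflower_curry", "other_veg", 55, 2.5, 45, 2, 0.06, 0.06, 0.5, 0.18, 57, 0, 0.9, 0.3, 25, 100),
    ("banana", "other_fruit", 90, 1.1, 9, 3, 0.03, 0.07, 0.7, 0.37, 20, 0, 0.3, 0.2, 5, 100),
    ("guava", "other_fruit", 70, 2.6, 230, 30, 0.07, 0.04, 1.1, 0.11, 49, 0, 0.3, 0.2, 18, 100),
    ("tea_milk_sugar", "other", 45, 0.8, 0, 10, 0.01, 0.03, 0.1, 0.01, 1, 0.1, 0.1, 0.1, 35, 150),
    ("fried_snack", "other", 450, 6.0, 1, 5, 0.10, 0.05, 1.5, 0.08, 20, 0, 1.5, 0.8, 25, 80),
    ("raksi_alcohol", "alcohol", 220, 0.1, 0, 0, 0.01, 0.01, 0.1, 0.01, 1, 0, 0.1, 0.1, 5, 150),
]

#: Typical portion median grams keyed by food code (log-normal median).
PORTION_MEDIANS = {row[0]: float(row[-1]) for row in _BASE_FOODS}
PORTION_SIGMA = 0.4

# daily probability that a member of each role eats from each food group
_GROUP_USE_PROBS = {
    #                      PW    MIL   HH
    "grains_roots_tubers": (1.00, 1.00, 1.00),
    "pulses":              (0.90, 0.90, 0.85),
    "nuts_seeds":          (0.12, 0.14, 0.14),
    "dairy":               (0.55, 0.50, 0.60),
    "flesh_foods":         (0.13, 0.13, 0.21),
    "eggs":                (0.06, 0.07, 0.12),
    "green_leafy_veg":     (0.35, 0.35, 0.33),
    "vit_a_fruit_veg":     (0.38, 0.38, 0.33),
    "other_veg":           (0.92, 0.92, 0.90),
    "other_fruit":         (0.11, 0.09, 0.10),
    "alcohol":             (0.00, 0.00, 0.03),
    "other":               (0.50, 0.50, 0.60),
}
_ROLE_COL = {"pregnant_woman": 0, "mother_in_law": 1, "household_head": 2}


def generate_fct(seed: int = 0, jitter_sd: float = 0.03) -> list[FoodComposition]:
    """Food-composition table for the synthetic study.

    27 foods covering every MDD-W group plus alcohol, with at least one
    rich source of each of the 11 micronutrients (e.g. chicken liver for
    vitamin A/B12/iron, guava for vitamin C, sesame for calcium/zinc).
    A small log-normal jitter (seeded) individualises the table between
    runs while keeping all values positive.
    """
    rng = np.random.default_rng(seed)
    out = []
    for row in _BASE_FOODS:
        code, group = row[0], row[1]
        values = np.asarray(row[2:-1], dtype=float)
        jitter = np.exp(rng.normal(0.0, jitter_sd, size=values.size))
        per = dict(zip(NUTRIENTS, values * jitter))
        out.append(FoodComposition(code, code.replace("_", " "), group, per))
    return out


def food_use_probs(fct: list[FoodComposition]) -> pd.DataFrame:
    """Daily consumption probability per food x role.

    The group-level probability is split evenly across foods in the
    group, except the staple (cooked rice), eaten every day by everyone.
    """
    foods = pd.DataFrame(
        {"food_code": [f.food_code for f in fct], "group": [f.mddw_group for f in fct]}
    )
    cols = {}
    for role, j in _ROLE_COL.items():
        probs = []
        for _, row in foods.iterrows():
            gp = _GROUP_USE_PROBS.get(row["group"], (0.1, 0.1, 0.1))[j]
            n_in_group = int((foods["group"] == row["group"]).sum())
            if row["food_code"] == "rice_cooked":
                probs.append(1.0)
            elif row["group"] == "grains_roots_tubers":
                # non-staple grains share the remaining grain variety
                probs.append(min(1.0, 0.45))
            else:
                probs.append(min(1.0, gp * 1.6 / n_in_group))
        cols[role] = probs
    return pd.DataFrame(cols, index=foods["food_code"])


# ---------------------------------------------------------------------------
# households and members


def _draw_members(rng, household_id):
    pw = MemberRecord(
        member_id=f"{household_id}-PW",
        household_id=household_id,
        role="pregnant_woman",
        sex="female",
        age=float(np.round(rng.normal(21.5, 3.0), 1)),
        body_weight=float(np.clip(np.round(rng.normal(50.0, 6.0), 1), 35.0, 80.0)),
        activity_level=str(rng.choice(["sedentary", "moderate"], p=[0.4, 0.6])),
        gestational_age=float(np.round(rng.uniform(32, 40), 1)),
        illness_any=bool(rng.random() < 0.13),
        fasting_any=bool(rng.random() < 0.10),
    )
    mil = MemberRecord(
        member_id=f"{household_id}-MIL",
        household_id=household_id,
        role="mother_in_law",
        sex="female",
        age=float(np.round(rng.normal(50.0, 6.0), 1)),
        body_weight=float(np.clip(np.round(rng.normal(48.0, 7.0), 1), 32.0, 85.0)),
        activity_level=str(rng.choice(["sedentary", "moderate"], p=[0.5, 0.5])),
        illness_any=bool(rng.random() < 0.12),
        fasting_any=bool(rng.random() < 0.13),
    )
    hh = MemberRecord(
        member_id=f"{household_id}-HH",
        household_id=household_id,
        role="household_head",
        sex="male",
        age=float(np.round(rng.normal(42.0, 12.0), 1)),
        body_weight=float(np.clip(np.round(rng.normal(55.0, 8.0), 1), 38.0, 95.0)),
        activity_level=str(
            rng.choice(["sedentary", "moderate", "heavy"], p=[0.2, 0.5, 0.3])
        ),
        illness_any=bool(rng.random() < 0.07),
        fasting_any=bool(rng.random() < 0.09),
    )
    return pw, mil, hh


def generate_households(
    config: SimulationConfig,
    energy_config: EnergyRequirementConfig | None = None,
) -> tuple[list[HouseholdRecord], list[MemberRecord], GroundTruth]:
    """Draw households, members and the true usual energy intakes."""
    rng = np.random.default_rng(config.seed)
    if energy_config is None:
        energy_config = default_energy_config()
    prev = config.covariate_prevalences

    households: list[HouseholdRecord] = []
    members: list[MemberRecord] = []
    triads: list[tuple[MemberRecord, MemberRecord, MemberRecord]] = []
    indiv_effects = []
    cluster_effects = []

    m_pw_hh = config.true_log_rdear_mean["PW:HH"]
    m_pw_mil = config.true_log_rdear_mean["PW:MIL"]
    a_hh = config.mean_log_adequacy_head
    a_pw_base = a_hh + m_pw_hh
    a_mil = a_pw_base - m_pw_mil

    p_caste_mid = prev.get("caste_middle", 0.43)
    p_caste_least = prev.get("caste_least_disadvantaged", 0.21)
    p_caste = [1.0 - p_caste_mid - p_caste_least, p_caste_mid, p_caste_least]

    hh_index = 0
    for c in range(config.n_clusters):
        cluster_id = f"C{c + 1:02d}"
        stratum = f"S{(c % max(config.n_strata, 1)) + 1}"
        u_cluster = rng.normal(0.0, config.sd_cluster)
        for _ in range(config.households_per_cluster):
            hh_index += 1
            household_id = f"H{hh_index:03d}"
            hrec = HouseholdRecord(
                household_id=household_id,
                cluster_id=cluster_id,
                stratum=stratum,
                earnings_parity=bool(rng.random() < prev.get("earnings_parity", 0.25)),
                gravidity="1+" if rng.random() < prev.get("gravidity_1plus", 0.68) else "0",
                empowerment=int(rng.binomial(10, 0.5)),
                asset_score=float(rng.normal(0.0, 1.0)),
                husband_overseas=bool(rng.random() < prev.get("husband_overseas", 0.20)),
                caste_group=str(
                    rng.choice(
                        ["disadvantaged", "middle", "least_disadvantaged"], p=p_caste
                    )
                ),
                season="monsoon"
                if rng.random() < prev.get("season_monsoon", 0.50)
                else "pre_monsoon",
            )
            households.append(hrec)
            triad = _draw_members(rng, household_id)
            triads.append(triad)
            members.extend(triad)
            indiv_effects.append(rng.normal(0.0, config.sd_individual, size=3))
            cluster_effects.append(u_cluster)

    # covariate effects on the pregnant woman's log adequacy, centred at
    # the realised covariate means so the marginal mean log-RDEAR equals
    # the configured truth in every realisation
    parity = np.array([h.earnings_parity for h in households], dtype=float)
    earn_shift = config.earnings_effect * (parity - parity.mean())

    truth_members = []
    truth_households = []
    base_adequacy = {
        "pregnant_woman": a_pw_base,
        "mother_in_law": a_mil,
        "household_head": a_hh,
    }
    ears = {
        mem.member_id: energy_ear(mem, energy_config)
        for triad in triads
        for mem in triad
    }
    adequacy_by_member: dict[str, float] = {}
    for i, (hrec, triad) in enumerate(zip(households, triads)):
        for j, mem in enumerate(triad):
            a = base_adequacy[mem.role] + indiv_effects[i][j]
            if mem.role == "pregnant_woman":
                a += earn_shift[i]
            adequacy_by_member[mem.member_id] = a

    # optional household-calorie covariate effect, applied to the pregnant
    # woman and centred at the realised mean household energy
    if config.hh_kcal_effect_on_log_mpa_ratio != 0.0:
        hh_kcal = np.array(
            [
                np.mean(
                    [
                        ears[m.member_id]
                        * np.exp(adequacy_by_member[m.member_id] + cluster_effects[i])
                        for m in triad
                    ]
                )
                for i, triad in enumerate(triads)
            ]
        ) / 1000.0
        shifts = config.hh_kcal_effect_on_log_mpa_ratio * (hh_kcal - hh_kcal.mean())
        for i, triad in enumerate(triads):
            adequacy_by_member[triad[0].member_id] += shifts[i]

    for i, (hrec, triad) in enumerate(zip(households, triads)):
        pw, mil, head = triad
        for mem in triad:
            a = adequacy_by_member[mem.member_id]
            truth_members.append(
                {
                    "member_id": mem.member_id,
                    "household_id": hrec.household_id,
                    "cluster_id": hrec.cluster_id,
                    "role": mem.role,
                    "energy_ear": ears[mem.member_id],
                    "true_log_adequacy": a,
                    "cluster_effect": cluster_effects[i],
                    "true_usual_energy": ears[mem.member_id]
                    * float(np.exp(a + cluster_effects[i])),
                }
            )
        truth_households.append(
            {
                "household_id": hrec.household_id,
                "true_log_rdear_pw_hh": adequacy_by_member[pw.member_id]
                - adequacy_by_member[head.member_id],
                "true_log_rdear_pw_mil": adequacy_by_member[pw.member_id]
                - adequacy_by_member[mil.member_id],
                "true_log_rdear_mil_hh": adequacy_by_member[mil.member_id]
                - adequacy_by_member[head.member_id],
            }
        )

    tm = pd.DataFrame(truth_members).set_index("member_id")
    th = pd.DataFrame(truth_households).set_index("household_id")
    return households, members, GroundTruth(tm, th, config)


# ---------------------------------------------------------------------------
# recalls

_MEAL_HOURS = np.array([7, 9, 11, 13, 16, 19, 21])
_MEAL_HOUR_P = np.array([0.18, 0.12, 0.22, 0.08, 0.10, 0.22, 0.08])
_OUTSIDE_P = {"pregnant_woman": 0.03, "mother_in_law": 0.10, "household_head": 0.30}
_PROXY_P = {"pregnant_woman": 0.0, "mother_in_law": 0.19, "household_head": 0.35}


def generate_recalls(
    config: SimulationConfig,
    members: list[MemberRecord],
    fct: list[FoodComposition],
    truth: GroundTruth,
    use_probs: pd.DataFrame | None = None,
) -> list[RecallVisit]:
    """Three recall visits per member, portion grams scaled to day targets."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    if use_probs is None:
        use_probs = food_use_probs(fct)
    codes = list(use_probs.index)
    energy_per_g = np.array(
        [next(f for f in fct if f.food_code == c).per_100g["energy_kcal"] / 100.0 for c in codes]
    )
    medians = np.array([PORTION_MEDIANS[c] for c in codes])
    visits: list[RecallVisit] = []
    for mem in members:
        probs = use_probs[mem.role].to_numpy()
        target_usual = float(truth.members.loc[mem.member_id, "true_usual_energy"])
        for visit_index in (1, 2, 3):
            day_energy = target_usual * float(
                np.exp(rng.normal(0.0, config.sd_day))
            )
            chosen = rng.random(len(codes)) < probs
            if not chosen.any():
                chosen[codes.index("rice_cooked")] = True
            grams = np.zeros(len(codes))
            grams[chosen] = medians[chosen] * np.exp(
                rng.normal(0.0, PORTION_SIGMA, int(chosen.sum()))
            )
            implied = float(grams @ energy_per_g)
            if implied <= 0:
                raise SimulationError(
                    f"no energy-bearing foods selected for {mem.member_id}"
                )
            grams *= day_energy / implied
            hours = rng.choice(_MEAL_HOURS, size=int(chosen.sum()), p=_MEAL_HOUR_P)
            outside = rng.random(int(chosen.sum())) < _OUTSIDE_P[mem.role]
            portions = [
                PortionRecord(
                    food_code=codes[i],
                    grams=float(grams[i]),
                    hour=int(h),
                    location="outside" if o else "home",
                )
                for i, h, o in zip(np.flatnonzero(chosen), hours, outside)
            ]
            proxy = visit_index > 1 and rng.random() < _PROXY_P[mem.role]
            visits.append(
                RecallVisit(
                    member_id=mem.member_id,
                    visit_index=visit_index,
                    portions=portions,
                    proxy_respondent=proxy,
                )
            )
    return visits


def simulate_study(config: SimulationConfig):
    """One full synthetic dataset: households, members, FCT, recalls, truth."""
    fct = generate_fct(seed=config.seed)
    households, members, truth = generate_households(config)
    visits = generate_recalls(config, members, fct, truth)
    return households, members, fct, visits, truth
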