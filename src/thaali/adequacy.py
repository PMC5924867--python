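"""Probability of adequacy (PA) and mean probability of adequacy (MPA).

The probability approach compares each person's usual intake of a nutrient
with the *distribution* of requirements in their demographic group: the
probability that intake covers the person's own (unknown) requirement.
For most nutrients the requirement distribution is taken as normal with
mean equal to the estimated average requirement (EAR) and a published SD.

Iron in non-pregnant adults is the exception: menstrual losses make the
requirement distribution right-skewed, so PA is read from a table of
probabilities over intake intervals instead of a normal CDF.  The table
shipped here is constructed by discretising a log-normal requirement
distribution rescaled to 5% dietary bioavailability (the absorbed
requirement divided by 0.05); see :func:`build_iron_table`.

Bioavailability enters only through the requirement parameters (e.g. the
pregnant iron EAR assumes 23% absorption, zinc 25% for women and 18% for
men); intakes are never rescaled.

MPA is the arithmetic mean of PA over exactly the 11 assessed
micronutrients; energy and protein are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .nutrients import MICRONUTRIENTS
from .records import MemberRecord

__all__ = [
    "RequirementDistribution",
    "IronProbabilityTable",
    "EnergyRequirementConfig",
    "PREGNANCY_INCREMENT_KCAL",
    "IRON_LOGNORMAL_MEDIAN_ABSORBED_MG",
    "IRON_LOGNORMAL_SIGMA",
    "default_requirements",
    "default_energy_config",
    "default_iron_table",
    "build_iron_table",
    "energy_ear",
    "pa_normal",
    "pa_iron_tabulated",
    "probability_of_adequacy",
    "mpa",
]

#: Additional energy cost of pregnancy, kcal/day.
PREGNANCY_INCREMENT_KCAL = 390.0

#: Median of the absorbed-iron requirement distribution (mg/day) used to
#: construct the default tabulated-iron PA table.
IRON_LOGNORMAL_MEDIAN_ABSORBED_MG = 1.1
#: Log-scale SD of the absorbed-iron requirement distribution.
IRON_LOGNORMAL_SIGMA = 0.35
#: Dietary bioavailability assumed for the tabulated iron PA.
IRON_BIOAVAILABILITY = 0.05


@dataclass
class RequirementDistribution:
    """Requirement distribution of one nutrient for one member role."""

    nutrient: str
    role: str
    kind: str  # "normal" or "tabulated"
    ear_mean: float | None = None
    ear_sd: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "tabulated"):
            raise ValueError(f"unknown requirement kind {self.kind!r}")
        if self.kind == "normal":
            if self.ear_mean is None or self.ear_sd is None or self.ear_sd <= 0:
                raise ValueError(
                    f"{self.nutrient}/{self.role}: normal kind needs ear_mean "
                    "and positive ear_sd"
                )


@dataclass
class IronProbabilityTable:
    """Probability of adequacy per intake interval for skewed iron needs.

    ``upper_bounds`` are the interval upper limits in mg/day (ascending);
    ``probabilities`` give the PA assigned to intakes at or below each
    bound (and above the previous bound).  Intakes above the last bound
    take the last probability.
    """

    upper_bounds: np.ndarray
    probabilities: np.ndarray
    bioavailability: float = IRON_BIOAVAILABILITY

    def __post_init__(self) -> None:
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.upper_bounds.size == 0:
            raise ValueError("iron probability table is empty")
        if self.upper_bounds.size != self.probabilities.size:
            raise ValueError("bounds and probabilities differ in length")
        if np.any(np.diff(self.upper_bounds) <= 0):
            raise ValueError("interval bounds must be strictly increasing")
        if np.any(np.diff(self.probabilities) < 0):
            raise ValueError("probabilities must be nondecreasing with intake")
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class EnergyRequirementConfig:
    """Energy EAR coefficients (kcal per kg body weight per day).

    Keyed by (sex, activity_level).  The defaults follow the Indian
    Council of Medical Research adult values expressed per kg reference
    weight.  Pregnancy adds a flat increment.
    """

    kcal_per_kg: dict[tuple[str, str], float] = field(default_factory=dict)
    pregnancy_increment: float = PREGNANCY_INCREMENT_KCAL

    def __post_init__(self) -> None:
        for key, v in self.kcal_per_kg.items():
            if v <= 0:
                raise ValueError(f"energy coefficient for {key} must be positive")


def _data_path(name: str):
    return resources.files("thaali.data").joinpath(name)


def default_requirements() -> list[RequirementDistribution]:
    """Requirement distributions shipped with the package.

    Normal EAR means/SDs per role follow WHO/FAO values (vitamin C,
    thiamin, riboflavin, niacin, B6, folate, B12), IOM values for calcium
    and pregnant iron (23% absorption), and IZiNCG values for zinc
    (25% absorption for women, 18% for men).  Iron for the mother-in-law
    and household head is tabulated.
    """
    df = pd.read_csv(_data_path("requirements_ear.csv"), comment="#")
    out = []
    for row in df.itertuples(index=False):
        mean = None if pd.isna(row.ear_mean) else float(row.ear_mean)
        sd = None if pd.isna(row.ear_sd) else float(row.ear_sd)
        out.append(
            RequirementDistribution(row.nutrient, row.role, row.kind, mean, sd, row.source)
        )
    return out


def default_energy_config() -> EnergyRequirementConfig:
    df = pd.read_csv(_data_path("energy_coefficients.csv"), comment="#")
    coeff = {
        (row.sex, row.activity_level): float(row.kcal_per_kg)
        for row in df.itertuples(index=False)
    }
    return EnergyRequirementConfig(kcal_per_kg=coeff)


def build_iron_table(
    median_absorbed: float = IRON_LOGNORMAL_MEDIAN_ABSORBED_MG,
    sigma: float = IRON_LOGNORMAL_SIGMA,
    bioavailability: float = IRON_BIOAVAILABILITY,
    prob_step: float = 0.02,
) -> IronProbabilityTable:
    """Construct a tabulated-iron PA table from its generating distribution.

    The absorbed requirement is log-normal with the given median and
    log-scale SD; the dietary requirement divides by ``bioavailability``.
    Interval bounds are placed at the requirement distribution's quantiles
    on a regular probability grid (step ``prob_step``), and each interval
    carries the midpoint probability, bounding the discretisation error by
    ``prob_step / 2``.
    """
    mu = np.log(median_absorbed / bioavailability)
    probs = np.arange(prob_step, 1.0, prob_step)
    bounds = np.exp(mu + sigma * norm.ppf(probs))
    # interval (bounds[i-1], bounds[i]] covers CDF mass (p[i-1], p[i]];
    # assign the midpoint, with p=0 below the first bound
    lower = np.concatenate([[0.0], probs[:-1]])
    mid = (lower + probs) / 2.0
    return IronProbabilityTable(bounds, mid, bioavailability)


def default_iron_table() -> IronProbabilityTable:
    """The frozen 5%-bioavailability iron PA table shipped as CSV."""
    df = pd.read_csv(_data_path("iron_pa_5pct_v1.csv"), comment="#")
    return IronProbabilityTable(
        df["upper_bound_mg"].to_numpy(), df["probability"].to_numpy()
    )


def energy_ear(member: MemberRecord, config: EnergyRequirementConfig) -> float:
    """Energy EAR (kcal/day) from sex, activity level and body weight."""
    key = (member.sex, member.activity_level)
    if key not in config.kcal_per_kg:
        raise KeyError(f"no energy coefficient for sex={member.sex!r}, "
                       f"activity={member.activity_level!r}")
    ear = config.kcal_per_kg[key] * member.body_weight
    if member.role == "pregnant_woman":
        ear += config.pregnancy_increment
    return ear


def pa_normal(usual: float, dist: RequirementDistribution) -> float:
    """PA under a normal requirement distribution: Phi((x - EAR) / SD)."""
    if dist.kind != "normal":
        raise TypeError(
            f"{dist.nutrient}/{dist.role}: pa_normal requires a normal "
            f"requirement distribution, got {dist.kind!r}"
        )
    return float(norm.cdf((usual - dist.ear_mean) / dist.ear_sd))


def pa_iron_tabulated(usual: float, table: IronProbabilityTable) -> float:
    """PA for tabulated iron: the probability of the interval containing
    the usual intake; clamped to the first/last interval beyond the range."""
    idx = int(np.searchsorted(table.upper_bounds, usual, side="left"))
    idx = min(idx, table.probabilities.size - 1)
    return float(table.probabilities[idx])


def probability_of_adequacy(
    usual: float,
    dist: RequirementDistribution,
    iron_table: IronProbabilityTable | None = None,
) -> float:
    """Dispatch PA by requirement kind."""
    if dist.kind == "normal":
        return pa_normal(usual, dist)
    if iron_table is None:
        raise ValueError(
            f"{dist.nutrient}/{dist.role}: tabulated requirement needs an "
            "iron probability table"
        )
    return pa_iron_tabulated(usual, iron_table)


def mpa(pa_map: Mapping[str, float]) -> float:
    """Mean probability of adequacy over exactly the 11 micronutrients."""
    expected = set(MICRONUTRIENTS)
    got = set(pa_map)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"MPA requires exactly the 11 micronutrients; missing={missing}, "
            f"extra={extra}"
        )
    vals = [pa_map[n] for n in MICRONUTRIENTS]
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("PA values must lie in [0, 1]")
    return float(np.mean(vals))
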