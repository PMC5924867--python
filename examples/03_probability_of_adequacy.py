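"""Probability of adequacy: normal requirements and the tabulated iron case.

PA compares a usual intake with the requirement distribution of the
person's demographic group.  Most nutrients use a normal distribution
(mean = EAR); iron in non-pregnant adults uses a probability table over
intake intervals because menstrual losses skew the requirement.
"""

from thaali import (
    default_iron_table,
    default_requirements,
    mpa,
    pa_iron_tabulated,
    pa_normal,
)
from thaali.nutrients import MICRONUTRIENTS

reqs = {(r.nutrient, r.role): r for r in default_requirements()}

# pregnant woman consuming 11 mg/d zinc against EAR 12 (SD 1.5)
dist = reqs[("zinc_mg", "pregnant_woman")]
print(f"pregnant zinc PA at 11 mg/d vs EAR {dist.ear_mean} ({dist.ear_sd}): "
      f"{pa_normal(11.0, dist):.3f}")

# tabulated iron for a male household head at 5% bioavailability
table = default_iron_table()
for intake in (10, 19, 30, 45):
    print(f"iron PA at {intake:2d} mg/d (tabulated, 5% bioavailability): "
          f"{pa_iron_tabulated(float(intake), table):.2f}")

# MPA averages PA over exactly the 11 assessed micronutrients
pa_map = {}
for nutrient in MICRONUTRIENTS:
    dist = reqs[(nutrient, "pregnant_woman")]
    usual = dist.ear_mean * 0.9  # everything at 90% of the EAR
    pa_map[nutrient] = pa_normal(usual, dist)
print(f"MPA at 90% of every EAR: {mpa(pa_map):.2f}")
# each PA < 0.5 since intake sits below the requirement mean, so the MPA
# lands well under one half
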