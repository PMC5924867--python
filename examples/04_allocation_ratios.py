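"""Pairwise allocation ratios: FS, FS:ES, RDEAR and the MPA ratio.

Hand-built single-household example showing how the four ratio families
read.  A ratio of 1 is perfect equity for that pair; logs are used for
inference because ratios are multiplicative.
"""

import math

from thaali import food_share, fs_es, mpa_ratio, pct_from_log, rdear
from thaali.inference import format_pct

# pregnant woman (a) vs household head (b)
pw_flesh, hh_flesh = 40.0, 75.0        # g/day of flesh foods
pw_kcal, hh_kcal = 2100.0, 2900.0      # energy intakes
pw_ear, hh_ear = 2450.0, 2500.0        # energy EARs (hers includes +390 kcal)
pw_mpa, hh_mpa = 0.37, 0.57            # mean probabilities of adequacy

fs = food_share(pw_flesh, hh_flesh)
fe = fs_es(pw_flesh, pw_kcal, hh_flesh, hh_kcal)
rd = rdear(pw_kcal, pw_ear, hh_kcal, hh_ear)
mr = mpa_ratio(pw_mpa, hh_mpa)

print(f"flesh-food FS      : {fs:.3f}  (she eats {fs:.0%} of his grams)")
print(f"flesh-food FS:ES   : {fe:.3f}  (per-kcal share, composition-adjusted)")
print(f"RDEAR              : {rd:.3f}  (energy relative to own requirement)")
print(f"MPA ratio          : {mr:.3f}")
for name, val in [("FS:ES", fe), ("RDEAR", rd), ("MPA ratio", mr)]:
    print(f"log {name:10s}: {math.log(val):+.3f} -> {format_pct(math.log(val))}")
# The log-RDEAR of -0.30 here reads "26% lower": her energy adequacy is
# about a quarter below the household head's.
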