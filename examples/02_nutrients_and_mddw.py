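"""Total nutrients from recall portions and score dietary diversity.

Takes one member's three recalls from a small synthetic survey, totals
intakes against the food-composition table, and prints the 3-day mean
energy, a few micronutrients, and the MDD-W score (10 food groups,
first recall only; >= 5 is an "adequate" diet).
"""

from thaali import SimulationConfig, build_profile, simulate_study

_, members, fct, visits, _ = simulate_study(
    SimulationConfig(n_clusters=2, households_per_cluster=2, seed=7)
)

member = members[0]  # a pregnant woman
own_visits = [v for v in visits if v.member_id == member.member_id]
profile = build_profile(own_visits, fct)

print(f"member {member.member_id} ({member.role}), {len(own_visits)} recalls")
mean = profile.mean_nutrients
print(f"3-day mean energy : {mean['energy_kcal']:7.0f} kcal/d")
print(f"            iron  : {mean['iron_mg']:7.1f} mg/d")
print(f"            folate: {mean['folate_ug']:7.0f} ug/d")
print(f"            zinc  : {mean['zinc_mg']:7.1f} mg/d")
print(f"MDD-W score (visit 1): {profile.mddw_score}/10 -> "
      f"{'adequate' if profile.mddw_adequate else 'inadequate'} (threshold 5)")
groups = [g for g, any_ in profile.consumed_any.items() if any_]
print(f"groups consumed over the 3 days: {', '.join(groups)}")
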