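"""Metastasis-probability prediction and derived rate summaries.

Turns a rate vector into per-state probabilities at clinically meaningful
times (including the "within 10 years of a given diameter" construction:
probability at imputed-age + 10), and prints the secondary/primary seeding
ratios and the blood-flow-normalized colonizing ability.
"""

import metaspread as ms

theta = ms.DEFAULT_TRUE_RATES

print("diameter  imputed age  P(any met within 10 further years)")
for d in (5.0, 10.0, 40.0):
    age = ms.diameter_to_age(d)
    row = ms.metastasis_probability(theta, t_years=age + 10.0)
    print(f"{d:6.0f} mm {age:10.1f} y {row['p_any_metastasis']:12.3f}")

row = ms.metastasis_probability(theta, t_years=2.0)
print(f"\nP(lung+liver+brain metastases at 2 y): {row['P15']:.2e}")
print(f"P(any metastasis at 2 y): {row['p_any_metastasis']:.4f}")

ratios = ms.derived_ratios(theta)
print(f"\nsecondary/primary seeding, liver (luli/tuli): {ratios['secondary_primary_liver']:.0f}")
print(f"secondary/primary seeding, brain (lubr/tubr): {ratios['secondary_primary_brain']:.0f}")
print(f"colonizing ability liver vs brain (blood-flow normalized): "
      f"{ratios['colonizing_ability']:.2f}")
print(f"lung influx {ratios['lung_influx']:.5f} << lung outflux {ratios['lung_outflux']:.4f}")
# Normalizing the two lung-outflow rates by each organ's share of cardiac
# output (6.5% liver, 12% brain) says tumor cells are ~5-6x better at
# colonizing liver tissue than brain tissue.
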