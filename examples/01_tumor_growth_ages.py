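"""Impute tumor age from diameter under the Gompertz growth law.

Builds the default growth law (alpha = 0.0359/day, beta = 0.0013/day, a
single 10-um cell growing toward a ~100 mm asymptote) and prints the
imputed age of typical tumors.  The ages are what the likelihood uses as
each patient's observation time.
"""

import metaspread as ms

growth = ms.GompertzParams()
print(f"asymptotic diameter: {growth.asymptotic_diameter_mm:.2f} mm")
print(f"alpha calibrated from sizes: {ms.calibrate_alpha(0.0013, 10, 100):.4f} /day")
print(f"cells in a 100 mm tumor: {ms.cell_count(100.0):.2e}")
print(f"years to lethal size at a constant 150-day doubling: "
      f"{ms.time_to_lethal_constant_doubling(150, 1e12):.1f}")
print()
for d in (5, 10, 40):
    age = ms.diameter_to_age(d, growth)
    print(f"a {d:2d} mm tumor is ~{age:.1f} years old")
# A 5 mm tumor is already ~2.4 years old: metastatic seeding has had years
# to act before the earliest plausible detection.
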