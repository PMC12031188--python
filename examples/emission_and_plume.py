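"""Emission rates and downwind concentrations for the default stockpile.

Builds the default scenario (2 m/s wind, 30 % moisture, 50 % dust removal,
500 m^3/h disturbance, 15 m pile), computes the dust emission rate of each
size fraction and the resulting ground-level concentrations out to 2 km.
"""

from dustrisk import (
    DEFAULT_CLASSES,
    StockpileScenario,
    concentration_profile,
    emission_rate,
)

scenario = StockpileScenario()

print("Emission rates (mg/s):")
for pclass in DEFAULT_CLASSES:
    print(f"  {pclass.label:6s} {emission_rate(scenario, pclass):8.4f}")

profile = concentration_profile([100, 500, 1000, 2000], scenario, DEFAULT_CLASSES)
print("\nGround-level concentration (ug/m^3) at breathing height:")
print(profile.pivot(index="distance_m", columns="class", values="concentration_ug_m3"))

print(
    "\nPM10 is emitted ~6.6x faster than PM2.5 (size multipliers) but its"
    "\nconcentration advantage shrinks downwind as gravitational settling"
    "\ndepletes the coarse fraction faster than the fine one."
)
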