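"""Compliance distances: how far downwind until standards are met?

Solves for the smallest distance beyond the plume's ground-level maximum
at which each dust fraction, and each metal carried on the dust, falls to
its ambient standard.
"""

from dustrisk import (
    PM10,
    PM25,
    MetalProfile,
    StockpileScenario,
    ToxicityValues,
    compliance_distance,
    metal_air_concentration,
    particle_concentration_fn,
)

# Uncontrolled worst case: no dust suppression, dry pile, maximum
# disturbance rate — the regime where buffer distances actually bind.
scenario = StockpileScenario(removal_rate=0.0, moisture=8.0, disturbance_rate=2500.0 / 3600.0)
tox = ToxicityValues()
fns = {p.label: particle_concentration_fn(scenario, p) for p in (PM25, PM10)}

print("Dust fractions:")
for p in (PM25, PM10):
    res = compliance_distance(p.air_quality_limit, fns[p.label])
    note = " (never exceeded)" if res.already_compliant else ""
    print(f"  {p.label:6s} limit {p.air_quality_limit:5.1f} ug/m^3 -> {res.distance:7.0f} m{note}")

profile = MetalProfile(
    {
        "Hg": {"PM2.5": 12000.0, "PM10": 6000.0},
        "As": {"PM2.5": 44000.0, "PM10": 22000.0},
    }
)
print("\nMetals carried on the dust (strongly contaminated pile):")
for metal in profile.metals:
    fn = lambda x, m=metal: metal_air_concentration(
        profile, m, {label: f(x) for label, f in fns.items()}
    )
    res = compliance_distance(tox.air_limit(metal), fn)
    tail = "not attained in 20 km window" if not res.attained else f"{res.distance:7.0f} m"
    print(f"  {metal:6s} limit {tox.air_limit(metal):g} ug/m^3 -> {tail}")
print("\nMore toxic metals (lower air limits) need larger buffer distances")
print("even when their absolute concentrations are smaller.")
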