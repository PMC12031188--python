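"""Carcinogenic and non-carcinogenic risk at a residential receptor.

Uses a measured-style metal content table (mg metal per kg dust, per size
fraction) and the modelled dust concentrations 500 m downwind to build the
per-metal CR/HQ table with its totals, then compares them to the
acceptability limits (CR 1e-6, HQ 1).
"""

from dustrisk import (
    CR_LIMIT,
    HQ_LIMIT,
    PM10,
    PM25,
    MetalProfile,
    StockpileScenario,
    particle_concentration_fn,
    risk_table,
)

scenario = StockpileScenario()
conc = {
    p.label: particle_concentration_fn(scenario, p)(500.0) for p in (PM25, PM10)
}
print("Dust at the residential receptor (ug/m^3):", {k: round(v, 4) for k, v in conc.items()})

contents = MetalProfile(
    {
        "Cd": {"PM2.5": 49.5, "PM10": 33.0},
        "Hg": {"PM2.5": 12.0, "PM10": 6.0},
        "As": {"PM2.5": 44.0, "PM10": 22.0},
        "Cr(VI)": {"PM2.5": 4.0, "PM10": 2.0},
    }
)
table = risk_table(contents, conc)
print("\nPer-metal risk table (CR dimensionless lifetime risk, HQ dimensionless):")
print(table.cells.to_string(index=False))
print(f"\nTotal CR = {table.cr_total:.3g}  (limit {CR_LIMIT:g})")
print(f"Total HQ = {table.hq_total:.3g}  (limit {HQ_LIMIT:g})")
print("A '-'/NaN CR cell means the metal has no inhalation slope factor (Hg).")
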