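"""Tornado sensitivity: which parameters move the exposure most?

Perturbs each chain parameter to +/-25 % of its default and reports the
larger-over-smaller ratio of the PM2.5 concentration at the residential
receptor, plus the full-range uncertainty span of the disturbance rate.
"""

from dustrisk import sensitivity_ratio, uncertainty_span
from dustrisk.uncertainty import DEFAULT_SENSITIVITY_PARAMETERS

print("+/-25% sensitivity multipliers (PM2.5 at 500 m):")
for name in DEFAULT_SENSITIVITY_PARAMETERS:
    print(f"  {name:17s} {sensitivity_ratio(name):6.3f}x")

span = uncertainty_span("disturbance_rate", 250 / 3600, 2500 / 3600)
print(f"\nDisturbance-rate full-range span: {span:.1f}x")
print("Moisture dominates (the emission factor falls as M^-1.4); particle")
print("density barely matters for 2.5 um particles at this distance.")
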