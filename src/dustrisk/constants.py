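"""Shipped default exposure, toxicity and regulatory reference values.

Every value here is a configurable default, not a hard-coded assumption:
the risk functions accept overrides for all of them.

Exposure parameters follow the adult inhalation route of the Chinese
construction-land risk-assessment guideline HJ 25.3-2019.  Slope factors
and inhalation reference doses are the commonly used inhalation toxicity
values (reference doses converted from reference concentrations at the
adult inhalation rate to body weight ratio of ~0.29 m^3/kg-d).  Ambient
metal limits are the GB 3095-2012 reference concentrations; soil screening
values are the GB 36600-2018 Class II (residential/industrial) screening
levels for the hexavalent-chromium and total-metal entries used here.
"""

from __future__ import annotations

#: The five risk-driving metals stably detected in slag dust.
KEY_METALS = ("Pb", "Cd", "Hg", "As", "Cr(VI)")

#: Metals carried through the carcinogenic / non-carcinogenic risk table.
#: Pb has neither an inhalation slope factor nor a reference dose in this
#: framework and is assessed through exceedance multiples only.
RISK_METALS = ("Cd", "Hg", "As", "Cr(VI)")

#: Adult inhalation exposure defaults (HJ 25.3-2019).
DEFAULT_EXPOSURE = {
    "DAIR": 14.5,  # daily air inhalation rate, m^3/d
    "ED": 24.0,  # exposure duration, a
    "EF": 350.0,  # exposure frequency, d/a
    "PIAF": 0.75,  # retained fraction of inhaled particulate, -
    "BW": 61.8,  # adult body weight, kg
    "AT_carcinogenic": 27740.0,  # lifetime averaging time, d (76 a)
    "AT_noncarcinogenic": 8760.0,  # ED * 365, d
    "SAF": 0.5,  # reference-dose allocation to inhaled dust, -
}

#: Per-metal inhalation toxicity and regulatory reference values.
#: sf: carcinogenic slope factor, (mg/kg-d)^-1 (None = not carcinogenic by
#:     inhalation in this framework -> no CR entry).
#: rfd: inhalation reference dose, mg/kg-d (None -> no HQ entry).
#: air_limit: ambient air reference concentration, ug/m^3 (annual).
#: soil_screening: soil Class II screening value, mg/kg.
DEFAULT_TOXICITY = {
    "Pb": {"sf": None, "rfd": None, "air_limit": 0.5, "soil_screening": 800.0},
    "Cd": {"sf": 6.3, "rfd": 2.86e-6, "air_limit": 0.005, "soil_screening": 65.0},
    "Hg": {"sf": None, "rfd": 8.57e-5, "air_limit": 0.05, "soil_screening": 38.0},
    "As": {"sf": 15.1, "rfd": 4.29e-6, "air_limit": 0.006, "soil_screening": 60.0},
    "Cr(VI)": {"sf": 42.0, "rfd": 2.86e-5, "air_limit": 2.5e-5, "soil_screening": 5.7},
}

#: Acceptability thresholds: lifetime excess cancer risk and hazard quotient.
CR_LIMIT = 1.0e-6
HQ_LIMIT = 1.0

#: Ambient TSP standard used as the dust-loading reference for the
#: potential health hazard index, ug/m^3.
TSP_LIMIT = 80.0
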