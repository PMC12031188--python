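# dustrisk

Environmental and health risk assessment of fugitive heavy-metal dust from
open slag stockpiles.

Open-air slag piles (magnesium slag in particular, whose dicalcium-silicate
phase transformation pulverises the material as it cools) shed PM2.5 and
PM10 dust that carries Pb, Cd, Hg, As and Cr(VI) toward downwind residential
areas. `dustrisk` chains the four models an assessor needs to quantify that
risk, with Monte Carlo uncertainty and tornado sensitivity on top:

1. **Emission** — AP-42-style aggregate-handling factor:
   `ER = V·ρ_b·k·0.0016·(U/2.2)^1.3 / (M/2)^1.4 · (1−η)`
   with wind speed `U` (m/s), moisture `M` (%), removal efficiency `η`,
   disturbance rate `V` (m³/s) and size multiplier `k` per fraction.
2. **Dispersion** — Gaussian plume with ground reflection for a source at
   stockpile height `h`, with piecewise power-law dispersion coefficients
   `σ_y(x), σ_z(x)` (neutral-class table shipped, configurable) and a
   gravitational-settling depletion factor
   `exp(−g·x·(ρ−ρ_a)·d² / (18·μ·U))` that makes the coarse fraction drop
   out faster than the fine one.
3. **Risk** — inhalation intake `Q = PM_i·DAIR·ED·PIAF·EF·10⁻⁶/(BW·AT)`,
   carcinogenic risk `CR = Q·C·SF` and hazard quotient
   `HQ = Q·C/(RfD·SAF)` per metal and size fraction, with exceedance
   multiples, compliance distances, size-fraction contributions and the
   PHI-E / PHI-H screening indices.
4. **Uncertainty** — seeded Monte Carlo over bounded parameter
   distributions, ±25 % tornado sensitivity ratios, and full-range
   uncertainty spans.

A seeded synthetic-cohort generator stands in for unpublished slag-sample
measurement matrices (80 samples × analytes × 2 size fractions, with
realistic censoring and fine-fraction enrichment).

## Worked example

```python
from dustrisk import (PM25, PM10, MetalProfile, StockpileScenario,
                      particle_concentration_fn, risk_table)

scenario = StockpileScenario()          # U=2 m/s, M=30 %, eta=0.5, V=500 m3/h, h=15 m
conc = {p.label: particle_concentration_fn(scenario, p)(500.0) for p in (PM25, PM10)}
contents = MetalProfile({"Cd": {"PM2.5": 49.5, "PM10": 33.0},
                         "As": {"PM2.5": 44.0, "PM10": 22.0}})
table = risk_table(contents, conc, metals=["Cd", "As"])
print(conc)
print(table.cr_total, table.hq_total)
```

prints

```
{'PM2.5': 0.014695191385077837, 'PM10': 0.041351019157021864}
1.9545255892232094e-09 0.0003692835039173259
```

— the dust concentrations 500 m downwind (µg/m³) and the summed lifetime
cancer risk and hazard quotient for Cd + As, both far below the
acceptability limits (10⁻⁶ and 1) at these contents and concentrations.
The `examples/` directory holds one short narrative script per capability
(emission/plume, risk table, Monte Carlo, tornado sensitivity, compliance
distances, synthetic cohorts); each prints its numbers with a line on what
they mean. The same operations are exposed as a thin CLI:

```bash
dustrisk emission            # ER per size class, CSV
dustrisk profile             # concentration vs distance, CSV
dustrisk sensitivity         # tornado ratios, CSV
dustrisk simulate-samples --n-samples 80 --seed 0
dustrisk report              # full pipeline + headline summary
```

## Layout

- `src/dustrisk/` — `emission`, `dispersion`, `risk`, `uncertainty`,
  `synthetic`, `config`/`pipeline`/`cli`, shipped constants in
  `constants.py` (all overridable).
- `docs/methods.md` — model assumptions, parameter defaults and their
  provenance, numerical choices, known limitations.
- `tests/` — unit, property and acceptance suites.
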