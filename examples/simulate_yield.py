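"""Simulate one full pod cycle: light interception, biomass, yield.

Each day's above-ground growth is SRAD × fSolar × RUE × f(CO2) × f(T) × 10
(kg ha⁻¹ day⁻¹); fSolar follows a logistic rise and senescent decline in
thermal time; the cycle stops when thermal time reaches the regional Tsum
and yield is the harvest-index (0.3) share of accumulated biomass.
"""

import datetime as dt

from cacaosim import (
    ARCHETYPES,
    REGION_PARAMS,
    generate_synthetic_weather,
    simulate_cycle,
)

series = generate_synthetic_weather(
    ARCHETYPES["Apartado"], dt.date(2019, 1, 1), dt.date(2020, 6, 30), seed=1
)
trace = simulate_cycle(series, dt.date(2019, 7, 12), REGION_PARAMS["Apartado"])

print(f"harvest DAF          : {trace.predicted_harvest_daf} (reached={trace.reached})")
print(f"peak fSolar          : {trace.fsolar.max():.3f}")
print(f"accumulated biomass  : {trace.total_biomass:8.0f} kg/ha")
print(f"predicted bean yield : {trace.yield_kg_ha:8.0f} kg/ha")
print(
    "\nThe yield is exactly 0.3 x the accumulated above-ground biomass; the\n"
    "fSolar peak near 0.94 means the canopy intercepted almost all incoming\n"
    "radiation at mid-cycle."
)
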