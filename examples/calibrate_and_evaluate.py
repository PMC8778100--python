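"""Calibrate RUE by grid search and score the fit with RRMSE.

Radiation-use efficiency for shaded cacao lies between 0.5 and
0.7 g MJ⁻¹; the calibrator simulates every flowering-date sample at each
grid value and keeps the RUE minimising the relative root mean square
error against observed yields.  Here the "observations" are produced by
the simulator itself at RUE = 0.6 with 5% noise, so recovering 0.6 is the
correct answer.
"""

import dataclasses
import datetime as dt

import numpy as np

from cacaosim import (
    ARCHETYPES,
    FloweringSample,
    REGION_PARAMS,
    calibrate_rue,
    generate_synthetic_weather,
    reconstructed_flowering_dates,
    simulate_cycle,
)

series = generate_synthetic_weather(
    ARCHETYPES["Apartado"], dt.date(2019, 1, 1), dt.date(2021, 3, 31), seed=1
)
region = REGION_PARAMS["Apartado"]
truth = dataclasses.replace(region, rue=0.6)

rng = np.random.default_rng(1)
samples = [
    FloweringSample(
        "Apartado",
        fd,
        observed_yield=simulate_cycle(series, fd, truth).yield_kg_ha
        * (1 + rng.normal(0, 0.05)),
    )
    for fd in reconstructed_flowering_dates()
]

result = calibrate_rue(series, samples, region)
for rue, score in zip(result.rue_grid, result.rrmse_per_rue):
    marker = "  <- selected" if rue == result.selected_rue else ""
    print(f"RUE {rue:.2f}  RRMSE {score:6.2f} %{marker}")

print(
    f"\nThe grid search recovered the generating RUE ({result.selected_rue});\n"
    "its RRMSE sits near the 5% observation-noise floor."
)
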