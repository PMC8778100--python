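"""Predict the pod harvest day from a flowering date.

Thermal time — the running sum of daily (mean temperature − 10 °C),
clamped at zero — accumulates from the flowering date (day 0); the pod is
mature on the first day the sum reaches the regional requirement Tsum.
Farmers traditionally harvest at a fixed 180 days after flowering (DAF);
the model shows how the right day shifts with the weather.
"""

import datetime as dt

from cacaosim import (
    ARCHETYPES,
    REGION_PARAMS,
    generate_synthetic_weather,
    predict_harvest_day,
)

fd = dt.date(2019, 7, 12)  # first flowering date of the field campaign

for region in ("Apartado", "Arauca", "Santander", "Cali", "Caldas"):
    series = generate_synthetic_weather(
        ARCHETYPES[region], dt.date(2019, 1, 1), dt.date(2020, 6, 30), seed=1
    )
    tsum = REGION_PARAMS[region].tsum
    pred = predict_harvest_day(series, fd, tsum)
    delta = pred.daf - 180
    print(
        f"{region:10s} Tsum {tsum:6.0f} C.day -> harvest at DAF "
        f"{pred.daf:3d} ({delta:+3d} d vs the 180-day calendar rule)"
    )

print(
    "\nA warm spell ripens pods days earlier than the calendar rule; a cool\n"
    "year delays them — the deviation is exactly what the model predicts."
)
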