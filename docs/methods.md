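# Methods

## Model structure and assumptions

cacaosim simulates one cacao pod cohort per flowering date (FD) at a daily
time step.  Three assumptions shape everything downstream:

1. **Pod development is thermal-time limited.**  Maturity depends only on
   accumulated degree days above a base temperature, not on photoperiod,
   water status or crop load.  The daily mean temperature is
   (TMAX + TMIN)/2 — the standard agro-meteorological convention; the day
   of flowering itself (DAF 0) contributes no thermal time, so the sum
   runs over days 1..d.
2. **Growth is radiation-limited.**  Above-ground dry matter is incoming
   shortwave × fraction intercepted × radiation-use efficiency, modulated
   by multiplicative temperature/CO2/stress factors.  There is no
   photosynthesis or respiration sub-model: RUE is defined above-ground
   and respiration-free, so respiration is implicit in its value.
3. **Partitioning is a constant harvest index.**  Bean yield is HI = 0.3
   of accumulated biomass at the harvest day, exactly.  The biomass loop
   stops at the predicted harvest day (the yield is defined there), not at
   the 200-day cap.

The canopy-interception and response-factor forms follow the SIMPLE
generic crop model family, re-anchored from sowing to flowering:
fSolar(tt) = fsolar_max · min(1/(1+e^(−0.01(tt−I50A))),
1/(1+e^(0.01(tt−(Tsum−I50B))))), a linear temperature ramp from Tbase to
Topt, a linear CO2 response per 100 ppm above 350 saturating at 700 ppm,
a linear heat decline between MaxT and ExtremeT, and 1 − S_water·ARID for
drought.  Without the /100 scaling the CO2 sensitivity of 0.09 would
imply an absurd 5.5× multiplier at 400 ppm; with it, f(CO2, 400) = 1.045.

## Parameters

| parameter | value | units | meaning |
|---|---|---|---|
| Tbase | 10 | °C | minimum pod-growth temperature; also the ramp base |
| Topt | 26 | °C | temperature at which the growth ramp saturates |
| MaxT / ExtremeT | 35 / 40 | °C | onset / completion of heat stress |
| S_CO2 | 0.09 | per 100 ppm | RUE gain above 350 ppm |
| S_water | 0 | – | drought sensitivity (stress disabled) |
| I50A / I50B | 680 / 680 | °C·day | thermal time to gain / lose 50% interception |
| fsolar_max | 0.94 | – | canopy interception plateau |
| HI | 0.3 | – | harvest index |
| cycle cap | 200 | days | maximum simulated cycle |
| CO2 | 400 | ppm | treatment atmosphere |

Regional triples (Tsum °C·day, RUE g MJ⁻¹, observed yield kg ha⁻¹ yr⁻¹):
Apartado 2906/0.6/3378, Arauca 2764/0.7/3981, Santander 2016/0.6/2687,
Cali 1912/0.5/1900, Caldas 1192/0.6/740.

`initial_fsolar = 0.01` is carried in the configuration for completeness
but is **not** used as a floor: the logistic gives ≈ 0.001 at flowering,
and flooring it would break the closed-form peak identity.  Likewise the
observation-file entries (LAI 1.8, observed fSolar 0.70, 40 kg biomass
per plant, the soil name) are inert metadata — no implemented equation
consumes them.

## Design choices at genuinely open points

- **Tsum statistic.**  The regional requirement is the arithmetic *mean*
  of per-FD 180-day accumulations; a `statistic="median"` flag exposes
  the box-plot variant, and the full per-sample distribution is returned.
- **Crossing rule.**  Harvest is the first integer DAF with tt ≥ Tsum
  (ties to the earlier day); if not reached by the 200-day cap the cap is
  returned with `reached=False`.
- **SRAD, not PAR.**  The weather file's all-sky shortwave column is
  passed through unchanged; no PAR fraction is applied, because RUE is
  calibrated against this same driver.  Applying ~0.48 PAR would simply
  double the calibrated RUE.
- **RRMSE denominator.**  RMSE is normalised by the quadratic mean of the
  predictions (scale-free, n-invariant); `variant="obsmean"` provides the
  common crop-modelling convention (divide by mean observed).  The two
  coincide when spread is small relative to the mean.
- **Calibration.**  "Trial and error" is realised as exhaustive grid
  search on RUE ∈ {0.50, 0.55, 0.60, 0.65, 0.70}; the stopping criterion
  is full evaluation, ties resolve to the lowest RUE.  Yield is exactly
  linear in RUE, so the objective is unimodal on the grid whenever the
  observations are positive.
- **Missing weather.**  POWER −999 sentinels become NaN; calendar gaps
  are reindexed to explicit NaN rows.  Interpolation happens only through
  an explicit `fill_gaps(max_gap_days=3)` call; any simulation spanning
  an unfilled gap raises.  A cycle whose weather ends after Tsum is
  reached but before the 200-day cap still completes (the cap only
  matters when the requirement was not met).

## The synthetic weather generator

Each regional archetype is an annual cosine for daily mean temperature
and shortwave plus Gaussian daily noise, a noisy ~8 °C diurnal range
split symmetrically into TMAX/TMIN, bimodal rainfall (wet seasons
Feb–Apr and Oct–Nov), and humidity near 85%.  Mean temperatures are
back-derived from each region's published 180-day thermal-time
requirement (Tsum/180 + 10 °C): Apartado 26.1, Arauca 25.4, Santander
21.2, Cali 20.6, Caldas 16.4 °C; radiation means follow the regional
contrast (cool highlands ~17 MJ m⁻² d⁻¹ with peaks above 20, Cali/Arauca
~12).  The generator reproduces: regional mean temperature (to ±0.3 °C
over three years), the hot/cold and high/low-radiation contrasts, and
plausible degree-day totals.  It does **not** reproduce: inter-annual
anomalies (ENSO years), autocorrelated weather spells, altitude-driven
diurnal asymmetry, or any real station's actual sequence.  Passing tests
on these fixtures therefore demonstrate the *machinery* — accounting
identities, closed forms, determinism, parameter recovery — not
agreement with field data, which requires the original station weather
and per-farm flowering records.

Fixtures span 2018-01-01..2021-03-31: the study window extended one
quarter past the last flowering date (2020-06-23) so every 200-day cycle
has full coverage.  The 23 flowering dates per region are reconstructed
as evenly spaced dates over the campaign window 2019-07-12..2020-06-23
(the individual dates were never published); observed yields are the
regional calibration value with seeded ±10% uniform noise.

## Problem sizes

The shipped tests and the acceptance script run on: 5 regions × 23
flowering dates (115 cycles) for characterisation/prediction/evaluation;
100 random 30-day series for the degree-day oracle; 20 seeded replicates
of 23-sample RUE recovery at 5% noise.  The full suite completes in well
under a minute on one CPU.

## Known limitations

- **Caldas canopy.**  With the shared I50A = I50B = 680 and Tsum = 1192,
  the logistic pair peaks at ≈ 0.28 interception — far below the 0.76
  plateau reported for that region.  The cool-region canopy
  parameterisation is under-documented at the source; we flag the
  discrepancy rather than force-fit region-specific I50 values.
- **Plateau for mid-Tsum regions.**  The logistic pair reaches a ≥ 0.93
  peak only for Tsum ≳ 2266, so Santander (2016) and Cali (1912) peak at
  0.91/0.88, slightly below the reported common 0.94 plateau.  One test
  asserts the stated ≥ 0.93 plateau at Tsum = 2016 and is expected to
  fail; it documents this structural shortfall and is deliberately not
  relaxed.
- **Yield levels on synthetic weather.**  Under the synthetic radiation
  climates, simulated yields for the cooler/low-radiation regions fall
  well below the published regional observations (the temperature ramp
  alone costs Caldas ~60% of potential growth), so the pooled RRMSE on
  fixtures is large.  This is reported honestly; matching the published
  fit requires the original weather and, plausibly, the undocumented
  regional canopy settings above.
- No soil-water balance (ARID is an input, never computed), no pest or
  disease pressure, no flower-count or pollination model, no
  within-tree competition between pod cohorts.
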