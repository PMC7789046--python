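# clisagri

Agro-climate risk toolkit for winter wheat: dynamic thermal-time phenology,
phenology-linked climate risk indicators, variety optimization and
disease-risk modelling — runnable end-to-end on synthetic daily weather.

## Who this is for

Agronomists, breeders and climate-service developers who need to quantify
the exposure of a wheat season to drought, excessive wetness, cold and heat
stress **during the sensitive growth stages**, rather than over fixed
calendar periods. The growth stages of a given season are simulated from
daily weather, so the windows over which risks are evaluated shift with the
thermal conditions of each year — a warm spring pulls flowering (and its
associated risk windows) earlier.

## What it computes

**Phenology.** A development stage (DVS) is accumulated daily from the
effective temperature `max(0, min(Tavg − Tb, Tmax,e))`:

- *two-phase model*: DVS 0 (sowing) → 1 (flowering, thermal requirement
  `TSUM1`) → 2 (maturity, `TSUM2`); the vegetative accumulation is
  multiplied by a vernalization factor `Vf` and a photoperiod factor `Pf`;
- *multi-phase model*: DVS 0 → 6 through six sub-phases
  (sowing–emergence, emergence–tillering, tillering–stem elongation,
  stem elongation–booting, booting–flowering, flowering–ripening), each with
  its own `TSUMi` and base temperature `Tbi`; `Vf·Pf` apply within
  sub-phases 2–5.

**Hydrological balance (non-parametric SPEI).** Reference
evapotranspiration by the modified Hargreaves–Samani equation
`ET0 = 0.0013·0.408·Ra·(Tavg+17)·max(TD − 0.0123·P, 0)^0.76`; the daily
climatic water balance `D = P − ET0` is summed over a stage window and
standardized by ranking the aggregate among same-window aggregates of all
available years (Weibull plotting position → standard normal quantile).

**16 indicators** over static or DVS-resolved windows: six SPEI windows,
pre-sowing rainfall cumulate, wet-day counts and maximum consecutive wet
runs around flowering, frost days (tmin < 2 °C) and hot days
(tmax > 28 °C) before and after flowering.

**Variety optimization.** Exhaustive `TSUM1 × TSUM2` grid scans for hazard
mapping, and a seeded genetic algorithm over the six sub-phase requirements
maximizing `−Σ penalties` (hinge `max(0, |SPEI| − 1)` per hydrological
indicator, hot-day fraction per heat indicator, a fixed penalty of 10 for a
season that fails to mature).

**Disease risk.** A kernel copula (product-Gaussian KDE in probit space on
rank pseudo-observations) between an indicator and observed disease
severity, giving conditional exceedance curves
`P(severity > s | indicator = x)` and the smallest indicator value at which
that probability reaches a chosen level.

## Worked example

```bash
# 12 years of synthetic Mediterranean weather (seeded, reproducible)
clisagri synth --out weather.csv --seed 3

# all 16 indicators for the season sown 25 Oct 2011, windows from phenology
clisagri indicators weather.csv --lat 44.4 --sowing-date 2011-10-25 \
    --ids 5,10,16 --out indicators.csv
```

`indicators.csv` then contains (values from this exact command):

```
id,name,window_start,window_end,value,risk_class,season_complete
5,SPEI heading-maturity,2012-05-14,2012-06-26,1.4260768722728474,moderately_wet,True
10,"days rainfall > 5 mm, heading-maturity",2012-05-14,2012-06-26,6.0,,True
16,"days tmax > 28 °C, end of flowering-maturity",2012-05-25,2012-06-26,5.0,,True
```

Reading: the simulated season reached heading on 14 May 2012 and maturity
on 26 Jun 2012; the water balance of that window ranks moderately wet
(SPEI +1.43) against the other eleven years; six days in the window had
more than 5 mm of rain (a wetness/disease-pressure signal), and five days
after flowering exceeded 28 °C (heat stress during grain filling).

The same library calls are available in Python:

```python
from clisagri import ClimateSpec, VarietyParams2, clis_agri, generate_series

series = generate_series(ClimateSpec(seed=3))
params = VarietyParams2(tsum1=800, tsum2=800, sowing_date="2011-10-25")
for r in clis_agri(series, params, selection=[5, 10, 16]):
    print(r.id, round(r.value, 2), r.risk_class)
```

Other entry points: `clisagri validate-weather`, `clisagri waterbalance`,
`clisagri spei`, `clisagri phenology`, `clisagri phenology-parameters
[--breeder]`, `clisagri grid-scan`, `clisagri breeder` (GA search with
fitness trace), `clisagri disease-risk`.

## Documentation

`docs/methods.md` describes the models, their assumptions, all tunable
parameters with units and defaults, the synthetic-weather generator, and
known limitations.
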