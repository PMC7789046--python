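# Methods

This note documents the models implemented in `clisagri`, their
assumptions, the tunable parameters that matter, the synthetic-weather
generator used for testing, and the numerical choices made where the design
was genuinely open.

## Thermal-time phenology

Crop development is tracked as a dimensionless development stage (DVS)
advanced each day by the *effective temperature*

    Teff = max(0, min(Tavg − Tb, Tmax,e))

i.e. the daily mean above a base temperature `Tb`, floored at zero and
capped at a maximum effective temperature `Tmax,e` (default 30 °C for
winter wheat: development rate saturates in hot weather and is insensitive
to temperatures above the cap).

**Two-phase model** (DVS 0 → 1 → 2). The vegetative phase accumulates
`Teff · Vf · Pf / TSUM1` until DVS = 1 (flowering); the reproductive phase
accumulates `Teff / TSUM2`, uncorrected, until DVS = 2 (maturity).
`TSUM1`, `TSUM2` are the variety's thermal requirements in growing degree
days (GDD); 600–1000 GDD each is the typical range for Mediterranean durum
varieties with `Tb = 0 °C`.

**Multi-phase model** (DVS 0 → 6). Six sub-phases — sowing–emergence,
emergence–tillering, tillering–stem elongation, stem elongation–booting,
booting–flowering, flowering–ripening — each with its own requirement
`TSUMi` and base temperature `Tbi`. Defaults are the mid-points of the
typical Italian durum ranges:

| sub-phase | TSUM range (GDD) | default | Tb (°C) |
|---|---|---|---|
| sowing–emergence | 120–200 | 160 | 2 |
| emergence–tillering | 35–140 | 87.5 | −2 |
| tillering–stem elongation | 100–220 | 160 | −2 |
| stem elongation–booting | 100–200 | 150 | 0 |
| booting–flowering | 50–150 | 100 | 0 |
| flowering–ripening | 450–550 | 500 | 9 |

Vernalization and photoperiod correction applies within sub-phases 2–5
only (emergence through flowering).

**Vernalization (Vf)** and **photoperiod (Pf)** are clamped-linear
responses in the convention of WOFOST-family crop models. Each day
contributes between 0 and 1 *effective vernalization days* through a
piecewise-linear temperature response (default: fully effective between 3
and 10 °C, ineffective outside [−4, 17] °C); `Vf` rises linearly from 0 to
1 as the accumulated state moves from `v_base` (default 0) to `v_sat`
(default 40 effective days). `Pf` rises linearly with astronomical
daylength between a critical (default 8 h) and an optimal (default 16 h)
photoperiod — wheat is a long-day crop. **These response parameters are
package defaults for a generic winter-hardy Mediterranean variety, not
measurements**; they are exposed on `VernalizationParams` /
`PhotoperiodParams` and can be disabled entirely (`vern=None`,
`photo=None`) to model insensitive varieties or idealized scenarios. There
is no devernalization; the state accumulates from sowing.

Numerical conventions:

- DVS is 0 on the sowing date; accumulation starts the day after sowing.
- A day whose increment crosses a phase boundary is split: the fraction of
  its thermal time needed to complete the current phase counts against that
  phase's requirement, the remainder accrues under the next phase's
  requirement and base temperature, so no thermal time is discarded. At
  most one boundary is crossed per day (never binding with daily increments
  ≤ 30 GDD against requirements ≥ 35 GDD).
- `Vf·Pf` multiplies the whole capped increment (cap applied first).
- Stage-threshold comparisons use a 1e-9 tolerance (`phenology.DVS_TOL`) so
  that a boundary missed only by accumulated floating-point rounding still
  resolves to the correct day.
- A season that does not reach maturity by series end yields a *flagged*
  track, not an error, so parameter scans over extreme requirements remain
  total; resolving a dynamic window beyond the attained DVS raises
  `IncompleteSeasonError` carrying the maximum DVS reached.

**Stage → DVS anchors.** The two-phase model only has flowering and
maturity as genuine boundaries; intermediate stages are conventional
anchors (emergence 0, tillering start 0.15, stem elongation 0.35, booting
0.75, heading 0.90, flowering 1.0, end of flowering 1.15, maturity 2.0),
configurable per call. Because emergence shares DVS 0 with sowing, the
dynamic sowing–emergence window degenerates to the sowing day; users who
need a distinct emergence date should set a small positive anchor. In the
multi-phase map the integer boundaries are real; heading (4.75) and end of
flowering (5.15) are interpolated conventions — flowering duration is not
itself modelled, so "end of flowering" is flowering plus a configurable
DVS offset.

## Water balance and the non-parametric standardized index

Reference evapotranspiration uses the modified Hargreaves–Samani equation
(Droogers & Allen constants):

    ET0 = 0.0013 · 0.408 · Ra · (Tavg + 17.0) · max(TD − 0.0123·P, 0)^0.76

with `Ra` the extraterrestrial radiation (MJ m⁻² day⁻¹) from standard
FAO-56 solar geometry (declination, inverse Earth–Sun distance, sunset
hour angle; the arccos argument is clamped so polar night/day behave), `TD
= Tmax − Tmin` and `P` daily precipitation. The 0.408 factor converts
radiation to mm of evaporation equivalent. Negative radicands (rainy days
with small diurnal range) and a negative temperature factor (Tavg < −17 °C)
clamp ET0 to 0. The temperature offset 17.0 is configurable (17.8 appears
in some variants of the formula). Daily climatic water balance:
`D = P − ET0`.

**Standardization.** The balance aggregated over a window is standardized
without fitting a distribution. The *reference sample* consists of
same-window aggregates obtained by shifting the window by whole calendar
years across the entire series (leave-current-in by default; a
leave-current-out switch exists; Feb 29 clamps to Feb 28). The evaluated
value is ranked within the union of the reference and itself without
double-counting:

    r = #(reference < v) + (#(reference = v) + 1) / 2

so a value that *is* a reference member (the leave-current-in case) takes
exactly that member's rank, a novel value takes the half-step rank between
its neighbours, and ties share the mean rank. The empirical probability is
the Weibull plotting position `p = r/(n+1)` (Gringorten
`(r−0.44)/(n+0.12)` available) and the index is `Φ⁻¹(p)`. Because `p` is
bounded away from 0 and 1, the index is always finite (at most ≈ ±2.7 for
a 100-year reference). Standardizing every member of its own reference
yields a sample with mean 0 and standard deviation 0.90 (n = 30) rising
toward 1 with n — the mild shrinkage is the usual discretization bias of
plotting positions. A reference below 10 years is an error; below 30 years
a warning is issued.

Severity classes: moderate drought (−1.5, −1], severe (−2, −1.5], extreme
≤ −2; mirrored on the wet side with band edges assigned to the more severe
class (exactly −1.5 → severe drought, exactly +2 → extremely wet).

## Indicators

Sixteen built-in indicators (six SPEI windows; pre-sowing rainfall
cumulate; counts of days above 10/40/5/40 mm; maximum consecutive runs
above 5 mm around flowering; frost days tmin < 2 °C booting–flowering; hot
days tmax > 28 °C before/after end of flowering). Threshold comparisons
are strict, as the definitions are worded ("above 5 mm" excludes exactly
5 mm); both the thresholds and the stage windows are configuration, not
constants. Day-count indicators are returned raw — converting counts into
risk levels requires local impact data, which is the role of the
disease-risk module. Windows are resolved either dynamically from a
simulated track or statically from a calendar of (month, day) anchors
appropriate for October-sown Mediterranean wheat (anchors with months
August–December belong to the sowing year, earlier months to the harvest
year). The pre-sowing window is the 30 days before sowing (configurable).

## Variety optimization

`grid_scan` evaluates the full TSUM1 × TSUM2 cross-product of the
two-phase model (incomplete seasons flagged, never fatal) and exports a
long-format table for hazard mapping.

The genetic algorithm searches the six-dimensional sub-phase requirement
space of the multi-phase model. Fitness is `−Σ weighted penalties`:

- each selected hydrological indicator contributes `max(0, |SPEI| − 1)` —
  zero while the window is neither in drought nor excessively wet;
- each day-count indicator contributes `count / window length` — the
  fraction of the window under stress;
- a season that fails to mature contributes a fixed penalty of 10, which
  dominates any feasible indicator penalty and repels the search from
  non-maturing varieties.

The maximum attainable score is 0. The default indicator selection is
(4, 5, 15, 16): hydrological balance during stem elongation–booting and
heading–maturity plus both heat-stress counts. This penalty design is this
package's own definition — it encodes the stated optimization intent
(avoid both drought and wetness, minimize heat exposure) but the resulting
score scale is artifact-defined, not comparable to other tools.

GA operators: tournament selection (size 3), uniform crossover (p = 0.7),
per-gene Gaussian mutation with σ = 10 % of the gene's range clipped to
bounds (p = 0.2 per gene), elitism 1 (making the best-so-far fitness
non-decreasing across generations), population 50, 200 generations by
default; everything is configurable and the whole search is deterministic
given the seed. Genes are continuous within the bounds table; an optional
`levels` argument restricts genes to discrete values, which is how the
search is validated against exhaustive enumeration. Fitness evaluations
are cached per chromosome, and the water balance is precomputed once per
series. Ensemble optimization scores a chromosome as the unweighted mean
of per-member fitnesses. Sowing-date adaptation is explored by re-running
the optimizer with a shifted `sowing_date`; no dedicated sowing-date
search is provided.

## Disease risk (kernel copula)

Pairs (indicator value, severity %) are rank-transformed to
pseudo-observations `u = rank/(n+1)` (average ranks for ties). The copula
density is a probit-transformation kernel estimate: a product-Gaussian KDE
fitted to `(Φ⁻¹(u), Φ⁻¹(v))` and divided by the normal density Jacobian.
Per-dimension Silverman bandwidths `h = σ · n^(−1/6)` are used rather than
a full covariance bandwidth, which would be singular for perfectly
rank-correlated margins; a `bw_scale` multiplier is exposed. The density
is non-negative by construction and integrates to 1 over the unit square
within ~1 % (midpoint quadrature; `copula_integral`). Because the model is
rank-based, strictly monotone transforms of either margin leave it exactly
unchanged.

Conditional exceedance `P(severity > s₀ | indicator = x)` integrates the
conditional density above the severity threshold, mapping data values onto
the unit square through tie-averaged empirical margins (0/1 strictly
outside the observed range; conditioning outside the range warns).
`risk_threshold` returns the smallest indicator value at which that
probability reaches a chosen level, scanning the *distinct observed values*
by default — the indicators feeding this model are day counts and
operational thresholds are stated in whole days — with a linear-grid scan
available; if the curve never crosses the level, an explicit `None`
sentinel is returned.

For testing, `generate_switchpoint_pairs` produces data with a built-in
dependence switch: severity ≈ 8 % below the switch-point (default 5) and
≈ 60 % above it, with Gaussian noise (σ = 6), over an indicator range of
0–10 so the switch sits mid-range of the observed counts, mirroring the
structure of wet-day/severity field data. Severity is treated as a
continuous percentage.

## Synthetic weather generator

The generator supplies the data structure the toolkit assumes, at desk
scale and without downloads: daily mean temperature is an annual sinusoid
(default mean 14 °C, half-amplitude 9 °C — a Po-valley-like climate) plus
Gaussian noise (σ = 2 °C), with the phase set so the minimum falls in
mid-January (configurable for other hemispheres); tmin/tmax sit
symmetrically around the mean with a fixed diurnal range (8 °C);
precipitation is an occurrence/amount process — Bernoulli wet days
(default probability 0.25, optionally monthly) with gamma-distributed
amounts (shape 0.8, skewed daily rainfall; mean wet-day amount 6 mm).
Twelve years are generated by default, enough to build SPEI references
(with the small-sample warning). Ensemble member *i* uses seed
`base_seed + i`, so members are individually reproducible.

What the generator does **not** emulate: temperature–precipitation
correlation, wet/dry spell persistence (occurrence is independent across
days, so synthetic maximum-consecutive-wet-day counts are short), weather
fronts and interannual modes, diurnal-range variability, and spatial
correlation. Passing tests therefore demonstrate correctness of the
computations, thermal-time logic and statistical machinery — not that
indicator climatologies match any particular station.

## Problem sizes used in validation

The automated checks run at desk scale by choice: simulator-vs-oracle
agreement on 100 two-year seasons; indicator-vs-naive agreement on 100
fixtures drawn from five 12-year series; GA-vs-exhaustive comparison on a
3-levels-per-gene space (729 chromosomes) with 20 seeded runs of a
30 × 25 GA; copula switch-point recovery over 20 replicates of 80 pairs;
warming monotonicity over 50 paired seasons. All random draws are seeded.

## Known limitations

- The vernalization/photoperiod parameterizations are generic defaults;
  serious variety work requires calibration against observed phenology,
  which is out of scope.
- The SPEI reference is built from calendar-shifted copies of the resolved
  window, not from re-simulated phenology in each reference year; with
  leave-current-in and short references (10–30 years) the index is
  conservative (|SPEI| ≲ 2.7 for n ≤ 100).
- Day-count risk levels are intentionally not classified without local
  impact data.
- The copula estimator smooths discontinuous dependence; with strongly
  imbalanced severity classes the extracted threshold can shift by about
  one indicator unit toward the larger class.
- Single-site only; no missing-data tolerance (explicit validation errors
  instead of gap-filling); °C and mm are assumed, never auto-detected.
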