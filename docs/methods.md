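# Methods

This note documents the model equations as implemented, the parameter
choices that matter, what the synthetic data do and do not emulate, and
the numerical and design decisions that were genuinely open.

## Reference evapotranspiration (weather module)

Daily ETo uses the FAO-56 Penman–Monteith chain: psychrometric constant
from station elevation, saturation vapour pressure from Tmax/Tmin,
actual vapour pressure from mean relative humidity, extraterrestrial
radiation from latitude and day of year, shortwave radiation from
sunshine duration through the Ångström relation with a = 0.25, b = 0.50
(measured solar radiation is accepted instead via a per-record flag),
albedo 0.23, longwave losses with the standard cloudiness and humidity
factors, and soil heat flux G = 0 at the daily step. The result is
clipped at zero. A pre-computed `eto` column in a weather CSV overrides
the computation, reproducing workflows that use a separate ETo
calculator.

Latitude and elevation are required arguments with no default: the
coordinates printed for the reference site are internally inconsistent
with its geography, so the station geometry is configuration, not a
constant. The synthetic climate spec carries Beijing-plausible defaults
(40.18° N, 36 m).

## Soil water balance

The profile is a stack of 0.1 m compartments. The reference profile
carries the three measured layers (0–0.3 m) and extends the deepest
measured layer's properties down to 1.3 m so the 1.2 m maximum rooting
depth fits; no deeper measurements exist, and this extension is an
assumption. The 3.5 m water table is treated as free drainage (no
capillary rise).

Daily order of operations, all in mm (1 %vol over 0.1 m = 1 mm):

1. **Runoff**: SCS curve number with S = 25400/CN − 254 and initial
   abstraction 0.2·S, no antecedent-moisture adjustment — the simplest
   dialect consistent with a single printed CN. Irrigation is assumed
   to be applied without runoff; saturation excess that cannot
   infiltrate anywhere joins the runoff term.
2. **Infiltration**: fills compartments toward saturation top-down.
3. **Drainage**: water above field capacity moves to the compartment
   below at a rate bounded by Ksat per day, cascading top-down; a full
   receiver backs water up.
4. **Evaporation**: from the uncovered fraction (1 − CC) of the surface
   compartment at up to Ke,max·ETo with Ke,max = 1.1. Stage 1 holds
   while cumulative depletion since the last wetting is below the
   readily evaporable water (REW = 9 mm); beyond it the rate falls
   linearly to zero at the totally evaporable water (field capacity
   down to the air-dry floor, 0.5·WP, of the top 0.1 m — 22.9 mm for
   the reference soil). Only the surface layer may dry below WP.
5. **Transpiration**: the demand (from the production module) is
   extracted from rooted compartments proportionally to their available
   water above WP, pro-rata for partially rooted compartments.

Closure `rain + irrigation = runoff + percolation + E + T + ΔS` holds by
construction and is asserted to 10⁻⁶ mm daily and seasonally in tests.

Roots expand from 0.3 m at emergence to 1.2 m following
`Zr = Zr,min + (Zr,max − Zr,min)·t_rel^(1/1.5)` with shape 1.5. The day
at which the maximum is reached is not part of the published parameter
set; the default is 150 days after sowing, i.e. roots complete expansion
during winter/early spring, a standard assumption for autumn-sown wheat.

## Canopy cover and stress

Cover grows per day as `cc·e^(Ks·CGC)` while cc ≤ CCx/2, then
`CCx − (CCx − cc)·e^(−Ks·CGC)`; the two branches join continuously with
the classical closed form. Senescence (from day 236 after sowing)
follows `cc(t) = cc_ref·[1 − 0.05·(e^{(CDC/cc_ref)·t} − 1)]` anchored at
the cover held when decline began, which reaches zero in finite time.

The published table prints CGC and CDC as "%/day" (0.03 and 0.09).
**They are implemented as fractional rates 0.03 d⁻¹ and 0.09 d⁻¹**: a
literal 0.0003 d⁻¹ could not reach CCx = 0.90 within a season, so the
"%" marks the unit of CC, not a division by 100.

Stress coefficients use the convex form
`Ks = 1 − (e^{s_rel·shape} − 1)/(e^{shape} − 1)` between the upper
(onset) and lower (full-stress) depletion thresholds. For leaf
expansion the pair is (0.20, 0.65) with shape 3; stomatal closure and
early senescence have printed onsets 0.65 and 0.70 with the lower
threshold at 1.0 (full stress only at wilting point) and shape 3.
Early senescence under stress multiplies cover by
`e^{−(1 − Ks_sen)·CDC}` per day — the minimal mechanism that makes a
severe drought collapse the canopy before the phenological date while
leaving unstressed seasons untouched.

`cc0` (cover at emergence) is not published; the default 0.045 is a
dense-sown wheat value and is calibratable. The LAI↔CC conversion uses
the Hsiao-form `cc = min(1, 1.005·(1 − e^{−0.6·LAI})^{1.2})` with its
closed-form inverse; manual LAI from leaf measurements uses the
standard wheat leaf-shape factor 0.83 (configurable).

Phenology is in calendar days after sowing (emergence 7, flowering 232
for 10 days, senescence 236, maturity 250 — the harvest date itself is
unpublished; 250 is consistent with late-June harvests and is
configurable). A growing-degree-day mode would be a natural extension;
the base/upper temperatures (0/26 °C) are carried in the parameter set
but unused.

## Production

Transpiration is `Tr = Ks,sto·Kc,Tr·cc*·ETo` with Kc,Tr = 1.1 at full
canopy and `cc* = min(1, 1.72cc − cc² + 0.30cc³)` the micro-advection
adjustment (sparse canopies transpire supra-proportionally). The cubic
slightly exceeds 1 at cc = 1, so it is capped to keep Tr ≤ Kc,Tr·ETo; a
`cc_adjustment` switch disables the cubic entirely.

Biomass: `B += NCWP·Tr/ETo` in g m⁻², reported ×10 as kg ha⁻¹, with
NCWP = 15 g m⁻² held constant through yield formation (no CO₂ or
fertility response — the trials were not nutrient-limited). Harvest
index ramps linearly from 0 at flowering to HI₀ = 0.46 at maturity.
Each flowering-window day with Tmin < 5 °C or Tmax > 35 °C fails its
share of pollination and scales the achievable HI proportionally; any
upward adjustment is capped at +15 % of HI₀ (no upward mechanism is
implemented, so the cap is inert but kept for config fidelity).

## Season driver and calibration

`run_season` is deterministic and logs per-day state. The initial
profile is at field capacity (the trials sowed into a profile at
maximum field capacity); `initial_water` exposes drier starts as a
fraction of plant-available water, used by the drought limiting-case
tests. `hold_at_field_capacity` resets the soil after each day — a
no-stress mode whose biomass must equal the analytic accumulation
`10·NCWP·Σ Kc,Tr·cc*` exactly, which the tests assert to 10⁻⁶.

Calibration minimises the RMSE between simulated and observed cover
(% units; biomass residuals, if provided, are weighted 1/100 so 1 %
cover ≈ 100 kg ha⁻¹) over bounded parameters from
{cgc, cdc, p_sen, p_exp_upper, cc0, hi0}. One free parameter uses
bounded scalar minimisation; several use Nelder–Mead with clipping.
The original study adjusted these parameters manually, so any bounded
derivative-free scheme is faithful to the procedure.

## Evaluation layer

E = 1 − SSE/SST (undefined for constant observations), RMSE, and OLS
lines via `scipy.stats.linregress`; R² is reported as the squared
Pearson correlation of the pairs, matching how simulated-vs-observed
regression panels are read, not as 1 − SSE/SST of the identity line.
Pooled table rows use all pairs with equal weight. WUE treats the
seasonal transpiration column of the trial summary as a depth in mm
(the printed WUE values are only consistent with that reading, e.g.
13072/(10·341.2) = 3.83 kg m⁻³) and converts ×10 to m³ ha⁻¹.

## Synthetic data: what it emulates, and what it does not

The generator targets the site's climate statistics: July mean Tmax
26.1 °C, January mean Tmin −4.7 °C (sinusoid + Gaussian anomalies with
a shared daily term so Tmax ≥ Tmin by construction), ~650 mm annual
rainfall concentrated in summer, and exact sowing-to-harvest totals per
season (rain depths inside the window are rescaled multiplicatively;
if the target is positive and no stochastic rain day fell, it errors
rather than inventing events). Humidity, wind and sunshine are drawn
around station-plausible values. Irrigation templates reproduce the
published schedules verbatim. Observation noise is Gaussian, truncated
so cover stays in [0, 100] %.

Not emulated: rain-spell persistence, winter dormancy of the crop
(calendar-day phenology keeps the canopy growing through winter at low
ETo), frozen-soil processes, and interannual structure. Consequently
the synthetic reference season transpires and yields more than the
field crop did (≈380 mm and ≈27 t ha⁻¹ biomass versus 341 mm and
13 t ha⁻¹); passing tests therefore demonstrate internal consistency,
budget closure, stress mechanics and parameter identifiability — not
field-level predictive accuracy, which would require the unpublished
field observation series.

## Numerical choices and degenerate inputs

- Closure and oracle tolerances: 10⁻⁶ mm / kg ha⁻¹ (double precision
  leaves ~10⁻¹³ in practice).
- The senescence exponential is guarded against overflow for
  near-zero reference covers (cover < 10⁻⁶ is treated as dead).
- ks_stress is exactly 1/0 on the plateaus, so threshold switching is
  discontinuity-free at the boundaries themselves.
- Weather CSVs are written with fixed 6-decimal formatting so
  write∘read∘write is bitwise stable; malformed rows report their file
  line number; date gaps are rejected before simulation.
- The sunset-hour-angle argument is clamped to [−1, 1] so polar
  latitudes do not produce NaNs.

## Irrigation-frequency behaviour

Adding an irrigation event to a schedule never decreases seasonal
Σ(Tr/ETo) or grain yield, and splitting a single application too large
for the root zone's remaining storage into smaller doses never yields
less than the lump — both asserted as properties. Strict monotonicity
of yield in the number of events at fixed total water does **not** hold
in this model family: very frequent small wettings keep the surface
layer in stage-1 evaporation and lose more water to E, so the yield
response to frequency is hump-shaped. This is a real two-way trade-off
(deep losses versus surface losses), not a numerical artefact.

## Known limitations

Calendar-day phenology without dormancy or GDD; no capillary rise,
salinity, fertility stress or CO₂ response; single-field scope; the
sub-0.3 m soil extension and `maturity_day`/`max_root_day`/`cc0`
defaults are assumptions exposed as configuration.
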