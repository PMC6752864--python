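# Methods

## Scope

`socsim` computes *attainable* SOC stocks — the asymptotic equilibrium a
soil approaches under fixed vegetation, management and near-past climate —
and mean mineralization rates, per land-use class and per territorial
unit. It is a "static world" model: climate normals repeat every year,
yields are constant, and no climate-change forcing is applied. Leaching,
erosion, fire and tillage are outside the model's process scope.

## Turnover kernel

Five pools (DPM, RPM, BIO, HUM, IOM), monthly step. Each active pool
loses the fraction `1 − exp(−k·a·b·c/12)` per month with rate constants
`k` = 10 (DPM), 0.3 (RPM), 0.66 (BIO), 0.02 (HUM) yr⁻¹. Published
restatements of these constants occasionally permute the BIO/HUM labels;
this package keeps the canonical RothC-26.3 assignment (BIO = 0.66,
HUM = 0.02), configurable through `RothCParams`.

Rate modifiers:

* **Temperature** `a = 47.91 / (1 + exp(106.06/(T + 18.27)))`, zero at
  and below −18.27 °C.
* **Moisture** — the accumulated topsoil moisture deficit grows by
  `0.75·pan − water` in months where evaporation exceeds water input and
  drains by the surplus otherwise (floored at zero). The maximum deficit
  is `(20 + 1.3·clay − 0.01·clay²)·depth/23` mm; bare soil cannot dry
  beyond max/1.8 (a deficit already deeper, inherited from covered
  months, is retained but does not grow). The modifier is 1 below 0.444
  of the maximum and declines linearly to 0.2 at the maximum. The
  default minimum of 0.2 is kept rather than the 0.1 dry-region variant;
  comparative applications report the two to be statistically
  indistinguishable at regional scale, and the value is configurable.
* **Cover** `c` = 0.6 for covered months, 1.0 bare.

Decomposed carbon splits into CO₂ : (BIO+HUM) as `x : 1` with
`x = 1.67(1.85 + 1.60·e^(−0.0786·clay))`, the remainder 46 % BIO / 54 %
HUM. Plant inputs split DPM : RPM by the class ratio (1.44 cropland and
grassland, 0.25 forest; the grassland default corresponds to improved
grassland — 0.67 would be the unimproved variant, also configurable).
Farmyard manure and grazing dung enter by the fixed FYM split
0.49/0.49/0.02 (DPM/RPM/HUM), applied uniformly over the twelve months
(no monthly manure calendar is assumed). Mass balance is exact by
construction: ΔSOC = inputs − CO₂ each month, and the test suite checks
it to 10⁻⁹ t C/ha over 10⁴ random steps.

Pool initialization from a measured total stock uses pedotransfer
regressions: IOM = 0.049·SOC^1.139, with RPM, HUM and BIO clay-dependent
functions and DPM the non-negative residual. The regressions nearly
exhaust the stock, so the residual is often a small number and
occasionally slightly negative; in that case DPM is clipped to zero and
the active pools rescaled to conserve the total (a RuntimeWarning is
emitted once per call site).

## Water and evaporation forcing

Potential evapotranspiration follows Thornthwaite (heat index
`I = Σ(T/5)^1.514` over months above 0 °C; exponent cubic in `I`;
day-length and month-length correction). Months at or below 0 °C
evaporate nothing; above 26.5 °C the standard quadratic high-temperature
branch applies, evaluated at no more than 38 °C (the quadratic's
plateau). Open-pan evaporation is 0.75·PET; the kernel applies its own
0.75 factor to open-pan when accruing moisture deficit, so PET→pan and
pan→ET are deliberately two distinct steps and are not double-counted.

Crop water requirement is kc·PET with a per-class monthly kc profile: a
development–mid–late trapezoid (0.35 → 1.15 → 0.70) over the growing
season for annual crops, constant 0.7 for permanent canopies. Irrigation
is the positive part of requirement minus precipitation, computed per
Monte-Carlo draw from that draw's precipitation; rainfed schedules
receive precipitation only, so irrigated water input dominates rainfed
month by month.

## Carbon inputs

Annual crop residue carbon: above-ground residue DM = slope·yield +
intercept; below-ground = bg_ratio·(yield + above); carbon content 0.40
kg C/kg DM throughout. If residues are removed only the below-ground
part enters the soil. Monthly allocation: 50 % in the harvest month and
50/3 % in each of the three months before (cereals; the same rule is
applied to other annual crops, for which no separate convention exists);
70 % in the pruning month and 30/4 % in each of the four months before
(permanent crops; "pruning months" is read as one month per crop);
uniform for forest and grassland. Allocation wraps across the year
boundary and conserves the annual total to 10⁻⁹.

Manure: fertilizer nitrogen (default 0.10 ± 0.02 t N/ha/yr) times the
scenario fraction (0, 50 or 100 % of N applied as manure) times the
manure C:N ratio of 14. Grassland additionally receives grazing dung,
stocking (0.5 ± 0.15 LU/ha) times an excretion rate of 0.3 t C per
livestock unit per year, as direct excretion carbon. Bedding material is
excluded. With these defaults the 100 %-manure scenario adds ≈1.4 t
C/ha/yr, a strong treatment; the computed fertilization effect scales
essentially linearly with the assumed N rate.

Forest litter ramps linearly from zero to the mature rate over the
maturity period (default 20 years) and is constant after. Mature rates
are zone-dependent defaults (0.8–4.5 t C/ha/yr broadleaf; needleleaf
85 % of broadleaf).

Soil cover: permanent crops, forests and grasslands are covered all
year; cereals with residues left likewise; other annual crops from
sowing to harvest inclusive.

### Water-limited yields

Irrigation raises attainable SOC only through carbon inputs — in the
kernel itself more water accelerates decomposition. The package models
the input side with the standard FAO-33 yield response: usable water in
a month is capped at that month's crop requirement, the seasonal
sufficiency `q` is summed usable water over summed requirement, and
relative yield is `max(0, 1 − ky(1 − q))` with ky = 1.25. Irrigated
schedules meet the requirement by construction (factor 1); rainfed crops
in water-limited units lose yield and hence residue carbon. On the
synthetic atlas this yields irrigation effects of roughly +0.3 to +9
t C/ha (mean ≈ +3–5), always non-negative in water-limited units —
residue retention remains the larger lever, and the two reinforce each
other.

## Monte-Carlo layer

100 iterations per unit × class × scenario, 86 simulated years, 87
stored annual stocks including t = 0. A master seed deterministically
spawns one seed per iteration; each iteration draws monthly temperatures
and precipitation, clay, initial SOC, yield, fertilizer N and stocking
once from independent normal distributions truncated at physical bounds
(rejection sampling with a clip fallback; zero standard deviations
reproduce the means exactly, collapsing the ensemble to a single
repeated trajectory). Climate months are drawn independently; no
cross-variable or spatial correlation is imposed. The moisture-deficit
state persists across the 86 years within a run.

## Exponential reduction

Each iteration's annual series is fitted separately with
`SOC(t) = K/α(1−e^(−αt)) + SOC₀e^(−αt)`, SOC₀ fixed to the series value
at the fit origin, by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, K > 0, 0 < α ≤ 50). Initial values are
tried from a grid of mineralization rates (0.02, 0.005, 0.05, 0.1, 0.3,
1.0 yr⁻¹; K₀ = α₀·SOC_end) until convergence; a series failing the whole
grid is returned flagged, never as silent NaN. A series that is constant
to within 10⁻⁹ (relative) short-circuits: the asymptote is the constant
level and α is reported at a nominal 0.05 yr⁻¹, since it is
unidentifiable there. Forest classes are fitted from the maturity year
onward, where litter input is constant and the reduced model applies;
the transient is never fitted. Fitting each iteration and then
aggregating (rather than fitting the ensemble mean) yields uncertainty
on K, α and K/α directly; summaries report mean, sample sd and a
normal-theory 95 % CI of the mean.

Settling times ("years to 95 % of attainable") are measured on the
ensemble-mean trajectory as the *last* year outside the band of 5 % of
the initial gap around the asymptote, so dip-and-recover forest
transitions are not credited for crossing the band early; values are
censored at the series length.

## Synthetic atlas

The generator emulates the statistical structure of the GIS products a
real deployment would intersect: four thermal zones (boreal, temperate,
subtropical, tropical) drawn from a configurable mix; per-unit seasonal
climate (annual-mean temperature, seasonal amplitude and annual
precipitation drawn uniformly within zone envelopes; northern-hemisphere
phase); clay and initial SOC uniform within configured ranges; each
variable's standard deviation set to `relative_sd` (default 0.10) times
the absolute value of its mean; day length from solar geometry at a
representative latitude band per zone. Feasibility masks: grassland
everywhere, forest classes only in their matching zone, each crop
feasible with a zone-dependent probability (0.25 boreal to 0.6
temperate), applied to all management variants of the crop at once.
Generation is bit-identical under a fixed seed.

What it does *not* emulate — and what passing tests therefore do not
show about real data: spatial autocorrelation between units, correlation
between climate, soil and yields within a unit, non-normal and skewed
input distributions (clay is empirically rarely normal), realistic
zone-conditional initial stocks (initial SOC is drawn independently of
climate, so e.g. low-stock warm units occur more often than in nature),
and country-level yield structure.

## Problem sizes

The test suite runs the qualitative atlas checks at 10 units × 50
iterations × 86 years and the calibration checks at 100 iterations;
`scripts/acceptance.py` uses 12 units × ~20 class/scenario combinations
× 100 iterations × 86 years plus a 500-unit null calibration, about one
minute on one CPU. Sizes are package defaults chosen to keep a full run
interactive; all scale linearly.

## Known limitations

* The single-pool reduction's asymptote is only as meaningful as the
  reduced model's fit. Started far from equilibrium, the fitted K/α
  tracks the 86-year window rather than the kernel's true multi-pool
  steady state (runs from SOC₀ = 30 vs 90 t C/ha under identical forcing
  fit asymptotes differing by ~30 %); near equilibrium the fit recovers
  the analytic steady state to ~1–2 %. This transient sensitivity is
  inherent to reducing a five-pool model to one pool and affects any use
  of the fitted "attainable" as a true equilibrium.
* Post-maturity forest fits can have poorly identified α when the
  post-ramp series is close to flat; attainable (the asymptote) remains
  stable, α less so.
* "Forests settle more slowly than croplands" holds in aggregate, not
  per pair: units whose initial stock is far below the cropland
  asymptote can show croplands drifting to equilibrium more slowly than
  a regrowing forest.
* Cropland-vs-grassland p-values are per-unit one-way ANOVA on the two
  100-member ensembles of fitted attainable stocks, reported raw with no
  multiple-testing correction (matching the per-unit 5 % convention of
  large-scale assessments); across thousands of units the expected 5 %
  false-positive share applies.
* Parameter uncertainty of the kernel itself (rate constants, modifier
  shapes) is not propagated; only input uncertainty is.
* Registry defaults (yields, residue coefficients, calendars, kc
  profiles, litter rates, fertilizer N, stocking) are round,
  crop-plausible configuration values, not a reproduction of any
  national dataset; conclusions drawn from the bundled synthetic atlas
  are methodological, not geographic.
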