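# Methods

This note documents the models, numerical choices and limitations behind
`warmsoil`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Chamber fluxes

The closed static chamber accumulates CO₂; the concentration slope over a
120-s window (ordinary least squares on the (t, ppm) points inside the
window; at least three points required) is converted to an areal flux with
the ideal-gas molar density of air, F = slope · p/(R·T_K) · V/A. Since ppm is
µmol mol⁻¹, the product is directly in µmol m⁻² s⁻¹; at 20 °C and 101.325 kPa
the molar density is 41.6 mol m⁻³, so a 1 ppm s⁻¹ slope under a 0.1-m
effective chamber height is 4.16 µmol m⁻² s⁻¹. A legacy arithmetic that
*multiplies* by the STP molar volume (22.41 L mol⁻¹ /1000) instead of
dividing by the ambient molar volume appears in some field protocols; it is
retained behind `compute_chamber_flux(..., literal=True)` strictly for
auditing old spreadsheets — its output is not in µmol m⁻² s⁻¹ and it never
feeds the budgets. Root-incubation fluxes use the same conversion on the
5–15-min window of the incubation record, normalised per gram of root dry
mass, with a configurable R² quality gate (default 0.99) on the linear fit.

## Temperature response and annual budgets

Soil CO₂ efflux is related to soil temperature at 5 cm by the Gaussian
response R(T) = R₀·exp(aT + bT²). The fit is plot-specific over a three-year
window (the year under consideration ± 1; truncated to two years at the
record edges), by Levenberg–Marquardt on the flux scale with starting values
from the exact quadratic regression of ln R on T. If the full model fails to
converge the pure-exponential reduction (b = 0) is fitted and flagged. With
b = 0, Q10 = e^{10a}. Chamber replicates (three per plot-date) are averaged
arithmetically before fitting; temperatures are plot-local daily means of
the half-hourly record. Fit quality under multiplicative lognormal noise of
σ = 0.2 sits near R² ≈ 0.9 on seasonal temperature spans, which is the noise
level the synthetic campaigns adopt.

Annual budgets are computed two ways: (i) *model route* — daily predicted
fluxes held for 86 400 s, summed over the calendar year and converted with
12.011 g C mol⁻¹; (ii) *interpolation route* — trapezoid integration of the
plot-mean measured fluxes over the year. On noiseless synthetic campaigns
with biweekly year-round sampling the two routes agree within 5%. When
campaigns stop under snow (the realistic chamber protocol), the
interpolation route holds shoulder-season fluxes through the winter and runs
~10% high; this is a property of the estimator, not a bug, and mirrors why
gap-free upscaling needs either a model or a snow-season flux method.

Temperature-log gaps are filled by (i) a neighbouring plot plus a constant
offset estimated from ≥ 7 days of pre-gap overlap, else (ii) linear
regression on air temperature lagged by one day; filled points carry a
provenance flag.

## Warming response and surplus efflux

The per-degree response statistic is 100·(R_w − R_c)/((T_w − T_c)·R_c),
which is zero when the treatments do not differ and recovers exactly 100·g
for data generated as R_w = R_c(1 + g·ΔT). Records with ΔT ≤ 2 °C (heating
off or failing) and records in suspension years are excluded; calendar years
are mapped to warming-year indices per cohort, because blocks entered the
experiment in two waves three years apart. Date-level responses are averaged
within block first, then across blocks per warming year (SD across blocks);
whether pooling across blocks directly would be preferable is unknowable
from the protocol, and the within-block-first choice keeps blocks
exchangeable. Surplus efflux is the block-wise sum of (warmed − control)
annual budgets from each block's first warming year, reported as mean ± SE
across blocks (n = number of blocks). VPD, when used as an interannual
driver, is derived from air temperature and relative humidity with the
Magnus saturation-vapour-pressure form (6.1094·exp(17.625T/(T+243.04)) hPa).

## SOC stocks and the compaction correction

Fine-soil bulk density excludes rock fragments from both mass and volume;
layer stocks are SOC%/100 · BD · thickness (×10 for kg C m⁻²). Because
long-term warming compacts the topsoil (~20% higher BD), warmed stocks are
compared over equal fine-soil mass: the equivalent-mass thickness of a
warmed layer is nominal · BD_control/BD_warmed, which by construction holds
exactly the control layer's fine-soil mass (BD_w · d·BD_c/BD_w = d·BD_c);
the stock correction applies this thickness ratio per layer and per plot
pair (never to treatment means), and the corrected layer *boundaries*
additionally subtract the surplus thickness accumulated above, so corrected
profiles stack (with treatment-typical densities, a 10-cm topsoil corrects
to ~8.4–8.9 cm and the 20-cm profile bottom to ~17 cm). Subtracting the
surplus from the thickness used in the stock itself would break mass
conservation (by BD_w·surplus), so position and mass roles are kept
separate. Seasonal SOC samples are pooled by arithmetic mean per plot-layer
before stocks; multi-core bulk densities pool mass and volume before the
ratio.

DOC fluxes multiply concentration (mg C L⁻¹) by water flux (mm ≡ L m⁻²),
/1000 → g C m⁻²; biweekly samples are pooled to months by volume-weighted
mean concentration.

The budget closure takes the cumulative surplus efflux up to the
stock-assessment year, removes the autotrophic share (default fraction 0.40,
held constant over years), and balances the heterotrophic remainder against
the observed stock change; the residual is the belowground carbon input
needed to close the budget, also expressed per year. The identities
heterotrophic = surplus·(1 − f_a), missing = heterotrophic − |ΔSOC| hold
exactly by construction and are property-tested.

## Radiocarbon model

Each depth (0–10, 10–20 cm) is an independent steady-state three-pool linear
system dC/dt = u + BC with u = (litter input, root input, 0); both inputs
default to the annual aboveground litterfall carbon (190 g C m⁻² yr⁻¹, 50%
C of dry mass) but are independently configurable, since equal inputs are a
modelling convention rather than a measurement. Construction validates
compartmental structure (negative diagonal, non-negative transfers, no
carbon-creating columns). Steady state is C* = −B⁻¹u, and total respiration
release equals total input.

¹⁴C content (fraction-modern-weighted) obeys dx/dt = u·F_atm(t) + (B − λI)x
with λ = 1/8267 yr⁻¹ and Δ¹⁴C = (F − 1)·1000 under the δ¹³C-corrected
convention. The forward solver steps the exact linear propagator e^{(B−λI)h}
with midpoint forcing (default h = 0.1 yr) from radioactive equilibrium with
the atmosphere at 1900; an independent LSODA route is kept for
cross-checking (the two agree to < 0.1‰ over the bomb transient). The
one-pool equilibrium reproduces F = k/(k+λ) to machine precision
(k = 0.01 → −11.95‰).

Fitting minimises sd-weighted Δ¹⁴C residuals over all observation years
jointly, optionally plus relative stock residuals (default 10% pseudo-sd so
stock and isotope misfit contribute comparably — the protocol leaves open
how strongly stocks constrained the fit, and a soft constraint is the
conservative reading). Levenberg–Marquardt with ≥ 5 jittered starts (best
kept). Identifiability note: from Δ¹⁴C alone the two SOC-transfer fractions
a₃₁, a₃₂ are nearly collinear whenever litter and fine-root signatures are
similar — only their input-weighted sum is well determined; the stock
residuals resolve the SOC stock scale, and noiseless round-trips then
recover all five parameters to < 1%. Because of this ridge (truncated by
a₃₁ ≥ 0), uncertainty statements use the likelihood-ratio (F-statistic)
joint region SSR(θ) ≤ SSR(θ̂)(1 + p/(n−p)·F_{0.95}), the standard confidence
region for nonlinear least squares; Wald ellipsoids from the local
covariance badly under-cover here and are not used. A 100-replicate
simulation at 5‰ observation noise attains ≥ 90% coverage of the generating
parameters with this region.

Age and transit-time distributions use the phase-type forms for linear
autonomous systems at steady state: system age density 1ᵀe^{aB}u / 1ᵀC*,
pool-i density (e^{aB}u)_i / C*_i, transit density −1ᵀBe^{tB}u / 1ᵀu. Bin
masses on the uniform grid (default 1 yr, 0–3000 yr) are computed as exact
CDF differences via the survival function (propagating e^{BΔa} once per
bin), so the discretised density integrates to one exactly; the grid doubles
until ≥ 99.9% of the mass is captured and the densities are renormalised to
the captured mass. Means come from the closed forms (−B⁻¹ applied to the
steady-state composition; total stock / total input for transit) and the
median from bracketing on the exact CDF with root refinement, so the
one-pool closed forms (mean 1/k, median ln2/k) are reproduced to ≥ 4
decimals regardless of grid. A 0–20 cm aggregate, when requested, is the
stock-weighted mixture of the two depth distributions — an interpretation,
since depths are modelled as non-interacting.

The Δ¹⁴C mass distribution of a pool at a sampling year maps each age-class
centre a to F_atm(year − a)·e^{−λa} (ages predating the curve take its
earliest, pre-bomb value) and accumulates class masses into Δ¹⁴C bins; its
mean agrees with the forward-model pool value within 2‰ at 1-yr age
resolution, which is the internal consistency check between the two
computations.

## Synthetic experiment

The generator emulates the study conditions: six paired blocks (two cohorts
starting three years apart), +4 °C on snow-free days (day-of-year 105–335)
from each block's first warming year, a suspension year (the 10th warming
year of the first cohort) with no offset, sinusoidal soil temperature with
AR(1) weather noise shared within a block, fluxes drawn from per-plot
Gaussian temperature responses with multiplicative lognormal noise
(σ = 0.2, matching the R² ≈ 0.9 fit quality of field campaigns), and
chamber geometry/pressure typical of a 900-m mountain site. The bomb curve
is analytic (baseline plateau to 1950, linear ramp to 900‰ at 1964,
16-yr-e-folding decline), standing in for a spliced observational record;
real two-column curves are accepted through the same reader. SOC inventories
are lognormal around carbonate-forest-soil layer means with ~20% higher bulk
density under warming; subsoil rock volume is uniform on 0–24%. The
radiocarbon generating rates give bulk-SOC mean ages of ~150 yr (topsoil)
and several centuries (subsoil), slightly faster under warming. Measurement
noise magnitudes (flux σ, 5‰ Δ¹⁴C) are free parameters of the generator, not
site calibrations. All streams derive named sub-seeds from one config seed,
so each table is independently byte-reproducible.

What passing tests show — and do not show: the pipeline recovers known
generating processes of exactly the assumed forms (Gaussian response,
multiplicative effects, three-pool steady state). Real data add model error
the generator does not emulate (moisture effects on respiration, drought
years, non-steady-state carbon inputs, lateral heterogeneity within plots,
snow-season flux methods), so recovery here bounds estimator behaviour, not
field accuracy.

## Problem sizes

Default test and acceptance runs use 2–6 blocks over 4–18 years, 100-replicate
fit simulations, 200 synthetic plot-year fits, and 500-draw property checks;
these sizes make the full suite and the acceptance script each complete in
about two minutes on one CPU while keeping Monte-Carlo standard errors well
inside the asserted tolerances.

## Known limitations

- Non-steady-state (transient-input) radiocarbon modelling, vertical carbon
  transfer between depths, and posterior (Monte-Carlo) uncertainty are out
  of scope.
- The snow-season flux method of the field protocol is not implemented; the
  model route carries winters in upscaling.
- The 40% autotrophic fraction in the budget closure is a constant; its
  interannual variation is unknown.
- Fit uncertainties assume independent Gaussian observation errors at the
  stated sd; Δ¹⁴C measurement error correlation within an AMS wheel is
  ignored.
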