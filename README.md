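# warmsoil

Analysis toolkit for long-term paired-plot **soil-warming experiments** in
forest ecosystems: from raw chamber CO₂ concentration slopes to annual carbon
budgets, treatment-response statistics, soil organic carbon (SOC) stock
accounting, and radiocarbon-constrained estimates of carbon age and transit
time. It is aimed at ecosystem biogeochemists who run (or re-analyse) warming
manipulations and want every step of the computational chain — not just the
statistics — reproducible and testable.

The package models a design in which paired 2 m × 2 m plots (one heated +4 °C
during the snow-free season, one control) are followed for nearly two decades
with biweekly–monthly chamber flux campaigns, half-hourly soil-temperature
logging, a soil inventory, litterfall monitoring, and Δ¹⁴C measurements of
litter, fine roots and bulk SOC at two sampling years. A synthetic-data module
generates all of these inputs with the experiment's statistical structure, so
the full pipeline runs and is tested without any external data.

## What it computes

**Chamber flux** from the concentration slope ΔC/Δt (ppm s⁻¹) with the
ideal-gas molar density of air:

    F = ΔC/Δt · p/(R·T_K) · V/A        [µmol CO₂ m⁻² s⁻¹]

**Temperature response** per plot, fitted over a 3-calendar-year window by
Levenberg–Marquardt:

    R(T) = R₀ · exp(aT + bT²)

with daily mean soil temperature driving daily flux predictions, summed to
annual budgets (g C m⁻² yr⁻¹); a trapezoid-between-campaigns estimate provides
an independent upscaling route.

**Warming response** per block and date, for records with ΔT > 2 °C outside
suspension years:

    response = 100 · (R_w − R_c) / ((T_w − T_c) · R_c)      [% per °C]

**SOC stocks** per layer as SOC% · BD_fine · depth, compared between
treatments on an equivalent-soil-mass basis (warmed layer thickness rescaled
by BD_control/BD_warmed to undo compaction), and a **budget closure** that
partitions the cumulative warming-induced surplus efflux into autotrophic and
heterotrophic shares and balances the latter against the stock change.

**Radiocarbon model**: a steady-state three-pool linear compartment system
(aboveground litter, fine roots, bulk SOC) per depth,

    dC/dt = u + B·C,   B = [[−k₁,0,0],[0,−k₂,0],[a₃₁k₁, a₃₂k₂, −k₃]]

forced by the atmospheric Δ¹⁴C history (bomb curve) with radioactive decay
λ = 1/8267 yr⁻¹. The five rates are fitted to Δ¹⁴C observations (and observed
stocks) by Levenberg–Marquardt; carbon **age** and **transit-time**
distributions follow from the phase-type forms f(a) ∝ 1ᵀe^{aB}u, and the
**Δ¹⁴C mass distribution** of a pool maps its age classes through the
atmospheric curve.

## Worked example

The numbered scripts under `analysis/` run the whole chain on the synthetic
experiment (6 blocks, 2005–2022, +4 °C snow-free warming, warming suspended
in 2014) and write tidy tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_flux_budgets.py
python analysis/03_warming_response.py
python analysis/04_soc_stocks.py
python analysis/05_radiocarbon.py
```

Output of `03_warming_response.py` (seed 1):

```
1836 block-dates, 255 dropped (dT <= 2 degC or suspension year 2014)
mean response: 8.7 %/degC across 18 warming years
cumulative surplus efflux (interpolation): 4.02 +/- 0.80 kg C m-2
cumulative surplus efflux (model): 2.64 +/- 0.75 kg C m-2
```

i.e. warming raised soil CO₂ efflux by ~9% per °C at the dates retained by
the ΔT filter, and over 18 years the warmed plots emitted ~4 kg C m⁻² more
than their paired controls (block-level SE). `05_radiocarbon.py` prints the
fitted carbon ages:

```
control 0-10 cm: SOC age 164 (114) yr, system 158 (108) yr, transit 48 yr
warmed  10-20 cm: SOC age 435 (302) yr, ...
warming rejuvenates SOC at 10-20 cm by 248 yr (mean age)
```

— the faster bulk-SOC turnover under warming shifts the age distribution
toward young, recently fixed carbon.

A `warmsoil` CLI exposes the same stages (`warmsoil run --out results/run
--seed 1`, plus `c14-fit` / `c14-age` / `c14-transit` / `c14-dist` for
radiocarbon work on user-supplied CSV tables); every run writes a manifest
(config, seed, file digests) that fully determines a re-run.

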