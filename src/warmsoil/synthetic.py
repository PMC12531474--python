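"""Synthetic inputs with the statistical structure of the warming experiment.

Generates every table the pipeline consumes: paired-plot daily soil climate
with a +4 degC snow-free-season warming offset (and a warming-suspension
year), chamber flux campaigns drawn from a Gaussian temperature response
with multiplicative lognormal noise, plot-level SOC inventories with
lognormal heterogeneity and warming-compacted bulk density, an analytic
bomb-spike atmospheric Delta-14C curve, and Delta-14C observations
forward-simulated from a known three-pool model.

All randomness flows from one config seed through named per-stream
sub-seeds, so each generator is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from warmsoil.flux import TempResponseParams, molar_air_density
from warmsoil.radiocarbon import AtmosphericCurve, CompartmentModel, forward_delta14c
from warmsoil.response import PlotPair

ROCK_DENSITY = 2.65  # g cm^-3, mineral rock fragments

# chamber geometry: 20 cm diameter, 10 cm height
CHAMBER_AREA = float(np.pi * 0.10**2)  # m^2
CHAMBER_VOLUME = CHAMBER_AREA * 0.10  # m^3
SITE_PRESSURE = 91_000.0  # Pa, ~910 m a.s.l.

_STREAMS = {
    "climate": 1,
    "campaign": 2,
    "inventory": 3,
    "radiocarbon": 4,
    "params": 5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults mirror the field setup: six paired blocks, +4 degC during the
    snow-free season (day-of-year 105-335), an 18-year record with the two
    cohort start years three years apart, warming suspended in the 10th
    warming year of the first cohort, ~20% higher bulk density under
    warming.
    """

    seed: int = 0
    n_blocks: int = 6
    warming_offset: float = 4.0
    snow_free_window: tuple[int, int] = (105, 335)
    years: tuple[int, int] = (2005, 2022)
    flux_noise_sigma: float = 0.2
    c14_noise_sigma: float = 5.0
    soc_lognormal_cv: float = 0.2
    bd_warming_ratio: float = 1.2
    cohort_lag_years: int = 3
    suspension_year: int | None = None  # default: 10th warming year of cohort 1

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.warming_offset < 0:
            raise ValueError("warming_offset must be >= 0")
        if self.years[1] < self.years[0]:
            raise ValueError("years range reversed")

    @property
    def suspension(self) -> int:
        if self.suspension_year is not None:
            return self.suspension_year
        return self.years[0] + 9

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass(frozen=True)
class BombCurveParams:
    """Analytic stand-in for the spliced observational bomb-14C record.

    Baseline plateau before 1950, linear rise to the peak, exponential
    relaxation back toward the baseline (e-folding ``decline_timescale``).
    """

    baseline: float = 0.0  # per mil
    peak_year: float = 1964.0
    peak_value: float = 900.0  # per mil
    decline_timescale: float = 16.0  # years

    def __post_init__(self) -> None:
        if self.peak_year <= 1950:
            raise ValueError("peak_year must be after 1950")
        if self.decline_timescale <= 0:
            raise ValueError("decline_timescale must be > 0")


def synth_atmospheric_curve(
    params: BombCurveParams = BombCurveParams(),
    year_range: tuple[float, float] = (1900.0, 2025.0),
    step: float = 0.5,
) -> AtmosphericCurve:
    """Piecewise analytic atmospheric Delta-14C curve on a uniform grid."""
    lo, hi = year_range
    if hi <= lo:
        raise ValueError("empty year range")
    if lo > 1900.0 or hi < 2022.0:
        raise ValueError("year_range must cover at least 1900-2022")
    years = np.arange(lo, hi + step / 2, step)
    vals = np.full_like(years, params.baseline)
    ramp = (years > 1950.0) & (years <= params.peak_year)
    vals[ramp] = params.baseline + (params.peak_value - params.baseline) * (
        years[ramp] - 1950.0
    ) / (params.peak_year - 1950.0)
    tail = years > params.peak_year
    vals[tail] = params.baseline + (params.peak_value - params.baseline) * np.exp(
        -(years[tail] - params.peak_year) / params.decline_timescale
    )
    return AtmosphericCurve(years, vals, provenance="synthetic")


def plot_pairs(config: SyntheticConfig) -> list[PlotPair]:
    """Paired-plot structure: half the blocks start warming three years later."""
    pairs = []
    split = (config.n_blocks + 1) // 2
    for b in range(1, config.n_blocks + 1):
        start = config.years[0] if b <= split else config.years[0] + config.cohort_lag_years
        pairs.append(
            PlotPair(
                block_id=f"B{b}",
                control_plot_id=f"B{b}-C",
                warmed_plot_id=f"B{b}-W",
                first_warming_year=start,
                suspension_years=frozenset({config.suspension}),
            )
        )
    return pairs


def _snow_free(doy: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    return (doy >= window[0]) & (doy <= window[1])


def synth_soil_climate(
    config: SyntheticConfig,
    mean_temp: float = 6.5,
    amplitude: float = 7.5,
    ar_phi: float = 0.8,
    ar_sigma: float = 1.0,
) -> pd.DataFrame:
    """Daily soil temperature (5 cm) per plot: plot_id, date, soil_temp_5cm_c.

    Control plots follow a sinusoidal annual cycle (coldest in late January)
    plus AR(1) day-to-day weather noise shared within a block; the paired
    warmed plot equals its control plus the warming offset on snow-free days
    from its first warming year on, except in the suspension year.
    """
    dates = pd.date_range(
        f"{config.years[0]}-01-01", f"{config.years[1]}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy()
    year = dates.year.to_numpy()
    seasonal = mean_temp - amplitude * np.cos(2.0 * np.pi * (doy - 28) / 365.25)
    rng = config.rng("climate")
    frames = []
    for pair in plot_pairs(config):
        noise = np.empty(len(dates))
        eps = rng.normal(0.0, ar_sigma, len(dates))
        noise[0] = eps[0]
        for i in range(1, len(dates)):
            noise[i] = ar_phi * noise[i - 1] + eps[i]
        control = seasonal + noise
        heated = (
            _snow_free(doy, config.snow_free_window)
            & (year >= pair.first_warming_year)
            & (year != config.suspension)
        )
        warmed = control + np.where(heated, config.warming_offset, 0.0)
        frames.append(
            pd.DataFrame(
                {"plot_id": pair.control_plot_id, "date": dates, "soil_temp_5cm_c": control}
            )
        )
        frames.append(
            pd.DataFrame(
                {"plot_id": pair.warmed_plot_id, "date": dates, "soil_temp_5cm_c": warmed}
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_true_params(config: SyntheticConfig) -> dict[str, TempResponseParams]:
    """Per-plot generating parameters of the Gaussian temperature response.

    Base rates near 1 umol m^-2 s^-1 at 0 degC equivalent, exponential
    sensitivity around a = 0.11 degC^-1 (Q10 ~ 3 at low T) with mild
    high-temperature curvature b < 0, jittered across plots.
    """
    rng = config.rng("params")
    out = {}
    for pair in plot_pairs(config):
        for plot in (pair.control_plot_id, pair.warmed_plot_id):
            out[plot] = TempResponseParams(
                plot_id=plot,
                window_years=config.years,
                R0=float(0.9 * np.exp(rng.normal(0.0, 0.1))),
                a=float(rng.normal(0.11, 0.005)),
                b=float(rng.normal(-0.0015, 0.0003)),
            )
    return out


def synth_flux_campaign(
    config: SyntheticConfig,
    climate: pd.DataFrame,
    true_params: dict[str, TempResponseParams] | None = None,
    sampling_interval_days: int = 14,
    n_chambers: int = 3,
    sampling_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Chamber flux campaign table in the flux-campaign CSV dialect.

    Measurement dates run at ``sampling_interval_days`` through each
    ``sampling_window`` (day-of-year; defaults to the snow-free window, as
    chambers cannot be run under snow — pass (1, 365) to emulate campaigns
    complemented by snow-season flux estimates); each plot-date carries
    ``n_chambers`` replicate chambers whose
    true flux R0*exp(a*T + b*T^2) is perturbed by lognormal noise and then
    re-expressed as the raw concentration slope the chamber would have
    recorded (so the flux engine is exercised end to end).
    """
    if true_params is None:
        true_params = default_true_params(config)
    rng = config.rng("campaign")
    clim = climate.set_index(["plot_id", "date"])["soil_temp_5cm_c"]
    lo_doy, hi_doy = sampling_window or config.snow_free_window
    rows = []
    for year in range(config.years[0], config.years[1] + 1):
        season = pd.date_range(
            pd.Timestamp(year, 1, 1) + pd.Timedelta(days=lo_doy - 1),
            pd.Timestamp(year, 1, 1) + pd.Timedelta(days=hi_doy - 1),
            freq=f"{sampling_interval_days}D",
        )
        for date in season:
            for plot, params in true_params.items():
                try:
                    soil_t = float(clim[(plot, date)])
                except KeyError:
                    continue
                air_t = soil_t + float(rng.normal(2.0, 1.5))
                density = molar_air_density(SITE_PRESSURE, air_t)
                for chamber in range(1, n_chambers + 1):
                    noise = (
                        float(np.exp(rng.normal(0.0, config.flux_noise_sigma)))
                        if config.flux_noise_sigma > 0
                        else 1.0
                    )
                    true_flux = float(params.predict(soil_t)) * noise
                    slope = true_flux / (density * CHAMBER_VOLUME / CHAMBER_AREA)
                    rows.append(
                        (
                            plot,
                            date + pd.Timedelta(hours=9, minutes=30),
                            f"ch{chamber}",
                            slope,
                            air_t,
                            SITE_PRESSURE,
                            CHAMBER_VOLUME,
                            CHAMBER_AREA,
                            soil_t,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "datetime",
            "chamber_id",
            "conc_slope_ppm_s",
            "air_temp_c",
            "pressure_pa",
            "volume_m3",
            "area_m2",
            "soil_temp_5cm_c",
        ],
    )


_LAYER_MEANS = {
    # layer: (SOC % control, SOC % warmed, BD control g cm^-3)
    "0-10": (12.3, 11.5, 0.53),
    "10-20": (7.1, 5.7, 0.59),
}


def synth_soc_inventory(
    config: SyntheticConfig,
    core_volume_cm3: float = 100.0,
    max_rock_fraction: float = 0.24,
    bd_plot_cv: float = 0.05,
) -> pd.DataFrame:
    """Per-plot soil inventory in the inventory CSV dialect.

    SOC concentrations are lognormal around carbonate-soil layer means;
    warmed bulk density is the control value times ``bd_warming_ratio``
    times plot-level noise. Rock volume fraction is negligible in the
    topsoil and uniform on [0, 0.24] in the subsoil.
    """
    rng = config.rng("inventory")
    rows = []
    for pair in plot_pairs(config):
        for layer, (conc_c, conc_w, bd_c_mean) in _LAYER_MEANS.items():
            bd_control = bd_c_mean * float(np.exp(rng.normal(0.0, bd_plot_cv)))
            bd_ratio = config.bd_warming_ratio * float(
                np.exp(rng.normal(0.0, bd_plot_cv))
            )
            for plot, treat, conc_mean, bd in (
                (pair.control_plot_id, "control", conc_c, bd_control),
                (pair.warmed_plot_id, "warmed", conc_w, bd_control * bd_ratio),
            ):
                sigma = np.sqrt(np.log1p(config.soc_lognormal_cv**2))
                conc = float(
                    conc_mean * np.exp(rng.normal(-sigma**2 / 2.0, sigma))
                )
                rock_frac = (
                    0.0 if layer == "0-10" else float(rng.uniform(0.0, max_rock_fraction))
                )
                rock_vol = rock_frac * core_volume_cm3
                fine_vol = core_volume_cm3 - rock_vol
                fine_mass = bd * fine_vol
                rock_mass = rock_vol * ROCK_DENSITY
                rows.append(
                    (
                        plot,
                        treat,
                        layer,
                        conc,
                        fine_mass + rock_mass,
                        rock_mass,
                        core_volume_cm3,
                        rock_vol,
                        10.0,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "treatment",
            "layer",
            "soc_pct",
            "core_total_mass_g",
            "core_rock_mass_g",
            "core_total_vol_cm3",
            "core_rock_vol_cm3",
            "nominal_thickness_cm",
        ],
    )


_DEFAULT_C14_RATES = {
    # (treatment, depth): k1, k2, k3, a31, a32 — turnover of litter and fine
    # roots on the order of 1-3 yr, bulk SOC on the order of 150 yr in the
    # topsoil and several centuries in the subsoil, faster under warming.
    ("control", "0-10"): (0.80, 0.50, 0.0065, 0.25, 0.35),
    ("warmed", "0-10"): (0.85, 0.55, 0.0068, 0.26, 0.36),
    ("control", "10-20"): (0.70, 0.45, 0.0015, 0.10, 0.20),
    ("warmed", "10-20"): (0.75, 0.50, 0.0022, 0.12, 0.24),
}

LITTERFALL_C_INPUT = 190.0  # g C m^-2 yr^-1, aboveground litter at 50% C


def default_radiocarbon_model(
    treatment: str = "control",
    depth: str = "0-10",
    litter_input: float = LITTERFALL_C_INPUT,
    root_input: float | None = None,
) -> CompartmentModel:
    """Study-condition three-pool model for one treatment and depth."""
    k1, k2, k3, a31, a32 = _DEFAULT_C14_RATES[(treatment, depth)]
    return CompartmentModel.from_rates(
        k1, k2, k3, a31, a32, litter_input, root_input, depth=depth, treatment=treatment
    )


def synth_radiocarbon_obs(
    model: CompartmentModel,
    curve: AtmosphericCurve,
    obs_years: tuple[float, ...] = (2012.0, 2019.0),
    noise_sigma: float = 5.0,
    seed: int = 0,
    t_start: float = 1900.0,
) -> pd.DataFrame:
    """Delta-14C observation table forward-simulated from a known model.

    One row per pool and observation year with Gaussian measurement noise of
    ``noise_sigma`` per mil; the reported measurement uncertainty
    ``sd_permil`` is the noise level (a nominal 1 per mil when noiseless).
    """
    lo, hi = curve.support
    if min(obs_years) < lo or max(obs_years) > hi:
        raise ValueError("observation year outside the atmospheric-curve support")
    rng = np.random.default_rng(seed)
    traj = forward_delta14c(model, curve, (t_start, float(max(obs_years))))
    t = traj.index.to_numpy()
    rows = []
    for year in obs_years:
        for pool in model.pool_names:
            true = float(np.interp(year, t, traj[pool].to_numpy()))
            noisy = true + (rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0)
            rows.append(
                (
                    float(year),
                    pool,
                    model.depth,
                    model.treatment,
                    noisy,
                    noise_sigma if noise_sigma > 0 else 1.0,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["year", "pool", "depth", "treatment", "delta14c_permil", "sd_permil"],
    )
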