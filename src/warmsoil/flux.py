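"""Chamber and incubation CO2 fluxes, temperature-response fitting, upscaling.

The measurement chain: a closed static chamber accumulates CO2; the
concentration slope (ppm s^-1) over a fixed window is converted to an areal
flux with the ideal-gas molar density of air; per-plot fluxes are related to
soil temperature at 5 cm with a Gaussian response

    R(T) = R0 * exp(a*T + b*T^2)

fitted over a three-calendar-year window, and daily mean soil temperatures
drive daily flux predictions that are summed to annual carbon budgets.
An interpolation-based annual budget (trapezoid between measurement dates)
provides an independent upscaling route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

R_GAS = 8.31446  # J mol^-1 K^-1
C_MOLAR_MASS = 12.011  # g mol^-1
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class FluxMeasurement:
    """One chamber measurement on one plot.

    conc_slope is the headspace CO2 accumulation rate in ppm s^-1 over the
    measurement window; geometry is the chamber volume (m^3) and footprint
    area (m^2); pressure in Pa; temperatures in degC.
    """

    plot_id: str
    datetime: pd.Timestamp
    chamber_id: str
    conc_slope: float
    air_temp: float
    pressure: float
    chamber_volume: float
    chamber_area: float
    soil_temp_5cm: float

    def __post_init__(self) -> None:
        if self.chamber_volume <= 0:
            raise ValueError(f"chamber_volume must be > 0, got {self.chamber_volume}")
        if self.chamber_area <= 0:
            raise ValueError(f"chamber_area must be > 0, got {self.chamber_area}")
        if not 50_000.0 <= self.pressure <= 110_000.0:
            raise ValueError(
                f"pressure {self.pressure} Pa outside plausible 50-110 kPa range"
            )


@dataclass(frozen=True)
class TempResponseParams:
    """Gaussian temperature-response parameters for one plot and window.

    R0 in umol m^-2 s^-1, a in degC^-1, b in degC^-2. ``window_years`` is the
    (first, last) calendar year of the fitting window. ``fallback_exponential``
    flags a fit that had to fix b = 0 after the full model failed to converge.
    """

    plot_id: str
    window_years: tuple[int, int]
    R0: float
    a: float
    b: float
    r_squared: float = float("nan")
    n_obs: int = 0
    fallback_exponential: bool = False

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError(f"R0 must be > 0, got {self.R0}")

    def predict(self, temp_c: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(temp_c, dtype=float)
        out = self.R0 * np.exp(self.a * t + self.b * t * t)
        return out if out.ndim else float(out)

    @property
    def q10(self) -> float:
        """Q10 implied at b = 0; for b != 0 the local Q10 at T = 0."""
        return float(np.exp(10.0 * self.a))


@dataclass(frozen=True)
class AnnualBudget:
    plot_id: str
    year: int
    cumulative_c: float  # g C m^-2 yr^-1
    method: str  # "model" | "interpolation"

    def __post_init__(self) -> None:
        if self.method not in ("model", "interpolation"):
            raise ValueError(f"unknown budget method {self.method!r}")


@dataclass
class TemperatureSeries:
    """Soil temperature at 5 cm for one plot, with per-point fill provenance.

    ``source`` entries are one of {"measured", "air-regression", "neighbor"}.
    """

    plot_id: str
    timestamps: pd.DatetimeIndex
    soil_temp_5cm: np.ndarray
    source: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.soil_temp_5cm = np.asarray(self.soil_temp_5cm, dtype=float)
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if len(self.timestamps) != len(self.soil_temp_5cm):
            raise ValueError("timestamps and values differ in length")
        if not self.source:
            self.source = ["measured"] * len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": self.plot_id,
                "timestamp": self.timestamps,
                "soil_temp_5cm_c": self.soil_temp_5cm,
                "source": self.source,
            }
        )


# ---------------------------------------------------------------------------
# slopes and chamber fluxes
# ---------------------------------------------------------------------------


def estimate_concentration_slope(
    seconds: np.ndarray, ppm: np.ndarray, window: float = 120.0
) -> float:
    """OLS slope (ppm s^-1) of headspace CO2 against time within ``window``.

    Uses the points with 0 <= t <= window; at least three are required.
    """
    t = np.asarray(seconds, dtype=float)
    c = np.asarray(ppm, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("seconds and ppm must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    mask = (t >= 0.0) & (t <= window)
    t, c = t[mask], c[mask]
    if t.size < 3:
        raise ValueError(f"need >= 3 points inside the {window}-s window, got {t.size}")
    if t[-1] - t[0] <= 0:
        raise ValueError("zero time span in window")
    slope, _ = np.polyfit(t, c, 1)
    return float(slope)


def molar_air_density(pressure_pa: float, temp_c: float) -> float:
    """Ideal-gas molar density of air, mol m^-3."""
    t_k = temp_c + 273.15
    if t_k <= 0:
        raise ValueError(f"absolute temperature must be > 0 K, got {t_k}")
    return pressure_pa / (R_GAS * t_k)


def compute_chamber_flux(m: FluxMeasurement, literal: bool = False) -> float:
    """Soil-surface CO2 flux, umol m^-2 s^-1, from one chamber measurement.

    Default: dimensionally consistent ideal-gas form
    ``slope(ppm s^-1) * p/(R*T_K) (mol m^-3) * V/A (m)`` — ppm being
    umol mol^-1, the product is umol m^-2 s^-1.

    ``literal=True`` reproduces, for audit only, the arithmetic
    ``slope * 273.15/(T_air+273.15) * p/1000 * 22.41/1000 * V/A`` as it is
    sometimes written with the STP molar volume as a multiplier; its output
    is NOT in umol m^-2 s^-1 and it should never feed the budgets.
    """
    if literal:
        return (
            m.conc_slope
            * 273.15
            / (m.air_temp + 273.15)
            * m.pressure
            / 1000.0
            * 22.41
            / 1000.0
            * m.chamber_volume
            / m.chamber_area
        )
    density = molar_air_density(m.pressure, m.air_temp)
    return m.conc_slope * density * m.chamber_volume / m.chamber_area


def compute_campaign_fluxes(campaign: pd.DataFrame) -> pd.DataFrame:
    """Vectorised chamber-flux column for a flux-campaign table.

    Adds ``flux_umol_m2_s`` computed with the ideal-gas form from
    conc_slope_ppm_s / air_temp_c / pressure_pa / volume_m3 / area_m2.
    """
    out = campaign.copy()
    t_k = out["air_temp_c"].to_numpy(dtype=float) + 273.15
    if np.any(t_k <= 0):
        raise ValueError("absolute air temperature must be > 0 K")
    density = out["pressure_pa"].to_numpy(dtype=float) / (R_GAS * t_k)
    out["flux_umol_m2_s"] = (
        out["conc_slope_ppm_s"].to_numpy(dtype=float)
        * density
        * out["volume_m3"].to_numpy(dtype=float)
        / out["area_m2"].to_numpy(dtype=float)
    )
    out["datetime"] = pd.to_datetime(out["datetime"])
    return out


def root_incubation_flux(
    minutes: np.ndarray,
    ppm: np.ndarray,
    chamber_volume: float,
    root_dry_mass: float,
    temp_c: float,
    pressure_pa: float = 101_325.0,
    fit_window: tuple[float, float] = (5.0, 15.0),
    r2_floor: float = 0.99,
) -> tuple[float, float]:
    """Root respiration per unit dry mass, umol CO2 g^-1 s^-1.

    A line is fitted to the CO2 rise between ``fit_window`` minutes (default
    5-15); the slope is converted to moles with the incubation-chamber volume
    and ideal-gas density at the incubation temperature, then normalised by
    root dry mass. Returns (flux, r_squared); raises if the linear fit falls
    below the ``r2_floor`` quality gate.
    """
    if root_dry_mass <= 0:
        raise ValueError("root_dry_mass must be > 0")
    if chamber_volume <= 0:
        raise ValueError("chamber_volume must be > 0")
    t = np.asarray(minutes, dtype=float)
    c = np.asarray(ppm, dtype=float)
    lo, hi = fit_window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3 or t.min() > lo or t.max() < hi:
        raise ValueError(f"series does not cover the {lo}-{hi} min window")
    tw, cw = t[mask] * 60.0, c[mask]  # minutes -> seconds
    slope, intercept = np.polyfit(tw, cw, 1)
    pred = slope * tw + intercept
    ss_res = float(np.sum((cw - pred) ** 2))
    ss_tot = float(np.sum((cw - cw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < r2_floor:
        raise ValueError(f"linear fit R^2 {r2:.4f} below QC floor {r2_floor}")
    density = molar_air_density(pressure_pa, temp_c)
    flux = slope * density * chamber_volume / root_dry_mass
    return float(flux), r2


# ---------------------------------------------------------------------------
# temperature response
# ---------------------------------------------------------------------------


def _gaussian_model(t: np.ndarray, r0: float, a: float, b: float) -> np.ndarray:
    return r0 * np.exp(a * t + b * t * t)


def fit_temperature_response(
    temps: np.ndarray,
    fluxes: np.ndarray,
    plot_id: str = "",
    window_years: tuple[int, int] = (0, 0),
    allow_fallback: bool = True,
) -> TempResponseParams:
    """Fit R(T) = R0*exp(a*T + b*T^2) by Levenberg-Marquardt least squares.

    Initial values come from a quadratic regression of ln(flux) on T, which
    is the exact solution of the log-linearised model. If the full model
    fails to converge, the pure-exponential reduction (b = 0) is fitted and
    flagged. R^2 is reported on the fitted (flux) scale.
    """
    t = np.asarray(temps, dtype=float)
    y = np.asarray(fluxes, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y) & (y > 0)
    t, y = t[ok], y[ok]
    if t.size < 6:
        raise ValueError(f"need >= 6 flux-temperature pairs, got {t.size}")
    if np.ptp(t) < 5.0:
        raise ValueError(f"temperature span {np.ptp(t):.2f} degC < 5 degC; degenerate")

    coef = np.polyfit(t, np.log(y), 2)  # b, a, ln R0
    b0, a0, lnr0 = float(coef[0]), float(coef[1]), float(coef[2])

    def _run(fix_b: bool) -> lmfit.minimizer.MinimizerResult:
        params = lmfit.Parameters()
        params.add("r0", value=max(np.exp(lnr0), 1e-8), min=1e-12)
        params.add("a", value=a0)
        params.add("b", value=0.0 if fix_b else b0, vary=not fix_b)

        def resid(p: lmfit.Parameters) -> np.ndarray:
            return _gaussian_model(t, p["r0"].value, p["a"].value, p["b"].value) - y

        return lmfit.minimize(resid, params, method="leastsq")

    result = _run(fix_b=False)
    fallback = False
    if not result.success and allow_fallback:
        result = _run(fix_b=True)
        fallback = True
    if not result.success:
        raise RuntimeError(f"temperature-response fit failed for plot {plot_id!r}")

    p = result.params
    pred = _gaussian_model(t, p["r0"].value, p["a"].value, p["b"].value)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TempResponseParams(
        plot_id=plot_id,
        window_years=window_years,
        R0=float(p["r0"].value),
        a=float(p["a"].value),
        b=float(p["b"].value),
        r_squared=r2,
        n_obs=int(t.size),
        fallback_exponential=fallback,
    )


def fit_plot_year(
    campaign: pd.DataFrame,
    plot_id: str,
    year: int,
    study_years: tuple[int, int] | None = None,
) -> TempResponseParams:
    """Fit the response for one plot-year over its three-year window.

    The window is (year-1, year, year+1), truncated at the study boundary to
    the two available years. ``campaign`` must carry columns
    plot_id / datetime / soil_temp_5cm_c / flux_umol_m2_s (chamber replicates
    are averaged per plot-date before fitting).
    """
    lo, hi = year - 1, year + 1
    if study_years is not None:
        lo, hi = max(lo, study_years[0]), min(hi, study_years[1])
    sub = campaign[
        (campaign["plot_id"] == plot_id)
        & (campaign["datetime"].dt.year >= lo)
        & (campaign["datetime"].dt.year <= hi)
    ]
    daily = plot_date_means(sub)
    return fit_temperature_response(
        daily["soil_temp_5cm_c"].to_numpy(),
        daily["flux_umol_m2_s"].to_numpy(),
        plot_id=plot_id,
        window_years=(lo, hi),
    )


def plot_date_means(campaign: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of chamber replicates per plot and measurement date."""
    work = campaign.assign(date=campaign["datetime"].dt.normalize())
    return work.groupby(["plot_id", "date"], as_index=False).agg(
        soil_temp_5cm_c=("soil_temp_5cm_c", "mean"),
        flux_umol_m2_s=("flux_umol_m2_s", "mean"),
    )


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------


def fill_temperature_gaps(
    series: TemperatureSeries,
    air_temp: pd.Series | None = None,
    neighbor: TemperatureSeries | None = None,
    pre_gap_days: int = 7,
    lag_days: int = 1,
) -> TemperatureSeries:
    """Fill missing soil temperatures (NaN) by neighbor offset or air regression.

    For each gap, (i) if a neighbor-plot series covers the gap and at least
    ``pre_gap_days`` of the pre-gap window, the gap is filled with
    ``neighbor + offset`` where the offset is the mean pre-gap difference;
    otherwise (ii) a linear regression of soil temperature on air temperature
    lagged by ``lag_days`` over the pre-gap window is used. Filled points are
    flagged in ``source``.
    """
    values = series.soil_temp_5cm.copy()
    source = list(series.source)
    ts = series.timestamps
    missing = ~np.isfinite(values)
    if not missing.any():
        return TemperatureSeries(series.plot_id, ts, values, source)

    neigh = None
    if neighbor is not None:
        neigh = pd.Series(neighbor.soil_temp_5cm, index=neighbor.timestamps)
    air = None
    if air_temp is not None:
        air = pd.Series(np.asarray(air_temp.values, dtype=float), index=air_temp.index)

    # contiguous gap runs
    idx = np.flatnonzero(missing)
    runs: list[tuple[int, int]] = []
    start = idx[0]
    for i, j in zip(idx[:-1], idx[1:]):
        if j != i + 1:
            runs.append((start, i))
            start = j
    runs.append((start, idx[-1]))

    pre_window = pd.Timedelta(days=pre_gap_days)
    lag = pd.Timedelta(days=lag_days)
    for i0, i1 in runs:
        gap_times = ts[i0 : i1 + 1]
        gap_start = gap_times[0]
        pre_mask = (ts >= gap_start - pre_window) & (ts < gap_start) & ~missing
        filled = False
        if neigh is not None:
            pre_n = neigh.reindex(ts[pre_mask])
            gap_n = neigh.reindex(gap_times)
            if pre_n.notna().all() and gap_n.notna().all() and pre_mask.sum() >= 2:
                offset = float(np.mean(values[pre_mask] - pre_n.to_numpy()))
                values[i0 : i1 + 1] = gap_n.to_numpy() + offset
                for k in range(i0, i1 + 1):
                    source[k] = "neighbor"
                filled = True
        if not filled and air is not None:
            pre_air = air.reindex(ts[pre_mask] - lag)
            gap_air = air.reindex(gap_times - lag)
            if pre_air.notna().all() and gap_air.notna().all() and pre_mask.sum() >= 3:
                slope, intercept = np.polyfit(pre_air.to_numpy(), values[pre_mask], 1)
                values[i0 : i1 + 1] = slope * gap_air.to_numpy() + intercept
                for k in range(i0, i1 + 1):
                    source[k] = "air-regression"
                filled = True
        if not filled:
            raise ValueError(
                f"no predictor overlaps the {pre_gap_days}-day pre-gap window "
                f"before {gap_start}"
            )
    return TemperatureSeries(series.plot_id, ts, values, source)


# ---------------------------------------------------------------------------
# upscaling
# ---------------------------------------------------------------------------


def daily_mean_temperature(log: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic daily means of (half-hourly) soil temperature per plot."""
    work = log.assign(date=log["timestamp"].dt.normalize())
    return work.groupby(["plot_id", "date"], as_index=False).agg(
        soil_temp_5cm_c=("soil_temp_5cm_c", "mean")
    )


def predict_daily_flux(
    params: TempResponseParams, daily_temp: pd.Series
) -> pd.Series:
    """Daily flux (umol m^-2 s^-1) from daily mean soil temperature."""
    return pd.Series(
        params.predict(daily_temp.to_numpy()), index=daily_temp.index, name="flux"
    )


def annual_sum_modeled(
    daily_flux: pd.Series, year: int, plot_id: str = ""
) -> AnnualBudget:
    """Annual cumulative efflux (g C m^-2 yr^-1) from complete daily fluxes.

    Each daily rate (umol m^-2 s^-1) is held for 86400 s and converted to
    grams of carbon (12.011 g mol^-1).
    """
    idx = pd.DatetimeIndex(daily_flux.index)
    sel = daily_flux[idx.year == year]
    n_days = 366 if pd.Timestamp(year=year, month=12, day=31).is_leap_year else 365
    if len(sel) != n_days:
        raise ValueError(f"year {year} has {len(sel)} daily values, expected {n_days}")
    total_umol = float(sel.sum()) * SECONDS_PER_DAY
    return AnnualBudget(plot_id, year, total_umol * C_MOLAR_MASS * 1e-6, "model")


def annual_sum_interpolated(
    dates: pd.DatetimeIndex, fluxes: np.ndarray, year: int, plot_id: str = ""
) -> AnnualBudget:
    """Annual cumulative efflux by trapezoid between measurement dates.

    Plot-mean fluxes (replicates already averaged) are linearly interpolated
    over the calendar year; values at the year boundaries are taken from the
    interpolant when measurements bracket the year, else held constant from
    the nearest measurement.
    """
    dates = pd.DatetimeIndex(dates)
    y = np.asarray(fluxes, dtype=float)
    order = np.argsort(dates.values)
    dates, y = dates[order], y[order]
    in_or_around = (dates.year >= year - 1) & (dates.year <= year + 1)
    dates, y = dates[in_or_around], y[in_or_around]
    if (dates.year == year).sum() < 2 and len(dates) < 2:
        raise ValueError(f"need >= 2 measurements to interpolate year {year}")
    start = pd.Timestamp(year=year, month=1, day=1)
    end = pd.Timestamp(year=year + 1, month=1, day=1)
    t = dates.view("int64") / 1e9  # seconds
    t0, t1 = start.value / 1e9, end.value / 1e9
    f0 = float(np.interp(t0, t, y))
    f1 = float(np.interp(t1, t, y))
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    yy = np.concatenate([[f0], y[inside], [f1]])
    if len(tt) < 2 or (inside.sum() == 0 and (t.min() > t1 or t.max() < t0)):
        raise ValueError(f"no usable measurements for year {year}")
    total_umol = float(np.trapezoid(yy, tt))
    return AnnualBudget(plot_id, year, total_umol * C_MOLAR_MASS * 1e-6, "interpolation")


def annual_budgets(
    campaign: pd.DataFrame,
    temperature_log: pd.DataFrame,
    years: range,
    study_years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Both budget routes for every plot and year; tidy long frame.

    Columns: plot_id, year, method, cumulative_c_g_m2. Fit failures for a
    plot-year propagate as warnings with that row absent.
    """
    daily_t = daily_mean_temperature(temperature_log)
    means = plot_date_means(campaign)
    rows = []
    for plot in sorted(campaign["plot_id"].unique()):
        pt = daily_t[daily_t["plot_id"] == plot].set_index("date")["soil_temp_5cm_c"]
        pm = means[means["plot_id"] == plot]
        for year in years:
            try:
                params = fit_plot_year(campaign, plot, year, study_years)
                dflux = predict_daily_flux(params, pt[pt.index.year == year])
                bm = annual_sum_modeled(dflux, year, plot)
                rows.append((plot, year, "model", bm.cumulative_c))
            except (ValueError, RuntimeError) as err:  # pragma: no cover - diag path
                warnings.warn(f"model budget {plot}/{year} skipped: {err}", stacklevel=2)
            try:
                bi = annual_sum_interpolated(
                    pd.DatetimeIndex(pm["date"]),
                    pm["flux_umol_m2_s"].to_numpy(),
                    year,
                    plot,
                )
                rows.append((plot, year, "interpolation", bi.cumulative_c))
            except ValueError as err:  # pragma: no cover - diag path
                warnings.warn(
                    f"interpolation budget {plot}/{year} skipped: {err}", stacklevel=2
                )
    return pd.DataFrame(
        rows, columns=["plot_id", "year", "method", "cumulative_c_g_m2"]
    )
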