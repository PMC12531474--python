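"""Paired-plot warming-response statistics.

The central statistic is the relative increase in soil CO2 efflux per degree
of soil warming, computed per block and sampling date from the paired
control/warmed fluxes and soil temperatures:

    response = 100 * (Rw - Rc) / ((Tw - Tc) * Rc)   [% per degC]

Records with a control/warmed temperature difference <= 2 degC (warming
system off or failing) and records in warming-suspension years are excluded.
Calendar years are relabelled to warming-year indices per plot cohort, since
blocks entered the experiment in two different years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DELTA_T_THRESHOLD = 2.0  # degC; below this the heating is considered off


@dataclass(frozen=True)
class PlotPair:
    block_id: str
    control_plot_id: str
    warmed_plot_id: str
    first_warming_year: int
    suspension_years: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.control_plot_id == self.warmed_plot_id:
            raise ValueError("control and warmed plot must differ")


def relative_increase_per_degC(rw: float, rc: float, tw: float, tc: float) -> float:
    """Relative CO2 efflux increase per 1 degC of warming, in % per degC."""
    if rc <= 0:
        raise ValueError(f"control flux must be > 0, got {rc}")
    if tw == tc:
        raise ValueError("temperature difference is zero")
    return 100.0 * (rw - rc) / ((tw - tc) * rc)


def filter_valid_pairs(
    records: pd.DataFrame,
    pairs: list[PlotPair],
    delta_t_threshold: float = DELTA_T_THRESHOLD,
) -> pd.DataFrame:
    """Retain block-date records with genuine warming; add warming-year index.

    ``records`` columns: block_id, date, r_control, r_warming, t_control,
    t_warming. Drops rows with Tw - Tc <= threshold and rows in the block's
    suspension years; computes the response statistic and the warming-year
    index (first warming year = 1) per cohort.
    """
    by_block = {p.block_id: p for p in pairs}
    unknown = set(records["block_id"]) - set(by_block)
    if unknown:
        raise ValueError(f"records reference unknown blocks: {sorted(unknown)}")
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["delta_t"] = df["t_warming"] - df["t_control"]
    year = df["date"].dt.year
    df["warming_year"] = [
        y - by_block[b].first_warming_year + 1 for b, y in zip(df["block_id"], year)
    ]
    suspended = np.array(
        [y in by_block[b].suspension_years for b, y in zip(df["block_id"], year)]
    )
    keep = (df["delta_t"] > delta_t_threshold) & ~suspended & (df["warming_year"] >= 1)
    df = df[keep].copy()
    df["response_pct_per_degc"] = [
        relative_increase_per_degC(rw, rc, tw, tc)
        for rw, rc, tw, tc in zip(
            df["r_warming"], df["r_control"], df["t_warming"], df["t_control"]
        )
    ]
    return df.reset_index(drop=True)


def annual_response_series(retained: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of the response per warming year, across blocks.

    Date-level responses are first averaged within each block, then the
    block means are averaged per warming-year index; the SD is the spread
    across block means (sample SD, ddof=1; 0 for a single block).
    """
    if retained.empty:
        raise ValueError("no retained records")
    block_means = (
        retained.groupby(["warming_year", "block_id"])["response_pct_per_degc"]
        .mean()
        .reset_index()
    )
    out = block_means.groupby("warming_year")["response_pct_per_degc"].agg(
        mean_response="mean",
        sd_response=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
        n_blocks="count",
    )
    return out.reset_index()


def surplus_efflux(
    budgets: pd.DataFrame,
    pairs: list[PlotPair],
    years: range,
    method: str = "interpolation",
) -> tuple[float, float, pd.Series]:
    """Cumulative warming-induced surplus efflux, kg C m^-2, mean +/- SE.

    Per block, sums (warmed - control) annual budgets over ``years`` starting
    at the block's first warming year, converts g to kg, then averages across
    blocks. Returns (mean, standard error, per-block sums). ``budgets`` is
    the tidy frame from :func:`warmsoil.flux.annual_budgets`.
    """
    sub = budgets[budgets["method"] == method]
    lut = sub.set_index(["plot_id", "year"])["cumulative_c_g_m2"]
    per_block = {}
    for p in pairs:
        total = 0.0
        for year in years:
            if year < p.first_warming_year:
                continue
            try:
                w = lut[(p.warmed_plot_id, year)]
                c = lut[(p.control_plot_id, year)]
            except KeyError as err:
                raise ValueError(
                    f"missing {method} budget for block {p.block_id}, year {year}"
                ) from err
            total += (w - c) / 1000.0
        per_block[p.block_id] = total
    vals = pd.Series(per_block, name="surplus_kg_c_m2")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, se, vals


def correlate_with_driver(
    annual_response: pd.Series, driver: pd.Series
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of annual responses vs a driver.

    Series are aligned on their index (warming year); at least three common
    years with non-zero variance on both sides are required.
    """
    joined = pd.concat([annual_response, driver], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"need >= 3 paired years, got {len(joined)}")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def vapor_pressure_deficit(air_temp_c: np.ndarray, rel_humidity_pct: np.ndarray) -> np.ndarray:
    """VPD (hPa) from air temperature and relative humidity.

    Magnus form for saturation vapour pressure over water:
    es = 6.1094 * exp(17.625*T/(T+243.04)) hPa.
    """
    t = np.asarray(air_temp_c, dtype=float)
    rh = np.asarray(rel_humidity_pct, dtype=float)
    es = 6.1094 * np.exp(17.625 * t / (t + 243.04))
    return es * (1.0 - rh / 100.0)
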