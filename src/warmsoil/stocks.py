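"""SOC stock accounting, compaction correction, DOC fluxes, budget closure.

Stocks are computed per plot and depth layer from fine-soil SOC
concentration, fine-soil bulk density (rock mass and volume excluded) and
layer thickness. Because warming compacted the topsoil (~20% higher bulk
density), warmed-plot stocks are compared on an equivalent-soil-mass basis:
the warmed layer thickness is rescaled by the control/warmed bulk-density
ratio so that both treatments are compared over the same fine-soil mass per
area, and the sub-layer boundary is shifted by the topsoil's surplus
thickness.

The budget closure partitions the cumulative warming-induced surplus efflux
into autotrophic and heterotrophic shares and balances the heterotrophic
share against the observed SOC stock change; the remainder is the
belowground carbon input needed to close the budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BulkDensityCore:
    """One bulk-density cylinder sample; masses in g, volumes in cm^3."""

    plot_id: str
    layer: str  # "0-10" | "10-20"
    total_mass: float
    rock_mass: float
    total_volume: float
    rock_volume: float

    def __post_init__(self) -> None:
        if self.rock_mass > self.total_mass:
            raise ValueError("rock mass exceeds total mass")
        if self.rock_volume >= self.total_volume:
            raise ValueError("rock volume must be < total volume")
        if self.rock_mass < 0 or self.rock_volume < 0:
            raise ValueError("rock fractions cannot be negative")


@dataclass(frozen=True)
class LayerStock:
    plot_id: str
    layer: str
    soc_concentration: float  # %
    bulk_density: float  # g cm^-3
    thickness: float  # cm
    stock: float  # kg C m^-2
    corrected_thickness: float | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.soc_concentration <= 60.0:
            raise ValueError(f"SOC concentration {self.soc_concentration}% implausible")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")


@dataclass(frozen=True)
class BudgetComponents:
    surplus_cum: float  # kg C m^-2
    autotrophic_fraction: float
    delta_soc: float  # kg C m^-2, negative = loss
    years: int
    heterotrophic_cum: float
    missing_input: float
    missing_input_annual: float


def fine_soil_bulk_density(core: BulkDensityCore) -> float:
    """Fine-soil bulk density, g cm^-3: rock-free mass over rock-free volume."""
    denom = core.total_volume - core.rock_volume
    if denom <= 0:
        raise ValueError("fine-soil volume must be > 0")
    return (core.total_mass - core.rock_mass) / denom


def soc_stock_layer(conc_pct: float, bd_g_cm3: float, thickness_cm: float) -> float:
    """Layer SOC stock, kg C m^-2, from concentration (%), BD, thickness.

    conc/100 * BD * thickness gives g C cm^-2; x10 converts to kg C m^-2.
    """
    if conc_pct < 0 or bd_g_cm3 < 0 or thickness_cm < 0:
        raise ValueError("inputs must be non-negative")
    return conc_pct / 100.0 * bd_g_cm3 * thickness_cm * 10.0


def corrected_thickness(
    bd_control: float,
    bd_warmed: float,
    nominal_thickness: float,
    surplus_above: float = 0.0,
) -> float:
    """Equivalent-mass layer thickness in the warmed plot, cm.

    The warmed thickness holding the same fine-soil mass as ``nominal``
    control cm is ``nominal * bd_control / bd_warmed``; for sub-layers the
    surplus thickness of the layers above (nominal minus corrected) is
    subtracted so corrected layer boundaries stack into a profile.
    A negative result means the correction exceeds the layer.
    """
    if bd_control <= 0 or bd_warmed <= 0:
        raise ValueError("bulk densities must be > 0")
    if surplus_above < 0:
        raise ValueError("surplus_above must be >= 0")
    corrected = nominal_thickness * bd_control / bd_warmed - surplus_above
    if corrected < 0:
        raise ValueError(
            f"corrected thickness {corrected:.2f} cm negative: correction exceeds layer"
        )
    return corrected


def corrected_stock_profile(
    control: list[LayerStock], warmed: list[LayerStock]
) -> tuple[list[LayerStock], float, float]:
    """Equivalent-mass-corrected warmed stocks per layer, plus 0-20 cm totals.

    Layers must be aligned top-down between treatments. The warmed stock in
    each layer is rescaled by the bulk-density ratio bd_control/bd_warmed
    (the ratio of equivalent-mass to nominal thickness), which makes the
    compared fine-soil mass per area identical between treatments layer by
    layer. Corrected layer boundaries additionally account for the surplus
    thickness accumulated above. Returns (corrected warmed layers,
    control profile total, corrected warmed profile total) in kg C m^-2.
    """
    if len(control) != len(warmed):
        raise ValueError("treatment profiles have different numbers of layers")
    out: list[LayerStock] = []
    surplus = 0.0
    total_c = 0.0
    total_w = 0.0
    for lc, lw in zip(control, warmed):
        if lc.layer != lw.layer:
            raise ValueError(f"mismatched layers {lc.layer!r} vs {lw.layer!r}")
        ratio = lc.bulk_density / lw.bulk_density
        thick_eq = lw.thickness * ratio
        boundary_thick = corrected_thickness(
            lc.bulk_density, lw.bulk_density, lw.thickness, surplus
        )
        out.append(
            LayerStock(
                plot_id=lw.plot_id,
                layer=lw.layer,
                soc_concentration=lw.soc_concentration,
                bulk_density=lw.bulk_density,
                thickness=lw.thickness,
                stock=lw.stock * ratio,
                corrected_thickness=boundary_thick,
                corrected=True,
            )
        )
        surplus += lw.thickness - thick_eq
        total_c += lc.stock
        total_w += lw.stock * ratio
    return out, total_c, total_w


def fine_soil_mass_per_area(bd_g_cm3: float, thickness_cm: float) -> float:
    """Fine-soil mass per area, g cm^-2."""
    return bd_g_cm3 * thickness_cm


def doc_flux(
    conc_mg_l: pd.Series,
    water_mm: pd.Series,
    pool_biweekly_to_monthly: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """DOC flux per period (g C m^-2) and annual sums.

    conc (mg C L^-1) x water (mm == L m^-2) / 1000 -> g C m^-2 per period.
    Both series must share a DatetimeIndex of period end dates. With
    ``pool_biweekly_to_monthly`` the biweekly samples are pooled to calendar
    months first, concentrations combined as the volume-weighted mean.
    """
    if len(conc_mg_l) != len(water_mm):
        raise ValueError("concentration and water series misaligned")
    if not conc_mg_l.index.equals(water_mm.index):
        raise ValueError("concentration and water series have different periods")
    if (np.asarray(conc_mg_l) < 0).any() or (np.asarray(water_mm) < 0).any():
        raise ValueError("negative concentrations or water amounts")
    conc = conc_mg_l.astype(float)
    water = water_mm.astype(float)
    if pool_biweekly_to_monthly:
        month = conc.index.to_period("M")
        mass = (conc * water).groupby(month).sum()  # mg m^-2 per month
        vol = water.groupby(month).sum()
        flux = mass / 1000.0  # g C m^-2 per month
        flux.index = vol.index
    else:
        flux = conc * water / 1000.0
        month = flux.index.to_period("M")
        flux = flux.groupby(month).sum()
    annual = flux.groupby(flux.index.year).sum()
    annual.index.name = "year"
    return flux, annual


def closed_budget(
    surplus_cum: float,
    autotrophic_fraction: float,
    delta_soc: float,
    years: int,
) -> BudgetComponents:
    """Carbon-budget closure for the warming-induced surplus efflux.

    heterotrophic_cum = surplus_cum * (1 - autotrophic_fraction);
    missing_input = heterotrophic_cum - |delta_soc| is the extra belowground
    carbon input required to reconcile the heterotrophic CO2 loss with the
    observed stock change; negative delta_soc denotes a stock loss.
    """
    if not 0.0 <= autotrophic_fraction <= 1.0:
        raise ValueError("autotrophic_fraction must be in [0, 1]")
    if years <= 0:
        raise ValueError("years must be > 0")
    het = surplus_cum * (1.0 - autotrophic_fraction)
    missing = het - abs(delta_soc)
    return BudgetComponents(
        surplus_cum=surplus_cum,
        autotrophic_fraction=autotrophic_fraction,
        delta_soc=delta_soc,
        years=years,
        heterotrophic_cum=het,
        missing_input=missing,
        missing_input_annual=missing / years,
    )


def plot_layer_stocks(inventory: pd.DataFrame) -> pd.DataFrame:
    """Per-plot-layer fine-soil BD and SOC stock from an inventory table.

    Expects columns plot_id, treatment, layer, soc_pct, core_total_mass_g,
    core_rock_mass_g, core_total_vol_cm3, core_rock_vol_cm3,
    nominal_thickness_cm. Multiple cores/season samples per plot-layer are
    averaged (cores via their pooled fine mass/volume; concentrations
    arithmetically) before the stock computation.
    """
    rows = []
    for (plot, treat, layer), grp in inventory.groupby(
        ["plot_id", "treatment", "layer"]
    ):
        fine_mass = (grp["core_total_mass_g"] - grp["core_rock_mass_g"]).sum()
        fine_vol = (grp["core_total_vol_cm3"] - grp["core_rock_vol_cm3"]).sum()
        if fine_vol <= 0:
            raise ValueError(f"non-positive fine-soil volume for {plot}/{layer}")
        bd = fine_mass / fine_vol
        conc = float(grp["soc_pct"].mean())
        thick = float(grp["nominal_thickness_cm"].iloc[0])
        rows.append(
            (plot, treat, layer, conc, bd, thick, soc_stock_layer(conc, bd, thick))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "treatment",
            "layer",
            "soc_pct",
            "bd_fine_g_cm3",
            "thickness_cm",
            "stock_kg_c_m2",
        ],
    )


def paired_corrected_stocks(
    stocks_df: pd.DataFrame, pairs: list
) -> pd.DataFrame:
    """Apply the compaction correction per plot pair; tidy result frame.

    ``pairs`` is a list of objects with control_plot_id / warmed_plot_id /
    block_id attributes (see :class:`warmsoil.response.PlotPair`). Layers are
    ordered top-down by their numeric upper boundary. Per-pair correction is
    computed before any across-pair averaging.
    """

    def _layers(plot: str) -> list[LayerStock]:
        sub = stocks_df[stocks_df["plot_id"] == plot].copy()
        sub["top"] = [float(s.split("-")[0]) for s in sub["layer"]]
        sub = sub.sort_values("top")
        return [
            LayerStock(
                plot_id=r.plot_id,
                layer=r.layer,
                soc_concentration=r.soc_pct,
                bulk_density=r.bd_fine_g_cm3,
                thickness=r.thickness_cm,
                stock=r.stock_kg_c_m2,
            )
            for r in sub.itertuples()
        ]

    rows = []
    for p in pairs:
        ctrl = _layers(p.control_plot_id)
        warm = _layers(p.warmed_plot_id)
        corrected, total_c, total_w = corrected_stock_profile(ctrl, warm)
        for lc, lw, lwc in zip(ctrl, warm, corrected):
            rows.append(
                (
                    p.block_id,
                    lc.layer,
                    lc.stock,
                    lw.stock,
                    lwc.stock,
                    lwc.corrected_thickness,
                )
            )
        rows.append((p.block_id, "0-20 total", total_c, sum(l.stock for l in warm), total_w, np.nan))
    return pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "layer",
            "control_stock_kg_c_m2",
            "warmed_stock_uncorrected_kg_c_m2",
            "warmed_stock_corrected_kg_c_m2",
            "corrected_thickness_cm",
        ],
    )
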