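"""Steady-state three-pool carbon model with radiocarbon constraints.

The model tracks carbon in aboveground litter, fine roots and bulk SOC at
one depth, with first-order decay (k1, k2, k3), transfer of a fraction of
the decayed litter and root carbon into bulk SOC (a31, a32) and constant
inputs u = (litter input, root input, 0):

    dC/dt = u + B C,   B = [[-k1, 0, 0], [0, -k2, 0], [a31*k1, a32*k2, -k3]]

At steady state C* = -B^-1 u. Radiocarbon enters through the atmospheric
Delta-14C history: pool 14C obeys the same linear dynamics with inputs
scaled by the atmospheric fraction modern and an extra radioactive-decay
sink (lambda = 1/8267 yr^-1). Because the system is linear and autonomous,
the age of carbon in each pool follows a phase-type distribution with
density f_i(a) = (e^{aB} u)_i / C*_i, and the transit-time (age at exit)
density is f_T(t) = -1^T B e^{tB} u / 1^T u. The Delta-14C mass
distribution of a pool at a sampling year maps each age class through the
atmospheric curve with radioactive decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq

LAMBDA_14C = 1.0 / 8267.0  # yr^-1, true mean-life decay constant of 14C

POOLS = ("aboveground_litter", "fine_roots", "bulk_soc")


# ---------------------------------------------------------------------------
# atmospheric curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtmosphericCurve:
    """Atmospheric Delta-14C history (per mil) on decimal calendar years."""

    years: np.ndarray
    delta14c: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        d14c = np.asarray(self.delta14c, dtype=float)
        if years.ndim != 1 or years.shape != d14c.shape or years.size < 2:
            raise ValueError("curve needs matching 1-D year/value arrays (>= 2 knots)")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "delta14c", d14c)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.years[0]), float(self.years[-1])

    def delta(self, year: np.ndarray | float) -> np.ndarray | float:
        """Delta-14C (per mil) by linear interpolation; clamped outside support."""
        out = np.interp(np.asarray(year, dtype=float), self.years, self.delta14c)
        return out if out.ndim else float(out)

    def fraction_modern(self, year: np.ndarray | float) -> np.ndarray | float:
        return 1.0 + np.asarray(self.delta(year)) / 1000.0


def splice_atmospheric_curve(
    records: list[tuple[str, pd.DataFrame]],
    grid_step: float = 0.1,
    max_gap_years: float = 2.0,
) -> AtmosphericCurve:
    """Join per-period Delta-14C tables into one interpolated curve.

    ``records`` are (source_name, table) pairs, each table with columns
    ``year`` and ``delta14c_permil`` sorted by year. Sources are ordered by
    their first year; where a later-period source overlaps an earlier one the
    later source wins (earlier rows at or past its start are dropped). A gap
    longer than ``max_gap_years`` between consecutive sources is an error.
    The joined knots are interpolated onto a uniform ``grid_step`` grid.
    """
    if not records:
        raise ValueError("no source tables given")
    tables = []
    for name, tab in records:
        t = tab[["year", "delta14c_permil"]].astype(float).sort_values("year")
        if t.empty:
            raise ValueError(f"source {name!r} is empty")
        tables.append((name, t))
    tables.sort(key=lambda item: item[1]["year"].iloc[0])
    pieces = []
    for i, (name, t) in enumerate(tables):
        if i + 1 < len(tables):
            cutoff = tables[i + 1][1]["year"].iloc[0]
            kept = t[t["year"] < cutoff]
            if kept.empty:
                continue
            # temporal gap between source coverages (overlap counts as zero)
            gap = max(0.0, cutoff - t["year"].iloc[-1])
        else:
            kept = t
            gap = 0.0
        if gap > max_gap_years:
            raise ValueError(
                f"gap of {gap:.1f} yr after source {name!r} exceeds {max_gap_years} yr"
            )
        pieces.append(kept)
    joined = pd.concat(pieces).drop_duplicates("year").sort_values("year")
    lo, hi = joined["year"].iloc[0], joined["year"].iloc[-1]
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = np.interp(grid, joined["year"], joined["delta14c_permil"])
    return AtmosphericCurve(grid, vals, provenance="observational splice")


# ---------------------------------------------------------------------------
# compartment model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentModel:
    """Linear compartmental model dC/dt = u + B C with validation.

    ``u`` in g C m^-2 yr^-1 per pool; ``B`` in yr^-1. Construction rejects
    non-compartmental matrices (non-negative diagonal, negative transfer
    rates, or column sums > 0, i.e. pools creating carbon).
    """

    u: np.ndarray
    B: np.ndarray
    pool_names: tuple[str, ...] = POOLS
    depth: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        B = np.asarray(self.B, dtype=float)
        n = u.size
        if B.shape != (n, n):
            raise ValueError(f"B must be {n}x{n} to match u")
        if np.any(np.diag(B) >= 0):
            raise ValueError("diagonal of B must be negative (decay rates)")
        off = B - np.diag(np.diag(B))
        if np.any(off < 0):
            raise ValueError("off-diagonal transfer rates must be >= 0")
        if np.any(B.sum(axis=0) > 1e-12):
            raise ValueError("column sums of B must be <= 0 (no carbon creation)")
        if np.any(u < 0) or not np.any(u > 0):
            raise ValueError("inputs must be >= 0 with at least one positive entry")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "B", B)

    @classmethod
    def from_rates(
        cls,
        k1: float,
        k2: float,
        k3: float,
        a31: float,
        a32: float,
        litter_input: float,
        root_input: float | None = None,
        depth: str = "",
        treatment: str = "",
    ) -> "CompartmentModel":
        """Three-pool model from decay rates, SOC-transfer fractions, inputs.

        Root input defaults to the litter input (equal entries in u), but is
        independently configurable.
        """
        if root_input is None:
            root_input = litter_input
        if not (0.0 <= a31 <= 1.0 and 0.0 <= a32 <= 1.0):
            raise ValueError("transfer fractions a31, a32 must be in [0, 1]")
        B = np.array(
            [
                [-k1, 0.0, 0.0],
                [0.0, -k2, 0.0],
                [a31 * k1, a32 * k2, -k3],
            ]
        )
        u = np.array([litter_input, root_input, 0.0])
        return cls(u=u, B=B, depth=depth, treatment=treatment)

    @property
    def rates(self) -> dict[str, float]:
        B = self.B
        return {
            "k1": -B[0, 0],
            "k2": -B[1, 1],
            "k3": -B[2, 2],
            "a31": B[2, 0] / -B[0, 0],
            "a32": B[2, 1] / -B[1, 1],
        }

    def steady_state(self) -> np.ndarray:
        """Steady-state stocks C* = -B^-1 u, g C m^-2 (all positive)."""
        x = -np.linalg.solve(self.B, self.u)
        if np.any(x <= 0):
            raise ValueError("steady-state stocks must be positive")
        return x

    def release_flux(self) -> float:
        """Total respiration release at steady state (equals total input)."""
        return float(-self.B.sum(axis=0) @ self.steady_state())


def steady_state_stocks(model: CompartmentModel) -> np.ndarray:
    return model.steady_state()


# ---------------------------------------------------------------------------
# forward Delta-14C
# ---------------------------------------------------------------------------


def forward_delta14c(
    model: CompartmentModel,
    curve: AtmosphericCurve,
    t_span: tuple[float, float] = (1900.0, 2022.0),
    dt: float = 0.1,
    method: str = "expm",
    lambda_decay: float = LAMBDA_14C,
) -> pd.DataFrame:
    """Per-pool Delta-14C trajectory under the atmospheric forcing.

    The 14C content x (in fraction-modern-weighted carbon units) obeys
    dx/dt = u * F_atm(t) + (B - lambda*I) x; the system starts at t_span[0]
    in radioactive equilibrium with the atmosphere at that date. Returns a
    frame indexed by decimal year with one Delta-14C column per pool.

    method="expm" steps the exact linear propagator with midpoint forcing
    (fast; default). method="ivp" integrates with scipy's LSODA as an
    independent route for cross-checking.
    """
    t0, t1 = t_span
    lo, hi = curve.support
    if t0 < lo or t1 > hi:
        raise ValueError(
            f"curve support {lo:.1f}-{hi:.1f} does not cover span {t0}-{t1}"
        )
    M = model.B - lambda_decay * np.eye(model.B.shape[0])
    xstar = model.steady_state()
    f0 = float(curve.fraction_modern(t0))
    x0 = -np.linalg.solve(M, model.u) * f0

    times = np.arange(t0, t1 + dt / 2, dt)
    if method == "ivp":

        def rhs(t: float, x: np.ndarray) -> np.ndarray:
            return model.u * float(curve.fraction_modern(t)) + M @ x

        sol = solve_ivp(
            rhs, (t0, t1), x0, t_eval=times, method="LSODA", rtol=1e-8, atol=1e-10
        )
        if not sol.success:
            raise RuntimeError(f"forward integration failed: {sol.message}")
        traj = sol.y.T
    elif method == "expm":
        E = expm(M * dt)
        S = (E - np.eye(M.shape[0])) @ np.linalg.inv(M)  # step response operator
        f_mid = np.asarray(curve.fraction_modern(times[:-1] + dt / 2.0))
        traj = np.empty((times.size, x0.size))
        traj[0] = x0
        x = x0
        for i in range(times.size - 1):
            x = E @ x + S @ (model.u * f_mid[i])
            traj[i + 1] = x
    else:
        raise ValueError(f"unknown method {method!r}")

    frac_modern = traj / xstar
    delta = (frac_modern - 1.0) * 1000.0
    return pd.DataFrame(delta, index=times, columns=list(model.pool_names))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model: CompartmentModel
    params: dict[str, float]
    stderr: dict[str, float]
    covar: np.ndarray | None
    chisqr: float
    success: bool
    at_bounds: list[str]
    n_starts: int
    lmfit_result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)


DEFAULT_BOUNDS = {
    "k1": (1e-4, 20.0),
    "k2": (1e-4, 20.0),
    "k3": (1e-5, 5.0),
    "a31": (0.0, 1.0),
    "a32": (0.0, 1.0),
}


def fit_model(
    observations: pd.DataFrame,
    curve: AtmosphericCurve,
    litter_input: float,
    root_input: float | None = None,
    stocks: dict[str, float] | None = None,
    stock_rel_sd: float = 0.10,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    t_start: float = 1900.0,
    dt: float = 0.1,
    depth: str = "",
    treatment: str = "",
) -> FitResult:
    """Levenberg-Marquardt fit of (k1, k2, k3, a31, a32) to Delta-14C data.

    ``observations`` columns: year, pool, delta14c_permil, sd_permil; all
    observation years are fitted together as one time series. Residuals are
    sd-weighted; observed steady-state stocks (g C m^-2 per pool) optionally
    enter as relative residuals scaled by ``stock_rel_sd`` so that stock and
    isotope misfit contribute on comparable scales. ``n_starts`` jittered
    initialisations are run and the best retained.
    """
    obs = observations.copy()
    required = {"year", "pool", "delta14c_permil", "sd_permil"}
    if not required.issubset(obs.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    unknown_pools = set(obs["pool"]) - set(POOLS)
    if unknown_pools:
        raise ValueError(f"unknown pools {sorted(unknown_pools)}")
    if (obs["sd_permil"] <= 0).any():
        raise ValueError("observation sd_permil must be > 0")
    n_free = 5
    n_resid = len(obs) + (len(stocks) if stocks else 0)
    if n_resid < n_free:
        raise ValueError(
            f"under-determined: {n_resid} residuals for {n_free} free parameters"
        )
    if obs["pool"].nunique() < 2:
        raise ValueError(
            "observations for a single pool cannot identify all five parameters"
        )
    years = np.sort(obs["year"].unique().astype(float))
    if len(years) < 2:
        raise ValueError("need observations at >= 2 years")
    t_end = float(years.max())

    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    init = dict(init or {"k1": 0.5, "k2": 0.3, "k3": 0.02, "a31": 0.3, "a32": 0.3})
    rng = np.random.default_rng(seed)

    pool_idx = {name: i for i, name in enumerate(POOLS)}
    obs_years = obs["year"].to_numpy(dtype=float)
    obs_pool = obs["pool"].map(pool_idx).to_numpy()
    obs_val = obs["delta14c_permil"].to_numpy(dtype=float)
    obs_sd = obs["sd_permil"].to_numpy(dtype=float)
    stock_vec = (
        np.array([stocks.get(p, np.nan) for p in POOLS]) if stocks else None
    )

    def build(p: lmfit.Parameters) -> CompartmentModel:
        return CompartmentModel.from_rates(
            p["k1"].value,
            p["k2"].value,
            p["k3"].value,
            p["a31"].value,
            p["a32"].value,
            litter_input,
            root_input,
            depth=depth,
            treatment=treatment,
        )

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        model = build(p)
        traj = forward_delta14c(model, curve, (t_start, t_end), dt=dt)
        t = traj.index.to_numpy()
        res = np.empty(n_resid)
        for j in range(len(obs_val)):
            pred = np.interp(obs_years[j], t, traj.iloc[:, obs_pool[j]].to_numpy())
            res[j] = (pred - obs_val[j]) / obs_sd[j]
        if stock_vec is not None:
            xs = model.steady_state()
            k = len(obs_val)
            for i, target in enumerate(stock_vec):
                if np.isfinite(target):
                    res[k] = (xs[i] / target - 1.0) / stock_rel_sd
                    k += 1
        return res

    best = None
    for start in range(n_starts):
        params = lmfit.Parameters()
        for name, value in init.items():
            lo, hi = bounds[name]
            if start > 0:
                if name.startswith("k"):
                    value = value * float(np.exp(rng.normal(0.0, 0.5)))
                else:
                    value = float(np.clip(value + rng.normal(0.0, 0.15), lo, hi))
            params.add(name, value=float(np.clip(value, lo, hi)), min=lo, max=hi)
        try:
            result = lmfit.minimize(residuals, params, method="leastsq")
        except Exception:  # singular trial start; keep going
            continue
        if result.success and (best is None or result.chisqr < best.chisqr):
            best = result
    if best is None:
        raise RuntimeError("all Levenberg-Marquardt starts failed to converge")

    fitted = {k: float(best.params[k].value) for k in init}
    stderr = {
        k: float(best.params[k].stderr) if best.params[k].stderr else float("nan")
        for k in init
    }
    at_bounds = [
        k
        for k in init
        if np.isclose(fitted[k], bounds[k][0], rtol=1e-6, atol=1e-12)
        or np.isclose(fitted[k], bounds[k][1], rtol=1e-6)
    ]
    return FitResult(
        model=build(best.params),
        params=fitted,
        stderr=stderr,
        covar=getattr(best, "covar", None),
        chisqr=float(best.chisqr),
        success=bool(best.success),
        at_bounds=at_bounds,
        n_starts=n_starts,
        lmfit_result=best,
    )


# ---------------------------------------------------------------------------
# age / transit-time distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeDistribution:
    """Distribution of carbon age (or transit time) on a uniform grid.

    ``age_grid`` holds bin left edges with uniform step; ``density`` is the
    bin mass divided by the step (yr^-1), normalised to integrate to one over
    the grid. ``mean`` and ``median`` come from the closed matrix forms and
    the exact cumulative distribution, not from the discretised density.
    """

    age_grid: np.ndarray
    density: np.ndarray
    scope: str
    mean: float
    median: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.age_grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        step = grid[1] - grid[0]
        if np.any(dens < -1e-12):
            raise ValueError("density must be non-negative")
        if abs(dens.sum() * step - 1.0) > 1e-6:
            raise ValueError("density must integrate to 1")
        object.__setattr__(self, "age_grid", grid)
        object.__setattr__(self, "density", np.clip(dens, 0.0, None))

    @property
    def step(self) -> float:
        return float(self.age_grid[1] - self.age_grid[0])

    @property
    def bin_masses(self) -> np.ndarray:
        return self.density * self.step

    def numeric_mean(self) -> float:
        """Mean of the discretised density (bin centres); diagnostic."""
        centres = self.age_grid + self.step / 2.0
        return float(np.sum(centres * self.bin_masses))


def _phase_type_distribution(
    B: np.ndarray,
    weights: np.ndarray,
    closed_mean: float,
    scope: str,
    age_step: float,
    max_age: float,
    mass_capture: float,
    hard_cap: float = 2.0e5,
) -> AgeDistribution:
    """Shared machinery: distribution of a with survival S(a) = c^T e^{aB} w.

    ``weights`` w is normalised so S(0) = 1 with c = 1; bin masses are exact
    CDF differences, so they sum to the captured mass, then renormalised.
    The grid doubles until >= ``mass_capture`` of the mass is inside.
    """
    w = weights / weights.sum()
    E = expm(B * age_step)

    def survival_series(n_bins: int) -> np.ndarray:
        out = np.empty(n_bins + 1)
        v = w.copy()
        out[0] = 1.0
        for i in range(1, n_bins + 1):
            v = E @ v
            out[i] = v.sum()
        return out

    current_max = max_age
    while True:
        n_bins = int(round(current_max / age_step))
        surv = survival_series(n_bins)
        captured = 1.0 - surv[-1]
        if captured >= mass_capture:
            break
        if current_max >= hard_cap:
            raise RuntimeError(
                f"could not capture {mass_capture:.1%} of mass within {hard_cap} yr"
            )
        current_max *= 2.0

    masses = surv[:-1] - surv[1:]
    masses = masses / captured
    grid = np.arange(n_bins) * age_step

    # exact median: bracket on the survival grid, refine on the true CDF
    cdf = 1.0 - surv
    j = int(np.searchsorted(cdf, 0.5))
    if j == 0:
        median = 0.0
    else:
        a_lo, a_hi = (j - 1) * age_step, j * age_step

        def cdf_at(a: float) -> float:
            return 1.0 - float(np.sum(expm(B * a) @ w))

        median = float(brentq(lambda a: cdf_at(a) - 0.5, a_lo, a_hi, xtol=1e-10))

    return AgeDistribution(
        age_grid=grid,
        density=masses / age_step,
        scope=scope,
        mean=closed_mean,
        median=median,
    )


def age_distribution(
    model: CompartmentModel,
    scope: str = "system",
    age_step: float = 1.0,
    max_age: float = 3000.0,
    mass_capture: float = 0.999,
) -> AgeDistribution:
    """Age distribution of carbon in the whole system or one pool.

    At steady state the age density of the system is
    f(a) = 1^T e^{aB} u / 1^T C*, and of pool i it is (e^{aB} u)_i / C*_i;
    equivalently the survival function is S(a) = c^T e^{aB} C* / c^T C* with
    c selecting the scope, which is what is evaluated here (exact bin
    masses). The mean uses the closed form -B^-1 applied to the steady-state
    composition.
    """
    xstar = model.steady_state()
    if scope == "system":
        closed_mean = float(np.sum(-np.linalg.solve(model.B, xstar)) / xstar.sum())
        return _phase_type_distribution(
            model.B, xstar, closed_mean, "system", age_step, max_age, mass_capture
        )
    if scope not in model.pool_names:
        raise ValueError(f"unknown scope {scope!r}")
    i = model.pool_names.index(scope)
    closed_mean = float((-np.linalg.solve(model.B, xstar))[i] / xstar[i])
    return _pool_age_distribution(model, i, closed_mean, age_step, max_age, mass_capture)


def _pool_age_distribution(
    model: CompartmentModel,
    i: int,
    closed_mean: float,
    age_step: float,
    max_age: float,
    mass_capture: float,
    hard_cap: float = 2.0e5,
) -> AgeDistribution:
    """Age distribution for one pool: survival S(a) = (e^{aB} C*)_i / C*_i."""
    xstar = model.steady_state()
    E = expm(model.B * age_step)

    def survival_series(n_bins: int) -> np.ndarray:
        out = np.empty(n_bins + 1)
        v = xstar.copy()
        out[0] = 1.0
        for n in range(1, n_bins + 1):
            v = E @ v
            out[n] = v[i] / xstar[i]
        return out

    current_max = max_age
    while True:
        n_bins = int(round(current_max / age_step))
        surv = survival_series(n_bins)
        captured = 1.0 - surv[-1]
        if captured >= mass_capture:
            break
        if current_max >= hard_cap:
            raise RuntimeError(
                f"could not capture {mass_capture:.1%} of mass within {hard_cap} yr"
            )
        current_max *= 2.0

    masses = (surv[:-1] - surv[1:]) / captured
    grid = np.arange(n_bins) * age_step
    cdf = 1.0 - surv
    j = int(np.searchsorted(cdf, 0.5))
    if j == 0:
        median = 0.0
    else:
        a_lo, a_hi = (j - 1) * age_step, j * age_step

        def cdf_at(a: float) -> float:
            return 1.0 - float((expm(model.B * a) @ xstar)[i] / xstar[i])

        median = float(brentq(lambda a: cdf_at(a) - 0.5, a_lo, a_hi, xtol=1e-10))
    return AgeDistribution(
        age_grid=grid,
        density=masses / age_step,
        scope=model.pool_names[i],
        mean=closed_mean,
        median=median,
    )


def transit_time_distribution(
    model: CompartmentModel,
    age_step: float = 1.0,
    max_age: float = 3000.0,
    mass_capture: float = 0.999,
) -> AgeDistribution:
    """Input-weighted distribution of the age of carbon at exit.

    Survival S(t) = 1^T e^{tB} u / 1^T u; the mean transit time equals the
    total steady-state stock divided by the total input.
    """
    closed_mean = float(model.steady_state().sum() / model.u.sum())
    return _phase_type_distribution(
        model.B, model.u.astype(float), closed_mean, "transit", age_step, max_age,
        mass_capture,
    )


def mixture_age_distribution(
    dists: list[AgeDistribution], weights: list[float], scope: str = "mixture"
) -> AgeDistribution:
    """Stock-weighted mixture of age distributions (e.g. 0-20 cm aggregate).

    Distributions must share the grid step; the mixture grid extends to the
    longest input grid. Mean is the weighted mean; the median is read from
    the mixed cumulative distribution (grid resolution).
    """
    if len(dists) != len(weights) or not dists:
        raise ValueError("need one weight per distribution")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    step = dists[0].step
    if any(abs(d.step - step) > 1e-12 for d in dists):
        raise ValueError("distributions must share the grid step")
    n = max(d.age_grid.size for d in dists)
    masses = np.zeros(n)
    for d, wi in zip(dists, w):
        masses[: d.age_grid.size] += wi * d.bin_masses
    masses /= masses.sum()
    grid = np.arange(n) * step
    cdf = np.cumsum(masses)
    j = int(np.searchsorted(cdf, 0.5))
    if j == 0:
        median = step / 2.0
    else:
        median = float(grid[j] + step * (0.5 - cdf[j - 1]) / masses[j])
    mean = float(np.sum(w * np.array([d.mean for d in dists])))
    return AgeDistribution(grid, masses / step, scope, mean, median)


# ---------------------------------------------------------------------------
# Delta-14C mass distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Delta14CDistribution:
    """Mass fractions of a pool across Delta-14C bins at a sampling year."""

    bin_edges: np.ndarray
    mass_fraction: np.ndarray
    sampling_year: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        frac = np.asarray(self.mass_fraction, dtype=float)
        if edges.size != frac.size + 1:
            raise ValueError("need len(bin_edges) == len(mass_fraction) + 1")
        if np.any(frac < 0):
            raise ValueError("mass fractions must be non-negative")
        if abs(frac.sum() - 1.0) > 1e-6:
            raise ValueError("mass fractions must sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "mass_fraction", frac)

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_delta14c(self) -> float:
        return float(np.sum(self.bin_centres * self.mass_fraction))


def age_to_delta14c(
    ages: np.ndarray, curve: AtmosphericCurve, sampling_year: float
) -> np.ndarray:
    """Delta-14C of carbon of given ages sampled in ``sampling_year``.

    Carbon of age a was fixed at (sampling_year - a) from an atmosphere at
    F_atm and has since decayed by e^{-lambda a}. Ages predating the curve
    take the curve's earliest (pre-bomb baseline) value.
    """
    a = np.asarray(ages, dtype=float)
    fix_year = np.clip(sampling_year - a, curve.support[0], None)
    f_atm = np.asarray(curve.fraction_modern(fix_year))
    return (f_atm * np.exp(-LAMBDA_14C * a) - 1.0) * 1000.0


def delta14c_mass_distribution(
    age_dist: AgeDistribution,
    curve: AtmosphericCurve,
    sampling_year: float,
    bins: int | np.ndarray = 60,
) -> Delta14CDistribution:
    """Map a carbon-age distribution to a Delta-14C mass distribution.

    Each age class (evaluated at its bin centre) is assigned the Delta-14C
    that carbon of that age carries at the sampling year; class masses are
    then accumulated into Delta-14C bins. Normalisation is preserved.
    """
    centres = age_dist.age_grid + age_dist.step / 2.0
    d14c = age_to_delta14c(centres, curve, sampling_year)
    masses = age_dist.bin_masses
    if np.isscalar(bins):
        if int(bins) < 1:
            raise ValueError("need at least one bin")
        lo, hi = float(d14c.min()), float(d14c.max())
        pad = max(1e-9, (hi - lo) * 1e-9)
        edges = np.linspace(lo - pad, hi + pad, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if edges.size < 2:
            raise ValueError("bin edges must have >= 2 entries")
    hist, _ = np.histogram(d14c, bins=edges, weights=masses)
    total = hist.sum()
    if total <= 0:
        raise ValueError("no mass falls inside the given bins")
    return Delta14CDistribution(edges, hist / total, sampling_year)
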