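"""Flux engine: slopes, chamber conversion, response fitting, budgets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warmsoil import flux


def _normal_equations_slope(t, y):
    """Independent OLS oracle via the explicit normal equations."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    return (n * np.sum(t * y) - t.sum() * y.sum()) / (n * np.sum(t * t) - t.sum() ** 2)


class TestConcentrationSlope:
    def test_exact_line(self):
        t = np.arange(0, 121, 10.0)
        assert flux.estimate_concentration_slope(t, 400 + 2 * t) == pytest.approx(2.0)

    def test_constant_series_zero_slope(self):
        t = np.arange(0, 121, 10.0)
        assert flux.estimate_concentration_slope(t, np.full_like(t, 400.0)) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_matches_normal_equations(self, rng):
        t = np.sort(rng.uniform(0, 120, 25))
        t += np.arange(25) * 1e-6  # strictly increasing
        y = 400 + 0.8 * t + rng.normal(0, 1.0, 25)
        ours = flux.estimate_concentration_slope(t, y)
        assert ours == pytest.approx(_normal_equations_slope(t, y), abs=1e-12)

    def test_window_restricts_points(self):
        t = np.array([0.0, 30, 60, 90, 120, 200, 300])
        y = 400 + 2 * t
        y[-2:] = 0.0  # corrupt points outside the window
        assert flux.estimate_concentration_slope(t, y, window=120) == pytest.approx(2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3 points"):
            flux.estimate_concentration_slope(np.array([0.0, 60.0]), np.array([400.0, 420.0]))


def _measurement(**kw):
    base = dict(
        plot_id="p1",
        datetime=pd.Timestamp("2020-06-01T09:30"),
        chamber_id="ch1",
        conc_slope=1.0,
        air_temp=20.0,
        pressure=101_325.0,
        chamber_volume=0.01,
        chamber_area=0.1,
        soil_temp_5cm=12.0,
    )
    base.update(kw)
    return flux.FluxMeasurement(**base)


class TestChamberFlux:
    def test_ideal_gas_reference_at_20c(self):
        # p/(R*T) = 101325/(8.31446*293.15) = 41.57 mol m^-3, times V/A = 0.1 m
        assert flux.compute_chamber_flux(_measurement()) == pytest.approx(4.157, abs=2e-3)

    def test_ideal_gas_reference_at_0c(self):
        assert flux.compute_chamber_flux(_measurement(air_temp=0.0)) == pytest.approx(
            4.4615, abs=2e-3
        )

    def test_zero_slope_zero_flux(self):
        assert flux.compute_chamber_flux(_measurement(conc_slope=0.0)) == 0.0

    @given(
        slope=st.floats(0.01, 10.0),
        temp=st.floats(-20.0, 35.0),
        pressure=st.floats(60_000.0, 105_000.0),
        height=st.floats(0.05, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_dimensional_oracle_randomized(self, slope, temp, pressure, height):
        """flux * A equals moles in chamber per second by direct dimensional analysis."""
        area = 0.0314
        m = _measurement(
            conc_slope=slope,
            air_temp=temp,
            pressure=pressure,
            chamber_volume=area * height,
            chamber_area=area,
        )
        # oracle: (ppm/s -> mol fraction/s) * (n = pV/RT mol in chamber) / area
        n_air = pressure * (area * height) / (flux.R_GAS * (temp + 273.15))
        oracle = slope * 1e-6 * n_air / area * 1e6
        assert flux.compute_chamber_flux(m) == pytest.approx(oracle, rel=1e-10)

    def test_literal_audit_mode_reproduces_printed_arithmetic(self):
        m = _measurement()
        expected = 1.0 * 273.15 / 293.15 * 101_325.0 / 1000 * 22.41 / 1000 * 0.01 / 0.1
        assert flux.compute_chamber_flux(m, literal=True) == pytest.approx(expected)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="chamber_volume"):
            _measurement(chamber_volume=-1.0)
        with pytest.raises(ValueError, match="pressure"):
            _measurement(pressure=20_000.0)


class TestRootIncubation:
    def _series(self, flux_umol_g_s, mass, volume=325e-6, temp=17.0, p=101_325.0):
        """Forward-construct a perfectly linear incubation series."""
        density = flux.molar_air_density(p, temp)
        slope = flux_umol_g_s * mass / (density * volume)  # ppm s^-1
        minutes = np.arange(0.0, 31.0)
        return minutes, 450 + slope * minutes * 60.0

    def test_round_trip_recovery(self):
        minutes, ppm = self._series(2.5e-3, mass=4.0)
        got, r2 = flux.root_incubation_flux(minutes, ppm, 325e-6, 4.0, temp_c=17.0)
        assert got == pytest.approx(2.5e-3, rel=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_doubling_mass_halves_flux(self):
        minutes, ppm = self._series(2.5e-3, mass=4.0)
        f1, _ = flux.root_incubation_flux(minutes, ppm, 325e-6, 4.0, temp_c=17.0)
        f2, _ = flux.root_incubation_flux(minutes, ppm, 325e-6, 8.0, temp_c=17.0)
        assert f2 == pytest.approx(f1 / 2.0)

    def test_noisy_series_fails_qc(self, rng):
        minutes = np.arange(0.0, 31.0)
        ppm = 450 + 0.5 * minutes + rng.normal(0, 40.0, len(minutes))
        with pytest.raises(ValueError, match="QC floor"):
            flux.root_incubation_flux(minutes, ppm, 325e-6, 4.0, temp_c=17.0)

    def test_window_not_covered(self):
        with pytest.raises(ValueError, match="window"):
            flux.root_incubation_flux(np.arange(0.0, 10.0), np.arange(10.0), 325e-6, 4.0, 17.0)


class TestTemperatureResponse:
    def _data(self, r0=0.8, a=0.12, b=-0.002, n=40, sigma=0.0, seed=5):
        rng = np.random.default_rng(seed)
        t = np.linspace(-2, 22, n)
        y = r0 * np.exp(a * t + b * t * t)
        if sigma:
            y = y * np.exp(rng.normal(0, sigma, n))
        return t, y

    def test_noiseless_recovery_four_significant_digits(self):
        t, y = self._data()
        p = flux.fit_temperature_response(t, y)
        assert p.R0 == pytest.approx(0.8, rel=1e-4)
        assert p.a == pytest.approx(0.12, rel=1e-4)
        assert p.b == pytest.approx(-0.002, rel=1e-4)
        assert p.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_q10_closed_form(self):
        t, y = self._data(a=0.0693, b=0.0)
        p = flux.fit_temperature_response(t, y)
        assert p.q10 == pytest.approx(np.exp(10 * 0.0693), rel=1e-4)
        assert p.q10 == pytest.approx(2.0, rel=1e-2)

    def test_scale_equivariance(self):
        t, y = self._data(sigma=0.15, seed=9)
        p1 = flux.fit_temperature_response(t, y)
        p2 = flux.fit_temperature_response(t, 3.7 * y)
        assert p2.R0 == pytest.approx(3.7 * p1.R0, rel=1e-6)
        assert p2.a == pytest.approx(p1.a, rel=1e-6)
        assert p2.b == pytest.approx(p1.b, rel=1e-6)

    def test_degenerate_span_rejected(self):
        t = np.linspace(10, 12, 10)
        with pytest.raises(ValueError, match="span"):
            flux.fit_temperature_response(t, np.exp(0.1 * t))

    def test_r2_band_matches_noise_level(self):
        """sigma=0.2 lognormal noise gives R^2 near 0.9 on seasonal data."""
        r2 = []
        for seed in range(12):
            t, y = self._data(n=30, sigma=0.2, seed=seed)
            r2.append(flux.fit_temperature_response(t, y).r_squared)
        assert 0.80 <= float(np.mean(r2)) <= 0.97


class TestPredictionAndBudgets:
    def test_exponent_zero_returns_r0(self):
        p = flux.TempResponseParams("p", (0, 0), R0=1.3, a=0.1, b=-0.01)
        # aT + bT^2 = 0 at T = -a/b = 10
        assert p.predict(10.0) == pytest.approx(1.3)
        assert p.predict(0.0) == pytest.approx(1.3)

    def test_monotone_when_b_zero(self):
        p = flux.TempResponseParams("p", (0, 0), R0=1.0, a=0.1, b=0.0)
        t = np.linspace(-5, 25, 50)
        assert np.all(np.diff(p.predict(t)) > 0)

    def test_argmax_at_minus_a_over_2b(self):
        p = flux.TempResponseParams("p", (0, 0), R0=1.0, a=0.12, b=-0.004)
        t = np.linspace(-10, 40, 5001)
        argmax = t[np.argmax(p.predict(t))]
        assert argmax == pytest.approx(-0.12 / (2 * -0.004), abs=0.02)

    def test_annual_sum_constant_flux(self):
        days = pd.date_range("2021-01-01", "2021-12-31", freq="D")
        s = pd.Series(1.0, index=days)
        b = flux.annual_sum_modeled(s, 2021)
        assert b.cumulative_c == pytest.approx(12.011 * 86400 * 365 * 1e-6, rel=1e-12)
        assert b.cumulative_c == pytest.approx(378.8, abs=0.1)

    def test_annual_sum_leap_year(self):
        days = pd.date_range("2020-01-01", "2020-12-31", freq="D")
        b = flux.annual_sum_modeled(pd.Series(1.0, index=days), 2020)
        assert b.cumulative_c == pytest.approx(12.011 * 86400 * 366 * 1e-6, rel=1e-12)

    def test_annual_sum_zero(self):
        days = pd.date_range("2021-01-01", "2021-12-31", freq="D")
        assert flux.annual_sum_modeled(pd.Series(0.0, index=days), 2021).cumulative_c == 0.0

    def test_missing_days_rejected(self):
        days = pd.date_range("2021-01-01", "2021-11-30", freq="D")
        with pytest.raises(ValueError, match="daily values"):
            flux.annual_sum_modeled(pd.Series(1.0, index=days), 2021)

    def test_interpolated_constant(self):
        dates = pd.DatetimeIndex(["2021-01-01", "2022-01-01"])
        b = flux.annual_sum_interpolated(dates, np.array([1.0, 1.0]), 2021)
        assert b.cumulative_c == pytest.approx(12.011 * 86400 * 365 * 1e-6, rel=1e-9)

    def test_interpolated_linear_ramp_mean_one(self):
        dates = pd.DatetimeIndex(["2021-01-01", "2022-01-01"])
        b = flux.annual_sum_interpolated(dates, np.array([0.0, 2.0]), 2021)
        assert b.cumulative_c == pytest.approx(12.011 * 86400 * 365 * 1e-6, rel=1e-9)

    def test_interpolation_converges_to_true_integral(self):
        """Riemann check: dense sampling of a smooth curve approaches its integral."""
        t_year = pd.date_range("2021-01-01", "2022-01-01", freq="h")
        doy = (t_year - t_year[0]).total_seconds() / 86400.0
        true_flux = 2.0 + 1.5 * np.sin(2 * np.pi * doy / 365.25)
        exact = np.trapezoid(true_flux, doy * 86400) * 12.011e-6
        errs = []
        for step in (30, 7, 1):
            sel = np.arange(0, len(t_year), step * 24)
            b = flux.annual_sum_interpolated(t_year[sel], true_flux[sel], 2021)
            errs.append(abs(b.cumulative_c - exact))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] / exact < 1e-3

    def test_single_measurement_rejected(self):
        with pytest.raises(ValueError):
            flux.annual_sum_interpolated(
                pd.DatetimeIndex(["2021-06-01"]), np.array([1.0]), 2021
            )


class TestGapFilling:
    def _series(self, values, start="2021-01-01"):
        ts = pd.date_range(start, periods=len(values), freq="D")
        return flux.TemperatureSeries("p1", ts, np.asarray(values, float))

    def test_no_gaps_identity(self):
        s = self._series(np.linspace(0, 10, 30))
        out = flux.fill_temperature_gaps(s)
        np.testing.assert_array_equal(out.soil_temp_5cm, s.soil_temp_5cm)
        assert out.source == ["measured"] * 30

    def test_neighbor_constant_offset(self):
        base = np.linspace(5, 15, 30)
        vals = base.copy()
        vals[12:16] = np.nan
        s = self._series(vals)
        neighbor = flux.TemperatureSeries(
            "p2", pd.date_range("2021-01-01", periods=30, freq="D"), base - 0.5
        )
        out = flux.fill_temperature_gaps(s, neighbor=neighbor)
        np.testing.assert_allclose(out.soil_temp_5cm[12:16], base[12:16], atol=1e-9)
        assert out.source[12:16] == ["neighbor"] * 4

    def test_air_regression_beats_noise(self, rng):
        n = 60
        ts = pd.date_range("2021-01-01", periods=n, freq="D")
        air = pd.Series(10 + 8 * np.sin(np.arange(n) / 9.0), index=ts)
        noise_sd = 0.3
        truth = 0.8 * air.shift(1).to_numpy() + 2.0
        observed = truth + rng.normal(0, noise_sd, n)
        observed[0] = truth[1]
        vals = observed.copy()
        vals[30:40] = np.nan
        s = flux.TemperatureSeries("p1", ts, vals)
        out = flux.fill_temperature_gaps(s, air_temp=air)
        rmse = float(np.sqrt(np.mean((out.soil_temp_5cm[30:40] - truth[30:40]) ** 2)))
        assert rmse < noise_sd
        assert set(out.source[30:40]) == {"air-regression"}

    def test_no_predictor_raises(self):
        vals = np.linspace(0, 5, 20)
        vals[10:12] = np.nan
        s = self._series(vals)
        with pytest.raises(ValueError, match="no predictor"):
            flux.fill_temperature_gaps(s)
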