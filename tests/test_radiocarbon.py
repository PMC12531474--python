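"""Compartment model, forward Delta-14C, fitting, age/transit distributions."""

import numpy as np
import pandas as pd
import pytest

from warmsoil import radiocarbon as rc
from warmsoil import synthetic as syn

LAM = rc.LAMBDA_14C


def one_pool(k=0.1, u=1.0):
    return rc.CompartmentModel(u=np.array([u]), B=np.array([[-k]]), pool_names=("pool",))


@pytest.fixture(scope="module")
def flat_curve():
    return rc.AtmosphericCurve(np.array([1800.0, 2100.0]), np.array([0.0, 0.0]))


class TestCompartmentValidity:
    def test_positive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            rc.CompartmentModel(u=np.array([1.0, 0.0]), B=np.array([[0.1, 0.0], [0.0, -0.2]]))

    def test_negative_transfer_rejected(self):
        with pytest.raises(ValueError, match="transfer"):
            rc.CompartmentModel(u=np.array([1.0, 0.0]), B=np.array([[-0.1, 0.0], [-0.05, -0.2]]))

    def test_carbon_creating_column_rejected(self):
        with pytest.raises(ValueError, match="column sums"):
            rc.CompartmentModel(u=np.array([1.0, 0.0]), B=np.array([[-0.1, 0.0], [0.2, -0.2]]))

    def test_transfer_fraction_bounds(self):
        with pytest.raises(ValueError, match="transfer fractions"):
            rc.CompartmentModel.from_rates(0.5, 0.5, 0.01, 1.2, 0.3, 190.0)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError, match="inputs"):
            rc.CompartmentModel(u=np.array([0.0]), B=np.array([[-0.1]]))


class TestSteadyState:
    def test_one_pool_u_over_k(self):
        assert rc.steady_state_stocks(one_pool(0.1, 1.0))[0] == pytest.approx(10.0)

    def test_litter_chain_gives_5700(self):
        """Litter input 190 with a31 = 0.3, k3 = 0.01 accumulates 5700 g C m^-2 SOC."""
        model = rc.CompartmentModel(
            u=np.array([190.0, 1e-9, 0.0]),
            B=np.array([[-1.0, 0.0, 0.0], [0.0, -0.5, 0.0], [0.3, 0.0, -0.01]]),
        )
        assert model.steady_state()[2] == pytest.approx(5700.0, rel=1e-6)

    def test_release_equals_input(self, topsoil_model):
        assert topsoil_model.release_flux() == pytest.approx(topsoil_model.u.sum(), rel=1e-12)


class TestForwardDelta14C:
    def test_zero_decay_fixed_point(self, flat_curve):
        """With lambda = 0 and a 0-permil atmosphere every pool sits at 0 permil."""
        model = syn.default_radiocarbon_model()
        traj = rc.forward_delta14c(model, flat_curve, (1900, 2022), lambda_decay=0.0)
        np.testing.assert_allclose(traj.to_numpy(), 0.0, atol=1e-9)

    def test_one_pool_equilibrium_closed_form(self, flat_curve):
        """Equilibrium fraction modern k/(k+lambda) -> -12.0 permil at k = 0.01."""
        traj = rc.forward_delta14c(one_pool(k=0.01), flat_curve, (1900, 2022))
        expected = (0.01 / (0.01 + LAM) - 1.0) * 1000.0
        assert traj.iloc[-1, 0] == pytest.approx(expected, abs=1e-4)
        assert traj.iloc[-1, 0] == pytest.approx(-12.0, abs=0.1)

    def test_fast_pool_lags_bomb_peak_by_about_one_year(self, bomb_curve):
        traj = rc.forward_delta14c(one_pool(k=1.0), bomb_curve, (1900, 2000))
        peak_year = float(traj.index[np.argmax(traj.iloc[:, 0].to_numpy())])
        assert 1964.4 < peak_year < 1965.8

    def test_expm_and_ivp_routes_agree(self, bomb_curve, topsoil_model):
        a = rc.forward_delta14c(topsoil_model, bomb_curve, (1900, 2019), dt=0.1)
        b = rc.forward_delta14c(topsoil_model, bomb_curve, (1900, 2019), dt=0.1, method="ivp")
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.1  # permil

    def test_short_curve_rejected(self, topsoil_model):
        short = rc.AtmosphericCurve(np.array([1950.0, 2000.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="support"):
            rc.forward_delta14c(topsoil_model, short, (1900, 2022))


class TestSplice:
    def _tab(self, years, vals):
        return pd.DataFrame({"year": years, "delta14c_permil": vals})

    def test_single_source_identity(self):
        tab = self._tab([1900.0, 1950.0, 2000.0], [0.0, 10.0, 100.0])
        curve = rc.splice_atmospheric_curve([("only", tab)])
        assert curve.delta(1950.0) == pytest.approx(10.0)
        assert curve.delta(1925.0) == pytest.approx(5.0)

    def test_identical_overlap_equals_either(self):
        a = self._tab([1900.0, 1950.0, 1960.0], [0.0, 10.0, 20.0])
        b = self._tab([1950.0, 1960.0, 2000.0], [10.0, 20.0, 50.0])
        curve = rc.splice_atmospheric_curve([("early", a), ("late", b)])
        for y in (1925.0, 1955.0, 1980.0):
            assert curve.delta(y) == pytest.approx(
                np.interp(y, [1900, 1950, 1960, 2000], [0, 10, 20, 50]), abs=1e-9
            )

    def test_later_source_wins_in_overlap(self):
        a = self._tab([1900.0, 1960.0, 1980.0], [0.0, 999.0, 999.0])
        b = self._tab([1955.0, 1980.0], [10.0, 30.0])
        curve = rc.splice_atmospheric_curve([("early", a), ("late", b)])
        assert curve.delta(1970.0) == pytest.approx(
            np.interp(1970.0, [1955, 1980], [10, 30]), abs=1e-6
        )

    def test_join_value_matches_hand_interpolation(self):
        a = self._tab([1900.0, 1949.0], [0.0, 8.0])
        b = self._tab([1951.0, 2000.0], [12.0, 60.0])
        curve = rc.splice_atmospheric_curve([("pre", a), ("post", b)])
        # linear between (1949, 8) and (1951, 12) -> 10 at 1950
        assert curve.delta(1950.0) == pytest.approx(10.0, abs=1e-6)

    def test_large_gap_rejected(self):
        a = self._tab([1900.0, 1940.0], [0.0, 5.0])
        b = self._tab([1950.0, 2000.0], [12.0, 60.0])
        with pytest.raises(ValueError, match="gap"):
            rc.splice_atmospheric_curve([("pre", a), ("post", b)])


class TestFit:
    def test_noiseless_round_trip(self, bomb_curve, topsoil_model):
        obs = syn.synth_radiocarbon_obs(topsoil_model, bomb_curve, noise_sigma=0.0, seed=1)
        stocks = dict(zip(topsoil_model.pool_names, topsoil_model.steady_state()))
        fit = rc.fit_model(obs, bomb_curve, litter_input=190.0, stocks=stocks, n_starts=3, seed=2)
        for name, true in topsoil_model.rates.items():
            assert fit.params[name] == pytest.approx(true, rel=1e-2)
        assert fit.success

    def test_single_pool_observations_under_determined(self, bomb_curve):
        obs = pd.DataFrame(
            {
                "year": [2012.0, 2019.0] * 3,
                "pool": ["bulk_soc"] * 6,
                "delta14c_permil": [80.0, 79.0] * 3,
                "sd_permil": [5.0] * 6,
            }
        )
        with pytest.raises(ValueError, match="single pool"):
            rc.fit_model(obs, bomb_curve, litter_input=190.0)

    def test_single_year_rejected(self, bomb_curve):
        obs = pd.DataFrame(
            {
                "year": [2019.0] * 6,
                "pool": list(rc.POOLS) * 2,
                "delta14c_permil": [40.0, 40.0, 80.0] * 2,
                "sd_permil": [5.0] * 6,
            }
        )
        with pytest.raises(ValueError, match=">= 2 years"):
            rc.fit_model(obs, bomb_curve, litter_input=190.0)


class TestAgeDistributions:
    def test_one_pool_exponential_closed_forms(self):
        dist = rc.age_distribution(one_pool(0.1), "system", max_age=200.0)
        assert dist.mean == pytest.approx(10.0, abs=1e-10)
        assert dist.median == pytest.approx(np.log(2) / 0.1, abs=1e-4)
        # density matches k*exp(-k*a) at bin midpoints
        centres = dist.age_grid + dist.step / 2
        np.testing.assert_allclose(
            dist.density[:50], 0.1 * np.exp(-0.1 * centres[:50]), rtol=2e-3
        )

    def test_numeric_mean_matches_closed_form(self, topsoil_model):
        dist = rc.age_distribution(topsoil_model, "bulk_soc")
        assert dist.numeric_mean() == pytest.approx(dist.mean, rel=1e-3)

    def test_density_normalised_and_mass_captured(self, topsoil_model):
        for scope in ("system", "bulk_soc", "fine_roots"):
            dist = rc.age_distribution(topsoil_model, scope)
            assert dist.density.sum() * dist.step == pytest.approx(1.0, abs=1e-9)

    def test_pool_age_exceeds_input_pool_age(self, topsoil_model):
        litter = rc.age_distribution(topsoil_model, "aboveground_litter")
        soc = rc.age_distribution(topsoil_model, "bulk_soc")
        assert soc.mean > litter.mean

    def test_transit_equals_age_for_one_pool(self):
        age = rc.age_distribution(one_pool(0.1), "system", max_age=200.0)
        transit = rc.transit_time_distribution(one_pool(0.1), max_age=200.0)
        assert transit.mean == pytest.approx(age.mean, abs=1e-10)
        assert transit.median == pytest.approx(age.median, abs=1e-8)

    def test_mean_transit_is_stock_over_input(self, topsoil_model):
        dist = rc.transit_time_distribution(topsoil_model)
        identity = topsoil_model.steady_state().sum() / topsoil_model.u.sum()
        assert dist.mean == pytest.approx(identity, rel=1e-12)
        assert dist.numeric_mean() == pytest.approx(identity, rel=1e-3)

    def test_slow_trap_pool_preserves_transit_identity(self):
        """A slow pool holding mass but fed a tiny input leaves stock/input intact."""
        model = rc.CompartmentModel(
            u=np.array([1.0, 1e-6, 0.0]),
            B=np.array([[-0.5, 0.0, 0.0], [0.0, -0.001, 0.0], [0.1, 0.0005, -0.02]]),
        )
        dist = rc.transit_time_distribution(model, max_age=6000.0)
        assert dist.mean == pytest.approx(model.steady_state().sum() / model.u.sum(), rel=1e-12)

    def test_warming_rejuvenates_soc(self, topsoil_model):
        """Raising k3 at fixed inputs lowers the SOC mean age."""
        r = topsoil_model.rates
        warmer = rc.CompartmentModel.from_rates(
            r["k1"], r["k2"], r["k3"] * 1.5, r["a31"], r["a32"], 190.0
        )
        base = rc.age_distribution(topsoil_model, "bulk_soc").mean
        warm = rc.age_distribution(warmer, "bulk_soc").mean
        assert warm < base

    def test_mixture_aggregation(self, topsoil_model):
        a = rc.age_distribution(topsoil_model, "bulk_soc")
        mix = rc.mixture_age_distribution([a, a], [6.3, 4.5])
        assert mix.mean == pytest.approx(a.mean, rel=1e-12)
        assert mix.density.sum() * mix.step == pytest.approx(1.0, abs=1e-9)


class TestDelta14CMassDistribution:
    def test_all_mass_at_age_zero(self, bomb_curve):
        dist_age = rc.AgeDistribution(
            age_grid=np.arange(5.0), density=np.array([1.0, 0, 0, 0, 0]),
            scope="pool", mean=0.5, median=0.5,
        )
        d = rc.delta14c_mass_distribution(dist_age, bomb_curve, 2019.0, bins=20)
        atm = rc.age_to_delta14c(np.array([0.5]), bomb_curve, 2019.0)[0]
        j = np.argmax(d.mass_fraction)
        assert d.bin_edges[j] <= atm <= d.bin_edges[j + 1]
        assert d.mass_fraction[j] == pytest.approx(1.0)

    def test_mass_conserved_after_binning(self, bomb_curve, topsoil_model):
        age = rc.age_distribution(topsoil_model, "bulk_soc")
        d = rc.delta14c_mass_distribution(age, bomb_curve, 2019.0, bins=40)
        assert d.mass_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_matches_forward_model_within_2_permil(self, bomb_curve, topsoil_model):
        """Dual route: age-distribution mapping vs the forward 14C balance."""
        age = rc.age_distribution(topsoil_model, "bulk_soc", age_step=1.0)
        centres = age.age_grid + age.step / 2
        mapped = float(
            np.sum(age.bin_masses * rc.age_to_delta14c(centres, bomb_curve, 2019.0))
        )
        traj = rc.forward_delta14c(topsoil_model, bomb_curve, (1900.0, 2019.0))
        fwd = float(np.interp(2019.0, traj.index, traj["bulk_soc"]))
        assert mapped == pytest.approx(fwd, abs=2.0)

    def test_empty_bins_rejected(self, bomb_curve, topsoil_model):
        age = rc.age_distribution(topsoil_model, "bulk_soc")
        with pytest.raises(ValueError, match="bin"):
            rc.delta14c_mass_distribution(age, bomb_curve, 2019.0, bins=0)
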