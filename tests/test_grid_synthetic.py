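import numpy as np
import pytest

from chillscape import (
    SyntheticParams,
    coarsen,
    make_grid,
    simulate_daily_obs,
    simulate_model_ensemble,
)
from chillscape.errors import InvalidArgumentError, InvalidGridError


class TestMakeGrid:
    def test_degenerate_single_cell(self):
        g = make_grid(1, fruit_fraction=1.0)
        assert g.n_cells == 1 and bool(g.fruit_area[0])

    def test_fruit_fraction_binomial_band(self):
        g = make_grid(100, fruit_fraction=0.3, seed=7)
        assert 20 <= int(g.fruit_area.sum()) <= 40

    def test_determinism(self):
        a = make_grid(50, fruit_fraction=0.3, seed=9)
        b = make_grid(50, fruit_fraction=0.3, seed=9)
        for attr in ("lon", "lat", "elevation", "fruit_area"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))
        assert list(a.region) == list(b.region)

    def test_region_split_by_longitude_median(self):
        g = make_grid(100, seed=1)
        east = g.lon[g.region == "east"]
        west = g.lon[g.region == "west"]
        assert east.min() >= west.max()

    def test_empty_ranges_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_grid(10, lat_range=(42.0, 40.0))
        with pytest.raises(InvalidArgumentError):
            make_grid(10, elev_range=(1000.0, 100.0))

    def test_coarsen_is_lattice_subset(self):
        g = make_grid(100, seed=2)
        c = coarsen(g, 5)
        assert c.nx == 2 and c.ny == 2
        assert set(c.cell_id).issubset(set(g.cell_id))
        with pytest.raises(InvalidGridError):
            coarsen(g, 50)


class TestSimulateObs:
    def test_flat_climate_every_day_identical(self, small_grid):
        p = SyntheticParams(
            noise_sd=0.0, seasonal_amplitude=0.0, lapse_rate=0.0, seed=1
        )
        f = simulate_daily_obs(small_grid, 1990, 1991, p)
        assert np.ptp(f.tmin) == 0.0 and np.ptp(f.tmax) == 0.0
        assert np.allclose(f.tmax - f.tmin, p.diurnal_range_mean)

    def test_lapse_rate_closed_form(self):
        g = make_grid(4, elev_range=(0.0, 1000.0), seed=0)
        # force exactly 0 m and 1000 m on two cells
        g.elevation[:] = [0.0, 1000.0, 500.0, 250.0]
        p = SyntheticParams(noise_sd=0.0, lapse_rate=6.5, seed=1)
        f = simulate_daily_obs(g, 1990, 1990, p)
        tmean = (f.tmin + f.tmax) / 2
        diff = tmean[0].mean() - tmean[1].mean()
        assert diff == pytest.approx(6.5, abs=1e-9)

    def test_thirty_years_is_10950_days(self, small_grid, quiet_params):
        f = simulate_daily_obs(small_grid, 1971, 2000, quiet_params)
        assert f.n_days == 10950

    def test_tmax_never_below_tmin(self, obs_small):
        assert np.all(obs_small.tmax >= obs_small.tmin)

    def test_bit_reproducible(self, small_grid):
        p = SyntheticParams(seed=17)
        a = simulate_daily_obs(small_grid, 1999, 2000, p)
        b = simulate_daily_obs(small_grid, 1999, 2000, p)
        np.testing.assert_array_equal(a.tmin, b.tmin)
        np.testing.assert_array_equal(a.tmax, b.tmax)


class TestEnsemble:
    def test_pure_additive_bias_exact(self, small_grid):
        p = SyntheticParams(
            noise_sd=0.0, model_bias_add=2.0, model_bias_mult=1.0, seed=4
        )
        obs = simulate_daily_obs(small_grid, 1995, 1996, p)
        (member,) = simulate_model_ensemble(small_grid, 1995, 1996, p, 1, "hist")
        np.testing.assert_allclose(member.tmin, obs.tmin + 2.0, atol=1e-12)
        np.testing.assert_allclose(member.tmax, obs.tmax + 2.0, atol=1e-12)

    def test_member_count(self, small_grid, quiet_params):
        members = simulate_model_ensemble(
            small_grid, 1999, 2000, quiet_params, 18, "hist"
        )
        assert len(members) == 18

    def test_unknown_scenario_rejected(self, small_grid, quiet_params):
        with pytest.raises(InvalidArgumentError):
            simulate_model_ensemble(small_grid, 1999, 2000, quiet_params, 1, "ssp585")

    def test_warming_trend_linear_per_decade(self, small_grid):
        p = SyntheticParams(noise_sd=0.0, model_bias_add=0.0, model_bias_mult=1.0,
                            warming_per_decade=0.3, seed=4)
        (hist,) = simulate_model_ensemble(small_grid, 2041, 2042, p, 1, "hist")
        (r45,) = simulate_model_ensemble(small_grid, 2041, 2042, p, 1, "rcp45")
        (r85,) = simulate_model_ensemble(small_grid, 2041, 2042, p, 1, "rcp85")
        lift45 = (r45.tmin - hist.tmin)[:, 0]
        assert lift45 == pytest.approx(0.3 * (2041 - 2006) / 10, abs=1e-9)
        np.testing.assert_allclose(r85.tmin - hist.tmin, 2 * (r45.tmin - hist.tmin))

    def test_zero_bias_ensemble_mean_converges_to_obs_climatology(self):
        g = make_grid(4, seed=3)
        p = SyntheticParams(model_bias_add=0.0, model_bias_mult=1.0, seed=21)
        members = simulate_model_ensemble(g, 1999, 2000, p, 50, "hist")
        stack = np.stack([(m.tmin + m.tmax) / 2 for m in members])
        mean = stack.mean(axis=0)
        obs = simulate_daily_obs(g, 1999, 2000, p)
        # closed-form expectation = deterministic part of the process
        base = (
            p.annual_mean_at_sea_level - p.lapse_rate * g.elevation / 1000.0
        )[:, None]
        seasonal = p.seasonal_amplitude * np.cos(
            2 * np.pi * (obs.doys - 197) / 365.0
        )[None, :]
        err = mean - (base + seasonal)
        assert np.abs(err.mean()) < 0.15
        assert np.sqrt((err**2).mean()) < 0.6
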