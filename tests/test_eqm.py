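import numpy as np
import pytest

from chillscape import (
    SyntheticParams,
    apply_transfer,
    build_transfer,
    empirical_quantiles,
    make_grid,
    self_adjust_diagnostics,
    simulate_daily_obs,
    simulate_model_ensemble,
)
from chillscape.eqm import DEFAULT_PROBS, correct_field
from chillscape.errors import CalibrationMismatchError, InsufficientSampleError


class TestEmpiricalQuantiles:
    def test_linear_rank_midpoint(self):
        q = empirical_quantiles(np.arange(1, 101), [0.5])
        assert q[0] == pytest.approx(50.5)

    def test_endpoints_are_min_max(self):
        v = np.array([3.0, -1.0, 7.0] * 10)
        q = empirical_quantiles(v, [0.0, 1.0])
        assert q[0] == -1.0 and q[1] == 7.0

    def test_constant_series(self):
        q = empirical_quantiles(np.full(50, 2.5), DEFAULT_PROBS)
        assert np.all(q == 2.5)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientSampleError):
            empirical_quantiles(np.arange(5), DEFAULT_PROBS)


class TestBuildTransfer:
    def test_identity(self, rng):
        x = rng.normal(size=500)
        t = build_transfer(x, x)
        np.testing.assert_allclose(t.obs_q, t.mod_q)
        assert len(t.probs) == 21

    def test_shift_equivariance(self, rng):
        x = rng.normal(size=500)
        t = build_transfer(x, x + 2.0)
        np.testing.assert_allclose(t.mod_q, t.obs_q + 2.0, atol=1e-12)

    def test_scale_equivariance(self, rng):
        x = np.abs(rng.normal(size=500))
        t = build_transfer(x, 1.5 * x)
        np.testing.assert_allclose(t.mod_q, 1.5 * t.obs_q, atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(CalibrationMismatchError):
            build_transfer(rng.normal(size=100), rng.normal(size=99))


class TestApplyTransfer:
    def test_identity_transfer_is_identity(self, rng):
        x = rng.normal(size=300)
        t = build_transfer(x, x)
        future = rng.normal(size=100) * 3
        np.testing.assert_allclose(apply_transfer(t, future), future, atol=1e-9)

    def test_constant_shift_removed_even_beyond_range(self, rng):
        x = rng.normal(size=1000)
        t = build_transfer(x, x + 2.0)
        future = np.array([-50.0, 0.0, 1.0, 50.0])
        np.testing.assert_allclose(apply_transfer(t, future), future - 2.0, atol=1e-9)

    def test_calibration_closure_at_all_knots(self, rng):
        obs = rng.normal(10, 3, size=10950)
        mod = rng.normal(12, 4, size=10950)
        t = build_transfer(obs, mod)
        corrected = apply_transfer(t, mod)
        got = np.quantile(corrected, DEFAULT_PROBS)
        assert np.max(np.abs(got - t.obs_q)) <= 0.05

    def test_rank_order_preserved(self, rng):
        obs = rng.normal(size=500)
        mod = rng.normal(1, 1.4, size=500)
        t = build_transfer(obs, mod)
        fut = np.sort(rng.normal(1, 2, size=200))
        out = apply_transfer(t, fut)
        assert np.all(np.diff(out) >= -1e-12)


class TestDiagnostics:
    def test_unbiased_model_no_differences(self, rng):
        x = rng.normal(size=2000)
        d = self_adjust_diagnostics(x, x).before_after()
        assert np.allclose(d["diff_before"], 0.0, atol=1e-9)
        assert np.allclose(d["diff_after"], 0.0, atol=1e-9)

    def test_additive_bias_recovered_at_median(self, rng):
        x = rng.normal(size=5000)
        d = self_adjust_diagnostics(x, x + 2.0).before_after().set_index("quantile")
        assert d.loc[0.50, "diff_before"] == pytest.approx(2.0, abs=0.15)
        assert abs(d.loc[0.50, "diff_after"]) < 0.02

    def test_scale_bias_shrinks_tail_differences(self, rng):
        x = rng.normal(size=5000)
        d = self_adjust_diagnostics(x, 1.3 * x).before_after().set_index("quantile")
        for q in (0.05, 0.95):
            assert abs(d.loc[q, "diff_after"]) < abs(d.loc[q, "diff_before"])


class TestKnownBiasRecovery:
    """Injected-bias recovery through the full synthetic + EQM path.

    Errors are measured as the grid-mean over 9 cells: a single 30-year
    cell series carries ~0.08 °C of pure sampling noise between the
    observed and modelled climatologies, which any quantile mapping
    transfers into its output; averaging over cells isolates the
    mapping's own systematic error.
    """

    GRID = make_grid(9, seed=2)

    @pytest.mark.parametrize("bias_add", [-3.0, -1.0, 1.0, 3.0])
    def test_additive_bias_recovered_under_warming(self, bias_add):
        grid = self.GRID
        p = SyntheticParams(model_bias_add=bias_add, model_bias_mult=1.0, seed=31)
        obs = simulate_daily_obs(grid, 1971, 2000, p)
        (hist,) = simulate_model_ensemble(grid, 1971, 2000, p, 1, "hist")
        (future,) = simulate_model_ensemble(grid, 2041, 2070, p, 1, "rcp45")
        truth_p = SyntheticParams(model_bias_add=0.0, model_bias_mult=1.0, seed=31)
        (truth,) = simulate_model_ensemble(grid, 2041, 2070, truth_p, 1, "rcp45")
        corrected, _ = correct_field(obs, hist, future)
        err = np.mean(corrected.tmin.mean(axis=1) - truth.tmin.mean(axis=1))
        assert abs(err) <= 0.1

    @pytest.mark.parametrize("bias_mult", [0.8, 1.2])
    def test_scale_bias_recovered_in_stationary_climate(self, bias_mult):
        grid = self.GRID
        p = SyntheticParams(model_bias_add=0.0, model_bias_mult=bias_mult, seed=37)
        obs = simulate_daily_obs(grid, 1971, 2000, p)
        (hist,) = simulate_model_ensemble(grid, 1971, 2000, p, 1, "hist")
        (future,) = simulate_model_ensemble(grid, 2001, 2030, p, 1, "hist")
        truth_p = SyntheticParams(model_bias_add=0.0, model_bias_mult=1.0, seed=37)
        (truth,) = simulate_model_ensemble(grid, 2001, 2030, truth_p, 1, "hist")
        corrected, _ = correct_field(obs, hist, future)
        for got, want in ((corrected.tmin, truth.tmin), (corrected.tmax, truth.tmax)):
            err = np.mean(got.mean(axis=1) - want.mean(axis=1))
            assert abs(err) <= 0.1

    def test_monotone_transfer_on_synthetic_cases(self, rng):
        grid = make_grid(1, seed=2)
        p = SyntheticParams(model_bias_add=1.0, model_bias_mult=1.2, seed=41)
        obs = simulate_daily_obs(grid, 1971, 2000, p)
        (hist,) = simulate_model_ensemble(grid, 1971, 2000, p, 1, "hist")
        _, transfers = correct_field(obs, hist, hist)
        for t in transfers:
            assert np.all(np.diff(t.obs_q) >= 0)
            assert np.all(np.diff(t.mod_q) >= 0)
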