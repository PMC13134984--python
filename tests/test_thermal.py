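import numpy as np
import pytest

from chillscape import (
    CHILL_WINDOW,
    HEAT_WINDOW,
    ChillState,
    accumulate_chill_portions,
    accumulate_gdh,
    chill_accumulate,
    chill_step,
    gdh_hour,
)
from chillscape.calendar365 import noleap_daily_index
from chillscape.errors import InvalidArgumentError, MissingDataError
from oracles import chill_portions_reference, gdh_reference


def _season_hourly(const_temp, start_year=1990, end_year=1992):
    years, doys = noleap_daily_index(start_year, end_year)
    hourly = np.full((len(years), 24), float(const_temp))
    return hourly, years, doys


class TestChillStep:
    def test_single_step_cannot_deliver(self):
        for t in (-5.0, 6.0, 20.0):
            out = chill_step(ChillState(), t)
            assert out.portions == 0.0
            assert out.intermediate_E >= 0.0

    def test_first_delivery_matches_reference_loop(self):
        state = ChillState()
        hours = 0
        while state.portions == 0.0 and hours < 500:
            state = chill_step(state, 6.0)
            hours += 1
        ref_portions, ref_e = chill_portions_reference([6.0] * hours)
        assert state.portions > 0.0
        assert state.portions == pytest.approx(ref_portions, abs=1e-12)
        assert state.intermediate_E == pytest.approx(ref_e, abs=1e-12)

    def test_hot_temperatures_never_deliver(self):
        state = ChillState()
        for _ in range(1000):
            state = chill_step(state, 35.0)
        assert state.portions == 0.0

    def test_nonfinite_temperature_rejected(self):
        with pytest.raises(InvalidArgumentError):
            chill_step(ChillState(), float("nan"))


class TestChillAccumulate:
    def test_matches_reference_on_random_paths(self, rng):
        temps = rng.uniform(-5.0, 30.0, size=(5, 1000))
        vec = chill_accumulate(temps)
        for i in range(5):
            ref, _ = chill_portions_reference(temps[i])
            assert vec[i] == pytest.approx(ref, abs=1e-9)

    def test_portions_nondecreasing_along_path(self, rng):
        temps = rng.uniform(-5.0, 30.0, size=400)
        state = ChillState()
        prev = 0.0
        for t in temps:
            state = chill_step(state, float(t))
            assert state.portions >= prev
            prev = state.portions

    def test_unimodal_in_constant_temperature(self):
        scan = np.arange(-5.0, 20.01, 0.5)
        cps = chill_accumulate(np.tile(scan[:, None], (1, 2880)))
        peak = int(np.argmax(cps))
        assert 0 < peak < len(scan) - 1
        # tolerance of one portion: delivery events are quantized
        assert np.all(np.diff(cps[: peak + 1]) >= -1.0)
        assert np.all(np.diff(cps[peak:]) <= 1.0)
        assert chill_accumulate(np.full(2880, 35.0)) == 0.0


class TestChillWindow:
    def test_window_is_120_days(self):
        assert CHILL_WINDOW.n_days == 120

    def test_constant_optimal_season(self):
        hourly, years, doys = _season_hourly(6.0)
        cp = accumulate_chill_portions(hourly, years, doys, 1990)
        ref, _ = chill_portions_reference([6.0] * 2880)
        assert cp == pytest.approx(ref, abs=1e-9)
        assert 80 < cp < 120

    def test_hot_season_zero(self):
        hourly, years, doys = _season_hourly(35.0)
        assert accumulate_chill_portions(hourly, years, doys, 1990) == 0.0

    def test_doubled_exposure_doubles_portions(self):
        single, _ = chill_portions_reference([6.0] * 2880)
        double, _ = chill_portions_reference([6.0] * 5760)
        assert double == pytest.approx(2 * single, abs=1.0)

    def test_incomplete_coverage_raises(self):
        hourly, years, doys = _season_hourly(6.0)
        with pytest.raises(MissingDataError):
            accumulate_chill_portions(hourly, years, doys, 1992)  # needs Feb 1993


class TestGdh:
    @pytest.mark.parametrize(
        "temp,expected", [(4.0, 0.0), (26.0, 22.0), (36.0, 0.0), (15.0, 11.0),
                          (40.0, 0.0), (0.0, 0.0)]
    )
    def test_closed_form_values(self, temp, expected):
        assert gdh_hour(temp) == pytest.approx(expected, abs=1e-9)

    def test_continuous_zero_outside_and_unimodal(self):
        scan = np.arange(-10.0, 50.0, 0.1)
        vals = gdh_hour(scan)
        assert np.all(vals >= 0.0) and np.all(vals <= 22.0 + 1e-12)
        assert np.all(vals[(scan < 4.0) | (scan > 36.0)] == 0.0)
        assert float(scan[np.argmax(vals)]) == pytest.approx(26.0, abs=0.1)
        # continuity: no jump larger than the 0.1 °C grid can explain
        assert np.max(np.abs(np.diff(vals))) < 0.35
        assert np.allclose(vals, [gdh_reference(t) for t in scan])

    def test_heat_window_is_59_days(self):
        assert HEAT_WINDOW.n_days == 59

    @pytest.mark.parametrize(
        "temp,total", [(26.0, 1416 * 22.0), (15.0, 1416 * 11.0), (0.0, 0.0)]
    )
    def test_window_totals_closed_form(self, temp, total):
        hourly, years, doys = _season_hourly(temp)
        assert accumulate_gdh(hourly, years, doys, 1990) == pytest.approx(total)
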