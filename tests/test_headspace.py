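import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferriflux.headspace import (
    CalibrationCurve,
    GasSample,
    HeadspaceState,
    RGAScan,
    SamplingEvent,
    R_GAS_L_ATM,
    calibrated_ratio,
    cumulative_methane,
    headspace_fractions,
    headspace_volume,
    max_rate_window,
    moles_in_headspace,
    production_rate,
    rga_gas_consumed,
    stable_average,
)


def make_scan(values_by_mz, bottle="b1", day=0.0):
    """Scan whose readout k carries values_by_mz[mz][k]."""
    n = len(next(iter(values_by_mz.values())))
    readouts = tuple(
        (18.0 * (k + 1), {mz: vals[k] for mz, vals in values_by_mz.items()})
        for k in range(n)
    )
    return RGAScan(bottle=bottle, day=day, readouts=readouts)


class TestStableAverage:
    def test_constant_signals(self):
        scan = make_scan({15: [2.0] * 8, 28: [1.0] * 8})
        assert stable_average(scan) == {15: 2.0, 28: 1.0}

    def test_mean_of_last_five(self):
        scan = make_scan({15: [9.0, 9.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        assert stable_average(scan, n_last=5) == {15: 3.0}

    def test_n_last_one_is_last_readout(self):
        scan = make_scan({15: [1.0, 2.0, 7.0]})
        assert stable_average(scan, n_last=1) == {15: 7.0}

    def test_too_few_readouts_names_scan(self):
        scan = make_scan({15: [1.0, 2.0]}, bottle="bx", day=3.0)
        with pytest.raises(ValueError, match="bx"):
            stable_average(scan, n_last=5)

    def test_unordered_readouts_rejected(self):
        with pytest.raises(ValueError, match="time-ordered"):
            RGAScan("b", 0.0, ((10.0, {15: 1.0}), (5.0, {15: 1.0})))

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            RGAScan("b", 0.0, ((10.0, {15: -1.0}),))


class TestCalibratedRatio:
    def test_identity_curve(self):
        curve = CalibrationCurve("CH4", 15, slope=1.0, intercept=0.0)
        assert calibrated_ratio(3.0, 6.0, curve) == pytest.approx(0.5)

    def test_slope_two(self):
        curve = CalibrationCurve("CH4", 15, slope=2.0, intercept=0.0)
        assert calibrated_ratio(1.0, 4.0, curve) == pytest.approx(0.5)

    def test_negative_clamped_with_warning(self):
        curve = CalibrationCurve("CH4", 15, slope=1.0, intercept=-0.1)
        with pytest.warns(UserWarning, match="clamped"):
            assert calibrated_ratio(0.05, 1.0, curve) == 0.0

    def test_zero_n2_rejected(self):
        curve = CalibrationCurve("CH4", 15, slope=1.0)
        with pytest.raises(ValueError, match="N2"):
            calibrated_ratio(1.0, 0.0, curve)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            CalibrationCurve("CH4", 15, slope=0.0)


class TestHeadspaceFractions:
    def test_zero_ratios(self):
        assert headspace_fractions(0.0, 0.0) == (0.0, 0.0, 1.0)

    def test_symmetric_thirds(self):
        f = headspace_fractions(1.0, 1.0)
        assert f == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_direct_substitution(self):
        assert headspace_fractions(2.0, 1.0) == pytest.approx((0.5, 0.25, 0.25))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            headspace_fractions(-0.1, 0.0)

    @given(
        r_ch4=st.floats(0, 1e6, allow_nan=False),
        r_co2=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(deadline=None)
    def test_fractions_sum_to_one(self, r_ch4, r_co2):
        f_ch4, f_co2, f_n2 = headspace_fractions(r_ch4, r_co2)
        assert abs(f_ch4 + f_co2 + f_n2 - 1.0) < 1e-12
        denom = r_ch4 + r_co2 + 1.0
        assert f_ch4 == pytest.approx(r_ch4 / denom)
        assert f_co2 == pytest.approx(r_co2 / denom)

    @given(
        r_lo=st.floats(0, 100),
        bump=st.floats(0.001, 100),
        r_co2=st.floats(0, 100),
        slope=st.floats(0.1, 10),
        intercept=st.floats(0, 1),
    )
    @settings(deadline=None)
    def test_monotone_calibration_preserves_ordering(
        self, r_lo, bump, r_co2, slope, intercept
    ):
        curve = CalibrationCurve("CH4", 15, slope=slope, intercept=intercept)
        a = calibrated_ratio(r_lo, 1.0, curve)
        b = calibrated_ratio(r_lo + bump, 1.0, curve)
        fa = headspace_fractions(a, r_co2)[0]
        fb = headspace_fractions(b, r_co2)[0]
        assert fb >= fa


class TestHeadspaceVolume:
    def test_initial_at_t0(self):
        events = [SamplingEvent(day=0.0)]
        assert headspace_volume(events, day=0.0) == 300.0

    def test_three_withdrawals(self):
        events = [SamplingEvent(day=d, liquid_ml=6.0) for d in (0.0, 2.0, 4.0)]
        assert headspace_volume(events) == 318.0
        assert headspace_volume(events, day=5.0) == 318.0

    def test_no_events(self):
        assert headspace_volume([], day=3.0) == 300.0
        assert headspace_volume([], initial_ml=250.0) == 250.0

    def test_strict_before_excludes_same_day(self):
        events = [SamplingEvent(day=0.0), SamplingEvent(day=2.0)]
        assert headspace_volume(events, day=2.0) == 306.0
        assert headspace_volume(events, day=2.0, include_same_day=True) == 312.0

    def test_unordered_rejected(self):
        events = [SamplingEvent(day=2.0), SamplingEvent(day=0.0)]
        with pytest.raises(ValueError, match="time-ordered"):
            headspace_volume(events)


class TestMolesInHeadspace:
    def test_zero_fraction(self):
        assert moles_in_headspace(0.0, 300.0) == 0.0

    def test_pv_over_rt_oracle(self):
        expected = 1.0 * 0.3 / (R_GAS_L_ATM * 298.0) * 0.1
        assert moles_in_headspace(0.1, 300.0) == pytest.approx(expected)
        assert moles_in_headspace(0.1, 300.0) == pytest.approx(1.227e-3, rel=1e-3)

    def test_full_headspace_is_ten_times(self):
        assert moles_in_headspace(1.0, 300.0) == pytest.approx(
            10 * moles_in_headspace(0.1, 300.0)
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fraction": -0.1, "volume_ml": 300.0},
            {"fraction": 1.1, "volume_ml": 300.0},
            {"fraction": 0.5, "volume_ml": -1.0},
            {"fraction": 0.5, "volume_ml": 300.0, "pressure_atm": 0.0},
            {"fraction": 0.5, "volume_ml": 300.0, "temperature_k": -10.0},
        ],
    )
    def test_non_physical_rejected(self, kwargs):
        with pytest.raises(ValueError):
            moles_in_headspace(**kwargs)


class TestRgaGasConsumed:
    def test_zero_duration(self):
        assert rga_gas_consumed(0.0) == 0.0

    def test_one_syringe(self):
        assert rga_gas_consumed(26.0) == pytest.approx(1.0)

    def test_three_minutes(self):
        assert rga_gas_consumed(180.0) == pytest.approx(180.0 / 26.0)
        assert rga_gas_consumed(180.0) == pytest.approx(6.92, abs=0.01)

    def test_nominal_three_minutes_rounds_to_seven(self):
        assert rga_gas_consumed(180.0, nominal=True) == 7.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rga_gas_consumed(-1.0)


def simulate_bottle_inventory(
    produced_curve, days, liquid_ml=6.0, gas_ml=7.0, initial_ml=300.0
):
    """Independent step-by-step bottle oracle (explicit mole inventory).

    Gas is removed at the measured composition *after* each measurement;
    liquid withdrawals enlarge the headspace for later timepoints only.
    Returns (samples for cumulative_methane, true cumulative production).
    """
    r_gas, t_k = 0.082057, 298.0
    removed = 0.0
    volume = initial_ml
    samples, true_cum = [], []
    for day in days:
        c = produced_curve(day)
        n_total = 1.0 * (volume / 1000.0) / (r_gas * t_k)
        f_ch4 = (c - removed) / n_total
        f_co2 = 0.2 * c / n_total
        samples.append(
            GasSample(
                day=day, f_ch4=f_ch4, f_co2=f_co2,
                volume_ml=volume, gas_removed_ml=gas_ml,
            )
        )
        true_cum.append(c)
        removed += f_ch4 * 1.0 * (gas_ml / 1000.0) / (r_gas * t_k)
        volume += liquid_ml
    return samples, true_cum


class TestCumulativeMethane:
    def test_single_timepoint(self):
        states = cumulative_methane(
            [GasSample(day=0.0, f_ch4=0.2, f_co2=0.1, volume_ml=300.0)]
        )
        assert states[0].n_produced == states[0].n_present

    def test_no_correction_when_first_fraction_zero(self):
        samples = [
            GasSample(day=0.0, f_ch4=0.0, f_co2=0.0, volume_ml=300.0),
            GasSample(day=5.0, f_ch4=0.1, f_co2=0.05, volume_ml=306.0, gas_removed_ml=0.0),
        ]
        states = cumulative_methane(samples)
        assert states[1].n_produced == states[1].n_present

    def test_explicit_arithmetic_oracle(self):
        # produced(2) = present(2) + 0.05 * (7 mL as moles)
        samples = [
            GasSample(day=0.0, f_ch4=0.05, f_co2=0.0, volume_ml=300.0, gas_removed_ml=7.0),
            GasSample(day=5.0, f_ch4=0.10, f_co2=0.0, volume_ml=306.0, gas_removed_ml=0.0),
        ]
        states = cumulative_methane(samples)
        correction = 0.05 * 1.0 * (7.0 / 1000.0) / (R_GAS_L_ATM * 298.0)
        assert states[1].n_produced == pytest.approx(
            states[1].n_present + correction, rel=1e-12
        )

    def test_current_removal_included_by_default(self):
        samples = [
            GasSample(day=0.0, f_ch4=0.05, f_co2=0.0, volume_ml=300.0, gas_removed_ml=7.0),
            GasSample(day=5.0, f_ch4=0.10, f_co2=0.0, volume_ml=306.0, gas_removed_ml=7.0),
        ]
        with_current = cumulative_methane(samples, include_current_removal=True)
        without = cumulative_methane(samples, include_current_removal=False)
        own = 0.10 * 1.0 * (7.0 / 1000.0) / (R_GAS_L_ATM * 298.0)
        assert with_current[1].n_produced == pytest.approx(
            without[1].n_produced + own, rel=1e-12
        )

    def test_brute_force_inventory_oracle(self):
        days = list(np.linspace(0, 30, 12))
        curve = lambda t: 2e-3 / (1 + math.exp(-0.5 * (t - 15)))
        samples, true_cum = simulate_bottle_inventory(curve, days)
        states = cumulative_methane(samples, include_current_removal=False)
        for state, truth in zip(states[1:], true_cum[1:]):
            assert state.n_produced == pytest.approx(truth, rel=1e-9)

    def test_removed_cum_non_decreasing(self):
        days = list(np.linspace(0, 30, 12))
        curve = lambda t: 2e-3 / (1 + math.exp(-0.5 * (t - 15)))
        samples, _ = simulate_bottle_inventory(curve, days)
        states = cumulative_methane(samples)
        removed = [s.n_removed_cum for s in states]
        assert all(b >= a for a, b in zip(removed, removed[1:]))

    def test_correction_strictly_raises_production(self):
        days = list(np.linspace(0, 30, 12))
        curve = lambda t: 2e-3 / (1 + math.exp(-0.5 * (t - 15)))
        samples, _ = simulate_bottle_inventory(curve, days)
        corrected = cumulative_methane(samples)
        uncorrected = [
            moles_in_headspace(s.f_ch4, s.volume_ml) for s in samples
        ]
        for state, raw in zip(corrected[1:], uncorrected[1:]):
            assert state.n_produced > raw

    def test_produced_at_least_present_after_first(self):
        days = list(np.linspace(0, 30, 12))
        curve = lambda t: 2e-3 / (1 + math.exp(-0.5 * (t - 15)))
        samples, _ = simulate_bottle_inventory(curve, days)
        for state in cumulative_methane(samples)[1:]:
            assert state.n_produced >= state.n_present

    def test_unordered_rejected(self):
        samples = [
            GasSample(day=5.0, f_ch4=0.1, f_co2=0.0, volume_ml=300.0),
            GasSample(day=0.0, f_ch4=0.1, f_co2=0.0, volume_ml=300.0),
        ]
        with pytest.raises(ValueError, match="time-ordered"):
            cumulative_methane(samples)


def states_from_produced(days, produced_mol):
    return [
        HeadspaceState(
            day=d, volume_ml=300.0, f_ch4=0.1, f_co2=0.1, f_n2=0.8,
            n_present=p, n_removed_cum=0.0, n_produced=p,
        )
        for d, p in zip(days, produced_mol)
    ]


class TestProductionRate:
    def test_flat_series(self):
        series = states_from_produced([0, 10, 20], [1e-3] * 3)
        assert production_rate(series, (0, 20)) == 0.0

    def test_linear_series_any_window(self):
        days = [0.0, 5.0, 10.0, 20.0]
        series = states_from_produced(days, [1e-4 * d for d in days])
        for window in [(0, 20), (2.5, 7.5), (5, 10)]:
            assert production_rate(series, window) == pytest.approx(0.1)

    def test_logistic_finite_difference_oracle(self):
        days = np.linspace(0, 30, 16)
        curve = lambda t: 2e-3 / (1 + np.exp(-0.5 * (t - 15)))
        series = states_from_produced(days, curve(days))
        # on-grid window: rate equals the secant slope of the curve
        expected = 1000 * (curve(16.0) - curve(12.0)) / 4.0
        assert production_rate(series, (12.0, 16.0)) == pytest.approx(expected)

    def test_window_outside_span_rejected(self):
        series = states_from_produced([0, 10], [0.0, 1e-3])
        with pytest.raises(ValueError, match="span"):
            production_rate(series, (5, 15))


class TestMaxRateWindow:
    def test_convex_series_picks_last_window(self):
        days = list(range(11))
        series = states_from_produced(days, [1e-5 * d**2 for d in days])
        window, _ = max_rate_window(series, 3.0)
        assert window == (7.0, 10.0)

    def test_logistic_window_contains_inflection(self):
        days = np.linspace(0, 30, 31)
        produced = 2e-3 / (1 + np.exp(-0.8 * (days - 15)))
        series = states_from_produced(days, produced)
        window, rate = max_rate_window(series, 3.0)
        assert window[0] <= 15.0 <= window[1]
        # brute-force oracle over every anchored window
        rates = {
            (d, d + 3.0): production_rate(series, (d, d + 3.0))
            for d in days if d + 3.0 <= days[-1]
        }
        best = max(rates, key=lambda w: rates[w])
        assert window == best
        assert rate == pytest.approx(rates[best])

    def test_flat_series_first_window_zero_rate(self):
        days = list(range(11))
        series = states_from_produced(days, [1e-3] * 11)
        window, rate = max_rate_window(series, 3.0)
        assert window == (0.0, 3.0)
        assert rate == 0.0

    def test_short_span_rejected(self):
        series = states_from_produced([0, 1], [0, 1e-3])
        with pytest.raises(ValueError, match="span"):
            max_rate_window(series, 3.0)
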