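"""Tests of the second-order memristor model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortexbcm import device
from cortexbcm.device import (
    DeviceParams,
    DeviceState,
    apply_pulse,
    calibrate_defaults,
    device_ppf_ratio,
    extract_nonlinearity,
    fit_ppf,
    nl_model,
    potentiation_depression_curve,
    ppf_model,
    pulse_train,
    relax,
    relaxation_offset,
    run_train,
)


class TestPPFModel:
    def test_zero_interval_sums_amplitudes(self):
        assert ppf_model(0, 40, 20, 1.0, 10.0) == pytest.approx(60.0)

    def test_long_interval_decays_to_zero(self):
        assert ppf_model(1e6, 50, 50, 0.28, 10.86) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        # 50*exp(-10.86/0.28) + 50*exp(-1) = 18.394 (fast phase fully gone)
        val = ppf_model(10.86, 50, 50, 0.28, 10.86)
        assert val == pytest.approx(50 * np.exp(-10.86 / 0.28) + 50 * np.e**-1)
        assert val == pytest.approx(18.394, abs=1e-3)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            ppf_model(1.0, 50, 50, 0.0, 10.0)


class TestPPFFit:
    INTERVALS = np.geomspace(0.1, 50, 20)

    def test_noiseless_round_trip(self):
        y = [ppf_model(d, 35, 55, 0.5, 12.0) for d in self.INTERVALS]
        fit = fit_ppf(self.INTERVALS, y)
        assert fit.tau1 == pytest.approx(0.5, rel=1e-4)
        assert fit.tau2 == pytest.approx(12.0, rel=1e-4)
        assert fit.c1 == pytest.approx(35, rel=1e-3)
        assert fit.c2 == pytest.approx(55, rel=1e-3)
        assert not fit.degenerate
        assert fit.tau1 <= fit.tau2

    def test_single_exponential_flagged_degenerate(self):
        y = 80 * np.exp(-self.INTERVALS / 5.0)
        assert fit_ppf(self.INTERVALS, y).degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ppf([1, 2, 3], [10, 5, 2])


class TestPulseDynamics:
    def test_zero_volt_pulse_changes_only_trace_and_clock(self, device_params):
        s0 = DeviceState.initial(device_params, 200.0)
        s1, epsc = apply_pulse(s0, 0.0, 5.0, device_params)
        assert s1.G == s0.G
        assert s1.u == s0.u + device_params.kappa_u
        assert s1.t == s0.t + 5.0
        assert epsc == 0.0

    def test_potentiating_pulse_increases_bounded(self, device_params):
        s0 = DeviceState.initial(device_params, 200.0)
        s1, epsc = apply_pulse(s0, 0.5, 5.0, device_params)
        assert device_params.G_min < s0.G < s1.G <= device_params.G_max
        assert epsc == pytest.approx(0.5 * s1.G)

    def test_saturated_state_does_not_potentiate(self, device_params):
        s0 = DeviceState(G_long=device_params.G_max)
        s1, _ = apply_pulse(s0, 0.5, 5.0, device_params)
        assert s1.G == device_params.G_max

    def test_relax_identity_at_zero(self, device_params):
        s = DeviceState(G_long=100.0, G_short=20.0, u=1.0, t=5.0)
        assert relax(s, 0.0, device_params) == s

    def test_relax_semigroup_property(self, device_params):
        s = DeviceState(G_long=100.0, G_short=20.0, u=1.5, t=0.0)
        one = relax(s, 70.0, device_params)
        two = relax(relax(s, 30.0, device_params), 40.0, device_params)
        assert one.G_short == pytest.approx(two.G_short)
        assert one.u == pytest.approx(two.u)

    def test_short_component_relaxes_within_200ms(self, device_params):
        s0 = DeviceState.initial(device_params, 100.0)
        s1, _ = apply_pulse(s0, 0.5, 5.0, device_params)
        peak = s1.G_short
        assert peak > 0
        s2 = relax(s1, 200.0, device_params)
        assert s2.G_short < 0.05 * peak


class TestRunTrain:
    def test_high_frequency_train_potentiates(self, device_params):
        train = pulse_train(10, 0.5, 5.0, 5.0)
        trace = run_train(DeviceState.initial(device_params, 100.0), train, device_params)
        assert trace.G[-1] > 100.0
        assert trace.epsc.shape == (10,)

    def test_history_dependent_four_train_sign_sequence(self, device_params):
        """100 Hz potentiates, 10 Hz from the elevated state depresses, 1 Hz
        holds steady, and 10 Hz from the relaxed state potentiates again."""
        state = DeviceState.initial(device_params, 100.0)
        deltas = []
        for freq in (100.0, 10.0, 1.0, 10.0):
            period = 1000.0 / freq
            G_start = state.G
            for _ in range(10):
                state, _ = apply_pulse(state, 0.5, 5.0, device_params)
                state = relax(state, period - 5.0, device_params)
            deltas.append(state.G - G_start)
        tol = 0.05 * abs(deltas[0])
        assert deltas[0] > tol
        assert deltas[1] < -tol
        assert abs(deltas[2]) < tol
        assert deltas[3] > tol

    def test_overlapping_pulses_rejected(self, device_params):
        train = pulse_train(3, 0.5, 5.0, 5.0)
        state = DeviceState(G_long=100.0, t=50.0)  # clock already past onset
        with pytest.raises(ValueError):
            run_train(state, train, device_params)


class TestPPFRatio:
    def test_strictly_decreasing_in_interval(self, device_params):
        ratios = [device_ppf_ratio(device_params, iv) for iv in (1, 2, 5, 10, 20, 50, 100)]
        assert all(r > 0 for r in ratios)
        assert np.all(np.diff(ratios) < 0)


class TestPotentiationDepression:
    def test_monotone_and_bounded(self, device_params):
        ltp, ltd = potentiation_depression_curve(device_params, n=100)
        assert np.all(np.diff(ltp) >= 0)
        assert np.all(np.diff(ltd) <= 0)
        assert ltp[0] >= device_params.G_min
        assert ltp[-1] <= device_params.G_max


class TestNonlinearity:
    def test_linear_curve_has_zero_index(self):
        assert extract_nonlinearity(np.linspace(50, 350, 100)) == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize(
        "nl,start,end", [(3.00, 50.0, 350.0), (3.98, 350.0, 50.0)]
    )
    def test_round_trip_at_reference_values(self, nl, start, end):
        curve = nl_model(100, nl, start, end)
        assert extract_nonlinearity(curve) == pytest.approx(nl, abs=0.05)

    def test_non_monotone_rejected(self):
        curve = np.concatenate([np.linspace(50, 200, 30), np.linspace(200, 100, 30)])
        with pytest.raises(ValueError, match="monotone"):
            extract_nonlinearity(curve)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            extract_nonlinearity(np.linspace(0, 1, 5))


class TestCalibration:
    def test_anchor_currents_reproduced(self, device_params):
        for interval, target in ((5.0, 76.3), (15.0, 62.1)):
            peak = device._peak_epsc(device_params, interval)
            assert peak == pytest.approx(target, rel=1e-3)

    def test_peak_epsc_decreases_with_interval(self, device_params):
        peaks = [device._peak_epsc(device_params, iv) for iv in (5.0, 10.0, 15.0)]
        assert np.all(np.diff(peaks) < 0)


class TestInvariants:
    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        n=st.integers(min_value=1, max_value=40),
    )
    def test_conductance_never_leaves_window(self, seed, n, device_params):
        rng = np.random.default_rng(seed)
        state = DeviceState.initial(
            device_params, rng.uniform(device_params.G_min, device_params.G_max)
        )
        for _ in range(n):
            amp = rng.choice([-1.0, -0.5, 0.5, 1.0])
            width = rng.uniform(1.0, 10.0)
            state, _ = apply_pulse(state, amp, width, device_params)
            state = relax(state, rng.uniform(0.0, 100.0), device_params)
            assert device_params.G_min - 1e-9 <= state.G <= device_params.G_max + 1e-9

    def test_relaxation_offset_monotone(self):
        d = [relaxation_offset(g0, 20.0) for g0 in (100.0, 200.0, 300.0)]
        assert np.all(np.diff(d) > 0)
        d = [relaxation_offset(300.0, dt) for dt in (5.0, 20.0, 80.0)]
        assert np.all(np.diff(d) > 0)


class TestParamsValidation:
    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError, match="G_min"):
            DeviceParams(G_min=400.0, G_max=350.0)

    def test_bad_retain_frac_rejected(self):
        with pytest.raises(ValueError):
            DeviceParams(retain_frac=1.5)

    def test_initial_state_must_be_inside_window(self, device_params):
        with pytest.raises(ValueError):
            DeviceState.initial(device_params, 10.0)
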