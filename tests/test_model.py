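"""Balloon-model dynamics, observation and simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balloonassim import (DEFAULT_PARAMS, HemodynamicParams, HemodynamicState,
                          StimulusTrain, bold_observation,
                          hemodynamic_derivatives, integrate_balloon,
                          neural_input, oxygen_extraction, simulate_bold)

PARAM_STRATEGY = st.builds(
    HemodynamicParams,
    epsilon=st.floats(0.05, 2.0),
    tau_s=st.floats(0.5, 4.0),
    tau_f=st.floats(0.5, 4.0),
    tau_0=st.floats(0.3, 3.0),
    E0=st.floats(0.1, 0.8),
    alpha=st.floats(0.1, 0.5),
    V0=st.floats(0.01, 0.3),
)


class TestNeuralInput:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 0.0),    # before the first onset
        (10.0, 1.0),   # onset is included (half-open interval)
        (20.0, 1.0),
        (30.0, 0.0),   # offset is excluded
        (100.0, 0.0),
    ])
    def test_boxcar_half_open_convention(self, t, expected):
        stim = StimulusTrain(onsets=(10.0,), durations=(20.0,), amplitude=1.0)
        assert neural_input(stim, t) == expected

    def test_invalid_trains_rejected(self):
        with pytest.raises(ValueError):
            StimulusTrain(onsets=(10.0, 5.0), durations=(1.0, 1.0))
        with pytest.raises(ValueError):
            StimulusTrain(onsets=(0.0, 5.0), durations=(6.0, 1.0))  # overlap
        with pytest.raises(ValueError):
            StimulusTrain(onsets=(0.0,), durations=(-1.0,))


class TestOxygenExtraction:
    def test_resting_inflow_returns_e0(self):
        for e0 in (0.1, 0.34, 0.7):
            assert oxygen_extraction(1.0, e0) == pytest.approx(e0)

    def test_flow_limits_of_the_closed_form(self):
        # extraction falls toward 0 as inflow grows and rises toward 1 as
        # inflow vanishes
        assert oxygen_extraction(1e6, 0.4) == pytest.approx(0.0, abs=1e-5)
        assert oxygen_extraction(1e-3, 0.4) == pytest.approx(1.0, abs=1e-5)
        assert oxygen_extraction(2.0, 0.4) < 0.4 < oxygen_extraction(0.5, 0.4)

    def test_closed_form_value(self):
        # E(2, 0.4) = 1 - 0.6**(1/2), evaluated independently
        assert oxygen_extraction(2.0, 0.4) == pytest.approx(
            1.0 - math.sqrt(0.6), abs=1e-12)

    def test_nonpositive_inflow_rejected(self):
        with pytest.raises(ValueError):
            oxygen_extraction(0.0, 0.4)
        with pytest.raises(ValueError):
            oxygen_extraction(-1.0, 0.4)


class TestDerivatives:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(params=PARAM_STRATEGY)
    def test_resting_state_is_fixed_point(self, params):
        d = hemodynamic_derivatives(HemodynamicState.rest(), params, 0.0)
        assert np.all(d == 0.0)

    def test_input_only_drives_signal_at_rest(self):
        params = HemodynamicParams(epsilon=0.5)
        d = hemodynamic_derivatives((0.0, 1.0, 1.0, 1.0), params, 1.0)
        np.testing.assert_allclose(d, [0.5, 0.0, 0.0, 0.0])

    def test_off_rest_values_match_closed_form(self):
        # independent term-by-term evaluation of the four equations
        p = HemodynamicParams(epsilon=0.54, tau_s=1.54, tau_f=2.46,
                              tau_0=0.98, E0=0.34, alpha=0.2)
        s, f, v, q = 0.1, 1.2, 1.05, 0.95
        E = 1.0 - (1.0 - p.E0) ** (1.0 / f)
        fv = v ** (1.0 / p.alpha)
        expected = [
            -s / p.tau_s - (f - 1.0) / p.tau_f,
            s,
            (f - fv) / p.tau_0,
            (f * E / p.E0 - fv * q / v) / p.tau_0,
        ]
        got = hemodynamic_derivatives((s, f, v, q), p, 0.0)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            hemodynamic_derivatives((0.0, -1.0, 1.0, 1.0), DEFAULT_PARAMS, 0.0)


class TestBoldObservation:
    def test_resting_signal_is_zero(self):
        assert bold_observation(1.0, 1.0, 0.4, 0.1) == 0.0

    def test_term_by_term_value(self):
        expected = 0.02 * (2.8 * 0.1 + 2.0 * (1.0 - 0.9 / 1.1) + 0.6 * (-0.1))
        assert bold_observation(1.1, 0.9, 0.4, 0.02) == pytest.approx(
            expected, rel=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(v=st.floats(0.5, 2.0), q=st.floats(0.5, 2.0),
           e0=st.floats(0.1, 0.8), v0=st.floats(0.01, 0.4),
           c=st.floats(0.25, 2.0))
    def test_linear_in_v0_with_zero_rest_intercept(self, v, q, e0, v0, c):
        y1 = bold_observation(v, q, e0, v0)
        y2 = bold_observation(v, q, e0, min(c * v0, 0.99))
        scale = min(c * v0, 0.99) / v0
        assert y2 == pytest.approx(scale * y1, rel=1e-12, abs=1e-15)

    def test_custom_coefficients(self):
        y = bold_observation(1.1, 0.9, 0.4, 0.1, coefficients=(1.0, 0.0, 0.0))
        assert y == pytest.approx(0.1 * (1.0 - 0.9))


class TestIntegration:
    def test_zero_stimulus_stays_at_rest(self):
        stim = StimulusTrain(onsets=(), durations=(), sampling_dt=2.0)
        traj = integrate_balloon(DEFAULT_PARAMS, stim, (0.0, 30.0))
        np.testing.assert_allclose(traj.states,
                                   np.tile([0.0, 1.0, 1.0, 1.0],
                                           (traj.states.shape[0], 1)),
                                   atol=1e-14)

    def test_step_halving_convergence(self):
        stim = StimulusTrain(onsets=(10.0,), durations=(20.0,), amplitude=0.3,
                             sampling_dt=2.0)
        coarse = integrate_balloon(DEFAULT_PARAMS, stim, (0.0, 60.0),
                                   dt_internal=0.02)
        fine = integrate_balloon(DEFAULT_PARAMS, stim, (0.0, 60.0),
                                 dt_internal=0.002)
        finer = fine.states[::10]
        err_coarse = np.max(np.abs(coarse.states - finer))
        mid = integrate_balloon(DEFAULT_PARAMS, stim, (0.0, 60.0),
                                dt_internal=0.01)
        err_mid = np.max(np.abs(mid.states[::1] - fine.states[::5][:len(mid.states)]))
        assert err_coarse < 1e-5
        assert err_mid < err_coarse  # error decreases with the step

    def test_return_to_rest_after_offset(self):
        stim = StimulusTrain(onsets=(10.0,), durations=(20.0,), amplitude=0.3,
                             sampling_dt=2.0)
        traj = integrate_balloon(DEFAULT_PARAMS, stim, (0.0, 200.0))
        rest = np.array([0.0, 1.0, 1.0, 1.0])
        dist = np.linalg.norm(traj.states - rest, axis=1)
        i_offset = np.searchsorted(traj.times, 90.0)   # 60 s past offset
        assert dist[-1] < dist[i_offset]
        assert dist[-1] < 1e-3

    def test_epsilon_v0_tradeoff_first_order(self):
        """Peak BOLD under (eps, V0) vs (eps/c, c*V0) agrees within 10 %

        for small-amplitude stimuli — the operational form of the statement
        that only the product eps*V0 is identifiable.
        """
        stim = StimulusTrain(onsets=tuple(20.0 + 40.0 * k for k in range(5)),
                             durations=(20.0,) * 5, amplitude=0.05,
                             sampling_dt=2.0)
        times = 2.0 * np.arange(120)
        base = DEFAULT_PARAMS.with_v0(0.02)
        p0 = np.max(np.abs(simulate_bold(base, stim, times).bold_noiseless))
        for c in (0.5, 2.0, 5.0):
            from dataclasses import replace

            p = replace(base, epsilon=base.epsilon / c, V0=base.V0 * c)
            peak = np.max(np.abs(simulate_bold(p, stim, times).bold_noiseless))
            assert abs(peak - p0) / p0 < 0.10


class TestSimulateBold:
    def test_zero_noise_equals_noiseless(self, block_stimulus, sample_times):
        sim = simulate_bold(DEFAULT_PARAMS, block_stimulus, sample_times,
                            noise_sd=0.0, seed=3)
        np.testing.assert_array_equal(sim.bold_noisy, sim.bold_noiseless)

    def test_seed_determinism(self, block_stimulus, sample_times):
        a = simulate_bold(DEFAULT_PARAMS, block_stimulus, sample_times,
                          noise_sd=0.005, seed=11)
        b = simulate_bold(DEFAULT_PARAMS, block_stimulus, sample_times,
                          noise_sd=0.005, seed=11)
        np.testing.assert_array_equal(a.bold_noisy, b.bold_noisy)

    def test_noise_sd_calibration(self, block_stimulus, sample_times):
        resid = []
        for seed in range(10):
            sim = simulate_bold(DEFAULT_PARAMS, block_stimulus, sample_times,
                                noise_sd=0.005, seed=seed)
            resid.append(sim.bold_noisy - sim.bold_noiseless)
        sd = np.std(np.concatenate(resid))
        assert 0.004 < sd < 0.006
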