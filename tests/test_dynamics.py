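import warnings
from dataclasses import replace

import numpy as np
import pytest

from rivalnorm import (
    ModelParams,
    NetworkState,
    SimulationBlowupError,
    make_condition,
    simulate,
)
from rivalnorm.dynamics import (
    adaptation_rhs,
    drive_conventional,
    drive_opponency_model,
    normalization_rhs,
)
from rivalnorm import noise as noise_mod
from rivalnorm.params import MONO_NEURONS, OPP_NEURONS, SUM_NEURONS

from oracles import steady_state

ALL_CONDITIONS = (
    "dichoptic_gratings",
    "monocular_plaid",
    "binocular_plaid",
    "monocular_grating",
    "binocular_grating",
)


class TestDrives:
    def test_monocular_drive_is_contrast_plus_noise(self, params):
        state = NetworkState()
        e = drive_conventional(state, np.array([0.5, 0, 0, 0]), np.zeros(6), params)
        np.testing.assert_allclose(e[:4], [0.5, 0, 0, 0])

    def test_summation_drive_sums_iso_oriented_monocular_rates(self, params):
        state = NetworkState(r_mono=np.array([0.5, 0, 0.5, 0]))
        e = drive_conventional(state, np.zeros(4), np.zeros(6), params)
        np.testing.assert_allclose(e[4:], [1.0, 0.0])

    def test_all_zero_inputs_give_zero_drives(self, params):
        e = drive_conventional(NetworkState(), np.zeros(4), np.zeros(6), params)
        assert not e.any()

    def test_opponency_drive_is_interocular_difference(self, params):
        state = NetworkState(
            r_mono=np.array([0, 0, 0.6, 0.6]), r_opp=np.zeros(4)
        )
        e = drive_opponency_model(state, np.zeros(4), np.zeros(10), params)
        np.testing.assert_allclose(e[6:8], [0.6, 0.6])  # RL before rectification
        np.testing.assert_allclose(e[8:10], [-0.6, -0.6])  # LR

    def test_opponency_feedback_subtracts_both_orientations(self, params):
        state = NetworkState(
            r_mono=np.zeros(4), r_opp=np.array([0.2, 0.2, 0.0, 0.0])
        )
        e = drive_opponency_model(
            state, np.array([0.5, 0, 0, 0]), np.zeros(10), params
        )
        assert e[0] == pytest.approx(0.1)  # 0.5 - (0.2 + 0.2)
        assert e[1] == pytest.approx(-0.4)  # left-B also inhibited
        assert e[2] == pytest.approx(0.0)  # right eye untouched by RL

    def test_adaptation_subtracts_from_drive_when_enabled(self, params):
        p_on = replace(params, adapt_enabled=True)
        a = np.zeros(6)
        a[0] = 0.4
        state = NetworkState(a=a)
        e_off = drive_conventional(state, np.array([0.5, 0, 0, 0]), np.zeros(6), params)
        e_on = drive_conventional(state, np.array([0.5, 0, 0, 0]), np.zeros(6), p_on)
        assert e_off[0] == pytest.approx(0.5)
        assert e_on[0] == pytest.approx(0.5 - 0.5 * 0.4)


class TestRhs:
    def test_zero_drive_zero_rate_is_fixed_point(self):
        rhs = normalization_rhs(np.zeros(4), np.zeros(4), np.ones((4, 4)), 0.5, 50.0)
        assert not rhs.any()

    def test_single_neuron_closed_form_fixed_point(self):
        # E = 0.5, sigma = 0.5: R* = 0.25 / (0.25 + 0.25) = 0.5
        rhs = normalization_rhs(
            np.array([0.5]), np.array([0.5]), np.array([[1.0]]), 0.5, 50.0
        )
        assert rhs[0] == pytest.approx(0.0, abs=1e-15)

    def test_four_neuron_symmetric_fixed_point(self):
        # binocular plaid drives: R* = 0.25 / (0.25 + 4*0.25) = 0.2
        E = np.full(4, 0.5)
        rhs = normalization_rhs(E, np.full(4, 0.2), np.ones((4, 4)), 0.5, 50.0)
        np.testing.assert_allclose(rhs, 0.0, atol=1e-15)

    def test_halfwave_rectification_before_squaring(self):
        rhs_neg = normalization_rhs(
            np.array([-3.0]), np.array([0.0]), np.array([[1.0]]), 0.5, 50.0
        )
        assert rhs_neg[0] == 0.0

    def test_adaptation_first_order_lowpass(self):
        assert adaptation_rhs(0.3, 0.3, 80.0) == pytest.approx(0.0)
        assert adaptation_rhs(1.0, 0.0, 80.0) == pytest.approx(1 / 80)
        # closed-form response: a(t) = r0 (1 - exp(-t/tau)) solves the ODE
        r0, tau, t = 0.4, 80.0, 13.0
        a = r0 * (1 - np.exp(-t / tau))
        dadt = adaptation_rhs(r0, a, tau)
        assert dadt == pytest.approx(r0 / tau * np.exp(-t / tau))


class TestSimulate:
    def test_zero_contrast_zero_noise_stays_at_zero(self, quiet_params):
        stim = make_condition("monocular_grating", 0.0, 2.0)
        res = simulate("conventional", stim, quiet_params, dt_ms=2.0, seed=0)
        assert not res.to_frame().drop(columns="time_ms").to_numpy().any()

    @pytest.mark.parametrize("model", ["conventional", "opponency"])
    @pytest.mark.parametrize("condition", ALL_CONDITIONS)
    def test_noise_free_steady_states_match_fixed_point_oracle(
        self, model, condition, quiet_params
    ):
        stim = make_condition(condition, 0.5, 8.0)
        res = simulate(model, stim, quiet_params, dt_ms=2.0, seed=0)
        oracle = steady_state(model, stim.sample(np.zeros(1))[0], quiet_params)
        np.testing.assert_allclose(res.r_mono[-1], oracle["r_mono"], atol=1e-6)
        np.testing.assert_allclose(res.r_sum[-1], oracle["r_sum"], atol=1e-6)
        if model == "opponency":
            np.testing.assert_allclose(res.r_opp[-1], oracle["r_opp"], atol=1e-6)

    def test_binocular_plaid_fixed_point_values(self, quiet_params):
        # the symmetric closed form: monocular rates 0.2, opponency silent
        stim = make_condition("binocular_plaid", 0.5, 5.0)
        res = simulate("opponency", stim, quiet_params, dt_ms=2.0, seed=0)
        np.testing.assert_allclose(res.r_mono[-1], 0.2, atol=1e-4)
        np.testing.assert_allclose(res.r_opp[-1], 0.0, atol=1e-4)

    @pytest.mark.parametrize("condition", ["binocular_plaid", "binocular_grating"])
    def test_opponency_silent_for_binocular_stimuli(self, quiet_params, condition):
        stim = make_condition(condition, 0.5, 6.0)
        res = simulate("opponency", stim, quiet_params, dt_ms=2.0, seed=0)
        assert np.abs(res.r_opp).max() == 0.0

    @pytest.mark.parametrize("model", ["conventional", "opponency"])
    def test_rates_nonnegative_and_finite_with_noise(self, model, params):
        stim = make_condition("dichoptic_gratings", 0.5, 10.0)
        res = simulate(model, stim, params, dt_ms=2.0, seed=3)
        frame = res.to_frame().drop(columns="time_ms").to_numpy()
        assert np.isfinite(frame).all()
        assert (res.r_mono >= 0).all() and (res.r_sum >= 0).all()
        assert (res.r_opp >= 0).all()

    def test_same_seed_bit_identical(self, params):
        stim = make_condition("dichoptic_gratings", 0.5, 4.0)
        a = simulate("opponency", stim, params, dt_ms=2.0, seed=9)
        b = simulate("opponency", stim, params, dt_ms=2.0, seed=9)
        for k in a.traces:
            np.testing.assert_array_equal(a.traces[k], b.traces[k])

    def test_eye_orientation_exchange_permutes_traces_exactly(self, params):
        # swapping eyes and orientations maps the dichoptic stimulus onto
        # itself; permuting the noise channels the same way must permute
        # the response traces exactly.
        stim = make_condition("dichoptic_gratings", 0.5, 6.0)
        n_steps = int(round(stim.duration_s * 1000 / 2.0))
        nm = noise_mod.generate(n_steps, 2.0, 10, replace(params.noise, seed=5))
        chan_perm = [3, 2, 1, 0, 5, 4, 9, 8, 7, 6]
        a = simulate("opponency", stim, params, dt_ms=2.0, seed=5, noise_matrix=nm)
        b = simulate(
            "opponency", stim, params, dt_ms=2.0, seed=5, noise_matrix=nm[chan_perm]
        )
        names = list(MONO_NEURONS) + list(SUM_NEURONS) + list(OPP_NEURONS)
        for i, j in enumerate(chan_perm):
            # equal to rounding error: the permuted normalization pool sums
            # the same four terms in a different order
            np.testing.assert_allclose(
                a.traces[names[j]], b.traces[names[i]], rtol=0, atol=1e-12
            )

    def test_nonstandard_dt_warns(self, quiet_params):
        stim = make_condition("binocular_plaid", 0.5, 1.0)
        with pytest.warns(UserWarning, match="standard steps"):
            simulate("conventional", stim, quiet_params, dt_ms=5.0, seed=0)

    def test_blowup_raises_with_step_diagnostic(self, params):
        stim = make_condition("binocular_plaid", 0.5, 100.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(SimulationBlowupError, match="step"):
                simulate("conventional", stim, params, dt_ms=200.0, seed=1)

    def test_adaptation_traces_recorded_and_track_rates(self, adapt_params):
        stim = make_condition("binocular_grating", 0.5, 20.0)
        res = simulate("opponency", stim, adapt_params, dt_ms=10.0, seed=2)
        assert "adapt_sum_A" in res.traces
        a = res.traces["adapt_sum_A"]
        assert a[0] < a[-1]  # adaptation accumulates under sustained drive
        assert (a >= 0).all()
        # adaptation lags far behind the rate (tau_a = 80 s >> 20 s)
        assert a[-1] < res.traces["sum_A"][-1]
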