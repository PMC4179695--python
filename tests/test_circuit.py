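"""Circuit dynamics: WM, spectral timing, PPTN, DA cell, three-factor rules."""

import math

import numpy as np
import pytest

from dacircuit import ModelParameters, TimingConfig, TrialType, run_session
from dacircuit.circuit import (
    CircuitIntegrationError,
    CircuitState,
    da_step,
    learn_excitatory,
    learn_inhibitory,
    pptn_step,
    run_trial,
    run_trial_reference,
    timing_activation,
    timing_peaks,
    timing_table,
    vs_step,
    wm_gate,
    wm_step,
)
from dacircuit.task import build_schedule, trial_timeline

DT = 0.001


class TestWorkingMemory:
    def test_fixed_point_under_sustained_input(self, params):
        """With the stimulus held on, x converges to M_x / (1 + A_x)."""
        x = 0.0
        for _ in range(2000):
            x = wm_step(x, 1.0, params, DT)
        assert x == pytest.approx(params.m_x / (1 + params.a_x), abs=1e-4)

    def test_decay_matches_closed_form(self, params):
        """With the stimulus off, x decays as exp(-tau_x * A_x * t)."""
        x0 = 0.98
        x = x0
        for _ in range(1000):  # 1 s
            x = wm_step(x, 0.0, params, DT)
        expected = x0 * math.exp(-params.tau_x * params.a_x * 1.0)
        assert x == pytest.approx(expected, rel=1e-3)
        assert 0.5 < x < 0.6  # partial decay over a 1 s gap

    def test_zero_state_is_absorbing_without_input(self, params):
        assert wm_step(0.0, 0.0, params, DT) == 0.0

    def test_bounds_under_arbitrary_square_waves(self, params):
        rng = np.random.default_rng(0)
        x = 0.0
        for on in rng.integers(0, 2, size=5000):
            x = wm_step(x, float(on), params, DT)
            assert 0.0 <= x <= params.m_x

    def test_gate_threshold_is_strict(self, params):
        assert wm_gate(0.31, params) == 1
        assert wm_gate(0.30, params) == 0

    def test_gate_latency_matches_inverted_rise(self, params):
        """Gate opens when the closed-form rise crosses theta_x (~12 ms)."""
        lam = params.tau_x * (1 + params.a_x)
        ceiling = params.m_x / (1 + params.a_x)
        expected = -math.log(1 - params.theta_x / ceiling) / lam
        x, steps = 0.0, 0
        while wm_gate(x, params) == 0:
            x = wm_step(x, 1.0, params, DT)
            steps += 1
        assert steps * DT == pytest.approx(expected, abs=2 * DT)
        assert 0.005 < steps * DT < 0.020

    def test_rejects_nonpositive_dt(self, params):
        with pytest.raises(ValueError):
            wm_step(0.0, 1.0, params, 0.0)


class TestSpectralTiming:
    def test_unit_peak_at_each_cell_delay(self, params):
        peaks = timing_peaks(params)
        for j in (0, params.n_timing // 2, params.n_timing - 1):
            f = timing_activation(peaks[j], params)
            assert f[j] == pytest.approx(1.0)
            assert f.max() == pytest.approx(1.0)

    def test_silent_before_gate_crossing(self, params):
        assert not timing_activation(None, params).any()

    def test_kernels_tile_interval_without_gaps(self, params):
        """Some cell is active at every delay in the spanned interval."""
        for elapsed in np.arange(params.t_first, params.t_last, 0.005):
            assert timing_activation(elapsed, params).sum() > 0.01

    def test_table_matches_direct_evaluation(self, params):
        table = timing_table(params, DT)
        for k in (0, 500, 1500, table.shape[1] - 1):
            np.testing.assert_allclose(
                table[:, k], timing_activation(k * DT, params), atol=1e-12
            )


class TestPPTN:
    def _pulse_response(self, params, duration=0.5, total=1.5):
        p, hab, out = 0.0, 1.0, []
        for t in range(int(total / DT)):
            reward = 1.0 if t * DT < duration else 0.0
            p, hab, pp = pptn_step(p, hab, 0.0, reward, params, DT)
            out.append(pp)
        return np.array(out)

    def test_silent_without_drive(self, params):
        p, hab = 0.0, 1.0
        for _ in range(100):
            p, hab, out = pptn_step(p, hab, 0.0, 0.0, params, DT)
        assert out == 0.0

    def test_integrated_response_linear_in_drive_weight(self, params):
        """Doubling w_RP doubles the integrated response to a reward pulse."""
        base = self._pulse_response(params).sum()
        doubled = self._pulse_response(
            ModelParameters(w_rp=2 * params.w_rp)
        ).sum()
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_sustained_input_gives_phasic_onset(self, params):
        out = self._pulse_response(params, duration=1.0, total=1.0)
        peak_t = out.argmax() * DT
        assert peak_t < 0.2                  # fast onset peak
        assert out[-1] < 0.6 * out.max()     # declines toward a lower plateau
        assert out[-1] > 0.0


class TestDACell:
    def test_baseline_at_rest(self, params):
        d = 0.0
        for _ in range(500):
            d, da = da_step(d, 0.0, 0.0, params, DT)
        assert da.rate == pytest.approx(params.baseline_rate)
        assert da.n_plus == 0.0 and da.n_minus == 0.0

    def test_dip_saturates_at_zero_floor(self, params):
        """Strong inhibition drives the rate to 0; the dip maxes at baseline."""
        d = 0.0
        for _ in range(500):
            d, da = da_step(d, 0.0, 10.0, params, DT)
        assert da.rate == 0.0
        assert da.n_minus == pytest.approx(params.baseline_rate)

    def test_burst_and_dip_are_mutually_exclusive(self, params):
        d = 0.0
        rng = np.random.default_rng(1)
        for _ in range(300):
            d, da = da_step(d, rng.uniform(0, 1), rng.uniform(0, 0.3),
                            params, DT)
            assert da.n_plus * da.n_minus == 0.0
            assert da.rate >= 0.0


class TestVentralStriatum:
    def test_decay_to_zero_without_drive(self, params):
        s = np.array([1.0, 0.5])
        for _ in range(2000):
            s, out = vs_step(s, np.zeros(2), np.zeros(2), 0.0, params, DT)
        assert np.allclose(s, 0.0, atol=1e-6)
        assert out == 0.0

    def test_output_threshold_suppresses_weak_drive(self, params):
        s = np.array([params.gamma_g - 0.01, 0.0])
        _, out = vs_step(s, np.zeros(2), np.zeros(2), 0.0, params, DT)
        assert out == 0.0


class TestLearningRules:
    def test_no_reinforcement_no_excitatory_change(self, params):
        w = np.array([0.3, 0.1])
        out = learn_excitatory(w, np.ones(2), np.array([2.0, 2.0]),
                               0.0, 0.0, params, DT)
        np.testing.assert_array_equal(out, w)

    def test_subthreshold_postsynaptic_blocks_learning(self, params):
        w = np.zeros(2)
        s = np.full(2, params.theta_s - 0.01)
        out = learn_excitatory(w, np.ones(2), s, 50.0, 0.0, params, DT)
        np.testing.assert_array_equal(out, w)

    def test_subthreshold_presynaptic_blocks_learning(self, params):
        w = np.zeros(2)
        x = np.full(2, params.theta_pre - 0.01)
        out = learn_excitatory(w, x, np.array([2.0, 2.0]), 50.0, 0.0,
                               params, DT)
        np.testing.assert_array_equal(out, w)

    def test_repeated_pairing_saturates_at_ceiling(self, params):
        """Bursts drive the weight monotonically toward w_max, never past."""
        w = np.zeros(2)
        previous = w.copy()
        for _ in range(20000):
            w = learn_excitatory(w, np.full(2, 0.9), np.array([1.5, 1.5]),
                                 30.0, 0.0, params, DT)
            assert (w >= previous).all()
            assert (w <= params.w_max_s).all()
            previous = w.copy()
        assert w[0] == pytest.approx(params.w_max_s, abs=1e-3)

    def test_inhibitory_requires_eligibility_and_reinforcement(self, params):
        z = np.full(params.n_timing, 0.1)
        f = np.zeros(params.n_timing)
        np.testing.assert_array_equal(
            learn_inhibitory(z, f, 30.0, 0.0, params, DT), z
        )
        f = timing_activation(1.0, params)
        np.testing.assert_array_equal(
            learn_inhibitory(z, f, 0.0, 0.0, params, DT), z
        )

    def test_inhibitory_bounded_by_ceiling(self, params):
        z = np.zeros(params.n_timing)
        f = timing_activation(1.0, params)
        for _ in range(20000):
            z = learn_inhibitory(z, f, 500.0, 0.0, params, DT)
        assert (z <= params.z_max + 1e-12).all()
        assert z.max() == pytest.approx(params.z_max, abs=1e-4)


class TestIntegration:
    def test_kernel_matches_reference_integrator(self, params, timing):
        """Compiled kernel and the op-composed pure-Python route agree."""
        tl = trial_timeline(TrialType.UR, timing, r_amp=params.r_amp)
        fast, slow = CircuitState.fresh(params), CircuitState.fresh(params)
        trace, _ = run_trial(fast, tl, params)
        rates_ref = run_trial_reference(slow, tl, params)
        from dacircuit.analysis import bin_rates
        np.testing.assert_allclose(
            trace.rates, bin_rates(rates_ref, timing.dt, 0.02), atol=1e-9
        )
        np.testing.assert_allclose(fast.w_s, slow.w_s, atol=1e-9)
        np.testing.assert_allclose(fast.z, slow.z, atol=1e-9)

    def test_zero_input_timeline_stays_at_baseline(self, params, timing):
        tl = trial_timeline(TrialType.PNR, timing)
        tl.i_lemon[:] = 0.0
        state = CircuitState.fresh(params)
        trace, _ = run_trial(state, tl, params)
        np.testing.assert_allclose(
            trace.rates, params.baseline_rate * 0.02, atol=1e-9
        )

    def test_untrained_ur_trial_reward_burst_only(self, params, timing):
        """Before learning: no DA response at S1, a strong burst at REW."""
        state = CircuitState.fresh(params)
        trace, _ = run_trial(
            state, trial_timeline(TrialType.UR, timing, params.r_amp), params
        )
        base = params.baseline_rate * 0.02
        s1 = trace.window_mean((timing.s1_onset, timing.s1_onset + 0.3))
        rew = trace.window_mean((timing.reward_onset, timing.reward_onset + 0.3))
        assert abs(s1 - base) < 0.005
        assert rew > 2 * base

    def test_session_determinism(self, params, timing):
        schedule = build_schedule({"PR": 6, "PNR": 6, "UR": 3, "UNR": 3}, seed=5)
        a = run_session(params, schedule, timing)
        b = run_session(params, schedule, timing)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.rates, tb.rates)
        np.testing.assert_array_equal(a.final_state.w_s, b.final_state.w_s)

    def test_empty_schedule_gives_empty_result(self, params, timing):
        schedule = build_schedule({"PR": 0, "PNR": 0, "UR": 0, "UNR": 0})
        result = run_session(params, schedule, timing)
        assert result.traces == []

    def test_three_factor_gating_blocks_all_plasticity(self, timing):
        """With the phasic DA signal silenced, no weight changes at all."""
        silent = ModelParameters(da_gain=0.0)
        schedule = build_schedule({"PR": 4, "PNR": 2, "UR": 2, "UNR": 2}, seed=0)
        result = run_session(silent, schedule, timing)
        assert not result.final_state.w_s.any()
        assert not result.final_state.z.any()

    def test_weight_bounds_throughout_session(self, params, baseline_session):
        state = baseline_session.final_state
        assert (state.w_s >= 0).all() and (state.w_s <= params.w_max_s).all()
        assert (state.z >= 0).all() and (state.z <= params.z_max).all()

    def test_opponency_cancels_predicted_reward(self, params, timing):
        """Training on fully predicted reward shrinks the reward burst."""
        schedule = build_schedule({"PR": 60, "PNR": 0, "UR": 0, "UNR": 0},
                                  seed=0, shuffle=False)
        result = run_session(params, schedule, timing)
        rew = (timing.reward_onset, timing.reward_onset + 0.3)
        first = result.traces[0].window_mean(rew)
        last = result.traces[-1].window_mean(rew)
        assert last < first

    def test_floor_asymmetry_in_session(self, params, baseline_session):
        """Attainable dip is bounded by the low baseline; bursts are not."""
        base = params.baseline_rate * 0.02
        lo = min(t.rates.min() for t in baseline_session.traces)
        hi = max(t.rates.max() for t in baseline_session.traces)
        assert lo >= 0.0
        assert base - lo <= base + 1e-12
        assert hi - base > base  # excitatory range exceeds inhibitory range

    def test_euler_convergence_on_halved_step(self, params, baseline_session):
        """Halving dt changes the S2 difference output by less than 1%."""
        from dacircuit.analysis import s2_output
        fine = run_session(params, baseline_session.schedule,
                           TimingConfig(dt=0.0005))
        coarse = s2_output(baseline_session)
        assert abs(s2_output(fine) - coarse) / abs(coarse) < 0.01

    def test_nonfinite_state_aborts_with_subsystem(self, timing):
        unstable = ModelParameters(lambda_d=1e9)
        schedule = build_schedule({"PR": 1, "PNR": 0, "UR": 0, "UNR": 0})
        with pytest.raises(CircuitIntegrationError, match="DA cell"):
            run_session(unstable, schedule, timing)
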