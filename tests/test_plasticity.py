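"""Objective shape, gradient identities, eligibility paths, shrinkage."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from convallis.plasticity import (
    ObjectiveParams,
    PlasticityParams,
    PlasticityState,
    accumulate_eligibility_direct,
    accumulate_eligibility_fast,
    apply_weight_updates,
    decompose_gprime,
    epsp_kernel,
    gprime,
    objective_g,
    shrink,
    update_mean_conductance,
)

OBJ = ObjectiveParams()
PAR = PlasticityParams()


class TestObjective:
    def test_valley_shape(self):
        # intermediate depolarization scores below both rest-side and
        # threshold-side voltages
        assert objective_g(-53.5, OBJ) < objective_g(-60.0, OBJ)
        assert objective_g(-53.5, OBJ) < objective_g(-50.0, OBJ)

    def test_threshold_side_rewarded_more_than_rest_side(self):
        assert objective_g(-50.0, OBJ) > objective_g(-60.0, OBJ)

    def test_continuous_and_bounded_on_physiological_range(self):
        v = np.linspace(-80, 20, 5001)
        g = objective_g(v, OBJ)
        assert np.all(np.isfinite(g))
        assert np.max(np.abs(np.diff(g))) < 0.1  # no jumps on a 0.02 mV grid

    def test_gprime_signs(self):
        assert gprime(-51.0, OBJ) > 0  # near-threshold: potentiation drive
        assert gprime(-56.0, OBJ) < 0  # intermediate: depression drive

    def test_gprime_is_analytic_derivative(self):
        v = np.linspace(-75, -40, 100)
        h = 1e-5
        numeric = (objective_g(v + h, OBJ) - objective_g(v - h, OBJ)) / (2 * h)
        np.testing.assert_allclose(gprime(v, OBJ), numeric, rtol=1e-6)

    def test_rest_drive_small_relative_to_threshold_drive(self):
        assert abs(gprime(-75.0, OBJ)) < 0.05 * abs(gprime(-51.0, OBJ))


class TestDecomposition:
    def test_identity_and_nonnegativity(self):
        phi_p, phi_m = decompose_gprime(OBJ)
        v = np.linspace(-80, 0, 1000)
        assert np.all(phi_p(v) >= 0)
        assert np.all(phi_m(v) >= 0)
        assert np.max(np.abs(phi_p(v) - phi_m(v) - gprime(v, OBJ))) < 1e-12

    def test_monotone_with_lower_ltd_half_activation(self):
        phi_p, phi_m = decompose_gprime(OBJ)
        v = np.linspace(-80, 0, 2000)
        assert np.all(np.diff(phi_p(v)) >= 0)
        assert np.all(np.diff(phi_m(v)) >= 0)
        # half-activation: phi_minus crosses half its max at a lower voltage
        half_p = v[np.searchsorted(phi_p(v), 0.5 * phi_p(v[-1]))]
        half_m = v[np.searchsorted(phi_m(v), 0.5 * phi_m(v[-1]))]
        assert half_m < half_p

    def test_vanishes_far_below_rest(self):
        phi_p, phi_m = decompose_gprime(OBJ)
        assert phi_p(-80.0) < 1e-6
        assert phi_m(-80.0) < 1e-2


class TestEpspKernel:
    def test_causality(self):
        assert epsp_kernel(-1.0, 5.0, 10.0) == 0.0

    def test_peak_location_and_height(self):
        tau_s, tau_e = 5.0, 10.0
        t_star = math.log(tau_e / tau_s) / (1 / tau_s - 1 / tau_e)
        assert epsp_kernel(t_star, tau_s, tau_e) == pytest.approx(1.0, rel=1e-12)
        t = np.linspace(0, 100, 10001)
        assert np.max(epsp_kernel(t, tau_s, tau_e)) <= 1.0 + 1e-12

    def test_integral_matches_quadrature(self):
        tau_s, tau_e = 5.0, 8.0
        slow, fast = max(tau_s, tau_e), min(tau_s, tau_e)
        t_peak = (slow * fast / (slow - fast)) * math.log(slow / fast)
        norm = math.exp(-t_peak / slow) - math.exp(-t_peak / fast)
        closed = (slow - fast) / norm
        numeric, _ = quad(lambda u: epsp_kernel(u, tau_s, tau_e), 0, 500)
        assert numeric == pytest.approx(closed, rel=1e-6)

    def test_alpha_limit_for_equal_constants(self):
        t = np.array([0.0, 5.0, 10.0])
        k = epsp_kernel(t, 5.0, 5.0)
        assert k[1] == pytest.approx(1.0, rel=1e-9)  # peak at tau
        assert k[0] == 0.0
        assert 0 < k[2] < 1


class TestMeanConductance:
    def _state(self):
        return PlasticityState.zeros(1, 1, membrane_time_constant=10.0)

    def test_zero_conductance_gives_membrane_tau(self):
        st = self._state()
        update_mean_conductance(st, np.zeros(1000), dt=0.1, averaging_time=100.0)
        assert st.effective_time_constant[0] == pytest.approx(10.0)

    def test_conductance_equal_to_leak_halves_tau(self):
        st = self._state()
        # long trace so the running average converges to g_L
        update_mean_conductance(
            st, np.full(200_000, 20.0), dt=0.1, averaging_time=100.0
        )
        assert st.effective_time_constant[0] == pytest.approx(5.0, rel=1e-3)

    def test_step_reaches_63_percent_after_one_averaging_time(self):
        st = self._state()
        n = 1000  # exactly one averaging_time at dt=0.1
        update_mean_conductance(st, np.full(n, 10.0), dt=0.1, averaging_time=100.0)
        assert st.mean_total_conductance[0] == pytest.approx(
            10.0 * (1 - math.exp(-1)), rel=1e-3
        )

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            update_mean_conductance(self._state(), np.array([-1.0]), 0.1, 10.0)


class TestEligibility:
    def test_no_spikes_zero(self, noisy_voltage_trace):
        P = accumulate_eligibility_direct(
            noisy_voltage_trace, [np.array([])], [0.0], OBJ, PAR, tau_eff=8.0
        )
        assert P[0] == 0.0

    def test_identical_synapses_identical_eligibility(self, noisy_voltage_trace):
        arr = np.array([100.0, 400.0, 900.0])
        P = accumulate_eligibility_fast(
            noisy_voltage_trace, [arr, arr.copy()], [0.0, 0.0], OBJ, PAR,
            tau_eff=8.0,
        )
        assert P[0] == P[1]

    def test_clamped_voltage_matches_geometric_closed_form(self):
        # V clamped at a constant: the double integral factorizes; compare
        # against an independently derived geometric-series evaluation
        dt, N = 0.1, 10_000
        v_clamp = -56.0
        V = np.full(N, v_clamp)
        arrivals = np.array([200.0, 350.0])
        tau_eff, tau_syn = 8.0, 5.0
        tau_p = PAR.eligibility_time_constant
        g0 = float(gprime(v_clamp, OBJ))

        slow, fast = max(tau_syn, tau_eff), min(tau_syn, tau_eff)
        t_peak = (slow * fast / (slow - fast)) * math.log(slow / fast)
        inv_norm = 1.0 / (math.exp(-t_peak / slow) - math.exp(-t_peak / fast))

        def geom(a_step, tau):
            # sum_{k>=a} e^{-(N-1-k)dt/tau_p} e^{-(k-a)dt/tau} dt
            n = N - a_step
            r = math.exp(dt / tau_p - dt / tau)
            lead = math.exp(-(N - 1 - a_step) * dt / tau_p)
            if abs(r - 1) < 1e-15:
                return lead * n * dt
            return lead * dt * (r**n - 1) / (r - 1)

        expected = 0.0
        for a in arrivals:
            a_step = int(round(a / dt))
            expected += inv_norm * (geom(a_step, slow) - geom(a_step, fast))
        expected *= PAR.eligibility_scale * g0 * (0.0 - (-75.0))

        P = accumulate_eligibility_direct(
            V, [arrivals], [0.0], OBJ, PAR, tau_eff=tau_eff, tau_syn=tau_syn,
            v_rest=-75.0, dt=dt,
        )
        assert P[0] == pytest.approx(expected, rel=1e-6)

    def test_fast_path_equals_direct_path(self, rng):
        # the module's central correctness property, on randomized instances
        for trial in range(10):
            n = 20_000
            v = -70 + 8 * np.sin(np.arange(n) * 0.002 * (trial + 1)) \
                + rng.normal(0, 1.5, n).cumsum() * 0.01
            v = np.clip(v, -80, -45)
            arrivals = [
                np.sort(rng.uniform(0, (n - 1) * 0.1, size=rng.integers(1, 40)))
                for _ in range(10)
            ]
            te = rng.uniform(3.0, 15.0)
            Pd = accumulate_eligibility_direct(
                v, arrivals, np.zeros(10), OBJ, PAR, tau_eff=te
            )
            Pf = accumulate_eligibility_fast(
                v, arrivals, np.zeros(10), OBJ, PAR, tau_eff=te
            )
            np.testing.assert_allclose(Pf, Pd, rtol=1e-6, atol=1e-12)

    def test_time_shift_invariance(self, rng):
        # shifting spikes and voltage by a common offset leaves P unchanged
        n = 30_000
        base = np.full(n, -75.0)
        window = -75 + 20 * np.exp(-((np.arange(4000) - 2000) ** 2) / 4e5)
        arr = np.array([180.0, 240.0])
        Ps = []
        for off_steps in (5000, 15000):
            v = base.copy()
            v[off_steps:off_steps + 4000] = window
            shifted = [arr + off_steps * 0.1]
            # measure relative to a long tail so the tau_p envelope matters
            # equally: compensate by the analytic decay factor
            P = accumulate_eligibility_direct(
                v, shifted, [0.0], OBJ, PAR, tau_eff=8.0
            )
            comp = math.exp((n - 1 - off_steps) * 0.1
                            / PAR.eligibility_time_constant)
            Ps.append(P[0] * comp)
        assert Ps[0] == pytest.approx(Ps[1], rel=1e-6)

    def test_arrival_outside_trace_rejected(self, noisy_voltage_trace):
        with pytest.raises(ValueError):
            accumulate_eligibility_fast(
                noisy_voltage_trace, [np.array([1e6])], [0.0], OBJ, PAR, 8.0
            )


class TestShrinkage:
    def test_dead_zone(self):
        assert shrink(0.0) == 0.0
        assert shrink(49.0) == 0.0
        assert shrink(-9.0) == 0.0

    def test_soft_threshold_outside(self):
        assert shrink(60.0) == pytest.approx(10.0)
        assert shrink(-20.0) == pytest.approx(-10.0)

    def test_monotone_continuous_lipschitz(self):
        p = np.linspace(-200, 200, 20001)
        o = shrink(p)
        d = np.diff(o) / np.diff(p)
        assert np.all(d >= -1e-12)
        assert np.all(d <= 1.0 + 1e-12)


class TestWeightUpdates:
    def test_zero_gate_no_change(self):
        w = np.array([1.0, 2.0])
        out = apply_weight_updates(w, np.array([500.0, -500.0]), PAR, gate=0.0)
        np.testing.assert_array_equal(out, w)

    def test_dead_zone_no_change(self):
        w = np.array([1.0, 2.0])
        out = apply_weight_updates(w, np.array([30.0, -5.0]), PAR, gate=1.0)
        np.testing.assert_array_equal(out, w)

    def test_clipped_at_bounds(self):
        par = PAR.replace(learning_rate=1.0)
        out = apply_weight_updates(
            np.array([9.5]), np.array([1000.0]), par, gate=1.0
        )
        assert out[0] == par.weight_max
        out = apply_weight_updates(
            np.array([0.5]), np.array([-1000.0]), par, gate=1.0
        )
        assert out[0] == par.weight_min

    def test_non_plastic_untouched(self):
        par = PAR.replace(learning_rate=1.0)
        w = np.array([1.0, 1.0])
        out = apply_weight_updates(
            w, np.array([100.0, 100.0]), par, gate=1.0,
            plastic=np.array([True, False]),
        )
        assert out[0] > 1.0
        assert out[1] == 1.0
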