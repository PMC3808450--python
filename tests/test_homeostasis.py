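"""Rate estimation, PI controller, plasticity gate, closed-loop behaviour."""

import math

import numpy as np
import pytest

from convallis.core_sim import Network, SynapseGroup, poisson_spike_trains
from convallis.homeostasis import (
    RateControllerState,
    controller_step,
    plasticity_gate,
    update_rate_estimate,
)
from convallis.training import PatternTrainer, make_rule


class TestRateEstimate:
    def test_silent_neuron_decays_to_zero(self):
        st = RateControllerState(target_rate=10.0, rate_estimate=20.0)
        for _ in range(100):
            update_rate_estimate(st, 0, 1000.0)
        assert st.rate_estimate < 20.0 * math.exp(-9.9)

    def test_steady_train_converges_to_true_rate(self):
        st = RateControllerState(target_rate=5.0)
        for _ in range(200):  # 200 s of steady 10 Hz
            update_rate_estimate(st, 10, 1000.0)
        assert st.rate_estimate == pytest.approx(10.0, rel=1e-6)

    def test_first_order_step_response(self):
        st = RateControllerState(target_rate=5.0)
        for _ in range(10):  # one time constant (10 s)
            update_rate_estimate(st, 10, 1000.0)
        assert st.rate_estimate == pytest.approx(10.0 * (1 - math.exp(-1)), rel=1e-6)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            update_rate_estimate(RateControllerState(target_rate=1.0), 1, 0.0)


class TestController:
    def test_neutral_point(self):
        st = RateControllerState(target_rate=10.0, rate_estimate=10.0)
        mult, _ = controller_step(st, 1000.0)
        assert mult == pytest.approx(1.0)

    def test_sustained_overshoot_scales_down(self):
        st = RateControllerState(target_rate=10.0, rate_estimate=15.0)
        prod = 1.0
        for _ in range(20):
            m, _ = controller_step(st, 1000.0)
            prod *= m
        assert prod < 1.0

    def test_multiplier_floored_positive(self):
        st = RateControllerState(target_rate=1.0, rate_estimate=1e4)
        m, _ = controller_step(st, 1000.0)
        assert m == st.min_multiplier > 0

    def test_integral_anti_windup_clamp(self):
        st = RateControllerState(target_rate=10.0, rate_estimate=30.0)
        for _ in range(10_000):
            controller_step(st, 1000.0)
        assert abs(st.integral) <= st.integral_clamp_factor * st.gate_width_I + 1e-9


class TestGate:
    def test_open_at_equilibrium(self):
        st = RateControllerState(target_rate=10.0, rate_estimate=10.0)
        assert plasticity_gate(st) == pytest.approx(1.0)

    def test_gaussian_tail(self):
        st = RateControllerState(target_rate=10.0)
        st.rate_estimate = st.target_rate + 3 * st.gate_width_e
        assert plasticity_gate(st) < 0.02

    def test_even_symmetry(self):
        a = RateControllerState(target_rate=10.0)
        b = RateControllerState(target_rate=10.0)
        a.rate_estimate, a.integral = 12.0, 5.0
        b.rate_estimate, b.integral = 8.0, -5.0
        assert plasticity_gate(a) == pytest.approx(plasticity_gate(b))

    def test_strictly_decreasing_in_error_magnitude(self):
        gs = []
        for e in (0.0, 1.0, 2.0, 4.0):
            st = RateControllerState(target_rate=10.0)
            st.rate_estimate = 10.0 + e
            gs.append(plasticity_gate(st))
        assert all(x > y for x, y in zip(gs, gs[1:]))


def _poisson_driven_trainer(target, seed=0, n_inputs=200, in_rate=8.0, w0=0.8):
    rng = np.random.default_rng(seed)
    net = Network(n_neurons=1, n_inputs=n_inputs)
    net.add_group(SynapseGroup(
        source_ids=np.arange(n_inputs), target_ids=np.zeros(n_inputs),
        weights=np.full(n_inputs, w0), delays=rng.uniform(0.1, 5.0, n_inputs),
        reversal_class="excitatory", plastic=True, source_kind="input",
    ))
    trainer = PatternTrainer(
        net, make_rule("rate-only"), target_rate=target,
        controller_kw={"rate_estimate": target}, seed=seed,
    )
    return net, trainer, rng


class TestClosedLoop:
    @pytest.mark.parametrize("target", [1.5, 10.0])
    def test_rate_converges_to_target(self, target):
        net, trainer, rng = _poisson_driven_trainer(target)
        rates = []
        for k in range(200):
            stim = poisson_spike_trains(
                np.full((net.n_inputs, 1), 8.0), 1000.0, seed=rng
            )
            res = trainer.run_pattern(stim, 1000.0)
            rates.append(res.spike_counts[0])
        assert np.mean(rates[-100:]) == pytest.approx(target, rel=0.10)

    def test_weights_never_negative(self):
        net, trainer, rng = _poisson_driven_trainer(10.0, w0=3.0)
        for _ in range(50):
            stim = poisson_spike_trains(
                np.full((net.n_inputs, 1), 8.0), 1000.0, seed=rng
            )
            trainer.run_pattern(stim, 1000.0)
            assert np.all(trainer.weights() >= 0.0)

    def test_gating_suppresses_plasticity_during_perturbation(self):
        # force a large rate error; cumulative |dw| from the voltage rule must
        # collapse relative to the ungated run
        totals = {}
        for gating in (True, False):
            rng = np.random.default_rng(3)
            net = Network(n_neurons=1, n_inputs=100)
            net.add_group(SynapseGroup(
                source_ids=np.arange(100), target_ids=np.zeros(100),
                weights=np.full(100, 1.2), delays=rng.uniform(0.1, 5.0, 100),
                reversal_class="excitatory", plastic=True, source_kind="input",
            ))
            rule = make_rule("convallis", freeze_accumulation_when_gated=False)
            # target far below the driven rate -> a persistent rate error
            trainer = PatternTrainer(
                net, rule, target_rate=5.0, gating=gating,
                controller_kw={"rate_estimate": 40.0, "scaling_gain": 0.0},
                seed=3,
            )
            total = 0.0
            for _ in range(10):
                w0 = trainer.weights().copy()
                stim = poisson_spike_trains(
                    np.full((100, 1), 15.0), 1000.0, seed=rng
                )
                trainer.run_pattern(stim, 1000.0)
                total += np.abs(trainer.weights() - w0).sum()
            totals[gating] = total
        assert totals[False] > 0
        assert totals[True] < 0.10 * totals[False]
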