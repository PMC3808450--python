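"""Integration scheme, spike shape, delays, and Poisson input generation."""

import math

import numpy as np
import pytest

from convallis.core_sim import (
    NeuronParams,
    SimState,
    SpikeTrainSet,
    SynapseGroup,
    poisson_spike_trains,
    run_chunk,
    simulate,
)
from conftest import single_neuron_net


class TestNeuronParams:
    def test_voltage_ordering_enforced(self):
        with pytest.raises(ValueError):
            NeuronParams(rest_potential=-50.0, reset_potential=-55.0)

    @pytest.mark.parametrize("field", [
        "membrane_time_constant", "refractory_period", "exc_syn_time_constant",
    ])
    def test_positive_time_constants(self, field):
        with pytest.raises(ValueError):
            NeuronParams(**{field: 0.0})

    def test_capacitance(self):
        p = NeuronParams(membrane_time_constant=10.0, leak_conductance=20.0)
        assert p.capacitance == 200.0


class TestSynapseGroup:
    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            SynapseGroup([0], [0], [-1.0], [1.0])

    def test_zero_delay_rejected(self):
        with pytest.raises(ValueError):
            SynapseGroup([0], [0], [1.0], [0.0])


class TestSpikeTrainSet:
    def test_strictly_increasing(self):
        with pytest.raises(ValueError):
            SpikeTrainSet([[1.0, 1.0, 2.0]])

    def test_schedule_roundtrip(self, rng):
        trains = [np.sort(rng.uniform(0, 99, 17)), np.sort(rng.uniform(0, 99, 5))]
        trains = [np.unique(np.round(t, 1)) for t in trains]
        s = SpikeTrainSet(trains, duration=100.0)
        steps, srcs = s.to_schedule(0.1, 1000)
        back = SpikeTrainSet.from_schedule(steps, srcs, 2, 0.1)
        for a, b in zip(s.trains, back.trains):
            np.testing.assert_allclose(a, b, atol=1e-9)


class TestIntegration:
    def test_rest_is_fixed_point(self):
        net = single_neuron_net(weight=1.0)
        res = simulate(net, SpikeTrainSet([[]]), duration=50.0, record_voltage=[0])
        assert np.all(res.voltage[0] == net.params.rest_potential)
        assert res.spikes.total_count() == 0

    def test_subthreshold_steady_state(self):
        # quasi-constant conductance via an enormous synaptic time constant
        p = NeuronParams(exc_syn_time_constant=1e9, adp_amplitude=0.0)
        net = single_neuron_net(weight=4.0, params=p)
        res = simulate(net, SpikeTrainSet([[1.0]]), duration=500.0,
                       record_voltage=[0])
        ge = 4.0
        gl = p.leak_conductance
        v_ss = (gl * p.rest_potential + ge * p.exc_reversal) / (gl + ge)
        assert v_ss < p.spike_threshold
        assert res.voltage[0, -1] == pytest.approx(v_ss, abs=0.01)

    def test_spike_shape_peak_ramp_reset(self):
        net = single_neuron_net(weight=60.0)
        res = simulate(net, SpikeTrainSet([[5.0]]), duration=30.0,
                       record_voltage=[0])
        p = net.params
        t0 = res.spikes.trains[0][0]
        k = int(round(t0 / net.dt))
        v = res.voltage[0]
        assert v[k] == p.spike_peak
        n_ref = int(round(p.refractory_period / net.dt))
        assert v[k + n_ref] == pytest.approx(p.reset_potential, abs=1e-4)
        # linear in between
        mid = k + n_ref // 2
        expected_mid = p.spike_peak + (p.reset_potential - p.spike_peak) * 0.5
        assert v[mid] == pytest.approx(expected_mid, abs=4.0)

    def test_voltage_never_exceeds_peak_nor_threshold_outside_ramp(self, rng):
        p = NeuronParams()
        net = single_neuron_net(weight=30.0, params=p)
        stim = SpikeTrainSet([np.unique(np.round(rng.uniform(0, 490, 200), 1))])
        res = simulate(net, stim, duration=500.0, record_voltage=[0])
        v = res.voltage[0]
        assert v.max() <= p.spike_peak + 1e-9
        # outside refractory windows, at step boundaries V stays subthreshold
        in_ramp = np.zeros(len(v), dtype=bool)
        for t in res.spikes.trains[0]:
            k = int(round(t / net.dt))
            in_ramp[k:k + int(round(p.refractory_period / net.dt)) + 1] = True
        assert np.all(v[~in_ramp] < p.spike_threshold)

    def test_suprathreshold_isi_matches_closed_form(self):
        # constant drive, ADP disabled: integrate the LIF between reset and
        # threshold analytically and add the refractory period
        p = NeuronParams(exc_syn_time_constant=1e9, adp_amplitude=0.0)
        ge = 12.0
        net = single_neuron_net(weight=ge, params=p)
        res = simulate(net, SpikeTrainSet([[1.0]]), duration=400.0)
        gl = p.leak_conductance
        v_inf = (gl * p.rest_potential + ge * p.exc_reversal) / (gl + ge)
        tau_eff = p.capacitance / (gl + ge)
        t_cross = tau_eff * math.log(
            (v_inf - p.reset_potential) / (v_inf - p.spike_threshold)
        )
        expected = p.refractory_period + t_cross
        isis = np.diff(res.spikes.trains[0])[3:]
        assert isis.std() < 1e-9  # perfectly regular
        assert isis.mean() == pytest.approx(expected, rel=0.03, abs=net.dt)

    def test_determinism_same_seed(self, rng):
        net = single_neuron_net(weight=20.0)
        net.background_rate = 500.0
        net.background_weight = 2.0
        stim = SpikeTrainSet([np.unique(np.round(rng.uniform(0, 900, 80), 1))])
        r1 = simulate(net, stim, duration=1000.0, seed=7, record_voltage=[0])
        r2 = simulate(net, stim, duration=1000.0, seed=7, record_voltage=[0])
        np.testing.assert_array_equal(r1.voltage, r2.voltage)
        np.testing.assert_array_equal(r1.spikes.trains[0], r2.spikes.trains[0])

    def test_empty_stimulus_no_background_silent(self):
        net = single_neuron_net(weight=5.0)
        res = simulate(net, SpikeTrainSet([[]]), duration=200.0)
        assert res.spikes.total_count() == 0

    def test_dt_halving_rate_robustness(self, rng):
        # same stimulus spikes on both grids; mean rate shifts < 5%
        spikes = np.sort(np.unique(np.round(rng.uniform(0, 19998, 4000), 1)))
        rates = []
        for dt in (0.1, 0.05):
            net = single_neuron_net(weight=14.0)
            net.dt = dt
            res = simulate(net, SpikeTrainSet([spikes]), duration=20_000.0)
            rates.append(len(res.spikes.trains[0]) / 20.0)
        assert rates[0] > 5.0  # actually firing
        assert abs(rates[0] - rates[1]) / rates[1] < 0.05

    def test_conductance_decay_exact_and_delay_respected(self):
        p = NeuronParams()
        net = single_neuron_net(weight=3.0, delay=2.3)
        cnet = net.compile()
        state = SimState(cnet)
        # spike emitted at step 10, delay 2.3 ms -> arrival step 33
        run_chunk(cnet, state, 1.0, stimulus=SpikeTrainSet([[0.0]]))
        # chunk 1: 1 ms simulated, no arrival yet (arrival at t=2.3)
        assert state.exc_conductance[0] == 0.0
        run_chunk(cnet, state, 5.0)
        # now 6 ms simulated; decay since arrival = 6.0 - 2.3 - dt steps
        n_decay = 60 - 23
        expected = 3.0 * math.exp(-n_decay * net.dt / p.exc_syn_time_constant)
        assert state.exc_conductance[0] == pytest.approx(expected, rel=1e-12)


class TestPoisson:
    def test_zero_rate_no_spikes(self):
        s = poisson_spike_trains(np.zeros((3, 10)), 100.0, seed=0)
        assert s.total_count() == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_spike_trains(np.full((1, 1), -1.0), 100.0)

    def test_constant_rate_count_within_4_sigma(self):
        rates = np.full((1, 1000), 5.0)  # 5 Hz for 1000 s
        s = poisson_spike_trains(rates, 1000.0, seed=3)
        n = len(s.trains[0])
        assert abs(n - 5000) < 4 * math.sqrt(5000)

    def test_piecewise_rate_confined_and_unbiased(self):
        # 10 Hz for 0.5 s then silence; mean count ~ 5 over many seeds
        rates = np.array([[10.0, 0.0]])
        counts = []
        for seed in range(1000):
            s = poisson_spike_trains(rates, 500.0, seed=seed)
            t = s.trains[0]
            assert len(t) == 0 or t.max() < 500.0
            counts.append(len(t))
        mean = np.mean(counts)
        assert mean == pytest.approx(5.0, abs=4 * math.sqrt(5.0 / 1000))
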