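"""Clock-driven simulation of conductance-based leaky integrate-and-fire neurons.

The neuron model is a conductance-based LIF with a "soft" reset intended to
mimic cortical pyramidal cells: on threshold crossing the voltage jumps to a
spike peak (+20 mV), decays linearly to a high reset value (-55 mV) over the
refractory period, after which an exponentially decaying after-depolarizing
(ADP) current is injected.  Synapses are transient conductance changes with
instantaneous rise and exponential decay, delivered after a per-connection
axonal delay.  Integration uses a fixed time step (default 0.1 ms): exact
exponential updates for the linear conductance/ADP subsystems and forward
Euler for the voltage.

Units throughout: time ms, voltage mV, conductance nS, current pA,
capacitance pF (so that g[nS]*V[mV] = I[pA] and dt[ms]*I[pA]/C[pF] = dV[mV]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "NeuronParams",
    "SynapseGroup",
    "SpikeTrainSet",
    "SimState",
    "Network",
    "SimulationError",
    "integrate_step",
    "simulate",
    "poisson_spike_trains",
    "DEFAULT_DT",
]

DEFAULT_DT = 0.1  # ms


class SimulationError(RuntimeError):
    """Raised when integration blows up or a recording buffer overflows."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class NeuronParams:
    """Membrane and synaptic parameters shared by all neurons of a network.

    The default values are standard cortical conductance-based LIF constants,
    consistent with the soft-reset scheme (rest < reset < threshold < peak).
    """

    membrane_time_constant: float = 10.0  # ms
    leak_conductance: float = 20.0  # nS
    rest_potential: float = -75.0  # mV
    spike_threshold: float = -50.0  # mV
    spike_peak: float = 20.0  # mV
    reset_potential: float = -55.0  # mV
    refractory_period: float = 2.0  # ms
    adp_amplitude: float = 50.0  # pA
    adp_time_constant: float = 20.0  # ms
    exc_syn_time_constant: float = 5.0  # ms
    inh_syn_time_constant: float = 10.0  # ms
    exc_reversal: float = 0.0  # mV
    inh_reversal: float = -80.0  # mV

    def __post_init__(self) -> None:
        if not (
            self.rest_potential
            < self.reset_potential
            < self.spike_threshold
            < self.spike_peak
        ):
            raise ValueError(
                "require rest < reset < threshold < peak, got "
                f"{self.rest_potential}, {self.reset_potential}, "
                f"{self.spike_threshold}, {self.spike_peak}"
            )
        for name in (
            "membrane_time_constant",
            "leak_conductance",
            "refractory_period",
            "adp_time_constant",
            "exc_syn_time_constant",
            "inh_syn_time_constant",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.adp_amplitude < 0:
            raise ValueError("adp_amplitude must be non-negative")

    @property
    def capacitance(self) -> float:
        """Membrane capacitance C = tau_m * g_L, in pF."""
        return self.membrane_time_constant * self.leak_conductance

    def replace(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


EXC = 0
INH = 1


@dataclass
class SynapseGroup:
    """A homogeneous block of connections.

    ``source_kind`` is either ``"input"`` (external spike sources, indexed
    against the network's input channels) or ``"neuron"`` (recurrent sources).
    Weights are non-negative conductance jumps in nS; the sign of the effect
    is carried by the reversal class.
    """

    source_ids: np.ndarray
    target_ids: np.ndarray
    weights: np.ndarray
    delays: np.ndarray  # ms
    reversal_class: str = "excitatory"
    plastic: bool = False
    source_kind: str = "input"
    name: str = ""

    def __post_init__(self) -> None:
        self.source_ids = np.asarray(self.source_ids, dtype=np.int64)
        self.target_ids = np.asarray(self.target_ids, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.delays = np.asarray(self.delays, dtype=np.float64)
        n = len(self.source_ids)
        if not (len(self.target_ids) == len(self.weights) == len(self.delays) == n):
            raise ValueError("source/target/weight/delay arrays must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("synaptic weights must be non-negative")
        if np.any(self.delays <= 0):
            raise ValueError("synaptic delays must be strictly positive")
        if self.reversal_class not in ("excitatory", "inhibitory"):
            raise ValueError("reversal_class must be 'excitatory' or 'inhibitory'")
        if self.source_kind not in ("input", "neuron"):
            raise ValueError("source_kind must be 'input' or 'neuron'")

    def __len__(self) -> int:
        return len(self.source_ids)


class SpikeTrainSet:
    """Per-source ordered spike times (ms); the common currency of the package."""

    def __init__(self, trains, duration: float | None = None):
        self.trains = [np.asarray(t, dtype=np.float64) for t in trains]
        for i, t in enumerate(self.trains):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times of train {i} must be strictly increasing")
            if len(t) and (t[0] < 0 or (duration is not None and t[-1] > duration)):
                raise ValueError(f"spike times of train {i} outside [0, duration]")
        self.duration = duration

    def __len__(self) -> int:
        return len(self.trains)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.trains[i]

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.trains], dtype=np.int64)

    def total_count(self) -> int:
        return int(self.counts().sum())

    def rates(self, duration: float | None = None) -> np.ndarray:
        """Mean firing rate per source in Hz."""
        dur = duration if duration is not None else self.duration
        if dur is None or dur <= 0:
            raise ValueError("duration required to compute rates")
        return self.counts() / (dur * 1e-3)

    def to_schedule(self, dt: float, n_steps: int):
        """Flatten to (step, source) arrays sorted by step, dropping spikes
        at or beyond ``n_steps``."""
        steps, srcs = [], []
        for i, t in enumerate(self.trains):
            s = np.round(t / dt).astype(np.int64)
            keep = s < n_steps
            steps.append(s[keep])
            srcs.append(np.full(keep.sum(), i, dtype=np.int64))
        if steps:
            step_arr = np.concatenate(steps)
            src_arr = np.concatenate(srcs)
        else:
            step_arr = np.empty(0, dtype=np.int64)
            src_arr = np.empty(0, dtype=np.int64)
        order = np.argsort(step_arr, kind="stable")
        return step_arr[order], src_arr[order]

    @staticmethod
    def from_schedule(steps, sources, n_sources: int, dt: float,
                      duration: float | None = None) -> "SpikeTrainSet":
        trains = [np.empty(0)] * n_sources
        steps = np.asarray(steps)
        sources = np.asarray(sources)
        order = np.lexsort((steps, sources))
        steps, sources = steps[order], sources[order]
        bounds = np.searchsorted(sources, np.arange(n_sources + 1))
        trains = [steps[bounds[i]:bounds[i + 1]] * dt for i in range(n_sources)]
        return SpikeTrainSet(trains, duration=duration)


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """A flat population of LIF neurons plus external input channels.

    ``groups`` hold the connectivity; ``compile()`` lowers them to the CSR
    arrays consumed by the simulation kernel.  Group weight arrays alias
    slices of the compiled flat weight vector, so in-place weight updates by
    plasticity rules are picked up by subsequent simulation calls.
    """

    n_neurons: int
    n_inputs: int = 0
    params: NeuronParams = field(default_factory=NeuronParams)
    groups: list = field(default_factory=list)
    background_rate: float = 0.0  # Hz, per-neuron independent Poisson drive
    background_weight: float = 0.0  # nS, excitatory
    positions: np.ndarray | None = None  # (n_neurons, 2) for spatial nets
    meta: dict = field(default_factory=dict)
    dt: float = DEFAULT_DT

    def __post_init__(self):
        self._compiled = None

    def add_group(self, group: SynapseGroup) -> SynapseGroup:
        n_src = self.n_inputs if group.source_kind == "input" else self.n_neurons
        if len(group) and (group.source_ids.max() >= n_src or group.source_ids.min() < 0):
            raise ValueError("source ids out of range")
        if len(group) and (group.target_ids.max() >= self.n_neurons or group.target_ids.min() < 0):
            raise ValueError("target ids out of range")
        self.groups.append(group)
        self._compiled = None
        return group

    @property
    def n_sources(self) -> int:
        return self.n_inputs + self.n_neurons

    def compile(self) -> "CompiledNetwork":
        if self._compiled is None:
            self._compiled = CompiledNetwork(self)
        return self._compiled


class CompiledNetwork:
    """CSR lowering of a Network (sorted by combined source index:
    external inputs first, then neurons)."""

    def __init__(self, net: Network):
        self.net = net
        dt = net.dt
        srcs, tgts, ws, dsteps, inhs = [], [], [], [], []
        group_slices = []
        offset = 0
        for g in net.groups:
            s = g.source_ids + (0 if g.source_kind == "input" else net.n_inputs)
            srcs.append(s)
            tgts.append(g.target_ids)
            ws.append(g.weights)
            d = np.maximum(1, np.round(g.delays / dt)).astype(np.int64)
            dsteps.append(d)
            inhs.append(
                np.full(len(g), INH if g.reversal_class == "inhibitory" else EXC,
                        dtype=np.uint8)
            )
            group_slices.append(slice(offset, offset + len(g)))
            offset += len(g)
        n_syn = offset
        if n_syn:
            src = np.concatenate(srcs)
            self.perm = np.argsort(src, kind="stable")
            src_sorted = src[self.perm]
            self.tgt = np.concatenate(tgts)[self.perm].astype(np.int32)
            self.dstep = np.concatenate(dsteps)[self.perm].astype(np.int32)
            self.inh = np.concatenate(inhs)[self.perm]
            self._flat_w = np.concatenate(ws)
        else:
            self.perm = np.empty(0, dtype=np.int64)
            src_sorted = np.empty(0, dtype=np.int64)
            self.tgt = np.empty(0, dtype=np.int32)
            self.dstep = np.empty(0, dtype=np.int32)
            self.inh = np.empty(0, dtype=np.uint8)
            self._flat_w = np.empty(0)
        self.indptr = np.searchsorted(
            src_sorted, np.arange(net.n_sources + 1)
        ).astype(np.int64)
        self.group_slices = group_slices
        # rebind group weight arrays as views into the flat vector so that
        # plasticity updates propagate without recompilation
        for g, sl in zip(net.groups, group_slices):
            g.weights = self._flat_w[sl]
        self.n_slots = int(self.dstep.max()) + 1 if n_syn else 1

    def csr_weights(self) -> np.ndarray:
        return self._flat_w[self.perm]


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


class SimState:
    """Instantaneous network state: voltages, conductances, ADP currents,
    refractory clocks and the delayed-delivery ring buffer."""

    def __init__(self, cnet: CompiledNetwork):
        net = cnet.net
        n = net.n_neurons
        p = net.params
        self.time = 0.0
        self.voltages = np.full(n, p.rest_potential)
        self.exc_conductance = np.zeros(n)
        self.inh_conductance = np.zeros(n)
        self.adp_current = np.zeros(n)
        self.refractory_clock = np.zeros(n)
        self.buffer = np.zeros((cnet.n_slots, n, 2))
        self.buffer_pos = 0


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_kernel(
    n_steps, dt,
    n_inputs, n_neurons,
    C, gL, Vrest, Vthr, Vpeak, Vreset, tref, adp_amp, dadp, de, di, Ee, Ei,
    indptr, tgt, w, dstep, inh,
    p_bg, bg_w,
    ext_step, ext_src,
    inj_step, inj_neuron, inj_amp,
    V, ge, gi, iadp, reft,
    buf, buf_pos,
    rec_row, recV,
    out_step, out_neuron, counts, gsum,
    seed,
):
    np.random.seed(seed)
    n_slots = buf.shape[0]
    n_out = 0
    cap = out_step.shape[0]
    ext_i = 0
    n_ext = ext_step.shape[0]
    inj_i = 0
    n_inj = inj_step.shape[0]
    for k in range(n_steps):
        slot = (buf_pos + k) % n_slots
        # 1. deliver conductance jumps scheduled for this step
        for i in range(n_neurons):
            ge[i] += buf[slot, i, 0]
            gi[i] += buf[slot, i, 1]
            buf[slot, i, 0] = 0.0
            buf[slot, i, 1] = 0.0
        # 2. route external spikes emitted at this step
        while ext_i < n_ext and ext_step[ext_i] == k:
            s = ext_src[ext_i]
            for c in range(indptr[s], indptr[s + 1]):
                a = (buf_pos + k + dstep[c]) % n_slots
                buf[a, tgt[c], inh[c]] += w[c]
            ext_i += 1
        # 3. background Poisson drive (delivered without delay)
        if p_bg > 0.0:
            for i in range(n_neurons):
                if np.random.random() < p_bg:
                    ge[i] += bg_w
        # 4. injected current events for this step
        inj_now_start = inj_i
        while inj_i < n_inj and inj_step[inj_i] == k:
            inj_i += 1
        # 5. membrane update
        for i in range(n_neurons):
            gsum[i] += ge[i] + gi[i]
            if reft[i] > 0.0:
                # imposed linear spike-shape decay; membrane equation suspended
                r = reft[i] - dt
                if r <= 1e-12:
                    V[i] = Vreset
                    iadp[i] += adp_amp
                    reft[i] = 0.0
                else:
                    V[i] = Vpeak + (Vreset - Vpeak) * (tref - r) / tref
                    reft[i] = r
            else:
                I = (
                    gL * (Vrest - V[i])
                    + ge[i] * (Ee - V[i])
                    + gi[i] * (Ei - V[i])
                    + iadp[i]
                )
                for j in range(inj_now_start, inj_i):
                    if inj_neuron[j] == i:
                        I += inj_amp[j]
                V[i] += dt * I / C
                if not np.isfinite(V[i]):
                    return n_out, 1
                if V[i] >= Vthr:
                    # spike: set to peak, start refractory ramp, route
                    V[i] = Vpeak
                    reft[i] = tref
                    if n_out >= cap:
                        return n_out, 2
                    out_step[n_out] = k
                    out_neuron[n_out] = i
                    n_out += 1
                    counts[i] += 1
                    s = n_inputs + i
                    for c in range(indptr[s], indptr[s + 1]):
                        a = (buf_pos + k + dstep[c]) % n_slots
                        buf[a, tgt[c], inh[c]] += w[c]
            iadp[i] *= dadp
            ge[i] *= de
            gi[i] *= di
            r_i = rec_row[i]
            if r_i >= 0:
                recV[r_i, k] = V[i]
    return n_out, 0


class SimResult:
    """Recordings from one simulation chunk."""

    def __init__(self, spikes: SpikeTrainSet, voltage=None, voltage_neurons=None,
                 mean_conductance=None, spike_counts=None, dt=DEFAULT_DT):
        self.spikes = spikes
        self.voltage = voltage  # (n_rec, n_steps) float32 or None
        self.voltage_neurons = voltage_neurons
        self.mean_conductance = mean_conductance  # per-neuron mean g_e+g_i, nS
        self.spike_counts = spike_counts
        self.dt = dt


def run_chunk(
    cnet: CompiledNetwork,
    state: SimState,
    duration: float,
    stimulus: SpikeTrainSet | tuple | None = None,
    record_voltage=None,
    injections=None,
    seed: int = 0,
    max_rate_hint: float = 400.0,
) -> SimResult:
    """Advance the network by ``duration`` ms, mutating ``state`` in place.

    ``stimulus`` is a SpikeTrainSet over the external input channels (or a
    pre-flattened ``(steps, sources)`` pair).  ``injections`` is an optional
    ``(steps, neurons, amplitudes_pA)`` triple of per-step current events.
    """
    net = cnet.net
    dt = net.dt
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_steps = int(round(duration / dt))
    if stimulus is None:
        ext_step = np.empty(0, dtype=np.int64)
        ext_src = np.empty(0, dtype=np.int64)
    elif isinstance(stimulus, SpikeTrainSet):
        if len(stimulus) != net.n_inputs:
            raise ValueError("stimulus must cover every input channel")
        ext_step, ext_src = stimulus.to_schedule(dt, n_steps)
    else:
        ext_step, ext_src = stimulus
    if injections is None:
        inj_step = np.empty(0, dtype=np.int64)
        inj_neuron = np.empty(0, dtype=np.int64)
        inj_amp = np.empty(0)
    else:
        inj_step, inj_neuron, inj_amp = injections
        order = np.argsort(inj_step, kind="stable")
        inj_step = np.asarray(inj_step, dtype=np.int64)[order]
        inj_neuron = np.asarray(inj_neuron, dtype=np.int64)[order]
        inj_amp = np.asarray(inj_amp, dtype=np.float64)[order]

    rec_row = np.full(net.n_neurons, -1, dtype=np.int64)
    if record_voltage is not None:
        rec_idx = np.asarray(record_voltage, dtype=np.int64)
        if len(rec_idx) and (rec_idx.max() >= net.n_neurons or rec_idx.min() < 0):
            raise ValueError("recorded neuron index out of range")
        rec_row[rec_idx] = np.arange(len(rec_idx))
        recV = np.empty((len(rec_idx), n_steps), dtype=np.float32)
    else:
        rec_idx = np.empty(0, dtype=np.int64)
        recV = np.empty((0, n_steps), dtype=np.float32)

    p = net.params
    cap = max(
        10_000,
        int(net.n_neurons * (duration * 1e-3) * max_rate_hint) + 100,
        len(ext_step) + 100,
    )
    out_step = np.empty(cap, dtype=np.int64)
    out_neuron = np.empty(cap, dtype=np.int32)
    counts = np.zeros(net.n_neurons, dtype=np.int64)
    gsum = np.zeros(net.n_neurons)

    n_out, status = _run_kernel(
        n_steps, dt,
        net.n_inputs, net.n_neurons,
        p.capacitance, p.leak_conductance, p.rest_potential, p.spike_threshold,
        p.spike_peak, p.reset_potential, p.refractory_period, p.adp_amplitude,
        math.exp(-dt / p.adp_time_constant),
        math.exp(-dt / p.exc_syn_time_constant),
        math.exp(-dt / p.inh_syn_time_constant),
        p.exc_reversal, p.inh_reversal,
        cnet.indptr, cnet.tgt, cnet.csr_weights(), cnet.dstep, cnet.inh,
        net.background_rate * dt * 1e-3, net.background_weight,
        ext_step, ext_src,
        inj_step, inj_neuron, inj_amp,
        state.voltages, state.exc_conductance, state.inh_conductance,
        state.adp_current, state.refractory_clock,
        state.buffer, state.buffer_pos,
        rec_row, recV,
        out_step, out_neuron, counts, gsum,
        np.uint32(seed),
    )
    if status == 1:
        raise SimulationError("non-finite membrane potential: integration blow-up")
    if status == 2:
        raise SimulationError("spike buffer overflow; raise max_rate_hint")
    state.buffer_pos = (state.buffer_pos + n_steps) % cnet.n_slots
    state.time += n_steps * dt
    spikes = SpikeTrainSet.from_schedule(
        out_step[:n_out], out_neuron[:n_out], net.n_neurons, dt, duration=duration
    )
    return SimResult(
        spikes,
        voltage=recV if record_voltage is not None else None,
        voltage_neurons=rec_idx,
        mean_conductance=gsum / n_steps,
        spike_counts=counts,
        dt=dt,
    )


def integrate_step(state: SimState, cnet: CompiledNetwork, dt: float | None = None,
                   seed: int = 0) -> tuple[SimState, SpikeTrainSet]:
    """Advance the network state by a single time step.

    Thin wrapper over the same kernel ``simulate`` uses, provided for
    inspection and unit testing of the integration scheme.
    """
    net = cnet.net
    if dt is not None and dt != net.dt:
        if dt <= 0:
            raise ValueError("dt must be positive")
        net.dt = dt
        net._compiled = None
        cnet = net.compile()
    res = run_chunk(cnet, state, net.dt, seed=seed)
    return state, res.spikes


def simulate(
    network: Network,
    stimulus: SpikeTrainSet | None = None,
    duration: float = 1000.0,
    seed: int = 0,
    record_voltage=None,
    state: SimState | None = None,
) -> SimResult:
    """Simulate ``network`` for ``duration`` ms from a fresh (or given) state.

    Deterministic given (network, stimulus, seed).  Returns the emitted
    spike trains and, optionally, dt-sampled voltage traces.
    """
    if stimulus is not None and stimulus.duration is not None and any(
        len(t) and t[-1] > duration for t in stimulus.trains
    ):
        raise ValueError("stimulus spikes must lie within [0, duration]")
    cnet = network.compile()
    if state is None:
        state = SimState(cnet)
    return run_chunk(
        cnet, state, duration, stimulus=stimulus,
        record_voltage=record_voltage, seed=seed,
    )


# ---------------------------------------------------------------------------
# Poisson input generation
# ---------------------------------------------------------------------------


def poisson_spike_trains(
    rate_series: np.ndarray,
    bin_width: float,
    seed=None,
    dt: float = DEFAULT_DT,
) -> SpikeTrainSet:
    """Inhomogeneous Poisson spike trains from piecewise-constant rates.

    ``rate_series`` is (n_sources, n_bins) in Hz, each bin ``bin_width`` ms
    wide.  Sampling is per-simulation-step Bernoulli with p = rate*dt, valid
    because rate*dt << 1 at the rates used here.
    """
    rate_series = np.atleast_2d(np.asarray(rate_series, dtype=np.float64))
    if np.any(rate_series < 0):
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_src, n_bins = rate_series.shape
    steps_per_bin = int(round(bin_width / dt))
    if steps_per_bin < 1:
        raise ValueError("bin_width must be at least one simulation step")
    duration = n_bins * bin_width
    p = np.repeat(rate_series * dt * 1e-3, steps_per_bin, axis=1)
    trains = []
    for i in range(n_src):
        hits = np.nonzero(rng.random(p.shape[1]) < p[i])[0]
        trains.append(hits * dt)
    return SpikeTrainSet(trains, duration=duration)
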