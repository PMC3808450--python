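"""Pattern-based training: one plasticity interface for all rules.

Simulation proceeds in pattern-length chunks (1 s by default, matching the
eligibility time constant and the backward-pass update cadence).  After each
pattern the active rule computes a per-synapse weight change from the
recorded activity, the homeostatic gate scales its expression, weights are
clipped to hard bounds, and the PI controller applies multiplicative
synaptic scaling to each neuron's plastic excitatory inputs.

Rules are registered by name: ``convallis``, ``rc-stdp``, ``nn-stdp``,
``rc-triplet`` and ``rate-only`` (homeostatic scaling without any
activity-dependent term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import plasticity as pl
from .baselines import StdpParams, TripletParams, TRIPLET_VISUAL_CORTEX
from .core_sim import Network, SimState, SpikeTrainSet, run_chunk
from .homeostasis import RateControllerState, controller_step, plasticity_gate, \
    update_rate_estimate

__all__ = ["PatternTrainer", "make_rule", "ConvallisRule", "StdpRule",
           "TripletRule", "RateOnlyRule", "RULE_NAMES"]

RULE_NAMES = ("convallis", "rc-stdp", "nn-stdp", "rc-triplet", "rate-only")


class _RuleBase:
    needs_voltage = False

    def bind(self, trainer: "PatternTrainer") -> None:
        self.trainer = trainer

    def pattern_update(self, ctx) -> np.ndarray:
        raise NotImplementedError


@dataclass
class PatternContext:
    """Everything a rule may consume about the pattern just simulated."""

    dt: float
    n_steps: int
    voltage: np.ndarray | None  # (n_targets, n_steps) float32
    target_rows: dict  # neuron id -> voltage row
    ext_spikes: SpikeTrainSet
    net_spikes: SpikeTrainSet
    mean_conductance: np.ndarray  # per neuron, nS


class ConvallisRule(_RuleBase):
    """Valley-objective gradient rule with eligibility carry-over.

    Eligibility decays by exp(-T/tau_p) between patterns and accumulates the
    fast backward-pass integral within each; weight changes are the shrunk
    eligibility times the learning rate (clipping and homeostatic gating are
    applied by the trainer).
    """

    needs_voltage = True

    def __init__(self, params: pl.PlasticityParams | None = None,
                 objective: pl.ObjectiveParams | None = None,
                 conductance_averaging_time: float = 10_000.0,
                 freeze_accumulation_when_gated: bool = True):
        self.params = params or pl.PlasticityParams()
        self.objective = objective or pl.ObjectiveParams()
        self.conductance_averaging_time = conductance_averaging_time
        self.freeze_accumulation_when_gated = freeze_accumulation_when_gated

    def bind(self, trainer):
        super().bind(trainer)
        npar = trainer.net.params
        n_tgt = len(trainer.target_neurons)
        self.state = pl.PlasticityState.zeros(
            n_tgt, trainer.n_plastic, npar.membrane_time_constant
        )
        self._tau_syn = npar.exc_syn_time_constant

    def pattern_update(self, ctx: PatternContext) -> np.ndarray:
        tr = self.trainer
        npar = tr.net.params
        T = ctx.n_steps * ctx.dt
        # running mean conductance -> effective time constant, per pattern
        a = math.exp(-T / self.conductance_averaging_time)
        gbar = self.state.mean_total_conductance
        gbar[...] = a * gbar + (1 - a) * ctx.mean_conductance[tr.target_neurons]
        tau_eff = npar.capacitance / (npar.leak_conductance + gbar)
        self.state.effective_time_constant[...] = tau_eff

        H = pl.gprime(ctx.voltage.astype(np.float64), self.objective)
        slow = np.empty_like(tau_eff)
        fast = np.empty_like(tau_eff)
        inv_peak = np.empty_like(tau_eff)
        for i, te in enumerate(tau_eff):
            slow[i], fast[i], inv_peak[i] = pl._kernel_constants(self._tau_syn, te)
        kappa = pl._kappa_multi(
            H, ctx.dt, self.params.eligibility_time_constant,
            self._tau_syn, slow, fast, inv_peak,
        )
        self.state.modulation_trace = H
        self.state.kappa_table = kappa
        S = pl._sum_kappa(
            kappa, tr.plastic_row, tr.plastic_src, tr.plastic_dstep,
            tr._src_indptr, tr._src_steps, ctx.n_steps,
        )
        P = self.state.eligibility
        P *= math.exp(-T / self.params.eligibility_time_constant)
        gain = self.params.eligibility_scale * (npar.exc_reversal - npar.rest_potential)
        if self.freeze_accumulation_when_gated:
            P += gain * S * tr.last_gate_per_synapse()
        else:
            P += gain * S
        return self.params.learning_rate * pl.shrink(
            P, self.params.theta_d, self.params.theta_p
        )


class _PairwiseRuleBase(_RuleBase):
    """Shared machinery for rules defined on (pre, post) spike trains.

    Spike lists for all plastic synapses are flattened to CSR arrays once per
    pattern and handed to batched event kernels (pre times are arrival times:
    emission plus the synaptic delay).
    """

    def _flat_trains(self, ctx: PatternContext):
        tr = self.trainer
        indptr, steps = tr._src_indptr, tr._src_steps
        n_in = tr.net.n_inputs
        pre_chunks, post_chunks = [], []
        pre_len = np.empty(tr.n_plastic, dtype=np.int64)
        post_len = np.empty(tr.n_plastic, dtype=np.int64)
        for j in range(tr.n_plastic):
            s = tr.plastic_src[j]
            pre = steps[indptr[s]:indptr[s + 1]] + tr.plastic_dstep[j]
            p = n_in + tr.plastic_tgt[j]
            post = steps[indptr[p]:indptr[p + 1]]
            pre_chunks.append(pre)
            post_chunks.append(post)
            pre_len[j] = len(pre)
            post_len[j] = len(post)
        cat = lambda chunks: (
            np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        )
        pre_indptr = np.concatenate([[0], np.cumsum(pre_len)])
        post_indptr = np.concatenate([[0], np.cumsum(post_len)])
        return cat(pre_chunks), pre_indptr, cat(post_chunks), post_indptr


class StdpRule(_PairwiseRuleBase):
    def __init__(self, params: StdpParams | None = None, learning_rate: float = 1.0):
        self.params = params or StdpParams()
        self.learning_rate = learning_rate

    def pattern_update(self, ctx):
        from .baselines import _stdp_batch

        p = self.params
        pre, pre_ptr, post, post_ptr = self._flat_trains(ctx)
        dw = _stdp_batch(
            pre, pre_ptr, post, post_ptr, ctx.dt,
            p.a_plus, p.a_minus, p.tau_plus, p.tau_minus,
            p.pairing_mode == "nearest_neighbour",
        )
        return self.learning_rate * dw


class TripletRule(_PairwiseRuleBase):
    def __init__(self, params: TripletParams = TRIPLET_VISUAL_CORTEX,
                 learning_rate: float = 1.0):
        self.params = params
        self.learning_rate = learning_rate

    def pattern_update(self, ctx):
        from .baselines import _triplet_batch

        p = self.params
        pre, pre_ptr, post, post_ptr = self._flat_trains(ctx)
        dw = _triplet_batch(
            pre, pre_ptr, post, post_ptr, ctx.dt,
            p.a2_plus, p.a2_minus, p.a3_plus, p.a3_minus,
            p.tau_plus, p.tau_minus, p.tau_x, p.tau_y,
        )
        return self.learning_rate * dw


class RateOnlyRule(_RuleBase):
    def pattern_update(self, ctx):
        return np.zeros(self.trainer.n_plastic)


def make_rule(name: str, **kw) -> _RuleBase:
    if name == "convallis":
        return ConvallisRule(**kw)
    if name == "rc-stdp":
        return StdpRule(params=kw.pop("params", None) or StdpParams(pairing_mode="all_to_all"), **kw)
    if name == "nn-stdp":
        p = kw.pop("params", None) or StdpParams()
        p.pairing_mode = "nearest_neighbour"
        return StdpRule(params=p, **kw)
    if name == "rc-triplet":
        return TripletRule(**kw)
    if name == "rate-only":
        return RateOnlyRule()
    raise ValueError(f"unknown rule {name!r}; choose from {RULE_NAMES}")


class PatternTrainer:
    """Drives pattern-by-pattern simulation, plasticity and homeostasis.

    ``plastic_groups`` selects which synapse groups the rule updates (default:
    every group flagged plastic).  The rate constraint, when enabled, attaches
    one PI controller per neuron that receives plastic input and scales those
    plastic excitatory inputs multiplicatively at pattern boundaries.
    """

    def __init__(
        self,
        net: Network,
        rule: _RuleBase,
        target_rate: float | None = None,
        rate_constraint: bool = True,
        gating: bool = True,
        weight_bounds: tuple | None = None,
        controller_kw: dict | None = None,
        seed: int = 0,
    ):
        self.net = net
        self.rule = rule
        self.cnet = net.compile()
        self.state = SimState(self.cnet)
        self.rng = np.random.default_rng(seed)
        self.rate_constraint = rate_constraint and target_rate is not None
        self.gating = gating and self.rate_constraint

        groups = [g for g in net.groups if g.plastic]
        if not groups:
            raise ValueError("network has no plastic synapse groups")
        self.plastic_groups = groups
        src, tgt, dstep, w_slices = [], [], [], []
        for g in groups:
            off = 0 if g.source_kind == "input" else net.n_inputs
            src.append(g.source_ids + off)
            tgt.append(g.target_ids)
            dstep.append(np.maximum(1, np.round(g.delays / net.dt)).astype(np.int64))
            w_slices.append(g.weights)  # views into the flat vector
        self.plastic_src = np.concatenate(src).astype(np.int64)
        self.plastic_tgt = np.concatenate(tgt).astype(np.int64)
        self.plastic_dstep = np.concatenate(dstep)
        self._w_views = w_slices
        self.n_plastic = len(self.plastic_src)

        if weight_bounds is None:
            p = getattr(rule, "params", None)
            weight_bounds = (
                getattr(p, "weight_min", 0.0), getattr(p, "weight_max", 10.0)
            )
        self.weight_bounds = weight_bounds

        self.target_neurons = np.unique(self.plastic_tgt)
        self.plastic_row = np.searchsorted(
            self.target_neurons, self.plastic_tgt
        ).astype(np.int64)
        self.controllers = {}
        if self.rate_constraint:
            for nrn in self.target_neurons:
                self.controllers[int(nrn)] = RateControllerState(
                    target_rate=target_rate, **(controller_kw or {})
                )
        self._last_gate = np.ones(len(self.target_neurons))
        self.history = {"rate": [], "gate": [], "multiplier": []}
        rule.bind(self)

    # -- helpers -----------------------------------------------------------

    def weights(self) -> np.ndarray:
        return np.concatenate([w for w in self._w_views])

    def set_weights(self, values: np.ndarray) -> None:
        off = 0
        for w in self._w_views:
            w[...] = values[off:off + len(w)]
            off += len(w)

    def last_gate_per_synapse(self) -> np.ndarray:
        return self._last_gate[self.plastic_row]

    def _build_src_csr(self, ext: SpikeTrainSet, internal: SpikeTrainSet, dt, n_steps):
        steps = []
        counts = np.zeros(self.net.n_sources + 1, dtype=np.int64)
        for i, t in enumerate(ext.trains):
            s = np.minimum(np.round(t / dt).astype(np.int64), n_steps - 1)
            steps.append(s)
            counts[i + 1] = len(s)
        for i, t in enumerate(internal.trains):
            s = np.minimum(np.round(t / dt).astype(np.int64), n_steps - 1)
            steps.append(s)
            counts[self.net.n_inputs + i + 1] = len(s)
        self._src_indptr = np.cumsum(counts)
        self._src_steps = (
            np.concatenate(steps) if steps else np.empty(0, dtype=np.int64)
        )

    # -- main loop ---------------------------------------------------------

    def run_pattern(
        self,
        stimulus: SpikeTrainSet | None,
        duration: float = 1000.0,
        plastic: bool = True,
        homeostasis: bool | None = None,
        record_voltage=None,
        injections=None,
    ):
        """Simulate one pattern and (optionally) apply plasticity and
        homeostasis.

        ``plastic=False, homeostasis=True`` runs a homeostasis-only pattern
        (controller and synaptic scaling without the activity-dependent
        rule), used to settle the rate constraint before learning starts.
        Returns the chunk's SimResult."""
        if homeostasis is None:
            homeostasis = plastic
        record = record_voltage
        if record is None and plastic and self.rule.needs_voltage:
            record = self.target_neurons
        res = run_chunk(
            self.cnet, self.state, duration,
            stimulus=stimulus, record_voltage=record, injections=injections,
            seed=int(self.rng.integers(2**31)),
        )
        if not plastic and not homeostasis:
            return res
        n_steps = int(round(duration / self.net.dt))
        ext = stimulus if stimulus is not None else SpikeTrainSet(
            [np.empty(0)] * self.net.n_inputs
        )
        self._build_src_csr(ext, res.spikes, self.net.dt, n_steps)
        voltage = None
        rows = {}
        if plastic and self.rule.needs_voltage:
            voltage = res.voltage
            rows = {int(n): i for i, n in enumerate(res.voltage_neurons)}
        ctx = PatternContext(
            dt=self.net.dt, n_steps=n_steps, voltage=voltage, target_rows=rows,
            ext_spikes=ext, net_spikes=res.spikes,
            mean_conductance=res.mean_conductance,
        )
        dw = self.rule.pattern_update(ctx) if plastic else np.zeros(self.n_plastic)

        # homeostasis: gate, expression, clip, then synaptic scaling
        gate = np.ones(len(self.target_neurons))
        mults = np.ones(len(self.target_neurons))
        if self.rate_constraint:
            for i, nrn in enumerate(self.target_neurons):
                c = self.controllers[int(nrn)]
                update_rate_estimate(c, res.spike_counts[nrn], duration)
                if self.gating:
                    gate[i] = plasticity_gate(c)
                mults[i], _ = controller_step(c, duration)
        self._last_gate = gate

        w = self.weights()
        w = np.clip(
            w + gate[self.plastic_row] * dw,
            self.weight_bounds[0], self.weight_bounds[1],
        )
        if self.rate_constraint:
            w = np.clip(
                w * mults[self.plastic_row],
                self.weight_bounds[0], self.weight_bounds[1],
            )
        self.set_weights(w)

        self.history["rate"].append(
            res.spike_counts[self.target_neurons] / (duration * 1e-3)
        )
        self.history["gate"].append(gate.copy())
        self.history["multiplier"].append(mults.copy())
        return res
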