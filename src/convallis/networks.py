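"""Network builders and spontaneous-state calibration.

Two architectures drive the learning experiments:

* feedforward — each output neuron receives plastic excitatory synapses from
  a random 50% subset of the input channels (initial weights U[0, 10] nS)
  and static inhibitory synapses from *all* channels (U[0, 40] nS), delays
  U[0.1, 5] ms;

* recurrent — a 4:1 excitatory/inhibitory sheet on a periodic unit square
  with uniform 5% connectivity, Gaussian-initialized weights (sd = mean/3,
  truncated at 0), independent 300 Hz Poisson background per neuron, and
  tonotopically organized external input (each channel projects to a small
  fraction of neurons with probability falling off as a Gaussian of torus
  distance from the channel's locus).  Only recurrent E->E synapses are
  plastic.

``calibrate_spontaneous_state`` searches the recurrent conductance scale for
an asynchronous-irregular spontaneous state at a target population rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_sim import Network, NeuronParams, SynapseGroup, SimState, run_chunk
from .metrics import population_cv_isi, pairwise_correlation

__all__ = [
    "FeedforwardSpec",
    "RecurrentSpec",
    "build_feedforward",
    "build_recurrent",
    "calibrate_spontaneous_state",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class FeedforwardSpec:
    n_outputs: int = 20
    exc_connection_prob: float = 0.5
    exc_init_range: tuple = (0.0, 10.0)  # nS
    inh_init_range: tuple = (0.0, 40.0)  # nS
    delay_range: tuple = (0.1, 5.0)  # ms
    target_rate: float = 1.5  # Hz
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.exc_connection_prob <= 1.0:
            raise ValueError("exc_connection_prob must lie in [0, 1]")
        for name in ("exc_init_range", "inh_init_range", "delay_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (low, high) pair")


def build_feedforward(
    spec: FeedforwardSpec, n_inputs: int, params: NeuronParams | None = None
) -> Network:
    """Feedforward network from ``n_inputs`` external channels to
    ``spec.n_outputs`` neurons."""
    if n_inputs <= 0:
        raise ValueError("input population must be non-empty")
    rng = np.random.default_rng(spec.seed)
    net = Network(
        n_neurons=spec.n_outputs, n_inputs=n_inputs,
        params=params or NeuronParams(),
    )
    src_e, tgt_e = [], []
    for o in range(spec.n_outputs):
        sel = np.nonzero(rng.random(n_inputs) < spec.exc_connection_prob)[0]
        src_e.append(sel)
        tgt_e.append(np.full(len(sel), o))
    src_e = np.concatenate(src_e)
    tgt_e = np.concatenate(tgt_e)
    net.add_group(SynapseGroup(
        source_ids=src_e,
        target_ids=tgt_e,
        weights=rng.uniform(*spec.exc_init_range, size=len(src_e)),
        delays=rng.uniform(*spec.delay_range, size=len(src_e)),
        reversal_class="excitatory", plastic=True, source_kind="input",
        name="ff_exc",
    ))
    src_i = np.tile(np.arange(n_inputs), spec.n_outputs)
    tgt_i = np.repeat(np.arange(spec.n_outputs), n_inputs)
    net.add_group(SynapseGroup(
        source_ids=src_i,
        target_ids=tgt_i,
        weights=rng.uniform(*spec.inh_init_range, size=len(src_i)),
        delays=rng.uniform(*spec.delay_range, size=len(src_i)),
        reversal_class="inhibitory", plastic=False, source_kind="input",
        name="ff_inh",
    ))
    net.meta["target_rate"] = spec.target_rate
    return net


@dataclass
class RecurrentSpec:
    n_total: int = 4500
    ei_ratio: float = 4.0  # excitatory : inhibitory
    connection_prob: float = 0.05
    mean_exc: float = 0.2  # nS, recurrent excitatory mean (calibrated)
    mean_inh: float = 0.8  # nS, recurrent inhibitory mean (calibrated)
    delay_range: tuple = (0.1, 5.0)
    background_rate: float = 300.0  # Hz
    background_weight: float = 3.2  # nS
    n_inputs: int = 93
    input_fraction: float = 0.05
    tonotopic_sigma: float = 0.2  # torus units
    input_mean: float | None = None  # defaults to mean_exc
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.connection_prob < 1.0:
            raise ValueError("connection_prob must lie in (0, 1)")
        if self.ei_ratio <= 0:
            raise ValueError("ei_ratio must be positive")

    @property
    def n_exc(self) -> int:
        return int(round(self.n_total * self.ei_ratio / (self.ei_ratio + 1.0)))

    @property
    def n_inh(self) -> int:
        return self.n_total - self.n_exc


def _torus_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b)
    d = np.minimum(d, 1.0 - d)
    return np.sqrt((d**2).sum(axis=-1))


def _truncated_gaussian(rng, mean, n):
    return np.maximum(0.0, rng.normal(mean, mean / 3.0, size=n))


def build_recurrent(spec: RecurrentSpec, params: NeuronParams | None = None) -> Network:
    """Recurrent E/I network with tonotopic external input.

    Excitatory neurons are indices [0, n_exc); inhibitory [n_exc, n_total).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    n_exc = spec.n_exc
    net = Network(
        n_neurons=n, n_inputs=spec.n_inputs, params=params or NeuronParams(),
        background_rate=spec.background_rate,
        background_weight=spec.background_weight,
        positions=rng.random((n, 2)),
    )
    # uniform sparse recurrent connectivity, no self-connections
    src_all, tgt_all = [], []
    block = 512
    for s0 in range(0, n, block):
        s1 = min(n, s0 + block)
        mask = rng.random((s1 - s0, n)) < spec.connection_prob
        mask[np.arange(s1 - s0), np.arange(s0, s1)] = False
        s_idx, t_idx = np.nonzero(mask)
        src_all.append(s_idx + s0)
        tgt_all.append(t_idx)
    src_all = np.concatenate(src_all)
    tgt_all = np.concatenate(tgt_all)
    is_exc_src = src_all < n_exc
    for exc, name, mean, plastic in (
        (True, "rec_exc", spec.mean_exc, True),
        (False, "rec_inh", spec.mean_inh, False),
    ):
        sel = is_exc_src if exc else ~is_exc_src
        src, tgt = src_all[sel], tgt_all[sel]
        if exc:
            # only E->E synapses are plastic; E->I synapses are static
            ee = tgt < n_exc
            for sub, sub_plastic, sub_name in (
                (ee, True, "rec_ee"), (~ee, False, "rec_ei"),
            ):
                net.add_group(SynapseGroup(
                    source_ids=src[sub], target_ids=tgt[sub],
                    weights=_truncated_gaussian(rng, mean, sub.sum()),
                    delays=rng.uniform(*spec.delay_range, size=sub.sum()),
                    reversal_class="excitatory", plastic=sub_plastic,
                    source_kind="neuron", name=sub_name,
                ))
        else:
            net.add_group(SynapseGroup(
                source_ids=src, target_ids=tgt,
                weights=_truncated_gaussian(rng, mean, len(src)),
                delays=rng.uniform(*spec.delay_range, size=len(src)),
                reversal_class="inhibitory", plastic=False,
                source_kind="neuron", name=name,
            ))
    # tonotopic external input: channel loci evenly spaced along the sheet
    input_mean = spec.input_mean if spec.input_mean is not None else spec.mean_exc
    n_targets = max(1, int(round(spec.input_fraction * n)))
    src_in, tgt_in = [], []
    for ch in range(spec.n_inputs):
        locus = np.array([(ch + 0.5) / spec.n_inputs, 0.5])
        d = _torus_distance(net.positions, locus)
        p = np.exp(-(d**2) / (2.0 * spec.tonotopic_sigma**2))
        p /= p.sum()
        tgt = rng.choice(n, size=n_targets, replace=False, p=p)
        src_in.append(np.full(n_targets, ch))
        tgt_in.append(tgt)
    src_in = np.concatenate(src_in)
    tgt_in = np.concatenate(tgt_in)
    net.add_group(SynapseGroup(
        source_ids=src_in, target_ids=tgt_in,
        weights=_truncated_gaussian(rng, input_mean, len(src_in)),
        delays=rng.uniform(*spec.delay_range, size=len(src_in)),
        reversal_class="excitatory", plastic=False, source_kind="input",
        name="tonotopic_input",
    ))
    net.meta["spec"] = spec
    net.meta["n_exc"] = n_exc
    return net


def _spontaneous_probe(net, duration, warmup, seed, diagnostics=False):
    cnet = net.compile()
    state = SimState(cnet)
    run_chunk(cnet, state, warmup, seed=seed)
    res = run_chunk(cnet, state, duration, seed=seed + 1)
    rate = res.spike_counts.sum() / net.n_neurons / (duration * 1e-3)
    if not diagnostics:
        return rate, res
    diag = {"rate": rate}
    try:
        diag["cv_isi"] = population_cv_isi(res.spikes.trains, min_spikes=5)
    except ValueError:
        diag["cv_isi"] = float("nan")
    try:
        diag["pairwise_correlation"] = pairwise_correlation(
            res.spikes.trains, duration, n_pairs=2000, bin_size=5.0, seed=seed
        )
    except ValueError:
        diag["pairwise_correlation"] = float("nan")
    return rate, diag


def calibrate_spontaneous_state(
    spec: RecurrentSpec,
    target_rate: float = 1.5,
    tolerance: float = 0.10,
    probe_duration: float = 5000.0,
    warmup: float = 1000.0,
    final_probe: float = 10_000.0,
    bracket: tuple | None = None,
    inh_ratio: float = 6.0,
    max_iter: int = 12,
    seed: int = 0,
    params: NeuronParams | None = None,
):
    """Find recurrent conductance means giving spontaneous activity at
    ``target_rate``.

    Searches a single scalar — the excitatory mean — with the inhibitory
    mean tied at ``inh_ratio`` times it (and the external input mean tied to
    the excitatory mean), by bisection on short probe simulations.  Returns
    ``(mean_exc, mean_inh, diagnostics)`` where diagnostics holds the rate,
    mean CV-ISI and mean pairwise correlation of the calibrated state over a
    longer final probe.
    """
    if bracket is None:
        # recurrent in-degree scales with network size; keep the searched
        # conductance range equivalent across scales
        bracket = (0.05, 1.2 * 4500.0 / spec.n_total)
    # build once at unit mean; rescale group weights per candidate
    base_spec = RecurrentSpec(**{**spec.__dict__, "mean_exc": 1.0, "mean_inh": inh_ratio,
                                 "input_mean": 1.0})
    net = build_recurrent(base_spec, params=params)
    cnet = net.compile()
    scaled = {}
    for g in net.groups:
        scaled[g.name] = g.weights.copy()

    def set_scale(m):
        for g in net.groups:
            g.weights[...] = scaled[g.name] * m

    def probe(m, s):
        set_scale(m)
        r, _ = _spontaneous_probe(net, probe_duration, warmup, seed=s)
        return r

    lo, hi = bracket
    r_lo = probe(lo, seed)
    r_hi = probe(hi, seed + 100)
    if (r_lo - target_rate) * (r_hi - target_rate) > 0:
        raise CalibrationError(
            f"target {target_rate} Hz not bracketed: rate({lo})={r_lo:.3f}, "
            f"rate({hi})={r_hi:.3f}"
        )
    increasing = r_hi > r_lo
    mid = 0.5 * (lo + hi)
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = probe(mid, seed + 200 + it)
        if abs(r_mid - target_rate) <= tolerance * target_rate:
            break
        if (r_mid < target_rate) == increasing:
            lo = mid
        else:
            hi = mid
    set_scale(mid)
    rate, diag = _spontaneous_probe(
        net, final_probe, warmup, seed=seed + 999, diagnostics=True
    )
    diag["mean_exc"] = mid
    diag["mean_inh"] = inh_ratio * mid
    if abs(rate - target_rate) > 2.5 * tolerance * target_rate:
        raise CalibrationError(
            f"calibration failed: final rate {rate:.3f} Hz vs target {target_rate} Hz "
            f"(diagnostics: {diag})"
        )
    return mid, inh_ratio * mid, diag
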