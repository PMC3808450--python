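"""In-vitro plasticity paradigm reproductions.

Classic slice-electrophysiology protocols run on one- or two-neuron
circuits with the rate constraint turned off: spike-pairing (STDP) curves,
frequency-dependent tetanic stimulation, spike triplets, and
pairing-repetition-frequency sweeps.  Postsynaptic spikes are forced by
brief suprathreshold current injections, the experimental analogue of
somatic current commands.  Outcomes are reported as percent weight change
relative to the initial synaptic strength (2 nS unless stated), measured
after the protocol plus two seconds of silence so eligibility decays.
"""

from __future__ import annotations

import numpy as np

from .core_sim import Network, SpikeTrainSet, SynapseGroup
from .training import ConvallisRule, PatternTrainer, make_rule

__all__ = [
    "run_pairing_curve",
    "run_tetanus",
    "run_triplet",
    "run_pairing_frequency",
    "connectivity_tuning_analysis",
]

PATTERN_MS = 1000.0
_INJ_AMP = 15_000.0  # pA: crosses threshold from rest in < 0.4 ms
_INJ_STEPS = 5  # 0.5 ms pulse
_SYN_DELAY = 0.1  # ms

# protocols use a smaller expression step than the learning tasks so that
# 60-100-event outcomes stay away from the hard weight bounds and report
# graded percent changes
PROTOCOL_LEARNING_RATE = 0.01


def _protocol_rule(rule):
    if not isinstance(rule, str):
        return rule()
    if rule == "convallis":
        from .plasticity import PlasticityParams

        return ConvallisRule(
            params=PlasticityParams(learning_rate=PROTOCOL_LEARNING_RATE)
        )
    return make_rule(rule)


def _spike_protocol(
    rule,
    pre_times,
    post_times,
    initial_weight: float = 2.0,
    silence_ms: float = 2000.0,
    seed: int = 0,
    dt: float = 0.1,
) -> float:
    """Run one two-neuron protocol; returns percent weight change.

    ``pre_times`` are presynaptic *spike* times (ms, absolute);
    ``post_times`` are the times at which postsynaptic spikes are forced.
    """
    pre_times = np.asarray(pre_times, dtype=np.float64)
    post_times = np.asarray(post_times, dtype=np.float64)
    net = Network(n_neurons=1, n_inputs=1, dt=dt)
    net.add_group(SynapseGroup(
        source_ids=[0], target_ids=[0], weights=[initial_weight],
        delays=[_SYN_DELAY], reversal_class="excitatory", plastic=True,
        source_kind="input", name="pair",
    ))
    trainer = PatternTrainer(net, rule, rate_constraint=False, seed=seed)
    t_end = 0.0
    for arr in (pre_times, post_times):
        if len(arr):
            t_end = max(t_end, arr.max())
    n_patterns = int(np.ceil((t_end + 10.0) / PATTERN_MS)) + int(
        round(silence_ms / PATTERN_MS)
    )
    w0 = float(trainer.weights()[0])
    for k in range(n_patterns):
        lo, hi = k * PATTERN_MS, (k + 1) * PATTERN_MS
        pre = pre_times[(pre_times >= lo) & (pre_times < hi)] - lo
        post = post_times[(post_times >= lo) & (post_times < hi)] - lo
        stim = SpikeTrainSet([pre])
        inj = None
        if len(post):
            # start each pulse slightly early so the threshold crossing lands
            # on the commanded time (< 0.5 ms jitter)
            starts = np.maximum(0, np.round((post - 0.3) / dt).astype(np.int64))
            steps = np.concatenate(
                [s + np.arange(_INJ_STEPS) for s in starts]
            )
            inj = (steps, np.zeros(len(steps), dtype=np.int64),
                   np.full(len(steps), _INJ_AMP))
        trainer.run_pattern(stim, PATTERN_MS, injections=inj)
    w1 = float(trainer.weights()[0])
    return 100.0 * (w1 - w0) / w0


def run_pairing_curve(
    dts,
    n_pairs: int = 60,
    rep_freq: float = 1.0,
    rule: str | object = "convallis",
    initial_weight: float = 2.0,
    seed: int = 0,
):
    """Spike-pairing (STDP) curve: percent weight change per pairing lag.

    ``dt > 0`` means the presynaptic spike leads the postsynaptic one.
    ``n_pairs`` pairings are repeated at ``rep_freq`` Hz.  Returns an array
    aligned with ``dts``.
    """
    out = []
    period = 1000.0 / rep_freq
    base = 500.0 + np.arange(n_pairs) * period
    for dt_pair in np.atleast_1d(dts):
        r = _protocol_rule(rule)
        out.append(_spike_protocol(
            r, base, base + dt_pair, initial_weight=initial_weight, seed=seed,
        ))
    return np.asarray(out)


def run_tetanus(
    frequencies,
    n_pulses: int = 100,
    rule: str | object = "convallis",
    n_seeds: int = 20,
    n_exc: int = 20,
    n_inh: int = 5,
    exc_weight: float = 3.5,
    inh_weight: float = 9.5,
    p_active: float = 0.5,
    seed: int = 0,
):
    """Tetanic stimulation: mean percent change of the excitatory weights as
    a function of pulse frequency.

    A single neuron receives ``n_exc`` plastic excitatory and ``n_inh``
    static inhibitory synapses; at each of ``n_pulses`` pulses every synapse
    is active with probability ``p_active``.  Averaged over ``n_seeds``
    independent realizations.
    """
    frequencies = np.atleast_1d(frequencies)
    results = np.zeros((len(frequencies), n_seeds))
    for fi, f in enumerate(frequencies):
        period = 1000.0 / f
        pulse_times = 500.0 + np.arange(n_pulses) * period
        duration = pulse_times[-1] + 10.0
        n_patterns = int(np.ceil(duration / PATTERN_MS)) + 2
        for s in range(n_seeds):
            rng = np.random.default_rng(seed + 1000 * fi + s)
            net = Network(n_neurons=1, n_inputs=n_exc + n_inh)
            net.add_group(SynapseGroup(
                source_ids=np.arange(n_exc), target_ids=np.zeros(n_exc),
                weights=np.full(n_exc, exc_weight),
                delays=np.full(n_exc, _SYN_DELAY),
                reversal_class="excitatory", plastic=True, source_kind="input",
            ))
            net.add_group(SynapseGroup(
                source_ids=n_exc + np.arange(n_inh), target_ids=np.zeros(n_inh),
                weights=np.full(n_inh, inh_weight),
                delays=np.full(n_inh, _SYN_DELAY),
                reversal_class="inhibitory", plastic=False, source_kind="input",
            ))
            r = _protocol_rule(rule)
            trainer = PatternTrainer(net, r, rate_constraint=False, seed=seed + s)
            w0 = trainer.weights().copy()
            active = rng.random((n_pulses, n_exc + n_inh)) < p_active
            for k in range(n_patterns):
                lo, hi = k * PATTERN_MS, (k + 1) * PATTERN_MS
                in_pat = (pulse_times >= lo) & (pulse_times < hi)
                trains = [
                    pulse_times[in_pat & active[:, i]] - lo
                    for i in range(n_exc + n_inh)
                ]
                trainer.run_pattern(SpikeTrainSet(trains), PATTERN_MS)
            w1 = trainer.weights()
            results[fi, s] = 100.0 * np.mean((w1 - w0) / w0)
    return results.mean(axis=1)


def run_triplet(
    ordering: str,
    intervals=(5.0, 5.0),
    n_reps: int = 60,
    rep_freq: float = 1.0,
    rule: str | object = "convallis",
    initial_weight: float = 2.0,
    seed: int = 0,
) -> float:
    """Spike-triplet protocol: ``post_pre_post`` or ``pre_post_pre`` triplets
    (intervals ms before/after the middle spike), repeated at ``rep_freq``
    Hz.  Returns percent weight change."""
    if ordering not in ("post_pre_post", "pre_post_pre"):
        raise ValueError("ordering must be post_pre_post or pre_post_pre")
    a, b = intervals
    period = 1000.0 / rep_freq
    mid = 500.0 + np.arange(n_reps) * period
    if ordering == "post_pre_post":
        pre = mid
        post = np.sort(np.concatenate([mid - a, mid + b]))
    else:
        post = mid
        pre = np.sort(np.concatenate([mid - a, mid + b]))
    r = _protocol_rule(rule)
    return _spike_protocol(r, pre, post, initial_weight=initial_weight, seed=seed)


def run_pairing_frequency(
    frequencies,
    dt_pair: float = 10.0,
    n_sweeps: int = 15,
    spikes_per_sweep: int = 5,
    sweep_rate: float = 0.1,  # Hz
    rule: str | object = "convallis",
    initial_weight: float = 2.0,
    seed: int = 0,
):
    """Pairing-repetition-frequency sweep (75 spike pairs in total).

    Each sweep is a burst of ``spikes_per_sweep`` pre/post pairs at the given
    pairing frequency, with fixed lag ``dt_pair`` (sign convention as in
    :func:`run_pairing_curve`); sweeps repeat at ``sweep_rate`` Hz (slower if
    a burst outlasts the sweep period).  Returns percent change per
    frequency.
    """
    out = []
    for f in np.atleast_1d(frequencies):
        # at low pairing frequencies consecutive sweeps merge into one
        # continuous pair train, as in the slice experiments
        sweep_period = max(1000.0 / sweep_rate, spikes_per_sweep * 1000.0 / f)
        pre = np.sort(np.concatenate([
            500.0 + k * sweep_period + np.arange(spikes_per_sweep) * 1000.0 / f
            for k in range(n_sweeps)
        ]))
        post = pre + dt_pair
        r = _protocol_rule(rule)
        out.append(_spike_protocol(
            r, pre, post, initial_weight=initial_weight, seed=seed,
        ))
    return np.asarray(out)


def connectivity_tuning_analysis(
    net,
    counts,
    labels,
    n_exc: int,
    group_name: str = "rec_ee",
    min_pairs: int = 10,
):
    """Mean recurrent E->E weight for same- vs different-preference pairs.

    ``counts`` is (utterances x n_exc) spike counts of the excitatory
    population; a neuron's preferred class is the argmax of its mean
    response.  Returns ``(mean_same, mean_diff, same_weights, diff_weights)``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    means = np.stack([counts[labels == c].mean(axis=0) for c in classes])
    pref = classes[np.argmax(means, axis=0)]
    group = next((g for g in net.groups if g.name == group_name), None)
    if group is None:
        raise ValueError(f"no synapse group named {group_name!r}")
    src, tgt = group.source_ids, group.target_ids
    valid = (src < n_exc) & (tgt < n_exc)
    same = pref[src[valid]] == pref[tgt[valid]]
    w = group.weights[valid]
    if same.sum() < min_pairs or (~same).sum() < min_pairs:
        raise ValueError("fewer than min_pairs connections in a preference group")
    return (
        float(w[same].mean()),
        float(w[~same].mean()),
        w[same].copy(),
        w[~same].copy(),
    )
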