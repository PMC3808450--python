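"""Baseline spike-timing-dependent plasticity rules.

Comparison rules used alongside the Convallis rule: classical additive
exponential-window STDP with all-to-all or nearest-neighbour spike pairing,
and the pair+triplet trace rule with the published visual-cortex and
hippocampal parameter fits.  All are pure event-based weight-change
computations; composition with the homeostatic rate constraint happens in
:mod:`convallis.training`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "StdpParams",
    "TripletParams",
    "TRIPLET_VISUAL_CORTEX",
    "TRIPLET_HIPPOCAMPAL",
    "stdp_weight_change",
    "triplet_weight_change",
    "grid_search_rcstdp",
]


@dataclass
class StdpParams:
    """Additive exponential STDP window.

    Convention: a post spike at lag +dt after a pre spike potentiates by
    ``a_plus * exp(-dt/tau_plus)``; the reverse order depresses by
    ``a_minus * exp(-dt/tau_minus)``.  Zero-lag pairs contribute nothing.
    """

    a_plus: float = 0.02  # nS
    a_minus: float = 0.022  # nS
    tau_plus: float = 20.0  # ms
    tau_minus: float = 20.0  # ms
    pairing_mode: str = "all_to_all"  # or "nearest_neighbour"
    weight_min: float = 0.0
    weight_max: float = 10.0

    def __post_init__(self):
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if self.pairing_mode not in ("all_to_all", "nearest_neighbour"):
            raise ValueError("pairing_mode must be all_to_all or nearest_neighbour")
        if not self.weight_min < self.weight_max:
            raise ValueError("weight bounds must be ordered")


@dataclass
class TripletParams:
    """Pair+triplet trace rule parameters (all-to-all interactions).

    ``a2_*`` are the pair amplitudes, ``a3_*`` the triplet amplitudes;
    ``tau_plus/tau_minus`` the fast pre/post detector constants and
    ``tau_x/tau_y`` the slow pre/post triplet constants (ms).
    """

    a2_plus: float
    a2_minus: float
    a3_plus: float
    a3_minus: float
    tau_plus: float = 16.8
    tau_minus: float = 33.7
    tau_x: float = 101.0
    tau_y: float = 125.0

    def __post_init__(self):
        for name in ("tau_plus", "tau_minus", "tau_x", "tau_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# Published all-to-all fits of the triplet rule (visual cortex and
# hippocampal culture data sets).
TRIPLET_VISUAL_CORTEX = TripletParams(
    a2_plus=5e-10, a2_minus=7.0e-3, a3_plus=6.2e-3, a3_minus=2.3e-4,
    tau_plus=16.8, tau_minus=33.7, tau_x=101.0, tau_y=125.0,
)
TRIPLET_HIPPOCAMPAL = TripletParams(
    a2_plus=6.1e-3, a2_minus=1.6e-3, a3_plus=6.7e-3, a3_minus=1.4e-3,
    tau_plus=16.8, tau_minus=33.7, tau_x=946.0, tau_y=27.0,
)


def _check_sorted(t, name):
    t = np.asarray(t, dtype=np.float64)
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError(f"{name} spike times must be sorted")
    return t


def stdp_weight_change(pre_times, post_times, p: StdpParams = StdpParams()) -> float:
    """Total additive STDP weight change (nS, before clipping) for one
    pre/post spike-train pair."""
    pre = _check_sorted(pre_times, "pre")
    post = _check_sorted(post_times, "post")
    if len(pre) == 0 or len(post) == 0:
        return 0.0
    if p.pairing_mode == "all_to_all":
        lag = post[:, None] - pre[None, :]  # >0: pre before post
        ltp = p.a_plus * np.exp(-lag[lag > 0] / p.tau_plus).sum()
        ltd = p.a_minus * np.exp(lag[lag < 0] / p.tau_minus).sum()
        return float(ltp - ltd)
    # nearest-neighbour: each post pairs with the latest preceding pre,
    # each pre with the latest preceding post
    dw = 0.0
    idx = np.searchsorted(pre, post, side="left") - 1
    for g, i in zip(post, idx):
        if i >= 0 and g > pre[i]:
            dw += p.a_plus * np.exp(-(g - pre[i]) / p.tau_plus)
    idx = np.searchsorted(post, pre, side="left") - 1
    for f, i in zip(pre, idx):
        if i >= 0 and f > post[i]:
            dw -= p.a_minus * np.exp(-(f - post[i]) / p.tau_minus)
    return float(dw)


def triplet_weight_change(
    pre_times, post_times, p: TripletParams = TRIPLET_VISUAL_CORTEX
) -> float:
    """Weight change under the pair+triplet trace rule.

    Event-based evaluation of the four-trace dynamics: fast/slow presynaptic
    traces (tau_plus, tau_x) and fast/slow postsynaptic traces (tau_minus,
    tau_y).  At each presynaptic spike the weight depresses in proportion to
    the fast post trace times ``(a2_minus + a3_minus * slow pre trace)``; at
    each postsynaptic spike it potentiates in proportion to the fast pre
    trace times ``(a2_plus + a3_plus * slow post trace)``.  Slow traces enter
    with their value just before the current spike, so with zero triplet
    amplitudes the rule reduces exactly to all-to-all pair STDP.
    Simultaneous pre/post spikes see only strictly earlier spikes.
    """
    pre = _check_sorted(pre_times, "pre")
    post = _check_sorted(post_times, "post")
    events = [(t, 0) for t in pre] + [(t, 1) for t in post]
    events.sort()
    r1 = r2 = o1 = o2 = 0.0  # fast pre, slow pre, fast post, slow post
    t_last = None
    dw = 0.0
    i = 0
    n = len(events)
    while i < n:
        t = events[i][0]
        if t_last is not None:
            d = t - t_last
            r1 *= np.exp(-d / p.tau_plus)
            r2 *= np.exp(-d / p.tau_x)
            o1 *= np.exp(-d / p.tau_minus)
            o2 *= np.exp(-d / p.tau_y)
        t_last = t
        # gather all events at this instant; contributions use pre-update traces
        j = i
        n_pre = n_post = 0
        while j < n and events[j][0] == t:
            if events[j][1] == 0:
                n_pre += 1
            else:
                n_post += 1
            j += 1
        dw -= n_pre * o1 * (p.a2_minus + p.a3_minus * r2)
        dw += n_post * r1 * (p.a2_plus + p.a3_plus * o2)
        r1 += n_pre
        r2 += n_pre
        o1 += n_post
        o2 += n_post
        i = j
    return float(dw)


@njit(cache=True)
def _stdp_batch(pre_steps, pre_indptr, post_steps, post_indptr, dt,
                a_plus, a_minus, tau_plus, tau_minus, nearest):
    """Per-synapse STDP over flattened (CSR) spike arrays, all synapses of a
    pattern at once."""
    n_syn = pre_indptr.shape[0] - 1
    dw = np.zeros(n_syn)
    for j in range(n_syn):
        p0, p1 = pre_indptr[j], pre_indptr[j + 1]
        q0, q1 = post_indptr[j], post_indptr[j + 1]
        if p1 == p0 or q1 == q0:
            continue
        acc = 0.0
        if nearest:
            for qi in range(q0, q1):
                g = post_steps[qi]
                best = -1.0
                for pi in range(p0, p1):
                    f = pre_steps[pi]
                    if f < g and (best < 0 or f > best):
                        best = f
                if best >= 0:
                    acc += a_plus * np.exp(-(g - best) * dt / tau_plus)
            for pi in range(p0, p1):
                f = pre_steps[pi]
                best = -1.0
                for qi in range(q0, q1):
                    g = post_steps[qi]
                    if g < f and (best < 0 or g > best):
                        best = g
                if best >= 0:
                    acc -= a_minus * np.exp(-(f - best) * dt / tau_minus)
        else:
            for pi in range(p0, p1):
                f = pre_steps[pi]
                for qi in range(q0, q1):
                    g = post_steps[qi]
                    lag = (g - f) * dt
                    if lag > 0:
                        acc += a_plus * np.exp(-lag / tau_plus)
                    elif lag < 0:
                        acc -= a_minus * np.exp(lag / tau_minus)
        dw[j] = acc
    return dw


@njit(cache=True)
def _triplet_batch(pre_steps, pre_indptr, post_steps, post_indptr, dt,
                   a2p, a2m, a3p, a3m, tp, tm, tx, ty):
    """Per-synapse pair+triplet trace rule over flattened spike arrays."""
    n_syn = pre_indptr.shape[0] - 1
    dw = np.zeros(n_syn)
    for j in range(n_syn):
        p0, p1 = pre_indptr[j], pre_indptr[j + 1]
        q0, q1 = post_indptr[j], post_indptr[j + 1]
        if p1 == p0 or q1 == q0:
            continue
        r1 = r2 = o1 = o2 = 0.0
        acc = 0.0
        pi, qi = p0, q0
        t_last = -1.0
        while pi < p1 or qi < q1:
            tpre = pre_steps[pi] * dt if pi < p1 else 1e18
            tpost = post_steps[qi] * dt if qi < q1 else 1e18
            t = tpre if tpre <= tpost else tpost
            if t_last >= 0.0:
                d = t - t_last
                r1 *= np.exp(-d / tp)
                r2 *= np.exp(-d / tx)
                o1 *= np.exp(-d / tm)
                o2 *= np.exp(-d / ty)
            t_last = t
            n_pre = 0
            n_post = 0
            while pi < p1 and pre_steps[pi] * dt == t:
                n_pre += 1
                pi += 1
            while qi < q1 and post_steps[qi] * dt == t:
                n_post += 1
                qi += 1
            acc -= n_pre * o1 * (a2m + a3m * r2)
            acc += n_post * r1 * (a2p + a3p * o2)
            r1 += n_pre
            r2 += n_pre
            o1 += n_post
            o2 += n_post
        dw[j] = acc
    return dw


def grid_search_rcstdp(
    a_plus_grid,
    scaling_gain_grid,
    *,
    a_minus_ratio: float = 1.1,
    duration: float = 60_000.0,
    seed: int = 0,
    stimulus_kw: dict | None = None,
):
    """Grid search over the STDP learning rate and the rate-constraint gain.

    For each (a_plus, scaling_gain) combination a single neuron is trained on
    the circular-Gaussian ensemble with the rate-constrained STDP rule, and
    the score is the skewness of its subthreshold membrane-potential
    distribution after training (higher = more selective).  Returns a
    (len(a_plus_grid), len(scaling_gain_grid)) score matrix and the argmax
    pair.
    """
    from .experiment import run_gaussian_task  # local import: avoids cycle
    from .metrics import subthreshold_skewness

    scores = np.full((len(a_plus_grid), len(scaling_gain_grid)), np.nan)
    for i, a_plus in enumerate(a_plus_grid):
        for j, gain in enumerate(scaling_gain_grid):
            stdp = StdpParams(a_plus=float(a_plus), a_minus=float(a_plus) * a_minus_ratio)
            res = run_gaussian_task(
                rule="rc-stdp",
                duration=duration,
                seed=seed,
                stdp_params=stdp,
                scaling_gain=float(gain),
                probe_voltage=True,
                **(stimulus_kw or {}),
            )
            scores[i, j] = subthreshold_skewness(
                res["probe_voltage"], res["probe_spikes"], dt=res["dt"]
            )
    best = np.unravel_index(np.nanargmax(scores), scores.shape)
    return scores, (float(a_plus_grid[best[0]]), float(scaling_gain_grid[best[1]]))
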