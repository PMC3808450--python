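"""The Convallis plasticity rule.

The rule performs stochastic gradient ascent on a valley-shaped objective
``g(V)`` of the subthreshold membrane potential: potentials near rest or near
spike threshold are rewarded, intermediate depolarizations penalized, and the
near-threshold side is rewarded more strongly.  Its derivative ``g'(V)``
modulates, for every synapse, the contribution of each presynaptic spike
(through the EPSP it would evoke) to a slowly decaying eligibility ``P_j``.
Weight changes are expressed only when the accumulated eligibility leaves a
dead zone ``[theta_d, theta_p]`` (soft-threshold "shrinkage"), which
suppresses plasticity from isolated spike coincidences.

Two equivalent evaluation paths are provided for the eligibility integral:

* :func:`accumulate_eligibility_direct` — literal summation over the time
  grid for every synapse (the reference semantics, O(n_syn * T/dt));
* :func:`accumulate_eligibility_fast` — a per-neuron lookup table ``kappa(t)``
  built by a single backward pass over the voltage trace (two backward
  first-order recursions, one per exponential of the EPSP kernel, composed
  with the eligibility accumulator), after which each synapse only sums
  ``kappa`` at its spike arrival times: O(T/dt + total spikes).

The exact analytic forms of the objective and of the shrinkage function are
reconstructions (documented in docs/methods.md); the constraint set they
satisfy — valley between -55 and -52 mV, threshold-side dominance,
derivative expressible as a difference of two non-negative sigmoids, dead
zone [-10, 50] — is fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "ObjectiveParams",
    "PlasticityParams",
    "PlasticityState",
    "objective_g",
    "gprime",
    "decompose_gprime",
    "epsp_kernel",
    "update_mean_conductance",
    "kappa_table",
    "accumulate_eligibility_direct",
    "accumulate_eligibility_fast",
    "shrink",
    "apply_weight_updates",
]


def _logistic(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def _softplus(x):
    return np.logaddexp(0.0, np.asarray(x, dtype=np.float64))


@dataclass
class ObjectiveParams:
    """Shape of the valley objective g(V).

    ``V0, sigma0`` locate the depression (low-threshold) sigmoid, ``V1,
    sigma1`` the potentiation (high-threshold) sigmoid; ``ltd_weight`` is the
    relative amplitude of the depression component.  The defaults place the
    valley of g between -55 and -52 mV.
    """

    V0: float = -55.0  # mV
    V1: float = -52.0  # mV
    sigma0: float = 4.0  # mV
    sigma1: float = 2.0  # mV
    ltd_weight: float = 0.38

    def __post_init__(self):
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigma0 and sigma1 must be positive")
        if not self.V0 < self.V1:
            raise ValueError("V0 must lie below V1")
        if not 0.0 < self.ltd_weight < 1.0:
            raise ValueError("ltd_weight must lie in (0, 1)")


@dataclass
class PlasticityParams:
    """Rule parameters.

    ``eligibility_scale`` converts the raw eligibility integral (mV*ms units)
    to the dimensionless scale on which the dead-zone thresholds -10/50 are
    defined; it is calibrated once so that a single +10 ms pre-post pairing
    lands just below ``theta_p`` while 1 Hz repetition crosses it (see
    docs/methods.md).
    """

    learning_rate: float = 0.0005  # nS per unit of shrunk eligibility
    eligibility_time_constant: float = 1000.0  # ms (tau_p)
    theta_d: float = -10.0
    theta_p: float = 50.0
    weight_min: float = 0.0  # nS
    weight_max: float = 10.0  # nS
    pattern_length: float = 1000.0  # ms
    eligibility_scale: float = 1.4  # 1/(mV*ms)

    def __post_init__(self):
        if not (self.theta_d < 0.0 < self.theta_p):
            raise ValueError("require theta_d < 0 < theta_p")
        if not self.weight_min < self.weight_max:
            raise ValueError("require weight_min < weight_max")
        if self.eligibility_time_constant <= 0:
            raise ValueError("eligibility_time_constant must be positive")

    def replace(self, **kw) -> "PlasticityParams":
        return replace(self, **kw)


@dataclass
class PlasticityState:
    """Per-neuron and per-synapse running state of the rule."""

    mean_total_conductance: np.ndarray  # nS, per neuron
    effective_time_constant: np.ndarray  # ms, per neuron
    eligibility: np.ndarray  # dimensionless, per synapse
    modulation_trace: np.ndarray | None = None  # H(t) = g'(V(t)), last pattern
    kappa_table: np.ndarray | None = None  # per-neuron backward lookup

    @classmethod
    def zeros(cls, n_neurons: int, n_synapses: int, membrane_time_constant: float):
        return cls(
            mean_total_conductance=np.zeros(n_neurons),
            effective_time_constant=np.full(n_neurons, membrane_time_constant),
            eligibility=np.zeros(n_synapses),
        )


# ---------------------------------------------------------------------------
# Objective and gradient
# ---------------------------------------------------------------------------


def objective_g(V, p: ObjectiveParams = ObjectiveParams()):
    """Valley-shaped voltage objective.

    g(V) = sigma1*softplus((V-V1)/sigma1) - c*sigma0*softplus((V-V0)/sigma0),
    the antiderivative of :func:`gprime`.  Near rest both terms vanish; the
    depression term carves a valley above V0 and the potentiation term
    dominates past V1, so voltages near threshold score higher than rest and
    both score higher than intermediate depolarizations.
    """
    V = np.asarray(V, dtype=np.float64)
    c = p.ltd_weight
    return (
        p.sigma1 * _softplus((V - p.V1) / p.sigma1)
        - c * p.sigma0 * _softplus((V - p.V0) / p.sigma0)
    )


def gprime(V, p: ObjectiveParams = ObjectiveParams()):
    """Analytic derivative of the objective: a difference of two sigmoids.

    Positive near spike threshold (potentiation drive), negative at
    intermediate depolarizations (depression drive), ~0 at rest.
    """
    V = np.asarray(V, dtype=np.float64)
    return _logistic((V - p.V1) / p.sigma1) - p.ltd_weight * _logistic(
        (V - p.V0) / p.sigma0
    )


def decompose_gprime(p: ObjectiveParams = ObjectiveParams()):
    """Split g' into its two non-negative coincidence-detector components.

    Returns ``(phi_plus, phi_minus)`` with ``phi_plus - phi_minus == gprime``
    pointwise: both are monotonically non-decreasing sigmoids of voltage, the
    depression detector ``phi_minus`` having the lower half-activation
    voltage (V0 < V1).
    """

    def phi_plus(V):
        return _logistic((np.asarray(V, dtype=np.float64) - p.V1) / p.sigma1)

    def phi_minus(V):
        return p.ltd_weight * _logistic(
            (np.asarray(V, dtype=np.float64) - p.V0) / p.sigma0
        )

    return phi_plus, phi_minus


# ---------------------------------------------------------------------------
# EPSP kernel and effective time constant
# ---------------------------------------------------------------------------


def epsp_kernel(t, tau_syn: float, tau_eff: float):
    """Causal, peak-normalized postsynaptic-potential kernel.

    A difference of decaying exponentials: conductance decay (tau_syn)
    filtered by the effective membrane time constant (tau_eff).  Peak value
    is 1 by convention; the synaptic drive scale is carried by
    ``(E_j - V_rest)`` and the learning rate.  For tau_syn == tau_eff the
    alpha-function limit ``t*e^(1-t/tau)/tau`` is used.
    """
    t = np.asarray(t, dtype=np.float64)
    if tau_syn <= 0 or tau_eff <= 0:
        raise ValueError("time constants must be positive")
    out = np.zeros_like(t)
    pos = t >= 0
    if abs(tau_syn - tau_eff) < 1e-9 * tau_syn:
        tau = tau_syn
        out[pos] = (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
        return out if out.ndim else float(out)
    slow, fast = max(tau_syn, tau_eff), min(tau_syn, tau_eff)
    t_peak = (slow * fast / (slow - fast)) * math.log(slow / fast)
    norm = math.exp(-t_peak / slow) - math.exp(-t_peak / fast)
    out[pos] = (np.exp(-t[pos] / slow) - np.exp(-t[pos] / fast)) / norm
    return out if out.ndim else float(out)


def _kernel_constants(tau_syn: float, tau_eff: float):
    """(tau_slow, tau_fast, 1/peak) for the difference-of-exponentials form,
    nudging the degenerate equal-constant case."""
    if abs(tau_syn - tau_eff) < 1e-9 * tau_syn:
        tau_eff = tau_eff * (1.0 + 1e-6)
    slow, fast = max(tau_syn, tau_eff), min(tau_syn, tau_eff)
    t_peak = (slow * fast / (slow - fast)) * math.log(slow / fast)
    norm = math.exp(-t_peak / slow) - math.exp(-t_peak / fast)
    return slow, fast, 1.0 / norm


def update_mean_conductance(
    state: PlasticityState,
    g_total,
    dt: float,
    averaging_time: float,
    capacitance: float = 200.0,
    leak_conductance: float = 20.0,
    neuron: int | None = None,
):
    """Exponential running average of the total synaptic conductance and the
    induced effective membrane time constant tau_eff = C/(g_L + g_bar).

    ``g_total`` is a conductance trace (nS, sampled at ``dt``) for one neuron
    (``neuron`` selects the row of the state; default 0).  The filter is the
    exact first-order exponential update, so a step input reaches 63% of its
    amplitude after one ``averaging_time``.
    """
    g_total = np.asarray(g_total, dtype=np.float64)
    if np.any(g_total < 0):
        raise ValueError("conductances must be non-negative")
    i = 0 if neuron is None else neuron
    a = math.exp(-dt / averaging_time)
    gbar = state.mean_total_conductance[i]
    # exact filter over the trace; vectorized via the geometric recursion
    n = len(g_total)
    decays = a ** np.arange(n - 1, -1, -1)
    gbar = gbar * a**n + (1.0 - a) * np.dot(decays, g_total)
    state.mean_total_conductance[i] = gbar
    state.effective_time_constant[i] = capacitance / (leak_conductance + gbar)
    return state


# ---------------------------------------------------------------------------
# Eligibility accumulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _kappa_multi(H, dt, tau_p, tau_syn, tau_slow, tau_fast, inv_peak):
    """Backward-pass lookup tables for several neurons at once.

    H is (n_neurons, n_steps) = g'(V(t)); tau_slow/tau_fast/inv_peak are
    per-neuron kernel constants.  Returns kappa of the same shape with
    kappa[r, k] = sum_{m>=k} dt * e^{-(T-t_m)/tau_p} H[r,m] * eps((m-k)dt).
    """
    R, N = H.shape
    kappa = np.empty((R, N))
    dp = math.exp(-dt / tau_p)
    for r in range(R):
        ds = math.exp(-dt / tau_slow[r])
        df = math.exp(-dt / tau_fast[r])
        Ks = 0.0
        Kf = 0.0
        q = 1.0  # e^{-(T - t_k)/tau_p}, T = last sample
        for k in range(N - 1, -1, -1):
            base = dt * q * H[r, k]
            Ks = base + ds * Ks
            Kf = base + df * Kf
            kappa[r, k] = inv_peak[r] * (Ks - Kf)
            q *= dp
    return kappa


@njit(cache=True)
def _sum_kappa(kappa, syn_row, syn_src, syn_dstep, src_indptr, src_steps, n_steps):
    """Sum kappa at the (delayed) arrival steps of every plastic synapse."""
    n_syn = syn_row.shape[0]
    S = np.zeros(n_syn)
    for j in range(n_syn):
        r = syn_row[j]
        s = syn_src[j]
        d = syn_dstep[j]
        for e in range(src_indptr[s], src_indptr[s + 1]):
            a = src_steps[e] + d
            if a < n_steps:
                S[j] += kappa[r, a]
    return S


def kappa_table(
    voltage_trace,
    objective: ObjectiveParams,
    params: PlasticityParams,
    tau_eff: float,
    tau_syn: float = 5.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Per-neuron backward lookup kappa(t) for one voltage trace."""
    H = gprime(np.asarray(voltage_trace, dtype=np.float64), objective)[None, :]
    slow, fast, inv_peak = _kernel_constants(tau_syn, tau_eff)
    return _kappa_multi(
        H, dt, params.eligibility_time_constant,
        tau_syn, np.array([slow]), np.array([fast]), np.array([inv_peak]),
    )[0]


def _arrival_steps(arrival_times, dt, n_steps):
    steps = []
    for t in arrival_times:
        s = np.round(np.asarray(t, dtype=np.float64) / dt).astype(np.int64)
        if len(s) and (s.min() < 0 or s.max() >= n_steps):
            raise ValueError("presynaptic arrival time outside the voltage trace")
        steps.append(s)
    return steps


def accumulate_eligibility_direct(
    voltage_trace,
    arrival_times,
    reversals,
    objective: ObjectiveParams = ObjectiveParams(),
    params: PlasticityParams = PlasticityParams(),
    tau_eff: float = 10.0,
    tau_syn: float = 5.0,
    v_rest: float = -75.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Reference (direct-summation) eligibility at pattern end.

    P_j = scale * (E_j - V_rest) *
          sum_k dt e^{-(T-t_k)/tau_p} g'(V(t_k)) sum_f eps(t_k - t_f)

    ``arrival_times`` is a list of per-synapse spike ARRIVAL time arrays
    (emission + delay, ms); ``reversals`` the per-synapse reversal potentials.
    This is the semantic oracle for :func:`accumulate_eligibility_fast`.
    """
    V = np.asarray(voltage_trace, dtype=np.float64)
    N = len(V)
    steps = _arrival_steps(arrival_times, dt, N)
    reversals = np.asarray(reversals, dtype=np.float64)
    tau_p = params.eligibility_time_constant
    H = gprime(V, objective)
    k = np.arange(N)
    w = dt * np.exp(-(N - 1 - k) * dt / tau_p) * H
    P = np.zeros(len(steps))
    for j, a in enumerate(steps):
        drive = np.zeros(N)
        for s in a:
            u = (k[s:] - s) * dt
            drive[s:] += epsp_kernel(u, tau_syn, tau_eff)
        P[j] = (reversals[j] - v_rest) * np.dot(w, drive)
    return params.eligibility_scale * P


def accumulate_eligibility_fast(
    voltage_trace,
    arrival_times,
    reversals,
    objective: ObjectiveParams = ObjectiveParams(),
    params: PlasticityParams = PlasticityParams(),
    tau_eff: float = 10.0,
    tau_syn: float = 5.0,
    v_rest: float = -75.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Backward-pass eligibility; equivalent to the direct path.

    Builds kappa(t) once for the postsynaptic neuron and sums it at each
    synapse's arrival steps: cost O(T/dt + total spikes) instead of
    O(n_syn * T/dt).  Valid when the EPSP kernel support is shorter than the
    pattern (kappa is truncated at the trace end).
    """
    V = np.asarray(voltage_trace, dtype=np.float64)
    N = len(V)
    steps = _arrival_steps(arrival_times, dt, N)
    reversals = np.asarray(reversals, dtype=np.float64)
    kap = kappa_table(V, objective, params, tau_eff, tau_syn, dt)
    P = np.array([kap[a].sum() for a in steps])
    return params.eligibility_scale * (reversals - v_rest) * P


# ---------------------------------------------------------------------------
# Shrinkage and weight update
# ---------------------------------------------------------------------------


def shrink(P, theta_d: float = -10.0, theta_p: float = 50.0):
    """Soft-threshold shrinkage: zero inside the dead zone, identity shifted
    by the crossed threshold outside.  Continuous, monotone, 1-Lipschitz."""
    if not theta_d < 0 < theta_p:
        raise ValueError("require theta_d < 0 < theta_p")
    P = np.asarray(P, dtype=np.float64)
    out = np.where(P > theta_p, P - theta_p, np.where(P < theta_d, P - theta_d, 0.0))
    return out if out.ndim else float(out)


def apply_weight_updates(
    weights,
    eligibility,
    params: PlasticityParams = PlasticityParams(),
    gate=1.0,
    plastic=None,
    out=None,
):
    """w_j <- clip(w_j + eta * Gamma * Omega(P_j), w_min, w_max).

    ``gate`` is the homeostatic plasticity gate in [0, 1] (scalar or
    per-synapse); non-plastic synapses (``plastic`` mask False) are left
    untouched.  With ``out=weights`` the update is in place.
    """
    weights = np.asarray(weights, dtype=np.float64)
    gate = np.asarray(gate, dtype=np.float64)
    if np.any(gate < 0) or np.any(gate > 1):
        raise ValueError("gate must lie in [0, 1]")
    dw = params.learning_rate * gate * shrink(
        eligibility, params.theta_d, params.theta_p
    )
    new = np.clip(weights + dw, params.weight_min, params.weight_max)
    if plastic is not None:
        new = np.where(np.asarray(plastic, dtype=bool), new, weights)
    if out is None:
        return new
    out[...] = new
    return out
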