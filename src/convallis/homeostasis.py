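"""Homeostatic firing-rate constraint.

Each neuron tracks its own firing rate as an exponential running average
(time constant 10 s) and a Proportional-Integral controller converts the
deviation from a target rate into a multiplicative scaling of the neuron's
plastic excitatory input weights ("synaptic scaling").  A gating term
suppresses expression of activity-dependent plasticity while either the rate
error or its integral is away from zero, implementing a projected-gradient
style alternation: homeostasis first, feature learning once the constraint
is restored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateControllerState",
    "update_rate_estimate",
    "controller_step",
    "plasticity_gate",
]


@dataclass
class RateControllerState:
    """Per-neuron PI rate-controller state.

    ``gamma`` weights the integral term; the gate widths set how far the
    error/integral may stray before plasticity is suppressed.  Defaults are
    reconstructions tuned for stable convergence without oscillation:
    gate_width_e = 0.2 * target, gate_width_I = 2 * gate_width_e * T_rate.
    """

    target_rate: float  # Hz
    rate_time_constant: float = 10_000.0  # ms (T = 10 s)
    gamma: float = 0.02
    scaling_gain: float = 0.032  # per Hz of control output, per second
    gate_width_e: float | None = None  # Hz
    gate_width_I: float | None = None  # Hz*s
    rate_estimate: float = 0.0  # Hz
    integral: float = 0.0  # Hz*s
    min_multiplier: float = 0.2
    integral_clamp_factor: float = 2.0  # anti-windup, in units of gate_width_I

    def __post_init__(self):
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.gate_width_e is None:
            self.gate_width_e = 0.2 * self.target_rate
        if self.gate_width_I is None:
            self.gate_width_I = 2.0 * self.gate_width_e * self.rate_time_constant * 1e-3
        if self.gate_width_e <= 0 or self.gate_width_I <= 0:
            raise ValueError("gate widths must be positive")

    @property
    def error(self) -> float:
        """e = r_hat - r0, in Hz."""
        return self.rate_estimate - self.target_rate


def update_rate_estimate(
    state: RateControllerState, spike_count: float, dt: float
) -> RateControllerState:
    """Fold ``spike_count`` spikes observed over ``dt`` ms into the running
    rate estimate (exact first-order exponential filter)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    inst = spike_count / (dt * 1e-3)  # Hz
    a = math.exp(-dt / state.rate_time_constant)
    state.rate_estimate = a * state.rate_estimate + (1.0 - a) * inst
    return state


def controller_step(state: RateControllerState, dt: float):
    """One PI update over a ``dt`` ms interval.

    Returns ``(scale_multiplier, state)``: the multiplicative factor to apply
    to the neuron's plastic excitatory input weights.  Above-target firing
    gives a multiplier < 1 (scaling down), below-target > 1; the multiplier
    is floored at a small positive value so weights can never change sign.
    """
    e = state.error
    dt_s = dt * 1e-3
    state.integral += e * dt_s
    clamp = state.integral_clamp_factor * state.gate_width_I
    state.integral = min(max(state.integral, -clamp), clamp)
    u = e + state.gamma * state.integral
    mult = 1.0 - state.scaling_gain * u * dt_s
    mult = max(mult, state.min_multiplier)
    return mult, state


def plasticity_gate(state: RateControllerState) -> float:
    """Gamma in (0, 1]: 1 iff both the rate error and its integral vanish,
    decaying as a product of Gaussians in each (even in both arguments)."""
    e = state.error
    return math.exp(
        -(e * e) / (2.0 * state.gate_width_e**2)
        - (state.integral * state.integral) / (2.0 * state.gate_width_I**2)
    )
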