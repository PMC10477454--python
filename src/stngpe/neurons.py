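"""Single-neuron dynamics for GPe and STN neurons.

Both nuclei are modeled as adaptive quadratic integrate-and-fire (aQIF,
Izhikevich-type) neurons.  GPe neurons carry a single recovery variable
``u1``; STN neurons carry an additional slow variable ``u2`` that activates
below a rebound threshold and produces post-hyperpolarization rebound
bursts.  Parameter defaults correspond to prototypic (type B) GPe neurons
and rebound-bursting STN neurons.

Units: membrane potential mV, currents pA, capacitance pF, conductance-like
parameters (k, b) nS, rates 1/ms, time ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GpeParams",
    "StnParams",
    "NeuronState",
    "gpe_drift",
    "stn_drift",
    "gpe_reset",
    "stn_reset",
    "stn_threshold",
    "sample_capacitances",
]


@dataclass
class GpeParams:
    """aQIF parameter set for a GPe neuron.

    ``theta`` is the intensity of the white membrane-potential noise
    (mV^2/ms); ``I_bias`` is the constant depolarizing current that sets the
    baseline firing rate.
    """

    C_mean: float = 68.0   # pF
    k: float = 0.943       # nS/mV
    v_r: float = -53.0     # mV
    v_t: float = -44.0     # mV
    a: float = 0.0045      # 1/ms
    b: float = 3.895       # nS
    v_peak: float = 25.0   # mV
    c: float = -58.36      # mV
    d: float = 0.353       # pA
    theta: float = 3.0     # mV^2/ms
    I_bias: float = 64.0   # pA

    def __post_init__(self) -> None:
        if self.C_mean <= 0:
            raise ValueError("C_mean must be positive")
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError("require v_r < v_t < v_peak")
        if self.a <= 0:
            raise ValueError("a must be positive")


@dataclass
class StnParams(GpeParams):
    """aQIF parameter set for an STN neuron.

    The extra slow variable ``u2`` opens only below the rebound threshold
    ``v_r_tilde`` (Heaviside gate) and enters the voltage equation with
    coupling ``w``.  ``w_tilde`` is carried for completeness but unused.
    """

    C_mean: float = 23.0
    k: float = 0.439
    v_r: float = -56.2
    v_t: float = -41.4
    a: float = 0.021
    b: float = 4.0
    v_peak: float = 15.4
    c: float = -47.7
    d: float = 17.1
    theta: float = 0.5
    I_bias: float = 56.1
    w: float = 0.1           # dimensionless u2 coupling
    w_tilde: float = 0.0     # listed but unused
    v_r_tilde: float = -60.0  # mV, rebound gate threshold
    a_tilde: float = 0.123   # 1/ms
    b_tilde: float = 0.015   # nS
    d_tilde: float = -68.4   # pA, u2 reset increment

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.v_r_tilde > self.v_r:
            raise ValueError("rebound threshold must not exceed v_r")


@dataclass
class NeuronState:
    """Dynamical state of a single neuron (``u2`` only used for STN)."""

    v: float
    u1: float = 0.0
    u2: float = 0.0
    C: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not np.isfinite([self.v, self.u1, self.u2]).all():
            raise ValueError("non-finite neuron state")
        if self.C < 0:
            raise ValueError("capacitance must be non-negative")


def _check_finite(state: NeuronState, I: float) -> None:
    if not (np.isfinite(state.v) and np.isfinite(state.u1)
            and np.isfinite(state.u2) and np.isfinite(I)):
        raise ValueError("invalid (non-finite) neuron state or current")


def gpe_drift(state: NeuronState, params: GpeParams, I: float) -> tuple[float, float]:
    """Deterministic drift (dv/dt, du1/dt) of a GPe neuron.

    dv/dt = [k (v - v_r)(v - v_t) - u1 + I] / C
    du1/dt = a (b (v - v_r) - u1)
    """
    _check_finite(state, I)
    C = state.C if state.C > 0 else params.C_mean
    v, u1 = state.v, state.u1
    dv = (params.k * (v - params.v_r) * (v - params.v_t) - u1 + I) / C
    du1 = params.a * (params.b * (v - params.v_r) - u1)
    return dv, du1


def stn_drift(state: NeuronState, params: StnParams, I: float) -> tuple[float, float, float]:
    """Deterministic drift (dv/dt, du1/dt, du2/dt) of an STN neuron.

    The u2 gate G(v) = H(v_r_tilde - v) opens only during hyperpolarization
    below the rebound threshold.
    """
    _check_finite(state, I)
    C = state.C if state.C > 0 else params.C_mean
    v, u1, u2 = state.v, state.u1, state.u2
    dv = (params.k * (v - params.v_r) * (v - params.v_t)
          - u1 - params.w * u2 + I) / C
    du1 = params.a * (params.b * (v - params.v_r) - u1)
    gate = 1.0 if v < params.v_r_tilde else 0.0
    du2 = params.a_tilde * (gate * params.b_tilde * (v - params.v_r_tilde) - u2)
    return dv, du1, du2


def gpe_reset(state: NeuronState, params: GpeParams) -> NeuronState:
    """Post-spike reset v -> c, u1 -> u1 + d.  Requires v >= v_peak."""
    if state.v < params.v_peak:
        raise ValueError("gpe_reset called below the spike threshold")
    return NeuronState(v=params.c, u1=state.u1 + params.d, u2=state.u2, C=state.C)


def stn_threshold(u2: float, params: StnParams) -> float:
    """Effective STN spike threshold v_peak + U*u2, U = (w|u2| + 1/w)^-1."""
    U = 1.0 / (params.w * abs(u2) + 1.0 / params.w)
    return params.v_peak + U * u2


def stn_reset(state: NeuronState, params: StnParams) -> NeuronState:
    """Post-spike reset for STN: v -> c - U*u2, u1 += d, u2 += d_tilde.

    U is evaluated at the pre-reset u2.
    """
    U = 1.0 / (params.w * abs(state.u2) + 1.0 / params.w)
    if state.v < params.v_peak + U * state.u2:
        raise ValueError("stn_reset called below the spike threshold")
    return NeuronState(
        v=params.c - U * state.u2,
        u1=state.u1 + params.d,
        u2=state.u2 + params.d_tilde,
        C=state.C,
    )


def sample_capacitances(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n membrane capacitances from Normal(mean, 0.1*mean).

    Draws are truncated from below at 0.2*mean to exclude non-physical
    near-zero capacitances; at std = 0.1*mean the truncation probability is
    ~1e-15, so statistics are unaffected.
    """
    if mean <= 0:
        raise ValueError("mean capacitance must be positive")
    if n < 1:
        raise ValueError("need at least one neuron")
    draws = rng.normal(mean, 0.1 * mean, size=n)
    return np.clip(draws, 0.2 * mean, None)
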