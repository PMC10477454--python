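"""Conductance-based synapse models and total-current assembly.

Each projection (source nucleus -> target nucleus) pools its input onto one
conductance state variable per postsynaptic neuron and receptor channel.
GABA and AMPA conductances decay exponentially and jump by ``G`` at each
delayed spike arrival.  NMDA channels use a difference of two exponentials
(slow decay minus fast rise) and a voltage-dependent magnesium block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ProjectionSpec",
    "ConductanceState",
    "default_projections",
    "decay_conductance",
    "decay_conductance_exact",
    "deliver_spike",
    "ionotropic_current",
    "nmda_current",
    "magnesium_block",
    "assemble_gpe_current",
    "assemble_stn_current",
]


@dataclass(frozen=True)
class ProjectionSpec:
    """Synaptic constants of one projection.

    For AMPA/GABA ``tau`` is the single decay time; for NMDA ``tau`` is the
    rise time and ``tau_decay`` the decay time of the slow component.
    ``G`` is the conductance increment per spike arrival (nS), ``delay`` the
    transmission delay (ms), and ``N_out`` the out-degree per presynaptic
    neuron.
    """

    source: str
    target: str
    receptor: str  # AMPA | NMDA | GABA
    tau: float
    delay: float
    G: float
    E: float
    N_out: int
    tau_decay: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delay < 0 or self.G < 0:
            raise ValueError("delay and G must be non-negative")
        if self.receptor == "NMDA":
            if self.tau_decay is None or self.tau_decay <= self.tau:
                raise ValueError("NMDA requires tau (rise) < tau_decay")

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}:{self.receptor}"


# NMDA/AMPA peak-conductance ratios for the two glutamatergic projections.
NMDA_RATIO = {"CTX->STN": 0.6, "STN->GPe": 0.36}


def default_projections(
    G_ctx_stn: float = 0.125,
    G_gpe_stn: float = 1.11,
    G_stn_gpe: float = 15.8,
    G_msn_gpe: float = 5.54,
    G_gpe_gpe: float = 0.44,
    N_stn_gpe: int = 3,
    mu_scale: float = 1.0,
) -> dict[str, ProjectionSpec]:
    """Reference projection table (defaults: N^STN,GPe = 3 conductance set).

    ``mu_scale`` multiplies every peak conductance (1.0 by default).
    """
    g = lambda x: x * mu_scale
    specs = [
        ProjectionSpec("CTX", "STN", "AMPA", tau=2.0, delay=1.0,
                       G=g(G_ctx_stn), E=0.0, N_out=3),
        ProjectionSpec("CTX", "STN", "NMDA", tau=2.0, tau_decay=100.0, delay=1.0,
                       G=g(NMDA_RATIO["CTX->STN"] * G_ctx_stn), E=0.0, N_out=3),
        ProjectionSpec("GPe", "STN", "GABA", tau=8.0, delay=1.0,
                       G=g(G_gpe_stn), E=-84.0, N_out=1),
        ProjectionSpec("STN", "GPe", "AMPA", tau=2.0, delay=1.0,
                       G=g(G_stn_gpe), E=0.0, N_out=N_stn_gpe),
        ProjectionSpec("STN", "GPe", "NMDA", tau=2.0, tau_decay=100.0, delay=1.0,
                       G=g(NMDA_RATIO["STN->GPe"] * G_stn_gpe), E=0.0, N_out=N_stn_gpe),
        ProjectionSpec("MSN", "GPe", "GABA", tau=5.0, delay=7.4,
                       G=g(G_msn_gpe), E=-85.0, N_out=10),
        ProjectionSpec("GPe", "GPe", "GABA", tau=5.0, delay=5.0,
                       G=g(G_gpe_gpe), E=-85.0, N_out=20),
        # CTX->MSN carries no conductance: it shifts the MSN rate kernel.
        ProjectionSpec("CTX", "MSN", "RATE", tau=1.0, delay=10.5,
                       G=0.0, E=0.0, N_out=1),
    ]
    return {s.label: s for s in specs}


@dataclass
class ConductanceState:
    """Pooled conductance of one (projection, postsynaptic neuron) channel."""

    g: float = 0.0
    g_slow: float = 0.0  # NMDA only
    g_fast: float = 0.0  # NMDA only

    def __post_init__(self) -> None:
        if min(self.g, self.g_slow, self.g_fast) < 0:
            raise ValueError("conductances must be non-negative")


def decay_conductance(g: float, tau: float, dt: float) -> float:
    """One forward-Euler decay step g <- g (1 - dt/tau)."""
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    if g < 0:
        raise ValueError("negative conductance")
    return g * (1.0 - dt / tau)


def decay_conductance_exact(g0: float, tau: float, t: float) -> float:
    """Closed-form decay g0 exp(-t/tau) (analytic reference)."""
    return g0 * math.exp(-t / tau)


def deliver_spike(state: ConductanceState, spec: ProjectionSpec) -> ConductanceState:
    """Apply one spike arrival: g += G (AMPA/GABA) or both NMDA components.

    Incrementing g_slow and g_fast by the same G makes the effective NMDA
    conductance (g_slow - g_fast) start at zero, rise with the fast time
    constant and decay with the slow one.
    """
    if spec.receptor == "NMDA":
        return replace(state, g_slow=state.g_slow + spec.G,
                       g_fast=state.g_fast + spec.G)
    return replace(state, g=state.g + spec.G)


def ionotropic_current(g: float, E: float, v: float) -> float:
    """AMPA/GABA current g (E - v) in pA (g nS, potentials mV)."""
    return g * (E - v)


def nmda_current(g_slow: float, g_fast: float, E: float, v: float) -> float:
    """NMDA current (g_slow - g_fast)(E - v), before the magnesium block."""
    return (g_slow - g_fast) * (E - v)


def magnesium_block(v: float) -> float:
    """Voltage-dependent magnesium block B(v) = 1/(1 + 0.28 exp(-0.062 v))."""
    return 1.0 / (1.0 + 0.28 * math.exp(-0.062 * v))


def assemble_gpe_current(
    v: float,
    g_stn_ampa: ConductanceState,
    g_stn_nmda: ConductanceState,
    g_msn_gaba: ConductanceState,
    g_gpe_gaba: ConductanceState,
    specs: dict[str, ProjectionSpec],
    I_bias: float = 64.0,
    noise: float = 0.0,
) -> float:
    """Total postsynaptic current into a GPe neuron.

    I = I_AMPA^STN + B(v) I_NMDA^STN + I_GABA^MSN + I_GABA^GPe + I_bias + noise.
    """
    I = ionotropic_current(g_stn_ampa.g, specs["STN->GPe:AMPA"].E, v)
    I += magnesium_block(v) * nmda_current(
        g_stn_nmda.g_slow, g_stn_nmda.g_fast, specs["STN->GPe:NMDA"].E, v)
    I += ionotropic_current(g_msn_gaba.g, specs["MSN->GPe:GABA"].E, v)
    I += ionotropic_current(g_gpe_gaba.g, specs["GPe->GPe:GABA"].E, v)
    return I + I_bias + noise


def assemble_stn_current(
    v: float,
    g_ctx_ampa: ConductanceState,
    g_ctx_nmda: ConductanceState,
    g_gpe_gaba: ConductanceState,
    specs: dict[str, ProjectionSpec],
    I_bias: float = 56.1,
    noise: float = 0.0,
) -> float:
    """Total postsynaptic current into an STN neuron.

    I = I_AMPA^CTX + B(v) I_NMDA^CTX + I_GABA^GPe + I_bias + noise.
    """
    I = ionotropic_current(g_ctx_ampa.g, specs["CTX->STN:AMPA"].E, v)
    I += magnesium_block(v) * nmda_current(
        g_ctx_nmda.g_slow, g_ctx_nmda.g_fast, specs["CTX->STN:NMDA"].E, v)
    I += ionotropic_current(g_gpe_gaba.g, specs["GPe->STN:GABA"].E, v)
    return I + I_bias + noise
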