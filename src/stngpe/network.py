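"""Assembly of the full CTX/MSN/STN/GPe circuit.

A :class:`Circuit` bundles the population layouts, the per-projection edge
lists, the synaptic constants and the Poisson-substitution flags used by
the simulation engine.  Reduced circuits for conductance calibration are
obtained with :func:`lesion_inputs` (cut a projection into selected
neurons) and :func:`substitute_poisson` (replace a dynamical nucleus by
Poisson generators at its coordinates).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .neurons import GpeParams, StnParams
from .stimulation import R_CTX, R_MSN
from .synapses import ProjectionSpec, default_projections
from .topology import (OFFSET_SCALE, NetworkGraph, PopulationLayout,
                       build_d_network, build_n_network, build_s_network,
                       place_neurons)

__all__ = [
    "Circuit",
    "build_circuit",
    "lesion_inputs",
    "substitute_poisson",
    "CONDUCTANCE_PRESETS",
]

#: fitted conductance sets (nS) for the two STN->GPe out-degrees.  The
#: "n3"/"n30" presets carry the values co-printed with the achieved rates;
#: "n3-table" carries the alternative tabulated G^MSN,GPe.
CONDUCTANCE_PRESETS = {
    "n3": dict(G_ctx_stn=0.125, G_gpe_stn=1.11, G_stn_gpe=15.8,
               G_msn_gpe=5.54, G_gpe_gpe=0.44, N_stn_gpe=3),
    "n3-table": dict(G_ctx_stn=0.125, G_gpe_stn=1.11, G_stn_gpe=15.8,
                     G_msn_gpe=5.81, G_gpe_gpe=0.44, N_stn_gpe=3),
    "n30": dict(G_ctx_stn=0.125, G_gpe_stn=1.11, G_stn_gpe=1.5,
                G_msn_gpe=12.0, G_gpe_gpe=0.21, N_stn_gpe=30),
}

#: default population sizes
SIZES = {"CTX": 1000, "MSN": 1000, "STN": 100, "GPe": 300}


@dataclass
class Circuit:
    """Wired circuit ready for simulation."""

    layouts: dict[str, PopulationLayout]
    graphs: dict[str, NetworkGraph]           # keyed "CTX->STN" etc.
    projections: dict[str, ProjectionSpec]    # keyed "CTX->STN:AMPA" etc.
    ctx_msn: np.ndarray                       # CTX index -> nearest MSN
    gpe_params: GpeParams = field(default_factory=GpeParams)
    stn_params: StnParams = field(default_factory=StnParams)
    r_ctx: float = R_CTX                      # 1/ms
    r_msn: float = R_MSN                      # 1/ms
    stn_poisson_rate: float | None = None     # Hz, None = dynamical
    gpe_poisson_rate: float | None = None
    network_type: str = "N"
    structure_seed: int = 0

    def n(self, nucleus: str) -> int:
        return self.layouts[nucleus].n

    def copy(self) -> "Circuit":
        return copy.deepcopy(self)


def _build_graph(network_type, pre, post, n_out, label, rng,
                 P=0.1, d=0.15, allow_self=True):
    if network_type == "N":
        return build_n_network(pre, post, n_out, label, allow_self=allow_self)
    if network_type == "D":
        base = build_n_network(pre, post, n_out, label, allow_self=allow_self)
        return build_d_network(base, pre, post, P, d, rng, allow_self=allow_self)
    if network_type == "S":
        return build_s_network(pre, post, n_out, label, allow_self=allow_self)
    raise ValueError(f"unknown network type {network_type!r}")


def build_circuit(
    network_type: str = "N",
    preset: str = "n3",
    structure_seed: int = 0,
    sizes: dict[str, int] | None = None,
    P: float = 0.1,
    d: float = 0.15,
    mu_scale: float = 1.0,
    conductances: dict | None = None,
) -> Circuit:
    """Place the four populations and wire all projections.

    ``preset`` selects a fitted conductance set (see
    :data:`CONDUCTANCE_PRESETS`); individual values can be overridden via
    ``conductances``.  ``network_type`` is "N", "D" (fraction ``P`` of
    edges displaced by ``d``) or "S" (every second target skipped).
    """
    sz = dict(SIZES)
    if sizes:
        sz.update(sizes)
    cond = dict(CONDUCTANCE_PRESETS[preset])
    if conductances:
        cond.update(conductances)
    projections = default_projections(mu_scale=mu_scale, **cond)

    rng = np.random.default_rng(structure_seed)
    layouts = {
        name: place_neurons(sz[name], 1.0, OFFSET_SCALE[name], rng, nucleus=name)
        for name in ("CTX", "MSN", "STN", "GPe")
    }

    n_out = {
        "CTX->STN": projections["CTX->STN:AMPA"].N_out,
        "GPe->STN": projections["GPe->STN:GABA"].N_out,
        "STN->GPe": projections["STN->GPe:AMPA"].N_out,
        "MSN->GPe": projections["MSN->GPe:GABA"].N_out,
        "GPe->GPe": projections["GPe->GPe:GABA"].N_out,
    }
    graphs = {}
    for label, no in n_out.items():
        src, dst = label.split("->")
        allow_self = label != "GPe->GPe"
        graphs[label] = _build_graph(network_type, layouts[src], layouts[dst],
                                     no, label, rng, P=P, d=d,
                                     allow_self=allow_self)

    # CTX -> MSN association: coordinate-nearest MSN per cortical generator.
    s_msn = layouts["MSN"].s
    ctx_msn = np.array([int(np.argmin(np.abs(s_msn - s)))
                        for s in layouts["CTX"].s], dtype=np.int64)

    return Circuit(layouts=layouts, graphs=graphs, projections=projections,
                   ctx_msn=ctx_msn, network_type=network_type,
                   structure_seed=structure_seed)


def lesion_inputs(circuit: Circuit, projection: str,
                  target_ids: np.ndarray | list[int]) -> Circuit:
    """Remove all edges of ``projection`` into the given target neurons.

    Returns a modified copy; everything else is untouched.
    """
    if projection not in circuit.graphs:
        raise KeyError(f"unknown projection {projection!r}")
    out = circuit.copy()
    g = out.graphs[projection]
    keep = ~np.isin(g.post, np.asarray(target_ids))
    out.graphs[projection] = NetworkGraph(
        g.projection, g.pre[keep], g.post[keep], g.displaced[keep])
    return out


def substitute_poisson(circuit: Circuit, nucleus: str, rate_hz: float) -> Circuit:
    """Replace the STN or GPe neurons by Poisson generators at ``rate_hz``.

    The generators keep the nucleus's coordinates and outgoing projections;
    they have no intrinsic dynamics, so their rate is invariant to synaptic
    input.
    """
    if nucleus not in ("STN", "GPe"):
        raise ValueError("only STN or GPe can be substituted")
    out = circuit.copy()
    if nucleus == "STN":
        out.stn_poisson_rate = rate_hz
    else:
        out.gpe_poisson_rate = rate_hz
    return out
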