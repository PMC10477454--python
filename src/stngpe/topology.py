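"""Placement of neurons on the feature axis and topographic network builders.

Every nucleus lives on a one-dimensional feature (somatotopic) axis
s in [-L/2, L/2], L = 1.  Three wiring schemes are provided:

* N-network -- each presynaptic neuron contacts its ``N_out`` coordinate-
  nearest postsynaptic neurons (intact somatotopy).
* D-network -- an N-network in which a random fraction ``P`` of edges is
  rewired to targets displaced by ``d`` along the axis (perturbed map).
* S-network -- as N, but only every second postsynaptic neuron (by index,
  starting from the nearest) is eligible, doubling the projection span.

Small random coordinate offsets make all pairwise distances distinct so the
constructions are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationLayout",
    "NetworkGraph",
    "place_neurons",
    "build_n_network",
    "build_d_network",
    "build_s_network",
    "validate_graph",
]

#: default per-neuron coordinate-offset scales (units of L)
OFFSET_SCALE = {"CTX": 1e-4, "MSN": 1e-4, "STN": 1e-3, "GPe": 1e-3}


@dataclass
class PopulationLayout:
    """Coordinates of one nucleus on the feature axis."""

    nucleus: str
    s: np.ndarray  # sorted coordinates, shape (n,)
    offset_scale: float = 0.0

    @property
    def n(self) -> int:
        return len(self.s)

    def centre_indices(self, fraction: float = 1.0 / 3.0) -> np.ndarray:
        """Indices of neurons with |s| < fraction/2 (centre band)."""
        return np.flatnonzero(np.abs(self.s) < fraction / 2.0)


@dataclass
class NetworkGraph:
    """Directed edge list of one projection."""

    projection: str
    pre: np.ndarray   # presynaptic indices
    post: np.ndarray  # postsynaptic indices
    displaced: np.ndarray = field(default=None)  # bool flags (D-networks)

    def __post_init__(self) -> None:
        if self.displaced is None:
            self.displaced = np.zeros(len(self.pre), dtype=bool)

    @property
    def n_edges(self) -> int:
        return len(self.pre)


def place_neurons(n: int, L: float = 1.0, offset_scale: float = 0.0,
                  rng: np.random.Generator | None = None,
                  nucleus: str = "") -> PopulationLayout:
    """Equidistant grid on [-L/2, L/2] plus per-neuron uniform offsets.

    Offsets are drawn uniformly from [0, offset_scale]; they break distance
    ties so that network construction is independent of edge-insertion order.
    """
    if n < 2:
        raise ValueError("need at least two neurons")
    s = np.linspace(-L / 2.0, L / 2.0, n)
    if offset_scale > 0:
        if rng is None:
            rng = np.random.default_rng()
        s = s + rng.uniform(0.0, offset_scale, size=n)
    return PopulationLayout(nucleus=nucleus, s=s, offset_scale=offset_scale)


def _nearest_targets(s_pre: float, s_post: np.ndarray, n_out: int,
                     exclude: int | None = None,
                     candidates: np.ndarray | None = None) -> np.ndarray:
    idx = np.arange(len(s_post)) if candidates is None else candidates
    if exclude is not None:
        idx = idx[idx != exclude]
    order = np.argsort(np.abs(s_post[idx] - s_pre), kind="stable")
    return idx[order[:n_out]]


def build_n_network(pre: PopulationLayout, post: PopulationLayout,
                    n_out: int, projection: str = "",
                    allow_self: bool = True) -> NetworkGraph:
    """Each presynaptic neuron targets its ``n_out`` nearest postsynaptic
    neurons by |s_post - s_pre| (ties broken by the random offsets).

    ``allow_self`` is set False for GPe->GPe so neurons never self-connect
    (pre and post must then be the same layout).
    """
    max_targets = post.n - (0 if allow_self else 1)
    if n_out > max_targets:
        raise ValueError("n_out exceeds the number of available targets")
    pres, posts = [], []
    for i in range(pre.n):
        exclude = None if allow_self else i
        tgt = _nearest_targets(pre.s[i], post.s, n_out, exclude=exclude)
        pres.extend([i] * n_out)
        posts.extend(tgt.tolist())
    return NetworkGraph(projection=projection,
                        pre=np.asarray(pres, dtype=np.int64),
                        post=np.asarray(posts, dtype=np.int64))


def build_d_network(base: NetworkGraph, pre: PopulationLayout,
                    post: PopulationLayout, P: float, d: float,
                    rng: np.random.Generator,
                    allow_self: bool = True) -> NetworkGraph:
    """Rewire a random fraction ``P`` of edges to displaced targets.

    Exactly round(P * n_edges) edges, drawn uniformly without replacement,
    are retargeted to the postsynaptic neuron minimizing |(s_post - d) -
    s_pre|; if that neuron is already a target of the same presynaptic
    neuron, the next-nearest displaced target is used so per-pre targets
    stay distinct.  Displaced targets whose shifted coordinate would fall
    outside the layout clamp to the nearest existing neuron.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    n_rewire = int(round(P * base.n_edges))
    new_post = base.post.copy()
    displaced = np.zeros(base.n_edges, dtype=bool)
    if n_rewire == 0:
        return NetworkGraph(base.projection, base.pre.copy(), new_post, displaced)
    chosen = rng.choice(base.n_edges, size=n_rewire, replace=False)
    for e in chosen:
        i = base.pre[e]
        taken = set(new_post[base.pre == i].tolist()) - {base.post[e]}
        exclude = None if allow_self else int(i)
        order = _nearest_targets(pre.s[i] + 0.0, post.s - d, post.n,
                                 exclude=exclude)
        for j in order:
            if int(j) not in taken:
                new_post[e] = j
                break
        displaced[e] = True
    return NetworkGraph(base.projection, base.pre.copy(), new_post, displaced)


def build_s_network(pre: PopulationLayout, post: PopulationLayout,
                    n_out: int, projection: str = "",
                    allow_self: bool = True) -> NetworkGraph:
    """Skipping topology: only every second postsynaptic neuron is eligible.

    For each presynaptic neuron the nearest postsynaptic neuron anchors the
    eligible set (same index parity); the ``n_out`` nearest eligible
    neurons are targeted, roughly doubling the projection span.
    """
    if n_out > int(np.ceil(post.n / 2)):
        raise ValueError("n_out too large for a skipping projection")
    pres, posts = [], []
    all_idx = np.arange(post.n)
    for i in range(pre.n):
        exclude = None if allow_self else i
        anchor = _nearest_targets(pre.s[i], post.s, 1, exclude=exclude)[0]
        candidates = all_idx[all_idx % 2 == anchor % 2]
        tgt = _nearest_targets(pre.s[i], post.s, n_out, exclude=exclude,
                               candidates=candidates)
        pres.extend([i] * n_out)
        posts.extend(tgt.tolist())
    return NetworkGraph(projection=projection,
                        pre=np.asarray(pres, dtype=np.int64),
                        post=np.asarray(posts, dtype=np.int64))


def validate_graph(graph: NetworkGraph, n_pre: int, n_post: int,
                   n_out: int, allow_self: bool = True) -> dict:
    """Check structural invariants; violations are reported, not raised.

    Returns a report with the violation list, the out-degree of every
    presynaptic neuron and the in-degree histogram (the latter is the
    substrate of the D-network multimodality analysis).
    """
    violations = []
    out_deg = np.bincount(graph.pre, minlength=n_pre)
    if not np.all(out_deg == n_out):
        violations.append(f"out-degree != {n_out} for "
                          f"{int(np.sum(out_deg != n_out))} neurons")
    if not allow_self and np.any(graph.pre == graph.post):
        violations.append("self-edges present")
    for i in np.unique(graph.pre):
        targets = graph.post[graph.pre == i]
        if len(np.unique(targets)) != len(targets):
            violations.append(f"duplicate targets for presynaptic neuron {i}")
            break
    in_deg = np.bincount(graph.post, minlength=n_post)
    return {
        "ok": not violations,
        "violations": violations,
        "out_degree": out_deg,
        "in_degree": in_deg,
        "in_degree_hist": np.bincount(in_deg),
    }
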