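"""Euler-Maruyama simulation of the circuit and spike-record handling.

The engine integrates the whole circuit at a fixed step (0.05 ms by
default), records every reset time as a spike time, and is fully
deterministic given the two seeds: the *heterogeneity* seed fixes
capacitances and initial conditions, the *noise* seed fixes membrane noise,
Poisson generators and stimulus recruitment.  Trials in the sense of the
analysis layer share the heterogeneity seed and differ in the noise seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .network import Circuit
from .neurons import GpeParams, StnParams, sample_capacitances
from .stimulation import MsnResponseKernel, StimulationProtocol, build_schedule, msn_rate_kernel
from .topology import NetworkGraph

__all__ = [
    "SimulationConfig",
    "SpikeRecord",
    "run_simulation",
    "run_trials",
    "mean_rate",
    "centre_subset",
    "integrate_neuron",
]

NUCLEI = ("CTX", "MSN", "STN", "GPe")


@dataclass
class SimulationConfig:
    """Run-level settings (durations in ms)."""

    duration: float
    dt: float = 0.05
    protocol: StimulationProtocol | None = None
    msn_kernel: MsnResponseKernel = field(default_factory=MsnResponseKernel)
    record_ctx: bool = False
    record_msn: bool = False
    record_trace: bool = False  # v(t) of neuron 0 in STN and GPe
    noise_form: str = "sqrt"    # "sqrt" (default) or "literal"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.noise_form not in ("sqrt", "literal"):
            raise ValueError("noise_form must be 'sqrt' or 'literal'")


@dataclass
class SpikeRecord:
    """Spike times per nucleus plus run metadata.

    ``spikes[nucleus]`` is a pair (neuron indices, spike times in ms),
    time-ordered.  Coordinates of every neuron are kept so analyses can
    select by feature-axis position.
    """

    spikes: dict[str, tuple[np.ndarray, np.ndarray]]
    coords: dict[str, np.ndarray]
    duration: float
    dt: float
    stim_events: list[tuple[float, float]]
    meta: dict = field(default_factory=dict)
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    def counts(self, nucleus: str, window: tuple[float, float],
               subset: np.ndarray | None = None) -> np.ndarray:
        """Per-neuron spike counts within [window[0], window[1]) ms."""
        ids, times = self.spikes[nucleus]
        n = len(self.coords[nucleus])
        m = (times >= window[0]) & (times < window[1])
        counts = np.bincount(ids[m], minlength=n)
        return counts if subset is None else counts[np.asarray(subset)]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for nuc, (ids, times) in self.spikes.items():
            frames.append(pd.DataFrame(
                {"nucleus": nuc, "neuron_id": ids, "time_ms": times}))
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save_hdf5(self, path) -> None:
        """Columnar HDF5 layout: /spikes/<nucleus>/{ids,times},
        /coords/<nucleus>, run metadata as root attributes."""
        import h5py

        with h5py.File(path, "w") as f:
            for nuc, (ids, times) in self.spikes.items():
                g = f.create_group(f"spikes/{nuc}")
                g.create_dataset("ids", data=ids)
                g.create_dataset("times_ms", data=times)
            for nuc, s in self.coords.items():
                f.create_dataset(f"coords/{nuc}", data=s)
            if self.stim_events:
                f.create_dataset("stim_events",
                                 data=np.asarray(self.stim_events))
            f.attrs["duration_ms"] = self.duration
            f.attrs["dt_ms"] = self.dt
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str)):
                    f.attrs[k] = v

    @classmethod
    def load_hdf5(cls, path) -> "SpikeRecord":
        import h5py

        with h5py.File(path, "r") as f:
            spikes = {nuc: (f[f"spikes/{nuc}/ids"][:],
                            f[f"spikes/{nuc}/times_ms"][:])
                      for nuc in f["spikes"]}
            coords = {nuc: f[f"coords/{nuc}"][:] for nuc in f["coords"]}
            events = [tuple(row) for row in f["stim_events"][:]] \
                if "stim_events" in f else []
            meta = {k: v for k, v in f.attrs.items()
                    if k not in ("duration_ms", "dt_ms")}
            return cls(spikes=spikes, coords=coords,
                       duration=float(f.attrs["duration_ms"]),
                       dt=float(f.attrs["dt_ms"]),
                       stim_events=events, meta=dict(meta))


def centre_subset(nucleus: str, n: int) -> np.ndarray:
    """Default analysis subsets away from the axis borders.

    STN: the centre third (indices 33..66 for n = 100); GPe: the centre 100
    neurons, |s| < 1/6, (indices 100..199 for n = 300).
    """
    if nucleus == "STN":
        return np.arange(n // 3, 2 * n // 3 + 1)
    return np.arange(n // 3, 2 * n // 3)


def _csr(graph: NetworkGraph, n_pre: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(graph.pre, kind="stable")
    indices = graph.post[order].astype(np.int64)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(indptr, graph.pre + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, indices


def _msn_table(kernel: MsnResponseKernel, dt: float) -> np.ndarray:
    """Per-step MSN spike probability vs step lag since CTX recruitment."""
    n = int(np.ceil((kernel.ctx_msn_delay + kernel.duration) / dt))
    lags = np.arange(n) * dt - kernel.ctx_msn_delay
    out = np.empty(n)
    for i, x in enumerate(lags):
        out[i] = (kernel.r_msn if x <= 0 else msn_rate_kernel(x, kernel)) * dt
    return out


def _noise_sd(theta: float, dt: float, form: str) -> float:
    if form == "literal":
        return 2.0 * theta * np.sqrt(dt)
    return np.sqrt(2.0 * theta * dt)


def run_simulation(circuit: Circuit, config: SimulationConfig,
                   het_seed: int = 0, noise_seed: int = 1) -> SpikeRecord:
    """Integrate ``circuit`` for ``config.duration`` ms.

    Raises ``FloatingPointError`` on numerical blow-up (non-finite membrane
    potential at the end of the run).
    """
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    n_ctx, n_msn = circuit.n("CTX"), circuit.n("MSN")
    n_stn, n_gpe = circuit.n("STN"), circuit.n("GPe")
    gp: GpeParams = circuit.gpe_params
    sp: StnParams = circuit.stn_params

    het = np.random.default_rng(het_seed)
    stn_C = sample_capacitances(sp.C_mean, n_stn, het)
    gpe_C = sample_capacitances(gp.C_mean, n_gpe, het)
    stn_v = het.uniform(sp.v_r, sp.v_t, n_stn)
    gpe_v = het.uniform(gp.v_r, gp.v_t, n_gpe)
    stn_u1 = np.zeros(n_stn)
    stn_u2 = np.zeros(n_stn)
    gpe_u1 = np.zeros(n_gpe)

    pj = circuit.projections
    steps_of = lambda ms: int(round(ms / dt))
    d_cs = steps_of(pj["CTX->STN:AMPA"].delay)
    d_gs = steps_of(pj["GPe->STN:GABA"].delay)
    d_sg = steps_of(pj["STN->GPe:AMPA"].delay)
    d_mg = steps_of(pj["MSN->GPe:GABA"].delay)
    d_gg = steps_of(pj["GPe->GPe:GABA"].delay)

    cs = _csr(circuit.graphs["CTX->STN"], n_ctx)
    gs = _csr(circuit.graphs["GPe->STN"], n_gpe)
    sg = _csr(circuit.graphs["STN->GPe"], n_stn)
    mg = _csr(circuit.graphs["MSN->GPe"], n_msn)
    gg = _csr(circuit.graphs["GPe->GPe"], n_gpe)

    # stimulus schedule -> step indices (must fit within the run)
    if config.protocol is not None:
        events = build_schedule(config.protocol)
        if events and events[-1][0] >= config.duration:
            raise ValueError("stimulation schedule exceeds the run duration")
        stim_steps = np.array([steps_of(t) for t, _ in events], dtype=np.int64)
        stim_s0 = np.array([s for _, s in events], dtype=np.float64)
        sigma_s = config.protocol.sigma_s
        kernel = config.msn_kernel
    else:
        events = []
        stim_steps = np.empty(0, dtype=np.int64)
        stim_s0 = np.empty(0, dtype=np.float64)
        sigma_s = 1.0
        kernel = config.msn_kernel
    msn_table = _msn_table(kernel, dt)

    stn_sub = circuit.stn_poisson_rate is not None
    gpe_sub = circuit.gpe_poisson_rate is not None
    p_stn_sub = (circuit.stn_poisson_rate or 0.0) * 1e-3 * dt
    p_gpe_sub = (circuit.gpe_poisson_rate or 0.0) * 1e-3 * dt

    noiseG = _noise_sd(gp.theta, dt, config.noise_form)
    noiseS = _noise_sd(sp.theta, dt, config.noise_form)

    T_ms = config.duration
    est = ((n_ctx * circuit.r_ctx + len(events) * 80.0 / max(T_ms, 1.0)
            + n_msn * circuit.r_msn) * (config.record_ctx or config.record_msn)
           + (n_stn + n_gpe) * 0.12) * T_ms
    cap = int(3 * est) + 200_000

    n_trace = n_steps + 1 if config.record_trace else 0
    trace_stn = np.zeros(n_trace)
    trace_gpe = np.zeros(n_trace)

    chunk = 4000  # steps per kernel call (noise pre-generated per chunk)
    for _attempt in range(4):
        spike_id = np.empty(cap, dtype=np.int32)
        spike_t = np.empty(cap, dtype=np.int32)
        stn_state = (stn_v.copy(), stn_u1.copy(), stn_u2.copy())
        gpe_state = (gpe_v.copy(), gpe_u1.copy())
        buf_cs = np.zeros((d_cs + 1, n_stn))
        buf_gs = np.zeros((d_gs + 1, n_stn))
        buf_sg = np.zeros((d_sg + 1, n_gpe))
        buf_mg = np.zeros((d_mg + 1, n_gpe))
        buf_gg = np.zeros((d_gg + 1, n_gpe))
        g_stn = [np.zeros(n_stn) for _ in range(4)]
        g_gpe = [np.zeros(n_gpe) for _ in range(5)]
        msn_t0 = np.full(n_msn, -1, dtype=np.int64)
        active = np.zeros(max(n_msn, 1), dtype=np.int64)
        cursor = np.zeros(3, dtype=np.int64)
        noise_rng = np.random.default_rng(int(noise_seed) + (1 << 32))
        overflow = 0
        for step0 in range(0, n_steps, chunk):
            nk = min(chunk, n_steps - step0)
            if not stn_sub and noiseS > 0.0:
                stn_noise = noise_rng.standard_normal((nk, n_stn))
            else:
                stn_noise = np.zeros((nk, max(n_stn, 1)))
            if not gpe_sub and noiseG > 0.0:
                gpe_noise = noise_rng.standard_normal((nk, n_gpe))
            else:
                gpe_noise = np.zeros((nk, max(n_gpe, 1)))
            overflow = _kernel.run_chunk(
                step0, nk, dt, int(noise_seed) % (2 ** 31),
                n_ctx, n_msn, n_stn, n_gpe,
                circuit.r_ctx * dt, circuit.r_msn * dt,
                int(stn_sub), p_stn_sub, int(gpe_sub), p_gpe_sub,
                gp.k, gp.v_r, gp.v_t, gp.a, gp.b, gp.v_peak, gp.c, gp.d,
                gp.I_bias, noiseG,
                sp.k, sp.v_r, sp.v_t, sp.a, sp.b, sp.v_peak, sp.c, sp.d,
                sp.I_bias, noiseS,
                sp.w, sp.v_r_tilde, sp.a_tilde, sp.b_tilde, sp.d_tilde,
                stn_C, *stn_state, gpe_C, *gpe_state,
                *cs, *gs, *sg, *mg, *gg, circuit.ctx_msn,
                pj["CTX->STN:AMPA"].G, pj["CTX->STN:NMDA"].G,
                pj["GPe->STN:GABA"].G,
                pj["STN->GPe:AMPA"].G, pj["STN->GPe:NMDA"].G,
                pj["MSN->GPe:GABA"].G, pj["GPe->GPe:GABA"].G,
                0.0, pj["GPe->STN:GABA"].E, pj["MSN->GPe:GABA"].E,
                1.0 - dt / pj["CTX->STN:AMPA"].tau,
                1.0 - dt / pj["CTX->STN:NMDA"].tau_decay,
                1.0 - dt / pj["CTX->STN:NMDA"].tau,
                1.0 - dt / pj["GPe->STN:GABA"].tau,
                1.0 - dt / pj["MSN->GPe:GABA"].tau,
                d_cs, d_gs, d_sg, d_mg, d_gg,
                buf_cs, buf_gs, buf_sg, buf_mg, buf_gg,
                *g_stn, *g_gpe,
                stim_steps, stim_s0, circuit.layouts["CTX"].s, sigma_s,
                msn_table, stn_noise, gpe_noise,
                int(config.record_ctx), int(config.record_msn),
                spike_id, spike_t, trace_stn, trace_gpe,
                msn_t0, active, cursor,
            )
            if overflow:
                break
        ns = int(cursor[0])
        if not overflow:
            break
        cap *= 2
    else:
        raise RuntimeError("spike buffer overflow after repeated retries")

    if not stn_sub and n_stn and not np.all(np.isfinite(stn_state[0])):
        raise FloatingPointError("STN membrane potential diverged")
    if not gpe_sub and n_gpe and not np.all(np.isfinite(gpe_state[0])):
        raise FloatingPointError("GPe membrane potential diverged")

    gid = spike_id[:ns].astype(np.int64)
    gt = spike_t[:ns].astype(np.float64) * dt
    offsets = {"CTX": 0, "MSN": n_ctx, "STN": n_ctx + n_msn,
               "GPe": n_ctx + n_msn + n_stn}
    sizes = {"CTX": n_ctx, "MSN": n_msn, "STN": n_stn, "GPe": n_gpe}
    spikes = {}
    for nuc in NUCLEI:
        m = (gid >= offsets[nuc]) & (gid < offsets[nuc] + sizes[nuc])
        spikes[nuc] = (gid[m] - offsets[nuc], gt[m])

    traces = {}
    if config.record_trace:
        if not stn_sub:
            traces["STN"] = trace_stn
        if not gpe_sub:
            traces["GPe"] = trace_gpe

    return SpikeRecord(
        spikes=spikes,
        coords={nuc: circuit.layouts[nuc].s.copy() for nuc in NUCLEI},
        duration=config.duration, dt=dt, stim_events=events,
        meta={"het_seed": het_seed, "noise_seed": noise_seed,
              "network_type": circuit.network_type,
              "noise_form": config.noise_form},
        traces=traces,
    )


def run_trials(circuit: Circuit, config: SimulationConfig, n_trials: int,
               het_seed: int = 0, noise_seed: int = 1) -> list[SpikeRecord]:
    """Repeat a run with shared heterogeneity and fresh noise per trial."""
    return [run_simulation(circuit, config, het_seed, noise_seed + 1000 * t)
            for t in range(n_trials)]


def mean_rate(record: SpikeRecord, nucleus: str,
              window: tuple[float, float] = (30_000.0, 40_000.0),
              subset: np.ndarray | None = None) -> float:
    """Population mean firing rate (Hz) over [window[0], window[1]) ms.

    ``subset`` defaults to the centre subset of the nucleus (see
    :func:`centre_subset`).
    """
    if window[1] > record.duration + record.dt:
        raise ValueError("window exceeds the simulated duration")
    n = len(record.coords[nucleus])
    if subset is None:
        subset = centre_subset(nucleus, n)
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty analysis subset")
    counts = record.counts(nucleus, window, subset)
    return float(counts.sum() / (len(subset) * (window[1] - window[0]) * 1e-3))


def integrate_neuron(params, I: float | np.ndarray, t_max: float,
                     dt: float = 0.05, v0: float | None = None,
                     C: float | None = None):
    """Forward-Euler integration of one isolated, noise-free neuron.

    ``I`` is a constant current or a per-step current array.  Returns
    (v trace including t=0, spike times in ms).  Used for single-neuron
    characterization and as the coarse side of step-refinement checks.
    """
    from .neurons import StnParams as _Stn

    is_stn = isinstance(params, _Stn)
    n = int(round(t_max / dt))
    I_arr = np.full(n, I, dtype=float) if np.isscalar(I) else np.asarray(I)
    C = C if C is not None else params.C_mean
    v = v0 if v0 is not None else params.v_r
    u1 = 0.0
    u2 = 0.0
    vs = np.empty(n + 1)
    vs[0] = v
    spikes = []
    for k in range(n):
        dvdt = params.k * (v - params.v_r) * (v - params.v_t) - u1 + I_arr[k]
        if is_stn:
            dvdt -= params.w * u2
            gate = 1.0 if v < params.v_r_tilde else 0.0
            u2n = u2 + dt * params.a_tilde * (
                gate * params.b_tilde * (v - params.v_r_tilde) - u2)
        vn = v + dt * dvdt / C
        u1n = u1 + dt * params.a * (params.b * (v - params.v_r) - u1)
        if is_stn:
            U = 1.0 / (params.w * abs(u2n) + 1.0 / params.w)
            if vn >= params.v_peak + U * u2n:
                spikes.append((k + 1) * dt)
                vn = params.c - U * u2n
                u1n += params.d
                u2n += params.d_tilde
            u2 = u2n
        else:
            if vn >= params.v_peak:
                spikes.append((k + 1) * dt)
                vn = params.c
                u1n += params.d
        v, u1 = vn, u1n
        vs[k + 1] = v
    return vs, np.asarray(spikes)
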