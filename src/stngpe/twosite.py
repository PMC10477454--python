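"""Two-site stimulation sweeps and priming-modulation surfaces.

For every grid point (delta_t, delta_s) two scenarios are simulated:

(i)  one-site stimulation of the test site at +delta_s/2 only, and
(ii) two-site stimulation: priming at -delta_s/2, then the test stimulus
     delta_t later at +delta_s/2.

The window-averaged responses F_(i), F_(ii) around the test site yield
``L_base`` (pre-test window T^-) and ``L_re`` (post-test window T^+).
Scenario (i) depends only on delta_s and is reused across the delta_t
rows; a second, independently seeded scenario-(i) run provides the
zero-priming noise floor used by the channel-width estimate.
"""

from __future__ import annotations

import numpy as np

from .analysis import (A_WIDTH, T_MINUS, T_PLUS, ModulationSurface,
                       compute_psth, l_base, l_re, window_average_response)
from .engine import SimulationConfig, SpikeRecord, run_trials
from .network import Circuit
from .stimulation import DEFAULT_SIGMA_S, StimulationProtocol, alignment_onsets

__all__ = ["two_site_sweep", "response_functions"]

_MARGIN = 250.0  # ms of data kept after the last test onset


def _run_protocol(circuit: Circuit, protocol: StimulationProtocol,
                  n_trials: int, het_seed: int, noise_seed: int,
                  dt: float) -> tuple[list[SpikeRecord], np.ndarray]:
    onsets = alignment_onsets(protocol)
    duration = float(onsets[-1] + T_PLUS + _MARGIN)
    cfg = SimulationConfig(duration=duration, dt=dt, protocol=protocol)
    recs = run_trials(circuit, cfg, n_trials, het_seed, noise_seed)
    return recs, onsets


def response_functions(records: list[SpikeRecord], nucleus: str,
                       onsets: np.ndarray, site: float,
                       a_width: float = A_WIDTH,
                       t_minus: float = T_MINUS,
                       t_plus: float = T_PLUS):
    """Window-averaged response F(t | site) and its lag axis."""
    coords = records[0].coords[nucleus]
    subset = np.flatnonzero(np.abs(coords - site) <= a_width / 2.0)
    psth = compute_psth(records, nucleus, onsets, subset=subset,
                        window=(-t_minus - 10.0, t_plus + 10.0))
    F = window_average_response(psth, coords, site, a_width)
    return F, psth.lags


def two_site_sweep(circuit: Circuit, delta_t: np.ndarray, delta_s: np.ndarray,
                   nuclei: tuple[str, ...] = ("STN", "GPe"),
                   n_stimuli: int = 500, n_trials: int = 1,
                   period: float = 1700.0, warmup: float = 40_000.0,
                   sigma_s: float = DEFAULT_SIGMA_S, dt: float = 0.05,
                   a_width: float = A_WIDTH, t_minus: float = T_MINUS,
                   t_plus: float = T_PLUS, het_seed: int = 0,
                   noise_seed: int = 1, compute_floor: bool = True) -> dict:
    """Compute L_base / L_re surfaces over the (delta_t, delta_s) grid.

    Returns {nucleus: ModulationSurface}; each surface's ``meta`` carries
    the zero-priming floor statistics ``floor_l_base`` / ``floor_l_re``
    (arrays over delta_s) when ``compute_floor`` is set.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    delta_s = np.asarray(delta_s, dtype=float)
    shape = (len(delta_t), len(delta_s))
    Lb = {nuc: np.zeros(shape) for nuc in nuclei}
    Lr = {nuc: np.zeros(shape) for nuc in nuclei}
    floor_b = {nuc: np.zeros(len(delta_s)) for nuc in nuclei}
    floor_r = {nuc: np.zeros(len(delta_s)) for nuc in nuclei}

    for j, ds in enumerate(delta_s):
        site = ds / 2.0
        proto_i = StimulationProtocol("one-site", period, n_stimuli,
                                      sigma_s, s0=site, warmup=warmup)
        rec_i, on_i = _run_protocol(circuit, proto_i, n_trials,
                                    het_seed, noise_seed + 17 * j, dt)
        F_i = {nuc: response_functions(rec_i, nuc, on_i, site, a_width,
                                       t_minus, t_plus) for nuc in nuclei}
        if compute_floor:
            rec_0, on_0 = _run_protocol(circuit, proto_i, n_trials,
                                        het_seed, noise_seed + 17 * j + 7, dt)
            for nuc in nuclei:
                F0, lags = response_functions(rec_0, nuc, on_0, site,
                                              a_width, t_minus, t_plus)
                floor_b[nuc][j] = l_base(F0, F_i[nuc][0], lags, t_minus)
                floor_r[nuc][j] = l_re(F0, F_i[nuc][0], lags, t_plus)
        for i, dtau in enumerate(delta_t):
            proto_ii = StimulationProtocol(
                "two-site", period, n_stimuli, sigma_s,
                delta_s=float(ds), delta_t=float(dtau), warmup=warmup)
            rec_ii, on_ii = _run_protocol(circuit, proto_ii, n_trials,
                                          het_seed,
                                          noise_seed + 1009 * (i + 1) + j, dt)
            for nuc in nuclei:
                F_ii, lags = response_functions(rec_ii, nuc, on_ii, site,
                                                a_width, t_minus, t_plus)
                Lb[nuc][i, j] = l_base(F_ii, F_i[nuc][0], lags, t_minus)
                Lr[nuc][i, j] = l_re(F_ii, F_i[nuc][0], lags, t_plus)

    out = {}
    for nuc in nuclei:
        meta = {"n_stimuli": n_stimuli, "n_trials": n_trials,
                "network_type": circuit.network_type}
        if compute_floor:
            meta["floor_l_base"] = floor_b[nuc]
            meta["floor_l_re"] = floor_r[nuc]
        out[nuc] = ModulationSurface(delta_t=delta_t, delta_s=delta_s,
                                     l_base=Lb[nuc], l_re=Lr[nuc],
                                     nucleus=nuc, t_minus=t_minus,
                                     t_plus=t_plus, a_width=a_width,
                                     meta=meta)
    return out
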