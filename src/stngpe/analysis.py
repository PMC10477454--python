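"""Peristimulus analyses: PSTHs, rate distributions, spatio-temporal maps,
two-site priming-modulation statistics and functional-channel width.

All estimators work on :class:`~stngpe.engine.SpikeRecord` objects.  PSTHs
are per-bin spike probabilities relative to the closest stimulus onset
(1 ms bins); the two-site statistics ``L_base``/``L_re`` integrate the
squared difference between the primed and unprimed window-averaged
responses before and after the test stimulus, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .engine import SpikeRecord, centre_subset

__all__ = [
    "PSTH",
    "RateHistogram",
    "SpatioTemporalMap",
    "ModulationSurface",
    "compute_psth",
    "rate_distribution",
    "count_modes",
    "spatiotemporal_map",
    "window_average_response",
    "l_base",
    "l_re",
    "channel_width",
]

T_MINUS = 190.0  # ms, pre-test integration window of L_base
T_PLUS = 200.0   # ms, post-test integration window of L_re
A_WIDTH = 0.045  # coordinate-averaging width (units of L)


@dataclass
class PSTH:
    """Per-neuron spike probability per 1 ms lag bin.

    ``prob`` has shape (n_neurons_in_subset, n_bins); ``mean`` averages over
    the subset.  Multi-trial averages are means of per-trial PSTHs.
    """

    edges: np.ndarray            # bin edges, ms relative to onset
    prob: np.ndarray
    subset: np.ndarray
    n_stimuli: int
    n_trials: int = 1

    @property
    def lags(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def mean(self) -> np.ndarray:
        return self.prob.mean(axis=0)


@dataclass
class RateHistogram:
    rates: np.ndarray            # per-neuron rates pooled over trials, Hz
    subset: np.ndarray
    window: tuple[float, float]
    n_trials: int


@dataclass
class SpatioTemporalMap:
    """Trial-averaged instantaneous rate p(t, s) per coordinate bin."""

    lag_edges: np.ndarray
    coord_edges: np.ndarray
    rate: np.ndarray             # (n_coord_bins, n_lag_bins), prob/ms/neuron
    nucleus: str
    n_stimuli: int
    n_trials: int


@dataclass
class ModulationSurface:
    """L_base / L_re over a (delta_t, delta_s) grid for one nucleus."""

    delta_t: np.ndarray
    delta_s: np.ndarray
    l_base: np.ndarray           # (n_dt, n_ds)
    l_re: np.ndarray
    nucleus: str
    t_minus: float = T_MINUS
    t_plus: float = T_PLUS
    a_width: float = A_WIDTH
    meta: dict = field(default_factory=dict)


def compute_psth(record: SpikeRecord | list[SpikeRecord], nucleus: str,
                 onsets: np.ndarray, subset: np.ndarray | None = None,
                 bin_width: float = 1.0,
                 window: tuple[float, float] = (-100.0, 300.0)) -> PSTH:
    """Spike probability per bin relative to stimulus onset.

    Counts are averaged over stimuli within a trial and then over trials
    (each record is one trial).  ``onsets`` must lie within every record.
    """
    records = record if isinstance(record, list) else [record]
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one stimulus onset")
    for r in records:
        if onsets.max() >= r.duration or onsets.min() < 0:
            raise ValueError("stimulus onsets outside the record")
    n = len(records[0].coords[nucleus])
    if subset is None:
        subset = centre_subset(nucleus, n)
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty neuron subset")
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    nb = len(edges) - 1
    pos = {int(i): k for k, i in enumerate(subset)}
    acc = np.zeros((len(subset), nb))
    for r in records:
        ids, times = r.spikes[nucleus]
        keep = np.isin(ids, subset)
        ids, times = ids[keep], times[keep]
        counts = np.zeros((len(subset), nb))
        # lag of each spike relative to the closest onset
        j = np.searchsorted(onsets, times)
        left = onsets[np.clip(j - 1, 0, len(onsets) - 1)]
        right = onsets[np.clip(j, 0, len(onsets) - 1)]
        lag = np.where(np.abs(times - left) <= np.abs(times - right),
                       times - left, times - right)
        m = (lag >= window[0]) & (lag < window[1])
        b = ((lag[m] - window[0]) // bin_width).astype(int)
        rows = np.array([pos[int(i)] for i in ids[m]], dtype=int)
        np.add.at(counts, (rows, b), 1.0)
        acc += counts / len(onsets)
    return PSTH(edges=edges, prob=acc / len(records), subset=subset,
                n_stimuli=len(onsets), n_trials=len(records))


def rate_distribution(records: list[SpikeRecord], nucleus: str,
                      windows: list[tuple[float, float]] | None = None,
                      subset: np.ndarray | None = None) -> RateHistogram:
    """Per-neuron mean rates pooled over trials (and rate windows).

    Default window: 9 s starting after 31 s of settling.  A single long
    record may supply several consecutive windows.
    """
    if windows is None:
        windows = [(31_000.0, 40_000.0)]
    n = len(records[0].coords[nucleus])
    if subset is None:
        subset = centre_subset(nucleus, n)
    subset = np.asarray(subset)
    rates = []
    for r in records:
        for w in windows:
            c = r.counts(nucleus, w, subset)
            rates.append(c / ((w[1] - w[0]) * 1e-3))
    return RateHistogram(rates=np.concatenate(rates), subset=subset,
                        window=windows[0], n_trials=len(records) * len(windows))


def count_modes(rates: np.ndarray, prominence: float = 0.08,
                grid: int = 512) -> int:
    """Number of modes of a rate sample, via KDE peak counting.

    Peaks of the Gaussian-KDE density with prominence above ``prominence``
    times the density maximum are counted as modes.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.std() == 0:
        return 1
    kde = gaussian_kde(rates)
    lo, hi = rates.min() - 2.0, rates.max() + 2.0
    x = np.linspace(lo, hi, grid)
    dens = kde(x)
    peaks, _ = find_peaks(dens, prominence=prominence * dens.max())
    return max(1, len(peaks))


def spatiotemporal_map(records: list[SpikeRecord], nucleus: str,
                       onsets: np.ndarray,
                       window: tuple[float, float] = (-100.0, 300.0),
                       coord_bin: float | None = None,
                       bin_width: float = 1.0) -> SpatioTemporalMap:
    """Trial-averaged instantaneous rate p(t, s) (prob/ms per neuron).

    Coordinate bins default to 0.01 L for STN/GPe and 0.001 L for CTX/MSN.
    """
    if coord_bin is None:
        coord_bin = 0.01 if nucleus in ("STN", "GPe") else 0.001
    coords = records[0].coords[nucleus]
    full = np.arange(len(coords))
    psth = compute_psth(records, nucleus, onsets, subset=full,
                        bin_width=bin_width, window=window)
    c_edges = np.arange(-0.5, 0.5 + coord_bin / 2, coord_bin)
    nb = len(c_edges) - 1
    rate = np.zeros((nb, psth.prob.shape[1]))
    counts = np.zeros(nb)
    rows = np.clip(((coords + 0.5) // coord_bin).astype(int), 0, nb - 1)
    for i, row in enumerate(rows):
        rate[row] += psth.prob[i]
        counts[row] += 1
    nzero = counts > 0
    rate[nzero] /= counts[nzero, None]
    return SpatioTemporalMap(lag_edges=psth.edges, coord_edges=c_edges,
                             rate=rate, nucleus=nucleus,
                             n_stimuli=len(onsets), n_trials=len(records))


def window_average_response(psth: PSTH, coords: np.ndarray, site: float,
                            a_width: float = A_WIDTH) -> np.ndarray:
    """Mean PSTH of the neurons with coordinates within site +- A/2.

    This is the response function F(t | site) entering the two-site
    statistics; ``psth`` must hold per-neuron rows for its subset and
    ``coords`` the full coordinate array of the nucleus.
    """
    if a_width <= 0:
        raise ValueError("averaging width must be positive")
    sel = np.abs(coords[psth.subset] - site) <= a_width / 2.0
    if not np.any(sel):
        raise ValueError("no neurons in the averaging window")
    return psth.prob[sel].mean(axis=0)


def _window_integral(F_ii: np.ndarray, F_i: np.ndarray, lags: np.ndarray,
                     lo: float, hi: float, bin_width: float) -> float:
    if F_ii.shape != F_i.shape:
        raise ValueError("misaligned response series")
    m = (lags >= lo) & (lags < hi)
    if not np.any(m):
        raise ValueError("integration window not covered by the series")
    d = F_ii[m] - F_i[m]
    return float(np.sum(d * d) * bin_width)


def l_base(F_ii: np.ndarray, F_i: np.ndarray, lags: np.ndarray,
           t_minus: float = T_MINUS, bin_width: float = 1.0) -> float:
    """Pre-test modulation: integral of |F_ii - F_i|^2 over [-T^-, 0).

    Lags are relative to the test-stimulus onset; the integral is a left
    Riemann sum on the PSTH grid.
    """
    return _window_integral(F_ii, F_i, lags, -t_minus, 0.0, bin_width)


def l_re(F_ii: np.ndarray, F_i: np.ndarray, lags: np.ndarray,
         t_plus: float = T_PLUS, bin_width: float = 1.0) -> float:
    """Evoked-response modulation: integral of |F_ii - F_i|^2 over [0, T^+)."""
    return _window_integral(F_ii, F_i, lags, 0.0, t_plus, bin_width)


def channel_width(surface: ModulationSurface, floor_values: np.ndarray,
                  statistic: str = "l_base", dt_index: int = -1,
                  n_floor_std: float = 3.0) -> dict:
    """Functional-channel width from a saturated-lag slice of the surface.

    The statistic (ln L) along delta_s at the chosen delta_t row is
    compared against a noise floor estimated from a zero-priming surrogate
    (``floor_values``: L statistics between independent unprimed runs).
    The width is the smallest delta_s at which the statistic drops below
    floor mean + ``n_floor_std`` floor std; if it never does, the width is
    flagged unbounded (the priming influence spans the probed range).
    """
    vals = getattr(surface, statistic)[dt_index]
    floor_values = np.asarray(floor_values, dtype=float)
    tiny = 1e-300
    floor_log = np.log(floor_values + tiny)
    thresh = floor_log.mean() + n_floor_std * max(floor_log.std(), 1e-12)
    logs = np.log(vals + tiny)
    below = np.flatnonzero(logs <= thresh)
    if np.all(logs <= thresh):
        width, unbounded = 0.0, False
    elif below.size == 0:
        width, unbounded = float(surface.delta_s[-1]), True
    else:
        width, unbounded = float(surface.delta_s[below[0]]), False
    return {"width": width, "unbounded": unbounded,
            "floor_log_mean": float(floor_log.mean()),
            "floor_log_std": float(floor_log.std()),
            "statistic_log": logs}
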