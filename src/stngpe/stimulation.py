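"""Cortical stimulation: spatial profiles, schedules and the striatal
stimulus-locked rate modulation.

A stimulus delivered at cortical coordinate ``s0`` recruits each cortical
Poisson generator independently with Lorentzian probability
P(s|s0) = 1 / (1 + ((s - s0)/sigma_s)^2); recruited generators emit one
spike at stimulus onset, superposed on their baseline stream.  Each
stimulus-recruited cortical spike switches the coordinate-nearest striatal
(MSN) generator onto a stereotyped rate kernel: a brief Gaussian burst,
a silent period, and a linear recovery ramp back to baseline.

One-site protocols deliver periodic single pulses; two-site protocols
deliver a priming pulse at -ds/2 and, dt later, a test pulse at +ds/2 in
every period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusProfile",
    "StimulationProtocol",
    "MsnResponseKernel",
    "stimulus_profile",
    "sample_ctx_stimulus_spikes",
    "msn_rate_kernel",
    "msn_spike_probability",
    "build_schedule",
    "alignment_onsets",
]

#: default stimulus-profile width (units of L)
DEFAULT_SIGMA_S = 0.05 / math.pi
#: baseline rates in 1/ms
R_CTX = 4.0e-3   # 4 Hz
R_MSN = 0.67e-3  # 0.67 Hz


@dataclass(frozen=True)
class StimulusProfile:
    """Lorentzian recruitment profile centred at ``s0`` with width sigma_s."""

    s0: float = 0.0
    sigma_s: float = DEFAULT_SIGMA_S

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")


@dataclass(frozen=True)
class StimulationProtocol:
    """One- or two-site periodic stimulation schedule.

    ``delta_s`` is the coordinate separation of the two sites (priming at
    -delta_s/2, test at +delta_s/2) and ``delta_t`` the inter-stimulus
    interval within a period (both ignored for one-site protocols, where
    pulses are centred at ``s0``).
    """

    mode: str = "one-site"  # "one-site" | "two-site"
    period: float = 1700.0  # ms
    n_stimuli: int = 500
    sigma_s: float = DEFAULT_SIGMA_S
    s0: float = 0.0
    delta_s: float = 0.0
    delta_t: float = 0.0
    warmup: float = 40_000.0  # ms of unstimulated settling before pulse 1

    def __post_init__(self) -> None:
        if self.mode not in ("one-site", "two-site"):
            raise ValueError(f"unknown stimulation mode {self.mode!r}")
        if self.n_stimuli < 1:
            raise ValueError("need at least one stimulus")
        if not (self.period > self.delta_t >= 0):
            raise ValueError("require period > delta_t >= 0")


@dataclass(frozen=True)
class MsnResponseKernel:
    """Parameters of the MSN stimulus-locked rate kernel (rates in 1/ms).

    The kernel peaks at ``eta`` at lag ``mu``, is silent on
    [2 mu, 2 mu + t_start), ramps back on [2 mu + t_start, 2 mu + t_end) and
    returns to the baseline rate ``r_msn`` afterwards.  ``ctx_msn_delay`` is
    the cortex-to-striatum transmission delay.
    """

    eta: float = 0.145
    mu: float = 2.1
    sigma: float = 2.1 / 3.0
    t_start: float = 100.0
    t_end: float = 300.0
    r_msn: float = R_MSN
    ctx_msn_delay: float = 10.5
    literal_ramp: bool = False  # dimensionally literal ramp variant

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.t_start >= self.t_end:
            raise ValueError("require mu > 0 and t_start < t_end")
        if self.eta <= self.r_msn:
            raise ValueError("peak rate must exceed baseline")

    @property
    def duration(self) -> float:
        """Lag after which the kernel has returned to baseline."""
        return 2.0 * self.mu + self.t_end


def stimulus_profile(s: float, s0: float, sigma_s: float = DEFAULT_SIGMA_S) -> float:
    """Recruitment probability P(s|s0) = 1/(1 + ((s-s0)/sigma_s)^2)."""
    x = (s - s0) / sigma_s
    return 1.0 / (1.0 + x * x)


def sample_ctx_stimulus_spikes(s_ctx: np.ndarray, profile: StimulusProfile,
                               rng: np.random.Generator) -> np.ndarray:
    """Indices of cortical generators recruited by one stimulus pulse.

    Each generator is included independently with probability P(s_i|s0);
    recruited generators spike once at stimulus onset.
    """
    p = 1.0 / (1.0 + ((s_ctx - profile.s0) / profile.sigma_s) ** 2)
    return np.flatnonzero(rng.random(len(s_ctx)) < p)


def msn_rate_kernel(t: float, kernel: MsnResponseKernel = MsnResponseKernel()) -> float:
    """MSN rate (1/ms) at lag ``t`` after the associated cortical spike.

    The recovery ramp rises linearly from 0 to the baseline rate (the
    printed, dimensionally literal ramp (t - t_start)/(t_end - t_start) is
    available via ``literal_ramp=True``).
    """
    if t <= 0:
        raise ValueError("kernel lag must be positive")
    k = kernel
    if t < 2.0 * k.mu:
        return k.eta * math.exp(-((t - k.mu) ** 2) / (2.0 * k.sigma ** 2))
    if t < 2.0 * k.mu + k.t_start:
        return 0.0
    if t < 2.0 * k.mu + k.t_end:
        frac = (t - 2.0 * k.mu - k.t_start) / (k.t_end - k.t_start)
        if k.literal_ramp:
            return (t - k.t_start) / (k.t_end - k.t_start)
        return k.r_msn * frac
    return k.r_msn


def msn_spike_probability(t: float, last_ctx_spike: float | None,
                          kernel: MsnResponseKernel, h: float) -> float:
    """Probability that an MSN fires in [t, t+h).

    If the MSN's associated cortical generator spiked (in response to a
    stimulus) at ``last_ctx_spike``, the kernel applies, shifted by the
    cortex-to-striatum delay; otherwise the baseline rate does.  When a new
    cortical stimulus spike arrives during an active kernel, the most
    recent one governs (memoryless restart).
    """
    if h > 1.0:
        raise ValueError("step h must not exceed 1 ms")
    if last_ctx_spike is None:
        return kernel.r_msn * h
    lag = t - last_ctx_spike - kernel.ctx_msn_delay
    if lag <= 0 or lag >= kernel.duration:
        return kernel.r_msn * h
    return msn_rate_kernel(lag, kernel) * h


def build_schedule(protocol: StimulationProtocol) -> list[tuple[float, float]]:
    """Expand a protocol into (onset time ms, site coordinate) events.

    One-site: onsets warmup + k*period at ``s0``.  Two-site: priming at
    warmup + k*period at -delta_s/2 and test delta_t later at +delta_s/2.
    """
    events = []
    for k in range(protocol.n_stimuli):
        t0 = protocol.warmup + k * protocol.period
        if protocol.mode == "one-site":
            events.append((t0, protocol.s0))
        else:
            events.append((t0, -protocol.delta_s / 2.0))
            events.append((t0 + protocol.delta_t, protocol.delta_s / 2.0))
    return events


def alignment_onsets(protocol: StimulationProtocol) -> np.ndarray:
    """Onset times of the test (or sole) stimulus in each period."""
    k = np.arange(protocol.n_stimuli)
    if protocol.mode == "two-site":
        return protocol.warmup + k * protocol.period + protocol.delta_t
    return protocol.warmup + k * protocol.period
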