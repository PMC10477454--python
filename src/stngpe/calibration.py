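"""Four-stage conductance calibration of the circuit.

The peak conductances are fitted sequentially so that population mean
firing rates in a cascade of reduced circuits match in-vivo reference
rates:

1. ``G^CTX,STN`` -- isolated CTX-STN circuit (GPe input cut), target
   20.7 Hz (STN rate after excitotoxic GPe lesion).
2. ``G^GPe,STN`` -- GPe replaced by Poisson generators at 30.4 Hz, target
   11.8 Hz (intact anesthetized STN rate).
3. ``G^STN,GPe`` -- STN replaced by Poisson generators at 11.8 Hz and all
   GABAergic input to GPe removed, target 47.12 Hz (the +55% GPe rate
   under GABA blockade: 1.55 x 30.4 Hz).
4. ``(G^MSN,GPe, G^GPe,GPe)`` -- intact circuit, joint target (11.8, 30.4)
   Hz via the weighted rate deviation ``delta_r``.

Each objective evaluation simulates 40 s, averages the centre-subset rate
over t in [30, 40) s and over several initial conditions, and the search
runs the Nelder-Mead simplex (tolerance 0.1) in log-conductance space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .engine import SimulationConfig, mean_rate, run_simulation
from .network import Circuit, build_circuit, substitute_poisson

__all__ = [
    "delta_r",
    "CalibrationStage",
    "CalibrationResult",
    "make_stage",
    "run_stage",
    "verify_conductances",
    "STAGE_TARGETS",
]

#: reference rates (Hz) and their biological standard deviations
R_STN_TARGET = 11.8
R_GPE_TARGET = 30.4
SIGMA_STN = 9.1
SIGMA_GPE = 11.4
#: +55% GABA-blockade target for the GPe, 1.55 x 30.4 Hz
R_GPE_BICUCULLINE = 1.55 * R_GPE_TARGET

STAGE_TARGETS = {1: 20.7, 2: R_STN_TARGET, 3: R_GPE_BICUCULLINE,
                 4: (R_STN_TARGET, R_GPE_TARGET)}


def delta_r(r_stn: float, r_gpe: float) -> float:
    """Weighted deviation |r_STN - 11.8|/9.1 + |r_GPe - 30.4|/11.4."""
    return (abs(r_stn - R_STN_TARGET) / SIGMA_STN
            + abs(r_gpe - R_GPE_TARGET) / SIGMA_GPE)


@dataclass
class CalibrationStage:
    """One stage of the sequential fit."""

    stage: int                      # 1..4
    free: list[str]                 # conductance keys being fitted
    fixed: dict[str, float]         # conductances fixed from prior stages
    n_stn_gpe: int = 3
    duration: float = 40_000.0      # ms per evaluation
    window: tuple[float, float] = (30_000.0, 40_000.0)
    n_initial_conditions: int = 4   # paper-faithful value: 12
    tol: float = 0.1
    max_iter: int = 60

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4):
            raise ValueError("stage must be 1..4")


@dataclass
class CalibrationResult:
    stage: int
    conductances: dict[str, float]
    achieved: dict[str, float]      # rates Hz
    objective: float
    trace: list[tuple[list[float], float]] = field(default_factory=list)
    converged: bool = True


def _stage_circuit(stage: int, cond: dict[str, float], n_stn_gpe: int) -> Circuit:
    """Reduced circuit for a calibration stage at the given conductances."""
    preset = "n3" if n_stn_gpe == 3 else "n30"
    if stage == 1:
        c = build_circuit("N", preset,
                          conductances={**cond, "G_gpe_stn": 0.0})
        return substitute_poisson(c, "GPe", 0.0)
    if stage == 2:
        c = build_circuit("N", preset, conductances=cond)
        return substitute_poisson(c, "GPe", R_GPE_TARGET)
    if stage == 3:
        # no GABAergic input to GPe: zero the MSN->GPe and GPe->GPe
        # conductances; GPe->STN is irrelevant since STN is Poisson
        c = build_circuit("N", preset,
                          conductances={**cond, "G_msn_gpe": 0.0,
                                        "G_gpe_gpe": 0.0})
        return substitute_poisson(c, "STN", R_STN_TARGET)
    return build_circuit("N", preset, conductances=cond)


def _stage_rates(stage: int, cond: dict[str, float], n_stn_gpe: int,
                 duration: float, window: tuple[float, float],
                 n_ic: int, base_seed: int = 0) -> dict[str, float]:
    circuit = _stage_circuit(stage, cond, n_stn_gpe)
    cfg = SimulationConfig(duration=duration)
    stn, gpe = [], []
    for ic in range(n_ic):
        rec = run_simulation(circuit, cfg, het_seed=base_seed + ic,
                             noise_seed=base_seed + 7919 * (ic + 1))
        if circuit.stn_poisson_rate is None:
            stn.append(mean_rate(rec, "STN", window))
        if circuit.gpe_poisson_rate is None:
            gpe.append(mean_rate(rec, "GPe", window))
    out = {}
    if stn:
        out["STN"] = float(np.mean(stn))
    if gpe:
        out["GPe"] = float(np.mean(gpe))
    return out


def make_stage(stage: int, n_stn_gpe: int = 3,
               prior: dict[str, float] | None = None,
               paper_faithful: bool = False, **kwargs) -> CalibrationStage:
    """Stage definition with the fitted keys and the prior-stage constants."""
    prior = dict(prior or {})
    free = {1: ["G_ctx_stn"], 2: ["G_gpe_stn"], 3: ["G_stn_gpe"],
            4: ["G_msn_gpe", "G_gpe_gpe"]}[stage]
    if paper_faithful:
        kwargs.setdefault("n_initial_conditions", 12)
    return CalibrationStage(stage=stage, free=free, fixed=prior,
                            n_stn_gpe=n_stn_gpe, **kwargs)


def run_stage(stage: CalibrationStage, x0: dict[str, float] | None = None,
              base_seed: int = 0) -> CalibrationResult:
    """Fit the stage's free conductances with Nelder-Mead (log space).

    The objective is |rate - target| (stages 1-3) or ``delta_r`` (stage 4);
    rates are averaged over ``n_initial_conditions`` fresh initial
    conditions per evaluation.  Non-convergence within the iteration cap
    returns the best point found, flagged in the result.
    """
    defaults = {"G_ctx_stn": 1.0, "G_gpe_stn": 6.82,
                "G_stn_gpe": 10.0, "G_msn_gpe": 5.0, "G_gpe_gpe": 0.5}
    start = {k: (x0 or {}).get(k, defaults[k]) for k in stage.free}
    trace: list[tuple[list[float], float]] = []

    def objective(logg: np.ndarray) -> float:
        cond = dict(stage.fixed)
        cond.update({k: float(np.exp(g)) for k, g in zip(stage.free, logg)})
        rates = _stage_rates(stage.stage, cond, stage.n_stn_gpe,
                             stage.duration, stage.window,
                             stage.n_initial_conditions, base_seed)
        if stage.stage == 4:
            val = delta_r(rates["STN"], rates["GPe"])
        elif stage.stage == 3:
            val = abs(rates["GPe"] - STAGE_TARGETS[3])
        else:
            val = abs(rates["STN"] - STAGE_TARGETS[stage.stage])
        trace.append(([float(np.exp(g)) for g in logg], val))
        return val

    res = optimize.minimize(
        objective, np.log([start[k] for k in stage.free]),
        method="Nelder-Mead", tol=stage.tol,
        options={"maxiter": stage.max_iter, "maxfev": 2 * stage.max_iter})
    best = dict(stage.fixed)
    best.update({k: float(np.exp(g)) for k, g in zip(stage.free, res.x)})
    achieved = _stage_rates(stage.stage, best, stage.n_stn_gpe,
                            stage.duration, stage.window,
                            stage.n_initial_conditions, base_seed)
    return CalibrationResult(stage=stage.stage, conductances=best,
                             achieved=achieved, objective=float(res.fun),
                             trace=trace, converged=bool(res.success))


def verify_conductances(n_stn_gpe: int = 3, n_seeds: int = 3,
                        duration: float = 40_000.0,
                        conductances: dict[str, float] | None = None,
                        base_seed: int = 0) -> dict:
    """Forward-check the fitted conductance set without re-optimizing.

    Simulates each stage's reduced circuit at the given (default: the
    fitted reference) conductances for ``n_seeds`` initial conditions and
    reports achieved rates with Monte-Carlo standard errors.
    """
    from .network import CONDUCTANCE_PRESETS

    preset = "n3" if n_stn_gpe == 3 else "n30"
    cond = dict(CONDUCTANCE_PRESETS[preset])
    cond.pop("N_stn_gpe")
    if conductances:
        cond.update(conductances)
    window = (duration - 10_000.0, duration)
    report = {}
    for stg in (1, 2, 3, 4):
        circuit = _stage_circuit(stg, cond, n_stn_gpe)
        cfg = SimulationConfig(duration=duration)
        rates: dict[str, list[float]] = {}
        for ic in range(n_seeds):
            rec = run_simulation(circuit, cfg, het_seed=base_seed + ic,
                                 noise_seed=base_seed + 104729 * (ic + 1))
            if circuit.stn_poisson_rate is None:
                rates.setdefault("STN", []).append(mean_rate(rec, "STN", window))
            if circuit.gpe_poisson_rate is None:
                rates.setdefault("GPe", []).append(mean_rate(rec, "GPe", window))
        report[stg] = {
            nuc: {"mean": float(np.mean(v)),
                  "se": float(np.std(v, ddof=1) / np.sqrt(len(v)))
                  if len(v) > 1 else 0.0,
                  "n_seeds": len(v)}
            for nuc, v in rates.items()
        }
    return report
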