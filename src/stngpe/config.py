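"""Experiment configuration: schema-validated YAML/JSON with reference
defaults, plus run manifests for reproducibility.

An empty config resolves to the reference setup: intact N-network,
N^STN,GPe = 3 conductance set, no stimulation, 40 s at dt = 0.05 ms.
Unknown keys are rejected with their field path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .engine import SimulationConfig
from .network import CONDUCTANCE_PRESETS, Circuit, build_circuit
from .stimulation import DEFAULT_SIGMA_S, StimulationProtocol

__all__ = ["ExperimentConfig", "load_config", "config_hash"]

#: named experiment presets (conductance set + out-degree)
PRESETS = {"n3", "n3-table", "n30"}


@dataclass
class NetworkBlock:
    type: str = "N"               # N | D | S
    preset: str = "n3"
    P: float = 0.1                # displaced fraction (D)
    d: float = 0.15               # displacement (D), units of L
    mu_scale: float = 1.0
    conductances: dict = field(default_factory=dict)
    sizes: dict = field(default_factory=dict)


@dataclass
class ProtocolBlock:
    enabled: bool = False
    mode: str = "one-site"
    period_ms: float = 1700.0
    n_stimuli: int = 500
    sigma_s: float = DEFAULT_SIGMA_S
    s0: float = 0.0
    delta_s: float = 0.0
    delta_t: float = 0.0
    warmup_ms: float = 40_000.0


@dataclass
class EngineBlock:
    dt: float = 0.05
    duration_ms: float = 40_000.0
    n_trials: int = 1
    structure_seed: int = 0
    het_seed: int = 0
    noise_seed: int = 1
    record_ctx: bool = False
    record_msn: bool = False
    noise_form: str = "sqrt"


@dataclass
class AnalysisBlock:
    psth_bin_ms: float = 1.0
    psth_window_ms: tuple = (-100.0, 300.0)
    rate_window_ms: tuple = (30_000.0, 40_000.0)
    t_minus: float = 190.0
    t_plus: float = 200.0
    a_width: float = 0.045


@dataclass
class ExperimentConfig:
    network: NetworkBlock = field(default_factory=NetworkBlock)
    protocol: ProtocolBlock = field(default_factory=ProtocolBlock)
    engine: EngineBlock = field(default_factory=EngineBlock)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)

    def build_circuit(self) -> Circuit:
        nb = self.network
        if nb.preset not in PRESETS:
            raise ValueError(f"unknown preset {nb.preset!r}")
        return build_circuit(nb.type, nb.preset, self.engine.structure_seed,
                             sizes=nb.sizes or None, P=nb.P, d=nb.d,
                             mu_scale=nb.mu_scale,
                             conductances=nb.conductances or None)

    def simulation_config(self) -> SimulationConfig:
        proto = None
        if self.protocol.enabled:
            p = self.protocol
            proto = StimulationProtocol(p.mode, p.period_ms, p.n_stimuli,
                                        p.sigma_s, p.s0, p.delta_s,
                                        p.delta_t, p.warmup_ms)
        e = self.engine
        return SimulationConfig(duration=e.duration_ms, dt=e.dt,
                                protocol=proto, record_ctx=e.record_ctx,
                                record_msn=e.record_msn,
                                noise_form=e.noise_form)

    def to_dict(self) -> dict:
        return asdict(self)


def _merge(cls, data: dict, path: str):
    """Dataclass construction with unknown-key rejection."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in (data or {}).items():
        if key not in fields:
            raise ValueError(f"unknown config key: {path}{key}")
        ftype = fields[key].type
        sub = {"network": NetworkBlock, "protocol": ProtocolBlock,
               "engine": EngineBlock, "analysis": AnalysisBlock}.get(key)
        if sub is not None and cls is ExperimentConfig:
            kwargs[key] = _merge(sub, val, f"{path}{key}.")
        else:
            kwargs[key] = tuple(val) if isinstance(val, list) else val
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> ExperimentConfig:
    """Load a YAML/JSON config, merging over the reference defaults.

    An empty or missing body yields the full default configuration.  A few
    common rate conventions are normalized: dt <= 0 or duration <= 0 are
    rejected via SimulationConfig validation on use.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
    if overrides:
        for k, v in overrides.items():
            data.setdefault(k, {}).update(v)
    cfg = _merge(ExperimentConfig, data, "")
    if cfg.engine.dt <= 0:
        raise ValueError("engine.dt must be positive")
    if cfg.engine.duration_ms <= 0:
        raise ValueError("engine.duration_ms must be positive")
    return cfg


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable short hash of the resolved configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(cfg: ExperimentConfig, out_dir: str | Path,
                   extra: dict | None = None) -> Path:
    """Write the resolved config + hash (and any extras) next to outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg.to_dict(), "config_hash": config_hash(cfg)}
    if extra:
        manifest.update(extra)
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    return p
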