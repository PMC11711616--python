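"""Pipeline configuration: YAML loading, validation, manifest hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["Thresholds", "PipelineConfig", "load_config", "config_hash"]


@dataclass
class Thresholds:
    """Analysis thresholds with their documented valid ranges."""

    rpkm: float = 10.0
    tss_window: int = 10_000
    rp_window: int = 100_000
    alpha_occupancy: float = 0.05
    alpha_deg: float = 0.01
    lfc_deg: float = 1.0
    ssgsea_weight: float = 0.25
    dispersion_floor: float = 0.01

    def __post_init__(self) -> None:
        checks = {
            "rpkm": (self.rpkm, 0.0, float("inf")),
            "tss_window": (self.tss_window, 1, 10**9),
            "rp_window": (self.rp_window, 1, 10**9),
            "alpha_occupancy": (self.alpha_occupancy, 0.0, 1.0),
            "alpha_deg": (self.alpha_deg, 0.0, 1.0),
            "lfc_deg": (self.lfc_deg, 0.0, float("inf")),
            "ssgsea_weight": (self.ssgsea_weight, 0.0, 10.0),
            "dispersion_floor": (self.dispersion_floor, 0.0, 10.0),
        }
        for name, (val, lo, hi) in checks.items():
            if not (lo <= val <= hi):
                raise ValueError(f"threshold {name}={val} outside [{lo}, {hi}]")


@dataclass
class PipelineConfig:
    """Top-level run configuration (paths, thresholds, seed, logging)."""

    outdir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {self.log_level!r}")
        # the simulation inherits the run seed unless set explicitly
        if self.simulation.seed == 0 and self.seed != 0:
            self.simulation.seed = self.seed

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    data.update(overrides)
    thresholds = _build(Thresholds, data.pop("thresholds", {}) or {}, "thresholds")
    simulation = _build(SimulationConfig, data.pop("simulation", {}) or {}, "simulation")
    cfg = _build(PipelineConfig, data, "pipeline")
    cfg.thresholds = thresholds
    cfg.simulation = simulation
    cfg.__post_init__()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration, for the run manifest."""
    payload = asdict(cfg)
    payload["simulation"]["chrom_lengths"] = dict(payload["simulation"]["chrom_lengths"])
    payload["simulation"]["n_peaks"] = dict(payload["simulation"]["n_peaks"])
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
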