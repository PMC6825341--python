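"""YAML-backed run configuration for the end-to-end pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .folding_engine import SimulationConfig


@dataclass
class RunConfig:
    """Thresholds, simulation parameters, and seeds for a pipeline run."""

    seed: int = 0
    nf_cutoff: float = 64.0
    nff_cutoff: float = 0.5
    identity_threshold: float = 0.8
    nf_switch: float = 50.0
    max_gap_fraction: float = 0.75
    max_identity: float = 0.90
    min_coverage: float = 0.75
    long_range_separation: int = 24
    simulation: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("nf_cutoff", "nff_cutoff", "identity_threshold",
                     "nf_switch", "max_gap_fraction", "max_identity",
                     "min_coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed if seed is None else seed)
        if seed is not None:
            params["seed"] = seed
        return SimulationConfig(**params)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top-level config must be a mapping")
    return RunConfig(**data)
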