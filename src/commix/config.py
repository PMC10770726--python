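"""Pipeline configuration: one structured object, loadable from YAML.

Blocks mirror the pipeline stages: design (pooling and inoculation),
simulation (GLV prior and passage protocol), observation (sequencing depth,
ambiguity, plating noise), analysis (detection threshold, pruning, pairing).
A single master seed drives everything; child seeds are derived per
(design, replicate, observation) so any community is re-simulable alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .design import PassageProtocol
from .glv import DEFAULT_CULTURE_VOLUME, DEFAULT_EXTINCTION_FLOOR, GLVPriorConfig

__all__ = ["DesignConfig", "ObservationConfig", "AnalysisConfig", "PipelineConfig"]


@dataclass
class DesignConfig:
    n_pools: int = 7
    pool_size: int = 8
    n_genera: int = 21
    total_titer: float = 1e6
    n_replicates: int = 3


@dataclass
class ObservationConfig:
    noise: bool = True
    depth: int = 50_000
    ambiguous_fraction: float = 0.2  # fraction of same-genus reads made ambiguous
    plating_cv: float = 0.1


@dataclass
class AnalysisConfig:
    detection_threshold: float = 0.01
    z_max: float = 1.0
    prune_population_on: str = "pop_log"  # or "pop_effect"
    aggregation: str = "aggregate"  # or "per_replicate"
    delta: int = 1


@dataclass
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    glv: GLVPriorConfig = field(default_factory=GLVPriorConfig)
    protocol: PassageProtocol = field(default_factory=PassageProtocol)
    observation: ObservationConfig = field(default_factory=ObservationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    extinction_floor: float = DEFAULT_EXTINCTION_FLOOR
    culture_volume: float = DEFAULT_CULTURE_VOLUME
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        blocks = {
            "design": DesignConfig,
            "glv": GLVPriorConfig,
            "protocol": PassageProtocol,
            "observation": ObservationConfig,
            "analysis": AnalysisConfig,
        }
        kwargs: dict = {}
        for name, klass in blocks.items():
            if name not in data:
                raise ValueError(f"missing config block: {name!r}")
            block = data[name]
            unknown = set(block) - set(klass.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
            kwargs[name] = klass(**block)
        for scalar in ("extinction_floor", "culture_volume", "seed"):
            if scalar in data:
                kwargs[scalar] = data[scalar]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
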