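"""Run configuration: one schema for every pipeline stage.

A :class:`RunConfig` collects the defaults of all stages (fusion gain,
detector thresholds, window geometry, ensemble size, split fraction,
posterior gate, seed). It round-trips through YAML and hashes to a short
digest that is embedded in a manifest written alongside every CLI output,
so any artifact can be traced back to the exact settings and seed that
produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classification import PipelineConfig, TrainConfig
from .orientation import FusionConfig
from .spotting import DetectionRule


@dataclass
class RunConfig:
    fs: float = 50.0
    gain: float = 0.1
    use_mag: bool = True
    elevation_deg: float = 45.0
    rate_dps: float = 400.0
    refractory_s: float = 1.0
    window_s: float = 2.0
    pre_share: float = 0.4
    n_trees: int = 160
    train_frac: float = 0.4
    score_threshold: float = 0.60
    seed: int = 0
    extra: dict = field(default_factory=dict)

    # -- stage views -----------------------------------------------------
    def fusion(self) -> FusionConfig:
        return FusionConfig(gain=self.gain, use_mag=self.use_mag)

    def rule(self) -> DetectionRule:
        return DetectionRule(
            elevation_deg=self.elevation_deg,
            rate_dps=self.rate_dps,
            refractory_s=self.refractory_s,
        )

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(
            fusion=self.fusion(),
            rule=self.rule(),
            window_s=self.window_s,
            pre_share=self.pre_share,
            score_threshold=self.score_threshold,
        )

    def training(self) -> TrainConfig:
        return TrainConfig(
            n_trees=self.n_trees,
            train_frac=self.train_frac,
            score_threshold=self.score_threshold,
            seed=self.seed,
        )

    # -- serialisation ---------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def digest(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]


def write_manifest(out_path: str | Path, cfg: RunConfig, **extra) -> Path:
    """Write ``<out>.manifest.yaml`` recording config, hash and seed."""
    out_path = Path(out_path)
    manifest = {
        "output": out_path.name,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "config": yaml.safe_load(cfg.to_yaml()),
    }
    manifest.update(extra)
    path = out_path.with_name(out_path.name + ".manifest.yaml")
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
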