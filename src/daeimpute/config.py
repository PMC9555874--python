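"""Pipeline configuration: one YAML file with per-stage sections.

All defaults match the published study conditions (correlation threshold
0.45, box half-width 500, 6000-SNP segment cap with 2500-SNP overlaps,
initial masking 80% down to 5 unmasked variants, 500-epoch cycles, batch
size 256, the coarse hyperparameter grid).  A single root seed feeds named
substreams for every stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .autoencoder import AutoencoderSpec
from .ld_tiling import TilingConfig
from .synthetic import BlockSpec
from .training import TrainingSchedule


@dataclasses.dataclass
class PanelConfig:
    vcf: str | None = None  # load a panel from VCF ...
    n_haplotypes: int = 1000  # ... or simulate one
    blocks: list[dict] = dataclasses.field(
        default_factory=lambda: [
            {"n_variants": 50, "within_block_r2": 0.9} for _ in range(4)
        ]
    )
    hotspot_gap_variants: int = 10
    test_fraction: float = 0.2
    observed_fraction: float = 0.05  # array-style masking at inference


@dataclasses.dataclass
class GridConfig:
    n_combinations: int = 0  # 0 disables the per-segment grid search
    epochs_per_cycle: int = 20
    max_epochs: int = 20


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "pipeline_out"
    panel: PanelConfig = dataclasses.field(default_factory=PanelConfig)
    tiling: TilingConfig = dataclasses.field(default_factory=TilingConfig)
    spec: AutoencoderSpec = dataclasses.field(default_factory=AutoencoderSpec)
    training: TrainingSchedule = dataclasses.field(
        default_factory=TrainingSchedule
    )
    grid: GridConfig = dataclasses.field(default_factory=GridConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # artifact location is not a scientific parameter
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def substream(self, name: str) -> np.random.Generator:
        """Named, reproducible random substream derived from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:4], "big"))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key, sub in (
            ("panel", PanelConfig),
            ("tiling", TilingConfig),
            ("spec", AutoencoderSpec),
            ("training", TrainingSchedule),
            ("grid", GridConfig),
        ):
            if key in d and isinstance(d[key], dict):
                field_names = {f.name for f in dataclasses.fields(sub)}
                bad = set(d[key]) - field_names
                if bad:
                    raise ValueError(
                        f"unknown fields in config section {key!r}: {sorted(bad)}"
                    )
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def block_specs(self) -> list[BlockSpec]:
        return [BlockSpec(**b) for b in self.panel.blocks]
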