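"""Pipeline configuration: a flat key-value document with strict key checking.

Every default mirrors the published screening protocol where one exists
(200-nt precursor flanks, >= 20 nt exact match, MFEI >= 0.70, <= 6 star
mismatches, ORFs >= 100 aa, MISA thresholds 10/6/5/5/5/5, primer constraints
100-300 bp / 18-25 nt / 55-62 degC with a 57 degC optimum).  Unrecognized
keys are a hard error so a typo cannot silently revert a parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    flank: int = 200
    min_match: int = 20
    mfei_threshold: float = 0.70
    max_star_mismatches: int = 6
    max_internal_gap: int = 3
    min_orf_aa: int = 100
    ssr_min_repeats: List[int] = field(default_factory=lambda: [10, 6, 5, 5, 5, 5])
    compound_max_interruption: int = 100
    exclude_mono: bool = True
    product_min: int = 100
    product_max: int = 300
    primer_len_min: int = 18
    primer_len_max: int = 25
    tm_min: float = 55.0
    tm_max: float = 62.0
    tm_opt: float = 57.0
    monovalent_mm: float = 50.0
    oligo_nm: float = 50.0
    primers_per_locus: int = 1
    energy_model: str = "stacking"
    both_strands: bool = False
    dedup_transcripts: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.ssr_min_repeats) != 6:
            raise ConfigError("ssr_min_repeats needs six values (unit sizes 1-6)")
        if self.energy_model not in ("stacking", "pair_count"):
            raise ConfigError(f"unknown energy_model {self.energy_model!r}")
        if self.mfei_threshold < 0:
            raise ConfigError("mfei_threshold must be >= 0")

    @property
    def ssr_thresholds(self) -> Dict[int, int]:
        return {u + 1: r for u, r in enumerate(self.ssr_min_repeats)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unrecognized configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a flat mapping")
        return cls.from_dict(data)
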