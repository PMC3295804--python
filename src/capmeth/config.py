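"""Pipeline configuration: one structured YAML file, strict round-trip.

Unknown keys are rejected so a typo cannot silently fall back to a default.
All stage randomness derives from the single global seed, fanned out to
per-stage substreams by stable text labels, so a stage run standalone with
the same config reproduces its in-pipeline output.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, is_dataclass

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


def stage_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class GenomeConfig:
    n_chroms: int = 1
    chrom_length: int = 100_000
    gc_fraction: float = 0.45
    island_n_per_chrom: int = 8
    island_length: int = 1500
    island_cpg_fraction: float = 0.25

    @property
    def island_spec(self) -> dict | None:
        if self.island_n_per_chrom <= 0:
            return None
        return {"n_per_chrom": self.island_n_per_chrom,
                "length": self.island_length,
                "cpg_fraction": self.island_cpg_fraction}


@dataclass
class MethylomeConfig:
    beta_high_a: float = 10.0
    beta_high_b: float = 1.0
    beta_low_a: float = 1.0
    beta_low_b: float = 20.0
    p_high: float = 0.7
    noncpg_level: float = 0.0


@dataclass
class TargetConfig:
    n_regions: int = 50
    min_len: int = 100
    max_len: int = 300


@dataclass
class HetConfig:
    density: float = 0.0005
    include_ambiguous: bool = True


@dataclass
class LibraryConfig:
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    read_length: int = 90
    n_fragments: int = 20000
    conversion_rate: float = 0.99
    inappropriate_conversion_rate: float = 0.0
    sequencing_error_rate: float = 0.001
    on_target_capture_prob: float = 0.8
    off_target_capture_prob: float = 0.08
    pcr_duplicate_mean: float = 1.67
    base_quality: int = 40
    strand_mode: str = "both"


@dataclass
class AlignerConfig:
    seed_length: int = 30
    seed_max_mismatches: int = 2
    total_max_mismatches: int = 5
    max_gaps: int = 0
    max_insert: int = 1000


@dataclass
class PlantedDmrConfig:
    fraction: float = 0.1
    shift: float = 0.4


@dataclass
class Thresholds:
    alpha: float = 0.01
    fold: float = 2.0
    diff: float = 20.0
    dropout_min_depth: int = 10
    min_allele_reads: int = 2
    concordance_min_depth: int = 9
    region_min_reads: int = 10
    min_base_quality: int = 0


@dataclass
class PipelineConfig:
    seed: int = 0
    n_genes: int = 6
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)
    hets: HetConfig = field(default_factory=HetConfig)
    library: LibraryConfig = field(default_factory=LibraryConfig)
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    planted_dmr: PlantedDmrConfig = field(default_factory=PlantedDmrConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)


def _build(dc_type, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping")
    known = {f.name for f in fields(dc_type)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    defaults = dc_type()
    kwargs = {}
    for name, value in data.items():
        current = getattr(defaults, name)
        if is_dataclass(current):
            kwargs[name] = _build(type(current), value, f"{where}.{name}")
        else:
            kwargs[name] = value
    try:
        return dc_type(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc
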