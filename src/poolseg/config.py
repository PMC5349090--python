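"""Run configuration: defaults, validation, YAML round-trip.

A run is configured by a nested mapping (YAML or JSON) with blocks for
the genome, markers, trait, pools, filters, scan and fine-mapping stages.
``validate_config`` fills defaults, checks invariants and returns a fully
resolved :class:`RunConfig`; errors are aggregated into one message.
Defaults mirror the reference study design: pools of 41 segregants from
386, ~40x pool and ~60x parent coverage, 30%/70% linkage thresholds,
phenotype cutoffs 20 and 16.3 mg/L, alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config", "echo_config"]


class ConfigError(ValueError):
    """Invalid run configuration (message lists every problem found)."""


@dataclass
class GenomeBlock:
    cm_per_kb: float = 0.4


@dataclass
class MarkerBlock:
    n_induced: int = 900
    n_background: int = 30_000


@dataclass
class LocusBlock:
    chrom: str
    pos: int
    klass: str  # "induced" | "background"
    effect: float
    requires_mito: bool = False
    partner: dict | None = None  # {"chrom":…, "pos":…, "klass":…}


@dataclass
class TraitBlock:
    superior_baseline: float = 13.9
    inferior_baseline: float = 49.8
    residual_sd: float = 1.5
    mito_prob: float = 1.0
    loci: list[dict] | str = "default"  # "default", "none", or explicit list


@dataclass
class PoolBlock:
    n_segregants: int = 386
    selected_size: int = 41
    random_size: int = 41
    pool_depth: float = 40.0
    parent_depth: float = 60.0
    error_rate: float = 0.005


@dataclass
class FilterBlock:
    min_depth: int = 25
    min_quality: float = 10.0
    parent_min_fraction: float = 0.90


@dataclass
class ScanBlock:
    lower: float = 0.30
    upper: float = 0.70
    min_markers: int = 10
    merge_gap: int = 5
    ci_level: float = 0.95


@dataclass
class FineMapBlock:
    selection_cutoff: float = 20.0  # mg/L, scan-pool cutoff
    refine_cutoff: float = 16.3  # mg/L, fine-mapping cutoff
    alpha: float = 0.01
    markers_per_region: int = 15
    missing_rate: float = 0.0
    bonferroni: bool = False


@dataclass
class DataPaths:
    selected_vcf: str = ""
    random_vcf: str = ""
    superior_parent_vcf: str = ""
    inferior_parent_vcf: str = ""
    phenotypes_tsv: str = ""


@dataclass
class RunConfig:
    seed: int = 1
    mode: str = "synthetic"  # "synthetic" | "data"
    out_dir: str = "poolseg_run"
    genome: GenomeBlock = field(default_factory=GenomeBlock)
    markers: MarkerBlock = field(default_factory=MarkerBlock)
    trait: TraitBlock = field(default_factory=TraitBlock)
    pools: PoolBlock = field(default_factory=PoolBlock)
    filters: FilterBlock = field(default_factory=FilterBlock)
    scan: ScanBlock = field(default_factory=ScanBlock)
    finemap: FineMapBlock = field(default_factory=FineMapBlock)
    data: DataPaths = field(default_factory=DataPaths)


_BLOCKS = {
    "genome": GenomeBlock,
    "markers": MarkerBlock,
    "trait": TraitBlock,
    "pools": PoolBlock,
    "filters": FilterBlock,
    "scan": ScanBlock,
    "finemap": FineMapBlock,
    "data": DataPaths,
}


def validate_config(raw: dict[str, Any] | None) -> RunConfig:
    """Fill defaults, check invariants, return the resolved config.

    Raises :class:`ConfigError` listing every violation found.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    cfg = RunConfig()
    for key in ("seed", "mode", "out_dir"):
        if key in raw:
            setattr(cfg, key, raw.pop(key))
    for name, cls in _BLOCKS.items():
        block_raw = raw.pop(name, None)
        if block_raw is None:
            continue
        if not isinstance(block_raw, dict):
            errors.append(f"{name}: expected a mapping")
            continue
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(block_raw) - known
        if unknown:
            errors.append(f"{name}: unknown keys {sorted(unknown)}")
        setattr(cfg, name, cls(**{k: v for k, v in block_raw.items() if k in known}))
    if raw:
        errors.append(f"unknown top-level keys {sorted(raw)}")

    if cfg.mode not in ("synthetic", "data"):
        errors.append(f"mode must be 'synthetic' or 'data', got {cfg.mode!r}")
    if not isinstance(cfg.seed, int):
        errors.append("seed must be an integer")
    if not 0.0 < cfg.scan.lower < cfg.scan.upper < 1.0:
        errors.append(
            f"scan thresholds must satisfy 0 < lower < upper < 1, "
            f"got lower={cfg.scan.lower}, upper={cfg.scan.upper}"
        )
    if cfg.genome.cm_per_kb <= 0:
        errors.append("genome.cm_per_kb must be > 0")
    if cfg.markers.n_induced < 0 or cfg.markers.n_background < 0:
        errors.append("marker counts must be >= 0")
    if not 0.0 <= cfg.trait.mito_prob <= 1.0:
        errors.append("trait.mito_prob must be in [0, 1]")
    if cfg.trait.residual_sd < 0:
        errors.append("trait.residual_sd must be >= 0")
    if cfg.pools.n_segregants <= 0:
        errors.append("pools.n_segregants must be > 0")
    if not 0 < cfg.pools.selected_size <= cfg.pools.n_segregants:
        errors.append("pools.selected_size must be in 1..n_segregants")
    if not 0 < cfg.pools.random_size <= cfg.pools.n_segregants:
        errors.append("pools.random_size must be in 1..n_segregants")
    if not 0.0 <= cfg.pools.error_rate < 0.5:
        errors.append("pools.error_rate must be in [0, 0.5)")
    if cfg.finemap.selection_cutoff <= 0 or cfg.finemap.refine_cutoff <= 0:
        errors.append("phenotype cutoffs must be > 0")
    if not 0.0 < cfg.finemap.alpha < 1.0:
        errors.append("finemap.alpha must be in (0, 1)")
    if cfg.mode == "data":
        for name in (
            "selected_vcf", "random_vcf", "superior_parent_vcf",
            "inferior_parent_vcf", "phenotypes_tsv",
        ):
            if not getattr(cfg.data, name):
                errors.append(f"data mode requires data.{name}")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def echo_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration back out as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
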