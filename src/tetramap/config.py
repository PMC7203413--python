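"""Pipeline configuration: every threshold of the analysis in one place.

Defaults are the published constants of the study design (100-bp thinning,
average depth 10, PL ambiguity 0.05, 6x hom-call floor, LOD 10, 1-cM bins,
map error probability 0.01, enrichment thresholds 1.82/0.55, alpha levels
0.05 and 0.001, run length 3, site filters Q20 / depth 10 / 30% missing).
Configs round-trip losslessly through YAML; unknown keys are rejected by
name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "results/pipeline"

    # simulation
    n_individuals: int = 141
    n_chromosomes: int = 2
    markers_per_chromosome: int = 50
    chrom_length_bp: int = 60_000_000
    chrom_length_cm: float = 120.0
    simplex_fraction: float = 0.5
    model: str = "random_chromosome"
    alpha: float | None = None
    mean_depth: float = 20.0
    error_rate: float = 0.005

    # genotype calling
    min_spacing_bp: int = 100
    min_avg_depth: float = 10.0
    ambiguity: float = 0.05
    hom_min_depth: int = 6
    bb_policy: str = "het"
    max_marker_missing: float = 0.3
    min_called_fraction: float = 0.2

    # linkage map
    min_lod: float = 10.0
    bin_cm: float = 1.0
    error_prob: float = 0.01

    # segregation
    t_hi: float = 1.82
    t_lo: float = 0.55
    alpha_marker: float = 0.05
    alpha_group: float = 0.001
    min_region_markers: int = 3
    max_region_gap_bp: int = 5_000_000

    # ancestry
    min_qual: float = 20.0
    min_site_depth: int = 10
    max_site_missing: float = 0.30
    min_run: int = 3
    propinquum_consensus: str = "all"
    roles: dict = field(default_factory=dict)

    # inputs (empty -> simulate)
    vcf: str | None = None
    ancestry_vcf: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
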