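"""End-to-end orchestration: simulate -> call -> map -> segregate -> ancestry.

Each stage is a function over the library modules; `run_pipeline` chains
them, writing every stage artifact (VCF, genotype matrices, map files,
summary tables, distortion sets, ancestry tallies) under one output
directory together with a manifest and the thresholds actually used. All
randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import calling, linkage, segregation
from .config import PipelineConfig
from .segmodels import SegModel
from .simulate import (
    GenomeLayout,
    simulate_bc1_population,
    simulate_gbs_vcf,
    simulate_mosaic_trio,
)

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_call",
    "stage_map",
    "stage_segregate",
    "stage_ancestry",
    "make_fixtures",
]


def _model(cfg: PipelineConfig) -> SegModel:
    if cfg.model == "custom":
        return SegModel("custom", cfg.alpha)
    return SegModel(cfg.model)


def _seeds(cfg: PipelineConfig) -> dict[str, int]:
    children = np.random.SeedSequence(cfg.seed).generate_state(4)
    return {
        "population": int(children[0] % 2**31),
        "reads": int(children[1] % 2**31),
        "mosaic": int(children[2] % 2**31),
    }


def stage_simulate(cfg: PipelineConfig, out: Path) -> Path:
    seeds = _seeds(cfg)
    layout = GenomeLayout.random(
        n_chromosomes=cfg.n_chromosomes,
        markers_per_chromosome=cfg.markers_per_chromosome,
        length_bp=cfg.chrom_length_bp,
        length_cm=cfg.chrom_length_cm,
        simplex_fraction=cfg.simplex_fraction,
        seed=seeds["population"],
    )
    pop = simulate_bc1_population(
        layout, cfg.n_individuals, _model(cfg), seeds["population"]
    )
    pop.truth.to_csv(out / "truth_matrix.csv", index_label="marker")
    pop.marker_table.to_csv(out / "marker_truth.csv", index_label="marker")
    vcf_path = out / "simulated.vcf"
    simulate_gbs_vcf(
        pop, cfg.mean_depth, cfg.error_rate, seeds["reads"], str(vcf_path)
    )
    logger.info("simulated %d markers x %d individuals", pop.truth.shape[0],
                pop.truth.shape[1])
    return vcf_path


def stage_call(cfg: PipelineConfig, vcf_path: Path, out: Path) -> calling.GenotypeMatrix:
    samples, records = calling.read_vcf(vcf_path)
    logger.info("raw sites: %d", len(records))
    records = calling.thin_sites(records, cfg.min_spacing_bp)
    logger.info("after %d-bp thinning: %d", cfg.min_spacing_bp, len(records))
    records = calling.filter_biallelic_depth(records, cfg.min_avg_depth)
    logger.info("after biallelic/depth>=%.0f filter: %d", cfg.min_avg_depth,
                len(records))
    matrix = calling.build_matrix(
        records,
        samples,
        max_marker_missing=cfg.max_marker_missing,
        ambiguity=cfg.ambiguity,
        hom_min_depth=cfg.hom_min_depth,
        bb_policy=cfg.bb_policy,
    )
    matrix = calling.drop_low_coverage_individuals(
        matrix, cfg.min_called_fraction
    )
    matrix.to_csv(out / "genotype_matrix.csv")
    matrix.qc_table().to_csv(out / "marker_qc.csv", index_label="marker")
    return matrix


def stage_map(cfg: PipelineConfig, matrix: calling.GenotypeMatrix, out: Path):
    groups = []
    clusters = linkage.cluster_markers(matrix, cfg.min_lod)
    # name groups by base chromosome + letter, in cluster order per chromosome
    letters: dict[str, int] = {}
    binned_all = []
    for cluster in clusters:
        if len(cluster) < 2:
            continue
        chrom = str(matrix.chrom.loc[cluster[0]])
        letters[chrom] = letters.get(chrom, 0) + 1
        gid = f"{chrom.lstrip('Chr0') or chrom}{chr(64 + letters[chrom])}"
        binned, bin_map = linkage.bin_markers(
            matrix, cluster, cfg.bin_cm, cfg.error_prob
        )
        order = linkage.order_markers(binned, binned.markers)
        lg = linkage.estimate_map(binned, order, gid, cfg.error_prob)
        groups.append(lg)
        binned_all.append(binned)
        rows = pd.DataFrame(
            {
                "group": gid,
                "marker": lg.marker_ids,
                "chrom": [binned.chrom.loc[m] for m in lg.marker_ids],
                "pos": [binned.pos.loc[m] for m in lg.marker_ids],
                "cm": np.round(lg.positions_cm, 3),
            }
        )
        rows.to_csv(out / f"map_{gid}.tsv", sep="\t", index=False)
    summary = linkage.group_summary_table(groups)
    summary.to_csv(out / "map_summary.csv", index=False)
    return groups, summary


def stage_segregate(cfg: PipelineConfig, matrix: calling.GenotypeMatrix,
                    groups, out: Path):
    seg = segregation.marker_segregation(matrix)
    seg.to_csv(out / "marker_segregation.csv")
    rows = []
    for g in groups:
        rows.append(
            {
                "LG": g.id,
                "ab_aa_ratio": round(g.summary["ab_aa_ratio"], 2),
                "class": segregation.classify_group(
                    g.summary["ab_aa_ratio"], cfg.t_hi, cfg.t_lo
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "group_classes.csv", index=False)
    flagged = segregation.detect_distorted_markers(seg, cfg.alpha_marker)
    regions = segregation.detect_distortion_regions(
        seg.loc[sorted(flagged)],
        cfg.min_region_markers,
        cfg.max_region_gap_bp,
    )
    segregation.regions_to_bed(regions, out / "distortion_regions.bed")
    return seg, flagged, regions


def stage_ancestry(cfg: PipelineConfig, out: Path):
    seeds = _seeds(cfg)
    if cfg.ancestry_vcf:
        vcf_path = Path(cfg.ancestry_vcf)
        roles = cfg.roles or {
            "target": "target",
            "control": "control",
            "propinquum": ["propinquum_1", "propinquum_2"],
        }
    else:
        vcf_path = out / "mosaic_trio.vcf"
        simulate_mosaic_trio(seed=seeds["mosaic"], out=str(vcf_path))
        roles = {
            "target": "target",
            "control": "control",
            "propinquum": ["propinquum_1", "propinquum_2"],
        }
    sites = anc.read_trio_vcf(vcf_path, roles)
    sites = anc.filter_sites(
        sites, cfg.min_qual, cfg.min_site_depth, cfg.max_site_missing
    )
    track = anc.classify_track(sites, cfg.propinquum_consensus)
    track.to_csv(out / "ancestry_track.tsv", sep="\t", index=False)
    tally = anc.tally_categories(track)
    tally.to_csv(out / "ancestry_tally.csv", index_label="category")
    runs = anc.detect_runs(track, "P", cfg.min_run)
    anc.runs_to_bed(runs, out / "propinquum_runs.bed")
    return track, tally, runs


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] | None = None):
    """Run the requested stages (default: all) and write a manifest."""
    stages = stages or ("simulate", "call", "map", "segregate", "ancestry")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_used.yaml")
    manifest: dict[str, object] = {"stages": list(stages), "seed": cfg.seed}
    try:
        vcf_path = Path(cfg.vcf) if cfg.vcf else None
        matrix = None
        groups: list = []
        if "simulate" in stages and vcf_path is None:
            vcf_path = stage_simulate(cfg, out)
            manifest["vcf"] = str(vcf_path)
        if "call" in stages:
            matrix = stage_call(cfg, vcf_path, out)
            manifest["n_markers"] = len(matrix.markers)
            manifest["n_individuals"] = len(matrix.individuals)
        if "map" in stages and matrix is not None:
            groups, summary = stage_map(cfg, matrix, out)
            manifest["n_groups"] = len(groups)
        if "segregate" in stages and matrix is not None:
            seg, flagged, regions = stage_segregate(cfg, matrix, groups, out)
            manifest["n_distorted"] = len(flagged)
            manifest["n_regions"] = len(regions)
        if "ancestry" in stages:
            track, tally, runs = stage_ancestry(cfg, out)
            manifest["n_runs"] = len(runs)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def make_fixtures(seed: int = 1, scale: str = "tiny",
                  out_dir: str | Path = "fixtures") -> dict[str, str]:
    """Write the small packaged datasets used by the test suite.

    'tiny' keeps everything to a handful of markers; 'small' covers two
    chromosomes at mapping density.
    """
    sizes = {"tiny": (1, 20, 40), "small": (2, 50, 141)}
    if scale not in sizes:
        raise ValueError(f"scale must be one of {sorted(sizes)}")
    n_chrom, m, n = sizes[scale]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(
        seed=seed,
        n_chromosomes=n_chrom,
        markers_per_chromosome=m,
        n_individuals=n,
        out_dir=str(out),
    )
    vcf = stage_simulate(cfg, out)
    seeds = _seeds(cfg)
    mosaic = out / "mosaic_trio.vcf"
    simulate_mosaic_trio(
        n_chromosomes=1,
        sites_per_chromosome=120,
        seed=seeds["mosaic"],
        out=str(mosaic),
    )
    return {"vcf": str(vcf), "mosaic": str(mosaic)}
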