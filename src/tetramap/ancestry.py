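"""Progenitor-allele classification of a hybrid polyploid genome.

A hybrid tetraploid thought to derive from two diploid progenitors (here a
Sorghum halepense-like target, with S. bicolor contributing the reference
and S. propinquum the donor subgenome) is compared site-by-site against
progenitor genotypes called on the same reference. Each filtered site gets
exactly one category:

* ``B``    — target homozygous for the reference (S. bicolor) allele;
* ``P``    — target homozygous for the S. propinquum allele;
* ``H_BP`` — heterozygous, one allele from each progenitor;
* ``H_PM`` — heterozygous, one propinquum allele and one novel allele;
* ``N_M``  — a non-progenitor (presumed new-mutation) allele with no
  propinquum allele present;
* ``UNKNOWN`` — missing data, disagreeing propinquum accessions (under the
  conservative consensus policy), or the conspecific control differing from
  the reference (intra-species polymorphism makes the reference allele
  uninformative).

UNKNOWN sites are excluded from the proportion denominator. Runs of at
least ``min_run`` consecutive propinquum-derived sites flag genomic blocks
resistant to recombination with the reference progenitor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "CATEGORIES",
    "AncestrySite",
    "Run",
    "read_trio_vcf",
    "filter_sites",
    "classify_site",
    "classify_track",
    "tally_categories",
    "detect_runs",
    "run_coverage",
    "runs_to_bed",
]

CATEGORIES = ("B", "H_BP", "H_PM", "N_M", "P", "UNKNOWN")


@dataclass
class AncestrySite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    target: tuple[int, ...] | None  # allele indices, 0 = ref
    control: tuple[int, ...] | None
    propinquum: tuple[tuple[int, ...] | None, ...]
    depths: dict[str, int]


@dataclass(frozen=True)
class Run:
    chrom: str
    start: int  # bp of first site, 1-based
    end: int  # bp of last site
    n_sites: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("run start must not exceed end")


def _gt(sample) -> tuple[int, ...] | None:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        return None
    return tuple(int(a) for a in gt)


def read_trio_vcf(path, roles: Mapping[str, str | Sequence[str]]) -> list[AncestrySite]:
    """Load sites for ancestry classification.

    ``roles`` maps 'target' and 'control' to sample names and 'propinquum'
    to one or more sample names.
    """
    prop_names = roles["propinquum"]
    if isinstance(prop_names, str):
        prop_names = [prop_names]
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            names = [roles["target"], roles["control"], *prop_names]
            depths = {}
            for s in names:
                dp = rec.samples[s].get("DP")
                depths[s] = 0 if dp is None else int(dp)
            sites.append(
                AncestrySite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=rec.qual,
                    target=_gt(rec.samples[roles["target"]]),
                    control=_gt(rec.samples[roles["control"]]),
                    propinquum=tuple(
                        _gt(rec.samples[s]) for s in prop_names
                    ),
                    depths=depths,
                )
            )
    return sites


def filter_sites(
    sites: Iterable[AncestrySite],
    min_qual: float = 20.0,
    min_depth: int = 10,
    max_missing: float = 0.30,
) -> list[AncestrySite]:
    """Site filter: QUAL >= min_qual; samples below min_depth become
    missing; sites whose missing fraction exceeds max_missing are dropped."""
    kept = []
    for s in sites:
        if s.qual is None or s.qual < min_qual:
            continue
        depths = list(s.depths.values())
        gts = [s.target, s.control, *s.propinquum]
        missing = sum(
            1 for gt, d in zip(gts, depths) if gt is None or d < min_depth
        )
        if missing / len(gts) > max_missing:
            continue
        names = list(s.depths)
        low = {name for name, d in s.depths.items() if d < min_depth}

        def _mask(gt, name):
            return None if name in low else gt

        kept.append(
            AncestrySite(
                s.chrom,
                s.pos,
                s.ref,
                s.alts,
                s.qual,
                _mask(s.target, names[0]),
                _mask(s.control, names[1]),
                tuple(_mask(g, n) for g, n in zip(s.propinquum, names[2:])),
                s.depths,
            )
        )
    return kept


def classify_site(
    target: tuple[int, ...] | None,
    propinquum: Sequence[tuple[int, ...] | None],
    control: tuple[int, ...] | None,
    consensus: str = "all",
) -> str:
    """Assign one ancestry category to a site (allele indices, 0 = reference).

    ``consensus='all'`` (conservative default) requires the propinquum
    accessions to agree, otherwise the site is UNKNOWN; ``'any'`` takes the
    union of their alleles.
    """
    if consensus not in ("all", "any"):
        raise ValueError(f"consensus must be 'all' or 'any', got {consensus!r}")
    props = [g for g in propinquum if g is not None]
    if target is None or control is None or not props:
        return "UNKNOWN"
    if any(a != 0 for a in control):
        return "UNKNOWN"  # control differs from reference
    if consensus == "all":
        if len(props) < len(propinquum) or len({tuple(sorted(g)) for g in props}) > 1:
            return "UNKNOWN"
        prop_set = set(props[0])
    else:
        prop_set = {a for g in props for a in g}

    t = set(target)
    if t == {0}:
        return "B"
    if len(t) == 1:  # homozygous non-reference
        return "P" if t <= prop_set else "N_M"
    # heterozygous
    non_ref = t - {0}
    if 0 in t:
        (a,) = non_ref
        return "H_BP" if a in prop_set else "N_M"
    # het between two non-reference alleles
    in_prop = non_ref & prop_set
    if in_prop == non_ref:
        return "P"
    if in_prop:
        return "H_PM"
    return "N_M"


def classify_track(
    sites: Sequence[AncestrySite], consensus: str = "all"
) -> pd.DataFrame:
    """Per-site ancestry categories, ordered along each chromosome."""
    rows = [
        (s.chrom, s.pos, classify_site(s.target, s.propinquum, s.control, consensus))
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "category"])
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        raise ValueError("duplicate site positions in track")
    return df


def tally_categories(track: pd.DataFrame) -> pd.DataFrame:
    """Counts per category plus proportions over non-UNKNOWN sites."""
    counts = (
        track["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    )
    classified = int(counts.drop("UNKNOWN").sum())
    if classified == 0:
        raise ValueError("no classified (non-UNKNOWN) sites")
    out = counts.to_frame("count")
    out["proportion"] = [
        c / classified if cat != "UNKNOWN" else np.nan
        for cat, c in counts.items()
    ]
    return out


def detect_runs(
    track: pd.DataFrame, target_category: str = "P", min_run: int = 3
) -> list[Run]:
    """Maximal blocks of >= min_run consecutive sites of one category."""
    runs: list[Run] = []
    for chrom, grp in track.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        cats = grp["category"].to_numpy()
        pos = grp["pos"].to_numpy()
        start = None
        for k in range(len(cats) + 1):
            hit = k < len(cats) and cats[k] == target_category
            if hit and start is None:
                start = k
            elif not hit and start is not None:
                if k - start >= min_run:
                    runs.append(
                        Run(str(chrom), int(pos[start]), int(pos[k - 1]), k - start)
                    )
                start = None
    return runs


def run_coverage(runs: Sequence[Run], chrom_sizes: Mapping[str, int]) -> float:
    """Fraction of the genome spanned by runs (interval union over bp)."""
    genome = sum(chrom_sizes.values())
    if genome <= 0:
        raise ValueError("chromosome sizes must be positive")
    covered = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in runs:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"run on unknown chromosome {r.chrom!r}")
        if r.end > chrom_sizes[r.chrom]:
            raise ValueError(
                f"run {r.chrom}:{r.start}-{r.end} beyond chromosome end"
            )
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        covered += cur_e - cur_s + 1
    return covered / genome


def runs_to_bed(runs: Sequence[Run], path) -> None:
    """Write runs as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in runs:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.n_sites}\n")
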