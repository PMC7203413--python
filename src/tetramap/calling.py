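"""GBS genotype calling and filtering: multi-sample VCF to a presence/absence matrix.

The caller follows a four-step recipe designed for early-generation
backcross populations genotyped at modest depth with a diploid caller:

1. thin sites within 100 bp of each other (nearby sites on one read carry
   little non-redundant information);
2. keep biallelic sites with mean per-sample depth >= 10;
3. call from the PL field: take the minimum-PL genotype, but assign MISSING
   when the second-largest genotype probability 10**(-PL/10) exceeds 0.05;
4. homozygous-reference calls below 6x coverage become MISSING.

Because the samples are tetraploid but the PLs are diploid-style, calls are
collapsed to donor-allele presence/absence: AA (hom reference) vs AB
(alt allele present). BB candidates map to AB by default (`bb_policy`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "HOM",
    "HET",
    "MISSING",
    "SiteRecord",
    "GenotypeMatrix",
    "read_vcf",
    "thin_sites",
    "filter_biallelic_depth",
    "call_genotype",
    "call_site",
    "build_matrix",
    "drop_low_coverage_individuals",
]

# call codes: presence/absence coding of tetraploid genotypes
HOM = 0  # AA, homozygous reference — donor allele absent
HET = 1  # AB, donor (alt) allele present
MISSING = -1

_CALL_LABELS = {HOM: "AA", HET: "AB", MISSING: "NA"}
_LABEL_CALLS = {v: k for k, v in _CALL_LABELS.items()}


@dataclass
class SiteRecord:
    """One VCF site with per-sample depth, allele depths and PLs."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    depth: np.ndarray  # (n_samples,)
    pl: np.ndarray  # (n_samples, 3), NaN where absent
    ad: np.ndarray | None = None  # (n_samples, 2)
    id: str | None = None
    qual: float | None = None

    @property
    def mean_depth(self) -> float:
        return float(np.mean(self.depth))


def read_vcf(path: str | Path) -> tuple[list[str], list[SiteRecord]]:
    """Load a multi-sample VCF into SiteRecords (requires FORMAT DP and PL)."""
    records: list[SiteRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        n = len(samples)
        for rec in vcf:
            depth = np.zeros(n, dtype=np.int64)
            pl = np.full((n, 3), np.nan)
            ad = np.zeros((n, 2), dtype=np.int64)
            for i, s in enumerate(samples):
                smp = rec.samples[s]
                dp = smp.get("DP")
                depth[i] = 0 if dp is None else dp
                pls = smp.get("PL")
                if pls is not None and len(pls) == 3 and None not in pls:
                    pl[i] = pls
                adv = smp.get("AD")
                if adv is not None and len(adv) >= 2 and None not in adv[:2]:
                    ad[i] = adv[:2]
            records.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    depth=depth,
                    pl=pl,
                    ad=ad,
                    id=rec.id,
                    qual=rec.qual,
                )
            )
    return samples, records


def thin_sites(
    records: Sequence[SiteRecord], min_spacing: int = 100
) -> list[SiteRecord]:
    """Greedy per-chromosome thinning: keep a site only if it lies at least
    ``min_spacing`` bp beyond the previously retained site. The first site of
    each chromosome is always kept. Input must be sorted by (chrom, pos)."""
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    kept: list[SiteRecord] = []
    last: dict[str, int] = {}
    for rec in records:
        prev = last.get(rec.chrom)
        if prev is None or rec.pos - prev >= min_spacing:
            kept.append(rec)
            last[rec.chrom] = rec.pos
    return kept


def filter_biallelic_depth(
    records: Iterable[SiteRecord], min_avg_depth: float = 10.0
) -> list[SiteRecord]:
    """Keep biallelic sites whose arithmetic mean per-sample depth (missing
    samples counting 0) reaches ``min_avg_depth``."""
    return [
        r
        for r in records
        if len(r.alts) == 1 and r.mean_depth >= min_avg_depth
    ]


def call_genotype(
    pl: Sequence[float],
    depth: int,
    ambiguity: float = 0.05,
    hom_min_depth: int = 6,
    bb_policy: str = "het",
) -> int:
    """Call one sample-site from its PL triple and read depth.

    The candidate is the minimum-PL genotype. The call becomes MISSING when
    the second-largest genotype probability 10**(-PL/10) exceeds the
    ambiguity threshold (ties in the minimum included), or when a
    hom-reference candidate has depth below ``hom_min_depth``. BB candidates
    map to HET (alt presence) under the default policy.
    """
    pl = np.asarray(pl, dtype=float)
    if pl.shape != (3,) or not np.all(np.isfinite(pl)) or np.any(pl < 0):
        raise ValueError(f"malformed PL triple: {pl!r}")
    if bb_policy not in ("het", "missing"):
        raise ValueError(f"bb_policy must be 'het' or 'missing', got {bb_policy!r}")
    p = np.power(10.0, -pl / 10.0)
    order = np.sort(p)[::-1]
    if order[1] > ambiguity:
        return MISSING
    candidate = int(np.argmin(pl))
    if np.sum(pl == pl[candidate]) > 1:
        # two genotypes equally likely: undecidable
        return MISSING
    if candidate == 0:
        return MISSING if depth < hom_min_depth else HOM
    if candidate == 2:
        return HET if bb_policy == "het" else MISSING
    return HET


def call_site(
    record: SiteRecord,
    ambiguity: float = 0.05,
    hom_min_depth: int = 6,
    bb_policy: str = "het",
) -> np.ndarray:
    """Vectorised `call_genotype` over all samples of a site."""
    pl = record.pl
    n = pl.shape[0]
    calls = np.full(n, MISSING, dtype=np.int8)
    ok = np.all(np.isfinite(pl), axis=1)
    if not np.any(ok):
        return calls
    p = np.power(10.0, -pl[ok] / 10.0)
    second = np.sort(p, axis=1)[:, 1]
    cand = np.argmin(pl[ok], axis=1)
    tied = np.sum(pl[ok] == np.min(pl[ok], axis=1, keepdims=True), axis=1) > 1
    depth = record.depth[ok]
    out = np.where(cand == 0, HOM, HET).astype(np.int8)
    if bb_policy == "missing":
        out = np.where(cand == 2, MISSING, out).astype(np.int8)
    out[second > ambiguity] = MISSING
    out[tied] = MISSING
    out[(cand == 0) & (depth < hom_min_depth)] = MISSING
    calls[ok] = out
    return calls


@dataclass
class GenotypeMatrix:
    """Markers x individuals presence/absence calls with depth metadata.

    ``calls`` holds int8 codes (HOM=0, HET=1, MISSING=-1); ``chrom``/``pos``
    index the markers physically; ``depth`` mirrors calls with read depths.
    """

    calls: pd.DataFrame
    chrom: pd.Series
    pos: pd.Series
    depth: pd.DataFrame | None = None

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)

    def counts(self) -> pd.DataFrame:
        """Per-marker nAA / nAB / nMissing."""
        v = self.calls.to_numpy()
        return pd.DataFrame(
            {
                "nAA": (v == HOM).sum(axis=1),
                "nAB": (v == HET).sum(axis=1),
                "nMissing": (v == MISSING).sum(axis=1),
            },
            index=self.calls.index,
        )

    def qc_table(self) -> pd.DataFrame:
        qc = self.counts()
        qc.insert(0, "chrom", self.chrom)
        qc.insert(1, "pos", self.pos)
        qc["missing_fraction"] = qc["nMissing"] / len(self.individuals)
        if self.depth is not None:
            qc["mean_depth"] = self.depth.mean(axis=1)
        return qc

    def subset(self, markers=None, individuals=None) -> "GenotypeMatrix":
        calls = self.calls
        depth = self.depth
        if markers is not None:
            calls = calls.loc[markers]
            depth = depth.loc[markers] if depth is not None else None
        if individuals is not None:
            calls = calls[individuals]
            depth = depth[individuals] if depth is not None else None
        return GenotypeMatrix(
            calls, self.chrom.loc[calls.index], self.pos.loc[calls.index], depth
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.calls.apply(lambda col: col.map(_CALL_LABELS))
        out.insert(0, "chrom", self.chrom)
        out.insert(1, "pos", self.pos)
        out.to_csv(path, index_label="marker")

    @staticmethod
    def from_csv(path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col="marker", keep_default_na=False)
        chrom = df.pop("chrom")
        pos = df.pop("pos").astype(np.int64)
        calls = df.apply(lambda col: col.map(_LABEL_CALLS)).astype(np.int8)
        return GenotypeMatrix(calls, chrom, pos)


def build_matrix(
    records: Sequence[SiteRecord],
    samples: Sequence[str],
    max_marker_missing: float = 0.3,
    ambiguity: float = 0.05,
    hom_min_depth: int = 6,
    bb_policy: str = "het",
) -> GenotypeMatrix:
    """Call every retained site and assemble the genotype matrix.

    Markers whose missing fraction exceeds ``max_marker_missing`` are
    dropped, as are monomorphic markers (no AA or no AB observed).
    """
    if not samples:
        raise ValueError("no samples")
    rows, ids, chroms, poss, depths = [], [], [], [], []
    n = len(samples)
    for i, rec in enumerate(records):
        calls = call_site(rec, ambiguity, hom_min_depth, bb_policy)
        if np.sum(calls == MISSING) / n > max_marker_missing:
            continue
        if not (np.any(calls == HOM) and np.any(calls == HET)):
            continue  # non-polymorphic
        mid = rec.id or f"{rec.chrom}_{rec.pos}"
        rows.append(calls)
        ids.append(mid)
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        depths.append(rec.depth)
    if not rows:
        calls_df = pd.DataFrame(
            np.empty((0, n), dtype=np.int8), columns=list(samples)
        )
        return GenotypeMatrix(
            calls_df,
            pd.Series(dtype=object),
            pd.Series(dtype=np.int64),
            pd.DataFrame(np.empty((0, n)), columns=list(samples)),
        )
    calls_df = pd.DataFrame(
        np.vstack(rows), index=ids, columns=list(samples), dtype=np.int8
    )
    depth_df = pd.DataFrame(
        np.vstack(depths), index=ids, columns=list(samples)
    )
    logger.info("build_matrix: %d markers retained", len(ids))
    return GenotypeMatrix(
        calls_df,
        pd.Series(chroms, index=ids),
        pd.Series(poss, index=ids),
        depth_df,
    )


def drop_low_coverage_individuals(
    matrix: GenotypeMatrix, min_called_fraction: float = 0.2
) -> GenotypeMatrix:
    """Remove individuals whose non-missing call fraction falls below the
    threshold (analogue of dropping very low-coverage samples)."""
    called = (matrix.calls != MISSING).mean(axis=0)
    keep = called[called >= min_called_fraction].index
    dropped = [s for s in matrix.individuals if s not in set(keep)]
    if dropped:
        logger.info(
            "dropping %d low-coverage individuals: %s", len(dropped), dropped
        )
    if len(keep) == 0:
        raise ValueError("all individuals removed by coverage filter")
    return matrix.subset(individuals=list(keep))
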