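"""Synthetic autotetraploid BC1F1 populations and GBS-style VCF output.

The generator emulates the mapping design of a (tetraploid inbred recurrent
parent) x (tetraploid F1 hybrid) backcross: the F1 carries donor alleles at
simplex or duplex dosage, transmits a two-chromatid gamete per chromosome,
and the recurrent parent contributes a null gamete, so progeny dosages are
0-2.

Two sampling modes are supported:

* **linked multilocus** (``alpha = 0`` only): per meiosis one of the three
  bivalent pairings is drawn uniformly; each bivalent transmits one
  chromatid whose homolog-of-origin switches along the chromosome as a
  no-interference (Haldane) crossover process on the cM scale. Marginally
  each locus segregates under random chromosome segregation.
* **single-locus** (any alpha in [0, 1/6]): marker genotypes are drawn
  independently from :func:`tetramap.segmodels.gamete_dosage_distribution`.
  Requesting linked simulation with alpha > 0 is an explicit error — the
  bivalent machinery realises alpha = 0 at every locus.

GBS reads are modelled per sample-site as depth ~ Poisson(mean_depth) with
alt reads ~ Binomial(depth, f), f the error-adjusted alt-allele fraction
dosage/4. PL fields are diploid-style three-genotype phred likelihoods
(alt fractions 0, 1/2, 1), normalised to a minimum of 0 — mimicking a
diploid caller applied to tetraploid samples whose coverage cannot resolve
heterozygous dosage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .segmodels import SegModel, gamete_dosage_distribution

__all__ = [
    "MarkerDef",
    "Chromosome",
    "GenomeLayout",
    "SimulatedPopulation",
    "simulate_bc1_population",
    "simulate_gbs_vcf",
    "simulate_mosaic_trio",
]

_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))

#: PL values are capped here (likelihood exactly zero under a genotype).
PL_CAP = 9999


@dataclass(frozen=True)
class MarkerDef:
    """A marker position with the donor-allele dosage of the F1 parent."""

    id: str
    chrom: str
    pos: int  # 1-based bp
    f1_dosage: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1")
        if not 0 <= self.f1_dosage <= 4:
            raise ValueError(f"marker {self.id}: f1_dosage must lie in 0..4")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float
    markers: tuple[MarkerDef, ...]

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError(f"{self.name}: cM length must be > 0")
        pos = [m.pos for m in self.markers]
        if pos != sorted(pos):
            raise ValueError(f"{self.name}: markers must be sorted by pos")
        if pos and pos[-1] > self.length_bp:
            raise ValueError(f"{self.name}: marker beyond chromosome end")

    def marker_cm(self) -> np.ndarray:
        """Genetic positions of the markers, bp mapped linearly to cM."""
        return np.array(
            [m.pos / self.length_bp * self.length_cm for m in self.markers]
        )


@dataclass(frozen=True)
class GenomeLayout:
    chromosomes: tuple[Chromosome, ...]

    def markers(self) -> list[MarkerDef]:
        return [m for c in self.chromosomes for m in c.markers]

    @property
    def n_markers(self) -> int:
        return sum(len(c.markers) for c in self.chromosomes)

    @staticmethod
    def random(
        n_chromosomes: int = 2,
        markers_per_chromosome: int = 50,
        length_bp: int = 60_000_000,
        length_cm: float = 120.0,
        simplex_fraction: float = 0.5,
        seed: int | None = None,
        chromosome_dosages: Sequence[int | None] | None = None,
    ) -> "GenomeLayout":
        """Random marker layout with a simplex/duplex dosage mix.

        The true dosage spectrum of the F1 is unknown in real populations,
        so the simplex:duplex mix is a parameter (default an even random
        split per marker). ``chromosome_dosages`` instead fixes one dosage
        class per chromosome (entries 1/2, or None for a random mix on that
        chromosome) — mimicking an F1 whose donor segments are homozygous
        or heterozygous at chromosome scale, which yields the
        class-homogeneous linkage groups seen in real maps.
        """
        rng = np.random.default_rng(seed)
        if chromosome_dosages is not None:
            if len(chromosome_dosages) != n_chromosomes:
                raise ValueError("need one dosage entry per chromosome")
        chroms = []
        for c in range(1, n_chromosomes + 1):
            pos = np.sort(
                rng.choice(
                    np.arange(1, length_bp + 1),
                    size=markers_per_chromosome,
                    replace=False,
                )
            )
            fixed = (
                chromosome_dosages[c - 1]
                if chromosome_dosages is not None
                else None
            )
            if fixed is None:
                dosages = np.where(
                    rng.random(markers_per_chromosome) < simplex_fraction, 1, 2
                )
            else:
                dosages = np.full(markers_per_chromosome, int(fixed))
            markers = tuple(
                MarkerDef(f"S{c}_{p}", f"Chr{c:02d}", int(p), int(d))
                for p, d in zip(pos, dosages)
            )
            chroms.append(
                Chromosome(f"Chr{c:02d}", length_bp, length_cm, markers)
            )
        return GenomeLayout(tuple(chroms))


@dataclass
class SimulatedPopulation:
    """True donor-allele dosages (0-2) of BC1 progeny, markers x individuals."""

    truth: pd.DataFrame
    layout: GenomeLayout
    model: SegModel
    seed: int
    marker_table: pd.DataFrame = field(repr=False, default=None)

    def het_fraction(self) -> pd.Series:
        """Observed fraction of progeny carrying the donor allele per marker."""
        return (self.truth > 0).mean(axis=1)


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def simulate_bc1_population(
    layout: GenomeLayout,
    n: int,
    model: SegModel,
    seed: int,
    linked: bool = True,
) -> SimulatedPopulation:
    """Simulate the true genotypes of a BC1F1 population.

    With ``linked=True`` (default) chromosomes are transmitted through the
    bivalent-pairing meiosis model (alpha = 0, Haldane crossovers). With
    ``linked=False`` every marker is drawn independently from its
    single-locus gamete distribution, which is the only mode supporting
    alpha > 0.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    alpha_pos = float(model.alpha) > 0
    multilocus = any(len(c.markers) > 1 for c in layout.chromosomes)
    if linked and alpha_pos and multilocus:
        raise ValueError(
            "unsupported combination: double reduction (alpha > 0) is only "
            "available in single-locus mode (linked=False); the bivalent "
            "meiosis simulator realises alpha = 0"
        )

    ss = np.random.SeedSequence(seed)
    pairing_rng, crossover_rng, locus_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    blocks: list[np.ndarray] = []
    ids: list[str] = []
    for chrom in layout.chromosomes:
        m = len(chrom.markers)
        if m == 0:
            continue
        ids += [mk.id for mk in chrom.markers]
        dosages = np.array([mk.f1_dosage for mk in chrom.markers])
        if not linked or alpha_pos:
            probs = np.stack(
                [
                    np.array(
                        gamete_dosage_distribution(int(d), model).as_tuple(),
                        dtype=float,
                    )
                    for d in dosages
                ]
            )  # m x 3, columns p0,p1,p2
            u = locus_rng.random((m, n))
            cum = np.cumsum(probs, axis=1)
            block = (u[:, :] >= cum[:, [0]]).astype(np.int8) + (
                u[:, :] >= cum[:, [1]]
            ).astype(np.int8)
            blocks.append(block)
            continue

        cm = chrom.marker_cm()
        r = _haldane_r(np.diff(cm))  # m-1 interval recombination fractions
        pairing = pairing_rng.integers(0, 3, size=n)
        dosage_block = np.zeros((m, n), dtype=np.int8)
        for p_idx, bivalents in enumerate(_PAIRINGS):
            sel = np.flatnonzero(pairing == p_idx)
            if sel.size == 0:
                continue
            for h_a, h_b in bivalents:
                # state 0 -> copying homolog h_a, 1 -> h_b, per marker
                start = crossover_rng.integers(0, 2, size=sel.size)
                flips = (
                    crossover_rng.random((sel.size, m - 1)) < r
                ).astype(np.int8)
                state = np.empty((sel.size, m), dtype=np.int8)
                state[:, 0] = start
                if m > 1:
                    state[:, 1:] = (
                        start[:, None] + np.cumsum(flips, axis=1)
                    ) % 2
                homolog = np.where(state == 0, h_a, h_b)  # sel x m
                allele = (homolog < dosages[None, :]).astype(np.int8)
                dosage_block[:, sel] += allele.T
        blocks.append(dosage_block)

    truth = pd.DataFrame(
        np.vstack(blocks),
        index=ids,
        columns=[f"I{i + 1:03d}" for i in range(n)],
        dtype=np.int8,
    )
    marker_table = pd.DataFrame(
        {
            "chrom": [m.chrom for m in layout.markers()],
            "pos": [m.pos for m in layout.markers()],
            "f1_dosage": [m.f1_dosage for m in layout.markers()],
        },
        index=ids,
    )
    return SimulatedPopulation(truth, layout, model, seed, marker_table)


def _pl_from_reads(k: int, depth: int, error_rate: float) -> tuple[int, int, int]:
    """Diploid-style PLs for alt-read count k of depth reads.

    Genotype alt fractions are 0, 1/2, 1; sequencing error moves the read
    alt probability to e, 1/2, 1-e. Likelihood-zero genotypes are capped.
    """
    if depth == 0:
        return (0, 0, 0)
    pls = []
    for p in (error_rate, 0.5, 1.0 - error_rate):
        if (p == 0.0 and k > 0) or (p == 1.0 and k < depth):
            ll = -math.inf
        else:
            ll = (k * math.log10(p) if k else 0.0) + (
                (depth - k) * math.log10(1.0 - p) if depth > k else 0.0
            )
        pls.append(ll)
    best = max(pls)
    return tuple(
        PL_CAP if ll == -math.inf else min(PL_CAP, round(10.0 * (best - ll)))
        for ll in pls
    )


def simulate_gbs_vcf(
    pop: SimulatedPopulation,
    mean_depth: float,
    error_rate: float,
    seed: int,
    out: str,
) -> str:
    """Write a GBS-style multi-sample VCF for a simulated population.

    Every sample-site record carries DP, AD and a three-value PL; GT is set
    missing (the downstream caller works from PL alone). Records are sorted
    by (chrom, pos). Returns the output path.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    samples = list(pop.truth.columns)

    header = pysam.VariantHeader()
    header.add_line('##source=tetramap-simulate')
    for chrom in pop.layout.chromosomes:
        header.contigs.add(chrom.name, length=chrom.length_bp)
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths (ref, alt)">'
    )
    header.add_line(
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
        '"Phred-scaled genotype likelihoods (ref-hom, het, alt-hom)">'
    )
    for s in samples:
        header.add_sample(s)

    markers = pop.layout.markers()
    try:
        vcf = pysam.VariantFile(out, "w", header=header)
    except OSError as exc:  # pragma: no cover - I/O context
        raise OSError(f"cannot write VCF to {out!r}: {exc}") from exc
    with vcf:
        for marker in markers:
            dosages = pop.truth.loc[marker.id].to_numpy()
            depth = rng.poisson(mean_depth, size=len(samples))
            f = dosages / 4.0
            p_alt = f * (1.0 - error_rate) + (1.0 - f) * error_rate
            alt = rng.binomial(depth, p_alt)
            rec = vcf.new_record(
                contig=marker.chrom,
                start=marker.pos - 1,
                stop=marker.pos,
                alleles=("A", "C"),
                id=marker.id,
            )
            rec.qual = 60.0
            for i, s in enumerate(samples):
                smp = rec.samples[s]
                smp["GT"] = (None, None)
                smp["DP"] = int(depth[i])
                smp["AD"] = (int(depth[i] - alt[i]), int(alt[i]))
                smp["PL"] = _pl_from_reads(int(alt[i]), int(depth[i]), error_rate)
            vcf.write(rec)
    return out


def simulate_mosaic_trio(
    n_chromosomes: int = 2,
    chrom_length_bp: int = 50_000_000,
    sites_per_chromosome: int = 300,
    mean_block_sites: float = 15.0,
    p_origin_propinquum: float = 0.35,
    het_block_fraction: float = 0.1,
    seed: int = 0,
    out: str | None = None,
) -> pd.DataFrame:
    """Build a synthetic hybrid genome spliced from progenitor haplotypes.

    Emulates the whole-genome comparison of a hybrid polyploid against its
    two progenitors plus a conspecific control: sites polymorphic between
    the reference progenitor (ref allele) and the donor progenitor (alt
    allele) are laid along each chromosome, and the hybrid's true origin
    switches in blocks (geometric block lengths in sites). Block origins are
    ``P`` (donor homozygous), ``B`` (reference homozygous) or ``H_BP``
    (one allele from each progenitor).

    Returns the per-site truth table (chrom, pos, category and genotypes);
    if ``out`` is given, also writes a 4-sample VCF (target, control,
    propinquum_1, propinquum_2) with uniform QUAL 60 and DP 30.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        chrom = f"Chr{c:02d}"
        pos = np.sort(
            rng.choice(
                np.arange(1, chrom_length_bp + 1),
                size=sites_per_chromosome,
                replace=False,
            )
        )
        i = 0
        while i < sites_per_chromosome:
            n_sites = 1 + rng.geometric(1.0 / mean_block_sites)
            u = rng.random()
            if u < p_origin_propinquum:
                origin = "P"
            elif u < p_origin_propinquum + het_block_fraction:
                origin = "H_BP"
            else:
                origin = "B"
            for p in pos[i : i + n_sites]:
                rows.append((chrom, int(p), origin))
            i += n_sites
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "category"])

    gt_map = {"P": (1, 1), "B": (0, 0), "H_BP": (0, 1)}
    truth["target_gt"] = truth["category"].map(gt_map)

    if out is not None:
        header = pysam.VariantHeader()
        header.add_line("##source=tetramap-mosaic (synthetic progenitor trio)")
        for c in range(1, n_chromosomes + 1):
            header.contigs.add(f"Chr{c:02d}", length=chrom_length_bp)
        header.add_line(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
        header.add_line(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
        )
        samples = ["target", "control", "propinquum_1", "propinquum_2"]
        for s in samples:
            header.add_sample(s)
        with pysam.VariantFile(out, "w", header=header) as vcf:
            for row in truth.itertuples():
                rec = vcf.new_record(
                    contig=row.chrom,
                    start=row.pos - 1,
                    stop=row.pos,
                    alleles=("A", "G"),
                )
                rec.qual = 60.0
                gts = {
                    "target": row.target_gt,
                    "control": (0, 0),
                    "propinquum_1": (1, 1),
                    "propinquum_2": (1, 1),
                }
                for s in samples:
                    rec.samples[s]["GT"] = gts[s]
                    rec.samples[s]["DP"] = 30
                vcf.write(rec)
    return truth
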