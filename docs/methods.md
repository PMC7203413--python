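# Methods

## Single-locus segregation models

An autotetraploid locus is described by the parent's donor-allele dosage
d ∈ 0..4 and a double-reduction coefficient α ∈ [0, 1/6] — the probability
that a gamete receives two chromatids of the same original homolog, which
requires a crossover between locus and centromere. The closed-form gamete
dosage distributions (`gamete_dosage_distribution`) are

| d | p₂ | p₁ | p₀ |
|---|----|----|----|
| 1 | α/4 | (1−α)/2 | 1/2 + α/4 |
| 2 | (1+2α)/6 | (4−4α)/6 | (1+2α)/6 |

with d = 0 degenerate, and d = 3, 4 by allele-swap symmetry. The three
named models fix α: random chromosome 0, random chromatid 1/7, maximum
equational 1/6. `enumerate_chromatid_gametes` re-derives the same
distributions by exhaustive enumeration (homolog pairs; all C(8,2)
chromatid pairs; or obligate-exchange centromere units averaged over the
three bivalent pairings, 24 legal pairs each) in `fractions.Fraction`
arithmetic, and the test suite asserts exact equality of the two routes
for every dosage and model. Backcross progeny scored for donor presence
segregate het:hom = (1−p₀):p₀; because p₀ increases with α for both
simplex and duplex loci, this ratio *decreases* with double reduction
(1:1 → 13:15 → 11:13 and 5:1 → 11:3 → 7:2).

## Meiosis simulator

The multilocus simulator (`simulate_bc1_population`) draws, per meiosis
and chromosome, one of the three bivalent pairings uniformly; each
bivalent transmits one chromatid whose homolog-of-origin flips along the
chromosome as a no-interference (Haldane) process — per marker interval of
d cM the flip probability is r = (1−e^(−2d/100))/2. Donor alleles sit on
the first d homologs. Marginally every locus realises random chromosome
segregation (α = 0); this is exact, not approximate. α > 0 is supported
only in single-locus mode (independent draws from the closed forms);
requesting linked simulation with α > 0 raises. Physical positions map
linearly to the chromosome's genetic length. Crossover interference is not
modelled, and neither are quadrivalents or preferential pairing.

The read layer (`simulate_gbs_vcf`) draws depth ~ Poisson(mean_depth) per
sample-site and alt reads ~ Binomial(depth, f(1−e) + (1−f)e) with
f = dosage/4. PLs are deliberately *diploid-style* (alt fractions 0, 1/2,
1), mimicking a diploid caller applied to tetraploid samples whose
coverage cannot resolve heterozygous dosage; likelihood-zero genotypes are
capped at PL 9999 and GT is written missing. All randomness flows from one
seed through independently spawned streams (pairing, crossovers, reads).

A consequence worth knowing: with any nonzero read error, a dosage-1
heterozygote (alt fraction 1/4) that happens to sample few alt reads is
*more* likely under the hom-reference-with-errors model than under the
diploid het model, so the caller produces a percent-level false-hom rate
for simplex hets that shrinks with depth (~9% at depth 20, ~1% at depth
30 with e = 0.005). This deflates observed het:hom ratios below their
polysomic expectations and inflates two-point map lengths — the same
pathologies seen in real presence/absence maps of polysomic data. Passing
tests on the noise-free settings therefore demonstrates correctness of the
machinery, not that real GBS data of arbitrary depth would map cleanly.

## Genotype calling

`call_genotype` follows the four-step recipe: candidate = minimum-PL
genotype; probabilities p = 10^(−PL/10); MISSING if the second-largest p
exceeds 0.05 (ties in the minimum included — two equally likely genotypes
are undecidable, and a depth-0 all-zero PL is the degenerate case);
MISSING if a hom-reference candidate has depth < 6. BB candidates map to
HET under the default `bb_policy="het"`: in a backcross to the
reference-homozygous parent the datum is alt-allele presence. Site-level
filters: greedy 100-bp thinning per chromosome (first site kept), exactly
one alt allele, arithmetic mean DP over *all* samples ≥ 10 (the denominator
is a convention; uncalled samples count 0). Markers are dropped at > 30%
missing calls or when monomorphic; individuals below a 20% called fraction
are removed (the source study says only "very low sequence coverage"; 0.2
is this package's default).

## Linkage maps

Two-point estimation uses backcross coding: recombinant iff calls differ;
r̂ = recombinants/informative, phase-flipped into [0, 0.5] when above 0.5
(flips are recorded); LOD = n·[r̂·log₁₀(2r̂) + (1−r̂)·log₁₀(2(1−r̂))]. For
duplex markers this is a knowingly biased proxy (mismatch ≈ (2/3)r near
coupling), accepted as in diploid-style mapping of polysomic data.

Clustering is single-linkage over pairs with LOD ≥ 10 and r̂ < 0.5, run
**per reference chromosome**. The restriction is not cosmetic: duplex
markers are heterozygous in ~5/6 of progeny, so two *unlinked* duplex
markers mismatch with probability ≈ 2·(5/6)·(1/6) ≈ 0.28, which the
1:1-null LOD misreads as linkage often enough (expected LOD ≈ 6 at
n = 141, upper tail past 10) to fuse chromosomes if clustering is run
genome-wide.

Binning collapses markers within 1 cM of provisional positions computed
from adjacent two-point rfs in physical order. Those rfs are first
de-attenuated for the configured genotyping-error probability e
(p_obs = r(1−2e₂) + e₂ with e₂ = 2e(1−e)); without this correction, error
alone pushes truly co-segregating markers past the bin width and their
relative order becomes unresolvable noise. Bin genotypes minimise missing
data: unanimous call, else majority, MISSING on ties.

De novo ordering is seriation: a greedy chain grown from the maximal-LOD
pair (nearest unused marker by rf at either end; ties by LOD, then
physical rank), refined by 2-opt segment reversals and or-opt relocations
of segments of length ≤ 3 until no move shortens the total adjacent
Kosambi length. One cleaning pass then blanks apparent double recombinants
spanning a single marker in the provisional order — the classic
genotyping-error signature — and re-runs the seriation. A
multipoint-likelihood ripple was evaluated and rejected: the two-state
chain it scores is misspecified for duplex presence/absence data and
degraded duplex orders. Orders are reported oriented with the physically
first marker leading; the objective is reversal-invariant.

Final distances come from per-interval EM over a two-state hidden chain
per individual (states = true HOM/HET; transitions = interval rf;
emissions correct with probability 1−error_prob, MISSING uninformative;
error_prob default 0.01), converged at relative log-likelihood change
< 1e-6 or 100 iterations (a warning is logged otherwise), then the Kosambi
function, cumulated from 0. Group summaries mirror published map tables:
marker count, length, average spacing = length/(markers−1), maximum
spacing, average AA and AB counts, and their ratio.

`merge_repulsion` tests whether a 1:5-type group is the repulsion phase of
a 5:1 group by inverting its calls and measuring cross-group LODs.

## Segregation analysis

Per marker: nAA/nAB counts, ratio, √ratio, and χ² (df = 1) against 1:1 and
5:1 with a direction sign. "Significantly higher than 5:1" is a two-sided
χ² at α = 0.05 filtered to the above direction; an exact one-sided
binomial is available as a cross-check and the type-I behaviour of the χ²
approximation is verified against the exact binomial rejection rate at
n = 141. Group classification uses the fixed published thresholds 1.82 /
0.55 with strict inequalities (boundary → balanced);
`ratio_threshold_from_alpha` solves (nAB−nAA)²/n = χ²₁(1−α) for
sensitivity analysis — note χ²₁(0.999) at n = 105 gives ≈ 1.95, not 1.82,
so the printed constants are treated as data, not re-derived. Pooling
across populations sums genotype counts before one test (Fisher's method
is available as an alternative). Distorted regions are maximal chains of
≥ 3 flagged markers with inter-marker gaps ≤ 5 Mb; the gap rule is this
package's choice, sized to the 1–6 Mb spans such studies report, and
configurable.

## Ancestry classification

Sites are filtered at QUAL ≥ 20, per-sample depth ≥ 10 (below → that
sample missing), and ≤ 30% missing across the named roles. Classification
of the target against two donor-progenitor accessions and a conspecific
control: UNKNOWN on missing data, on control ≠ hom-reference
(intra-species polymorphism), or on disagreeing donor accessions under the
conservative `consensus="all"` (``"any"`` takes their allele union); then
B (hom-ref), P (hom donor allele), H_BP (het ref/donor), H_PM (het
donor/novel — only reachable at multi-allelic sites, hence rare), N_M
(novel allele, no donor allele present; the het ref/novel case is assigned
here). Proportions exclude UNKNOWN from the denominator. Runs are maximal
blocks of ≥ 3 consecutive donor-classified sites; genome coverage is the
union of run spans over the summed chromosome lengths. The mosaic-trio
generator splices B/P/H-BP blocks with geometric lengths (mean 15 sites,
35% donor, 10% het) so classification and run recovery can be checked
against known truth; it does not model genotyping noise in the progenitor
calls or mixed-ancestry sites below marker resolution.

## Problem sizes and defaults

Simulated study conditions follow the source design where stated:
populations of 141 and 105 individuals, 50 markers per chromosome,
marker-level thresholds as printed (100 bp, depth 10, 0.05, 6×, LOD 10,
1 cM, error 0.01, 1.82/0.55, α = 0.05/0.001, runs ≥ 3, Q20/10/30%).
Unstated conditions are package choices: 60-Mb / 120-cM chromosomes
(sorghum-scale), an even simplex:duplex mix by default with an option to
fix one dosage class per chromosome (dosage class is a segment-scale
property of a real F₁, which is what makes real linkage groups
class-homogeneous), GBS depth 20 and read error 0.005 in the analysis
scripts, and recovery checks on two chromosomes rather than ten to keep
the suite fast. Monte-Carlo checks use 10⁵ progeny (single-locus
convergence) and 10⁴ null markers (type-I calibration).

## Known limitations

- Double reduction is single-locus only; no interference, quadrivalents,
  or preferential pairing.
- Presence/absence coding discards dosage: duplex two-point rfs are
  biased, duplex map lengths inflated, and duplex/simplex markers on one
  chromosome generally fall into separate linkage groups.
- The diploid-PL caller has an intrinsic false-hom rate for low-dosage
  heterozygotes at finite depth with nonzero read error.
- Ordering is heuristic seriation; adjacent markers closer than roughly
  the rf sampling noise (~1/√n in cM) are not reliably orderable, which is
  precisely what the 1-cM binning absorbs.
- The ancestry decision table assumes a largely homozygous control and
  donor accessions; heterozygous progenitor calls reduce to UNKNOWN under
  the default consensus policy.
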