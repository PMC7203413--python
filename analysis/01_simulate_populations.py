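#!/usr/bin/env python
"""Simulate two BC1F1 mapping populations and their GBS read data.

Emulates the study design: a tetraploid F1 (donor alleles at simplex or
duplex dosage, here one chromosome of each class plus one mixed) backcrossed
to the recurrent inbred, giving an H4-like population of 141 individuals and
an H6-like population of 105. Reads are Poisson depth 20 (GBS-scale) with
0.5% base error; truth matrices and VCFs go to results/analysis/.
"""

from pathlib import Path

from tetramap.segmodels import SegModel
from tetramap.simulate import (
    GenomeLayout,
    simulate_bc1_population,
    simulate_gbs_vcf,
)

OUT = Path("results/analysis")
POPULATIONS = {"H4": (141, 11), "H6": (105, 12)}
MEAN_DEPTH = 20.0
ERROR_RATE = 0.005


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout = GenomeLayout.random(
        n_chromosomes=3,
        markers_per_chromosome=50,
        seed=2024,
        chromosome_dosages=(1, 2, None),
    )
    for name, (n, seed) in POPULATIONS.items():
        pop = simulate_bc1_population(
            layout, n, SegModel("random_chromosome"), seed=seed
        )
        pop.truth.to_csv(OUT / f"{name}_truth.csv", index_label="marker")
        pop.marker_table.to_csv(OUT / f"{name}_markers.csv",
                                index_label="marker")
        vcf = OUT / f"{name}.vcf"
        simulate_gbs_vcf(pop, MEAN_DEPTH, ERROR_RATE, seed=seed + 100,
                         out=str(vcf))
        het = pop.het_fraction()
        by_class = pop.marker_table.join(het.rename("het")).groupby(
            "f1_dosage"
        )["het"].mean()
        print(f"{name}: n={n}, {pop.truth.shape[0]} markers -> {vcf}")
        for dosage, h in by_class.items():
            expected = {1: 0.5, 2: 5 / 6}[dosage]
            print(
                f"  dosage-{dosage} markers: mean het fraction "
                f"{h:.3f} (expected {expected:.3f})"
            )


if __name__ == "__main__":
    main()
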