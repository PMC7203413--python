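"""Shared fixtures: simulated populations, GBS VCFs and the mosaic trio.

Everything is generated programmatically at session scope; seeds are fixed
so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetramap import calling
from tetramap.segmodels import SegModel
from tetramap.simulate import (
    GenomeLayout,
    simulate_bc1_population,
    simulate_gbs_vcf,
    simulate_mosaic_trio,
)

RC = SegModel("random_chromosome")


@pytest.fixture(scope="session")
def mapping_layout():
    """Two 60-Mb / 120-cM chromosomes, 50 markers each, simplex/duplex mix."""
    return GenomeLayout.random(
        n_chromosomes=2, markers_per_chromosome=50, seed=20240
    )


@pytest.fixture(scope="session")
def rc_population(mapping_layout):
    """BC1F1 of n=141 under random chromosome segregation."""
    return simulate_bc1_population(mapping_layout, 141, RC, seed=77)


@pytest.fixture(scope="session")
def clean_matrix(rc_population, tmp_path_factory):
    """Noise-free depth-30 GBS calls of the n=141 population (plus truth)."""
    vcf = tmp_path_factory.mktemp("vcf") / "clean.vcf"
    simulate_gbs_vcf(rc_population, 30.0, 0.0, seed=5, out=str(vcf))
    samples, records = calling.read_vcf(vcf)
    records = calling.thin_sites(records)
    records = calling.filter_biallelic_depth(records)
    matrix = calling.build_matrix(records, samples)
    return rc_population, matrix


@pytest.fixture(scope="session")
def error_matrix():
    """n=141 calls carrying 0.5% genotyping error, for recovery checks.

    One simplex and one duplex chromosome (dosage class is a chromosome-
    scale property of the F1, which is what makes real linkage groups
    class-homogeneous), 50 markers each over 120 cM.
    """
    layout = GenomeLayout.random(
        n_chromosomes=2,
        markers_per_chromosome=50,
        seed=20240,
        chromosome_dosages=(1, 2),
    )
    pop = simulate_bc1_population(layout, 141, RC, seed=77)
    rng = np.random.default_rng(606)
    calls = (pop.truth > 0).astype(np.int8)
    flips = pd.DataFrame(
        rng.random(calls.shape) < 0.005,
        index=calls.index,
        columns=calls.columns,
    )
    calls = calls.mask(flips, 1 - calls).astype(np.int8)
    matrix = calling.GenotypeMatrix(
        calls,
        pop.marker_table["chrom"],
        pop.marker_table["pos"].astype(np.int64),
    )
    return pop, matrix


@pytest.fixture(scope="session")
def mosaic(tmp_path_factory):
    """Synthetic progenitor trio VCF and per-site origin truth."""
    vcf = tmp_path_factory.mktemp("trio") / "mosaic.vcf"
    truth = simulate_mosaic_trio(seed=404, out=str(vcf))
    return str(vcf), truth
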