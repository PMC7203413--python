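"""Two-point linkage, clustering, binning, ordering and map estimation."""

import numpy as np
import pandas as pd
import pytest

from tetramap.calling import HET, HOM, MISSING, GenotypeMatrix
from tetramap.linkage import (
    bin_markers,
    cluster_markers,
    estimate_map,
    estimate_rf,
    kosambi,
    kosambi_inverse,
    merge_repulsion,
    order_markers,
    pairwise_linkage,
)
from tetramap.segmodels import SegModel
from tetramap.simulate import Chromosome, GenomeLayout, MarkerDef, simulate_bc1_population


def _matrix(rows: dict, chrom=None, pos=None) -> GenotypeMatrix:
    calls = pd.DataFrame(
        {f"I{i}": col for i, col in enumerate(zip(*rows.values()))},
        index=list(rows),
        dtype=np.int8,
    )
    ids = list(rows)
    chrom = chrom or {m: "c1" for m in ids}
    pos = pos or {m: 1000 * (k + 1) for k, m in enumerate(ids)}
    return GenotypeMatrix(
        calls, pd.Series(chrom), pd.Series(pos, dtype=np.int64)
    )


def _simplex_population(n=200, m=30, seed=8, length_cm=60.0):
    markers = tuple(
        MarkerDef(f"M{i:02d}", "Chr01", 10_000 * (i + 1), 1) for i in range(m)
    )
    layout = GenomeLayout((Chromosome("Chr01", 10_000 * (m + 1), length_cm, markers),))
    pop = simulate_bc1_population(
        layout, n, SegModel("random_chromosome"), seed=seed
    )
    calls = (pop.truth > 0).astype(np.int8)
    return pop, GenotypeMatrix(
        calls,
        pd.Series({mk.id: mk.chrom for mk in markers}),
        pd.Series({mk.id: mk.pos for mk in markers}, dtype=np.int64),
    )


class TestKosambi:
    def test_anchor_values(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.2) == pytest.approx(25 * np.log(1.4 / 0.6), rel=1e-12)

    def test_strictly_increasing_and_linear_near_zero(self):
        r = np.linspace(0.0, 0.49, 200)
        d = kosambi(r)
        assert np.all(np.diff(d) > 0)
        small = np.array([1e-4, 1e-3, 5e-3])
        assert np.allclose(kosambi(small), 100 * small, rtol=1e-3)

    def test_inverse_round_trip(self):
        r = np.array([0.01, 0.1, 0.25, 0.4])
        assert np.allclose(kosambi_inverse(kosambi(r)), r, rtol=1e-10)


class TestTwoPoint:
    def test_identical_columns_give_rf_zero_max_lod(self):
        col = np.array([HOM, HET] * 50, dtype=np.int8)
        pl = estimate_rf(col, col)
        assert pl.rf == 0.0
        assert pl.lod == pytest.approx(100 * np.log10(2), rel=1e-12)

    def test_independent_columns_give_negligible_lod(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 400).astype(np.int8)
        b = rng.integers(0, 2, 400).astype(np.int8)
        assert estimate_rf(a, b).lod < 3

    def test_complement_columns_flip_phase(self):
        col = np.array([HOM, HET] * 50, dtype=np.int8)
        pl = estimate_rf(col, 1 - col)
        assert pl.phase_flipped and pl.rf == 0.0

    def test_too_few_informative_is_flagged(self):
        a = np.array([HOM, MISSING, MISSING], dtype=np.int8)
        b = np.array([HOM, HOM, HOM], dtype=np.int8)
        pl = estimate_rf(a, b)
        assert not pl.defined and pl.rf == 0.5 and pl.lod == 0.0

    def test_simulated_pair_recovers_haldane_rf(self):
        # 10 cM apart -> Haldane r = (1 - exp(-0.2))/2 = 0.0906
        markers = (
            MarkerDef("A", "Chr01", 1, 1),
            MarkerDef("B", "Chr01", 1_000_000, 1),
        )
        layout = GenomeLayout(
            (Chromosome("Chr01", 1_000_000, 10.0 * 1_000_000 / 999_999, markers),)
        )
        pop = simulate_bc1_population(
            layout, 10_000, SegModel("random_chromosome"), seed=17
        )
        calls = (pop.truth > 0).astype(np.int8).to_numpy()
        r_true = 0.5 * (1 - np.exp(-0.2))
        pl = estimate_rf(calls[0], calls[1])
        se = np.sqrt(r_true * (1 - r_true) / 10_000)
        assert abs(pl.rf - r_true) < 3 * se

    def test_pairwise_matches_scalar(self, clean_matrix):
        _, mat = clean_matrix
        sub = mat.subset(markers=mat.markers[:12])
        r, lod, n_inf, _ = pairwise_linkage(sub)
        x = sub.calls.to_numpy()
        for i in range(0, 12, 5):
            for j in range(i + 1, 12, 3):
                pl = estimate_rf(x[i], x[j])
                assert r[i, j] == pytest.approx(pl.rf, abs=1e-12)
                assert lod[i, j] == pytest.approx(pl.lod, abs=1e-9)
                assert n_inf[i, j] == pl.n_informative


class TestClustering:
    def test_chromosomes_never_mix(self, clean_matrix):
        _, mat = clean_matrix
        groups = cluster_markers(mat, min_lod=10)
        for g in groups:
            assert len({mat.chrom.loc[m] for m in g}) == 1

    def test_infinite_lod_gives_singletons(self, clean_matrix):
        _, mat = clean_matrix
        groups = cluster_markers(mat, min_lod=np.inf)
        assert all(len(g) == 1 for g in groups)

    def test_duplicated_marker_joins_its_twin(self):
        col = np.array([HOM, HET] * 30, dtype=np.int8)
        rng = np.random.default_rng(2)
        other = rng.integers(0, 2, 60).astype(np.int8)
        mat = _matrix({"m1": col, "m2": col.copy(), "m3": other})
        groups = cluster_markers(mat, min_lod=10)
        partition = {frozenset(g) for g in groups}
        assert frozenset({"m1", "m2"}) in partition

    def test_invariant_to_marker_input_order(self, clean_matrix):
        _, mat = clean_matrix
        sub = mat.subset(markers=mat.markers[:30])
        shuffled = sub.subset(
            markers=list(np.random.default_rng(3).permutation(sub.markers))
        )
        a = {frozenset(g) for g in cluster_markers(sub)}
        b = {frozenset(g) for g in cluster_markers(shuffled)}
        assert a == b


class TestBinning:
    def test_singleton_bin_equals_marker(self):
        col = np.array([HOM, HET, HOM, HET], dtype=np.int8)
        mat = _matrix({"m1": col}, pos={"m1": 500})
        binned, bin_map = bin_markers(mat, ["m1"])
        assert bin_map == {"m1": ["m1"]}
        assert (binned.calls.loc["m1"].to_numpy() == col).all()

    def test_cosegregating_markers_merge_and_fill_missing(self):
        base = [HET, HET, HOM, HOM, HET, HOM]
        rows = {
            "m1": base,
            "m2": [MISSING, HET, HOM, MISSING, HET, HOM],
        }
        mat = _matrix(rows, pos={"m1": 100, "m2": 110})
        binned, bin_map = bin_markers(mat, list(rows), bin_cm=1.0)
        assert bin_map == {"m1": ["m1", "m2"]}
        assert binned.calls.iloc[0].to_list() == base

    def test_conflicting_calls_tie_to_missing(self):
        # forced single bin isolates the merge rule from the distances
        rows = {
            "m1": [HET, HET, HOM],
            "m2": [HOM, MISSING, HOM],
        }
        mat = _matrix(rows, pos={"m1": 100, "m2": 110})
        binned, _ = bin_markers(mat, list(rows), bin_cm=1e9)
        # (AB,AA) 1-1 conflict -> NA; (AB,NA) -> AB; (AA,AA) -> AA
        assert binned.calls.iloc[0].to_list() == [MISSING, HET, HOM]

    def test_distant_markers_stay_separate(self, clean_matrix):
        _, mat = clean_matrix
        group = cluster_markers(mat, 10)[0]
        binned, bin_map = bin_markers(mat, group, bin_cm=1.0)
        assert sum(len(v) for v in bin_map.values()) == len(group)
        assert len(binned.markers) <= len(group)


class TestOrdering:
    def test_recovers_simulated_order(self):
        _, mat = _simplex_population(n=200, m=10, length_cm=50.0)
        order = order_markers(mat, mat.markers)
        assert order == mat.markers or order == mat.markers[::-1]

    def test_shuffled_noiseless_gradient_is_sorted(self):
        _, mat = _simplex_population(n=300, m=8, length_cm=70.0, seed=12)
        rng = np.random.default_rng(4)
        shuffled = list(rng.permutation(mat.markers))
        order = order_markers(mat, shuffled)
        assert order == sorted(order, key=lambda m: mat.pos.loc[m]) or (
            order == sorted(order, key=lambda m: -mat.pos.loc[m])
        )

    def test_two_markers_tie_break_by_position(self):
        col = np.array([HOM, HET] * 10, dtype=np.int8)
        mat = _matrix({"b": col, "a": col.copy()}, pos={"b": 2000, "a": 1000})
        assert order_markers(mat, ["b", "a"]) == ["a", "b"]


class TestMapEstimation:
    def test_zero_rf_interval_is_zero_cm(self):
        col = np.array([HOM, HET] * 40, dtype=np.int8)
        mat = _matrix({"m1": col, "m2": col.copy()})
        lg = estimate_map(mat, ["m1", "m2"], error_prob=0.0)
        assert lg.length_cm == pytest.approx(0.0, abs=1e-3)

    def test_em_fixed_point_equals_two_point_on_noiseless_data(self):
        _, mat = _simplex_population(n=250, m=6, length_cm=80.0, seed=21)
        x = mat.calls.to_numpy()
        lg = estimate_map(mat, mat.markers, error_prob=0.0)
        two_point = np.array(
            [estimate_rf(x[k], x[k + 1]).rf for k in range(5)]
        )
        assert np.allclose(lg.rf, two_point, atol=1e-4)

    def test_summary_ratio_is_mean_ab_over_mean_aa(self, clean_matrix):
        _, mat = clean_matrix
        group = cluster_markers(mat, 10)[0]
        lg = estimate_map(mat, group, "1A")
        counts = mat.subset(markers=group).counts()
        assert lg.summary["ab_aa_ratio"] == pytest.approx(
            counts["nAB"].mean() / counts["nAA"].mean()
        )
        assert lg.summary["n_markers"] == len(group)
        assert lg.summary["avg_spacing_cm"] == pytest.approx(
            lg.length_cm / (len(group) - 1)
        )

    def test_objective_invariant_under_reversal(self):
        _, mat = _simplex_population(n=150, m=7, seed=30)
        lg_fwd = estimate_map(mat, mat.markers, error_prob=0.0)
        lg_rev = estimate_map(mat, mat.markers[::-1], error_prob=0.0)
        assert lg_fwd.length_cm == pytest.approx(lg_rev.length_cm, rel=1e-9)


class TestRepulsionMerge:
    def test_exact_complement_coalesces(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 100).astype(np.int8)
        mat = _matrix({"m1": a, "m2": (1 - a).astype(np.int8)})
        report = merge_repulsion(mat, ["m1"], ["m2"])
        assert report.coalesces and report.max_lod == pytest.approx(
            100 * np.log10(2)
        )

    def test_independent_groups_do_not_merge(self):
        rng = np.random.default_rng(6)
        rows = {f"m{i}": rng.integers(0, 2, 141).astype(np.int8) for i in range(6)}
        mat = _matrix(rows)
        report = merge_repulsion(mat, ["m0", "m1", "m2"], ["m3", "m4", "m5"])
        assert not report.coalesces

    def test_empty_group_is_error(self, clean_matrix):
        _, mat = clean_matrix
        with pytest.raises(ValueError):
            merge_repulsion(mat, [], mat.markers[:2])
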