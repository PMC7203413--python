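"""Chi-square segregation tests, enrichment thresholds, distortion calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetramap.segregation import (
    BALANCED,
    BICOLOR_ENRICHED,
    HALEPENSE_ENRICHED,
    chisq_ratio_test,
    classify_group,
    cross_population_distortion,
    detect_distorted_markers,
    detect_distortion_regions,
    marker_segregation,
    ratio_threshold_from_alpha,
)


def _seg_frame(rows):
    """rows: marker -> (chrom, pos, nAA, nAB)."""
    recs = []
    for mid, (chrom, pos, naa, nab) in rows.items():
        s51, p51, d51 = chisq_ratio_test(nab, naa, (5, 1))
        recs.append(
            {
                "marker": mid,
                "chrom": chrom,
                "pos": pos,
                "nAA": naa,
                "nAB": nab,
                "p_5_1": p51,
                "direction_5_1": d51,
            }
        )
    return pd.DataFrame(recs).set_index("marker")


class TestChisq:
    @pytest.mark.parametrize(
        "nab, naa, expected", [((50), 50, (1, 1)), (100, 20, (5, 1))]
    )
    def test_exact_fit_gives_zero_statistic(self, nab, naa, expected):
        stat, p, _ = chisq_ratio_test(nab, naa, expected)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_extreme_case(self):
        # all 120 het vs 5:1: X2 = 400/100 + 400/20 = 24
        stat, p, direction = chisq_ratio_test(120, 0, (5, 1))
        assert stat == pytest.approx(24.0)
        assert p == pytest.approx(9.6e-7, rel=0.05)
        assert direction == "above"

    def test_symmetric_in_counts_for_1_1(self):
        s1, p1, d1 = chisq_ratio_test(70, 30, (1, 1))
        s2, p2, d2 = chisq_ratio_test(30, 70, (1, 1))
        assert s1 == s2 and p1 == p2 and (d1, d2) == ("above", "below")

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            chisq_ratio_test(0, 0, (1, 1))


def test_marker_segregation_ratios_and_sqrt_order(clean_matrix):
    _, mat = clean_matrix
    seg = marker_segregation(mat)
    counts = mat.counts().loc[seg.index]
    assert np.allclose(seg["ratio"], counts["nAB"] / counts["nAA"])
    # sqrt transform preserves the ratio ranking
    assert (
        seg["ratio"].rank(method="first").tolist()
        == seg["sqrt_ratio"].rank(method="first").tolist()
    )


class TestClassification:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (3.84, HALEPENSE_ENRICHED),
            (1.0, BALANCED),
            (0.28, BICOLOR_ENRICHED),
            (1.82, BALANCED),  # boundary values stay balanced
            (0.55, BALANCED),
        ],
    )
    def test_threshold_classes(self, ratio, expected):
        assert classify_group(ratio) == expected

    def test_thresholds_are_reciprocal(self):
        for n, alpha in ((105, 0.001), (141, 0.05), (80, 0.01)):
            t_hi, t_lo = ratio_threshold_from_alpha(n, alpha)
            assert t_hi * t_lo == pytest.approx(1.0)
            assert t_hi > 1 > t_lo

    def test_vanishing_evidence_drives_threshold_to_one(self):
        t_hi, _ = ratio_threshold_from_alpha(100, 1 - 1e-12)
        assert t_hi == pytest.approx(1.0, abs=1e-4)

    def test_threshold_consistent_with_exact_binomial_boundary(self):
        """The continuous solve at n=105, alpha=0.001 must separate exactly
        the count outcomes the chi-square test rejects (enumeration over
        nAB = 0..105)."""
        n, alpha = 105, 0.001
        t_hi, t_lo = ratio_threshold_from_alpha(n, alpha)
        crit = stats.chi2.ppf(1 - alpha, 1)
        for k in range(n + 1):
            stat = (2 * k - n) ** 2 / n
            ratio = k / (n - k) if k < n else np.inf
            if ratio > 1:
                assert (stat > crit) == (ratio > t_hi)
            elif ratio < 1:
                assert (stat > crit) == (ratio < t_lo)

    def test_group_classification_consistent_with_group_chisq(self):
        """Classifying a group's average counts by the alpha-derived ratio
        thresholds agrees with running the chi-square on those counts."""
        n = 105
        t_hi, t_lo = ratio_threshold_from_alpha(n, 0.001)
        for nab in (20, 40, 52, 53, 60, 80, 90):
            naa = n - nab
            stat, p, _ = chisq_ratio_test(nab, naa, (1, 1))
            cls = classify_group(nab / naa, t_hi, t_lo)
            assert (p < 0.001) == (cls != BALANCED)


class TestDistortion:
    def test_maximal_distortion_flagged(self):
        seg = _seg_frame({"m1": ("c1", 100, 0, 141), "m2": ("c1", 200, 24, 117)})
        flagged = detect_distorted_markers(seg)
        assert "m1" in flagged and "m2" not in flagged

    def test_empty_frame_gives_empty_set(self):
        assert detect_distorted_markers(pd.DataFrame()) == set()

    def test_intersection_requires_both_populations(self):
        a = _seg_frame({"m1": ("c1", 100, 0, 141), "m2": ("c1", 200, 24, 117)})
        b = _seg_frame({"m1": ("c1", 100, 30, 111), "m2": ("c1", 200, 20, 121)})
        inter, _ = cross_population_distortion(a, b)
        assert inter == set()

    def test_exact_5_1_not_pooled_significant(self):
        a = _seg_frame({"m1": ("c1", 100, 20, 100)})
        b = _seg_frame({"m1": ("c1", 100, 20, 100)})
        _, pooled = cross_population_distortion(a, b)
        assert pooled == set()

    def test_pooling_detects_shared_moderate_distortion(self):
        # 11:1 in both populations, n=141+105 pooled
        a = _seg_frame({"m1": ("c1", 100, 12, 129)})
        b = _seg_frame({"m1": ("c1", 100, 9, 96)})
        inter, pooled = cross_population_distortion(a, b)
        assert "m1" in pooled
        # independent oracle: one-sided exact binomial tail under 5:1
        n = 141 + 105
        p_exact = stats.binom.sf(129 + 96 - 1, n, 5 / 6)
        assert p_exact < 0.05

    def test_fisher_combination_agrees_here(self):
        a = _seg_frame({"m1": ("c1", 100, 12, 129)})
        b = _seg_frame({"m1": ("c1", 100, 9, 96)})
        _, pooled = cross_population_distortion(a, b, method="fisher")
        assert "m1" in pooled


class TestRegions:
    def test_three_markers_form_one_region(self):
        flagged = pd.DataFrame(
            {
                "chrom": ["c2"] * 3,
                "pos": [1_000_000, 2_500_000, 4_600_000],
            },
            index=["a", "b", "c"],
        )
        regions = detect_distortion_regions(flagged, max_gap_bp=5_000_000)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_significant) == (1_000_000, 4_600_000, 3)

    def test_two_markers_insufficient(self):
        flagged = pd.DataFrame(
            {"chrom": ["c1", "c1"], "pos": [100, 200]}, index=["a", "b"]
        )
        assert detect_distortion_regions(flagged) == []

    def test_large_gap_splits_chains(self):
        pos = [1, 2, 3, 50, 51, 52]
        flagged = pd.DataFrame(
            {"chrom": ["c1"] * 6, "pos": [p * 1_000_000 for p in pos]},
            index=list("abcdef"),
        )
        regions = detect_distortion_regions(flagged, max_gap_bp=5_000_000)
        assert [(r.start, r.end) for r in regions] == [
            (1_000_000, 3_000_000),
            (50_000_000, 52_000_000),
        ]
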