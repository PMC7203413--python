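"""Progenitor-allele classification, tallies, runs and genome coverage."""

import numpy as np
import pandas as pd
import pytest

from tetramap import ancestry as anc
from tetramap.ancestry import (
    AncestrySite,
    Run,
    classify_site,
    classify_track,
    detect_runs,
    filter_sites,
    run_coverage,
    tally_categories,
)

HOM_REF = (0, 0)
HOM_ALT = (1, 1)
HET_RA = (0, 1)


def _site(qual=60.0, depths=(30, 30, 30, 30), target=HOM_REF,
          control=HOM_REF, prop=(HOM_ALT, HOM_ALT)):
    names = ["target", "control", "p1", "p2"]
    return AncestrySite(
        "Chr01", 100, "A", ("G",), qual, target, control, tuple(prop),
        dict(zip(names, depths)),
    )


class TestFilter:
    def test_low_qual_removed(self):
        assert filter_sites([_site(qual=19.0)]) == []

    def test_high_missing_fraction_removed(self):
        # 2 of 4 samples below depth 10 -> 0.5 > 0.3
        assert filter_sites([_site(depths=(30, 30, 5, 5))]) == []

    def test_clean_site_retained_and_low_depth_masked(self):
        kept = filter_sites([_site(depths=(30, 30, 30, 5))])
        assert len(kept) == 1
        assert kept[0].propinquum == (HOM_ALT, None)

    def test_good_site_passes_all_thresholds(self):
        assert len(filter_sites([_site(depths=(12, 12, 12, 12))])) == 1


class TestClassify:
    @pytest.mark.parametrize(
        "target, prop, control, expected",
        [
            (HOM_REF, (HOM_ALT, HOM_ALT), HOM_REF, "B"),
            (HOM_ALT, (HOM_ALT, HOM_ALT), HOM_REF, "P"),
            (HET_RA, (HOM_ALT, HOM_ALT), HOM_REF, "H_BP"),
            # alt allele absent from both progenitors -> new mutation
            (HOM_ALT, (HOM_REF, HOM_REF), HOM_REF, "N_M"),
            (HET_RA, (HOM_REF, HOM_REF), HOM_REF, "N_M"),
            # het between a propinquum alt and a second, novel alt
            ((1, 2), (HOM_ALT, HOM_ALT), HOM_REF, "H_PM"),
            ((1, 2), ((2, 2), (2, 2)), HOM_REF, "H_PM"),
            # control polymorphic vs the reference -> uninformative
            (HOM_ALT, (HOM_ALT, HOM_ALT), HOM_ALT, "UNKNOWN"),
            (HOM_REF, (HOM_ALT, HOM_ALT), HET_RA, "UNKNOWN"),
            # missing data
            (None, (HOM_ALT, HOM_ALT), HOM_REF, "UNKNOWN"),
            (HOM_REF, (None, None), HOM_REF, "UNKNOWN"),
        ],
    )
    def test_decision_table(self, target, prop, control, expected):
        assert classify_site(target, prop, control) == expected

    def test_disagreeing_accessions_conservative_vs_any(self):
        prop = (HOM_ALT, HOM_REF)
        assert classify_site(HOM_ALT, prop, HOM_REF, consensus="all") == "UNKNOWN"
        assert classify_site(HOM_ALT, prop, HOM_REF, consensus="any") == "P"

    def test_one_missing_accession_under_all_policy(self):
        prop = (HOM_ALT, None)
        assert classify_site(HOM_ALT, prop, HOM_REF, consensus="all") == "UNKNOWN"
        assert classify_site(HOM_ALT, prop, HOM_REF, consensus="any") == "P"

    def test_every_site_gets_exactly_one_category(self, mosaic):
        vcf, truth = mosaic
        sites = anc.read_trio_vcf(
            vcf,
            {
                "target": "target",
                "control": "control",
                "propinquum": ["propinquum_1", "propinquum_2"],
            },
        )
        track = classify_track(filter_sites(sites))
        assert track["category"].isin(anc.CATEGORIES).all()
        assert len(track) == len(truth)


class TestTally:
    def test_unknown_excluded_from_denominator(self):
        track = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "pos": [1, 2, 3, 4],
                "category": ["B", "B", "P", "UNKNOWN"],
            }
        )
        tally = tally_categories(track)
        assert tally.loc["B", "proportion"] == pytest.approx(2 / 3)
        assert tally.loc["P", "proportion"] == pytest.approx(1 / 3)
        assert np.isnan(tally.loc["UNKNOWN", "proportion"])
        assert tally["count"].sum() == 4

    def test_all_unknown_is_error(self):
        track = pd.DataFrame(
            {"chrom": ["c"], "pos": [1], "category": ["UNKNOWN"]}
        )
        with pytest.raises(ValueError):
            tally_categories(track)


class TestRuns:
    def _track(self, cats, chrom="c1"):
        return pd.DataFrame(
            {
                "chrom": [chrom] * len(cats),
                "pos": [(i + 1) * 1000 for i in range(len(cats))],
                "category": list(cats),
            }
        )

    def test_minimal_run_detected(self):
        runs = detect_runs(self._track(["P", "P", "P", "B"]))
        assert runs == [Run("c1", 1000, 3000, 3)]

    def test_interrupted_sites_do_not_run(self):
        assert detect_runs(self._track(["P", "P", "B", "P", "P"])) == []

    def test_alternating_track_has_no_runs(self):
        assert detect_runs(self._track(["P", "B"] * 50)) == []

    def test_runs_are_maximal_and_disjoint(self, mosaic):
        vcf, truth = mosaic
        runs = detect_runs(truth)
        by_chrom = truth.set_index(["chrom", "pos"])["category"]
        prev_end = {}
        for r in runs:
            assert r.n_sites >= 3
            assert r.start > prev_end.get(r.chrom, -1)
            prev_end[r.chrom] = r.end
            chrom_sites = truth[truth.chrom == r.chrom].sort_values("pos")
            inside = chrom_sites[
                (chrom_sites.pos >= r.start) & (chrom_sites.pos <= r.end)
            ]
            assert (inside.category == "P").all()
            # maximality: the flanking sites are not P
            before = chrom_sites[chrom_sites.pos < r.start]
            after = chrom_sites[chrom_sites.pos > r.end]
            if len(before):
                assert before.iloc[-1].category != "P"
            if len(after):
                assert after.iloc[0].category != "P"


class TestCoverage:
    def test_full_chromosome_run(self):
        runs = [Run("c1", 1, 10_000_000)]
        sizes = {"c1": 10_000_000, "c2": 90_000_000}
        assert run_coverage(runs, sizes) == pytest.approx(0.10)

    def test_no_runs_zero_coverage(self):
        assert run_coverage([], {"c1": 1000}) == 0.0

    def test_overlapping_runs_counted_once(self):
        runs = [Run("c1", 1_000_001, 5_000_000), Run("c1", 3_000_001, 8_000_000)]
        cov = run_coverage(runs, {"c1": 100_000_000})
        assert cov == pytest.approx(7_000_000 / 100_000_000)

    def test_run_beyond_chromosome_end_is_error(self):
        with pytest.raises(ValueError):
            run_coverage([Run("c1", 1, 2000)], {"c1": 1000})
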