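"""Segregation-ratio tests, group enrichment classification and distortion regions.

Each marker of a backcross population is summarised by its non-missing
AA/AB counts and het:hom ratio, tested by chi-square (df=1) against the
polysomic expectations 1:1 (simplex, random chromosome segregation) and
5:1 (duplex). Linkage groups are classified as donor-enriched, balanced or
recurrent-enriched from their average AB/AA ratio against fixed thresholds
(defaults 1.82 / 0.55, the published constants for n=105); distorted
markers can be intersected or pooled across two populations; and distorted
regions are maximal chains of at least ``min_markers`` flagged markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import GenotypeMatrix

__all__ = [
    "chisq_ratio_test",
    "marker_segregation",
    "classify_group",
    "ratio_threshold_from_alpha",
    "detect_distorted_markers",
    "cross_population_distortion",
    "detect_distortion_regions",
    "DistortionRegion",
]

HALEPENSE_ENRICHED = "halepense_enriched"
BALANCED = "balanced"
BICOLOR_ENRICHED = "bicolor_enriched"


def chisq_ratio_test(
    n_ab: int, n_aa: int, expected: tuple[float, float] = (5.0, 1.0)
) -> tuple[float, float, str]:
    """Chi-square goodness of fit of (nAB, nAA) to an expected het:hom ratio.

    Returns (statistic, p, direction), direction being 'above', 'below' or
    'equal' according to the observed het fraction relative to expectation.
    """
    eh_num, eh_den = expected
    if eh_num <= 0 or eh_den <= 0:
        raise ValueError("expected ratio components must be positive")
    n = n_ab + n_aa
    if n < 1:
        raise ValueError("no genotyped individuals")
    eh = eh_num / (eh_num + eh_den)
    e = np.array([n * eh, n * (1.0 - eh)])
    o = np.array([n_ab, n_aa], dtype=float)
    stat = float(np.sum((o - e) ** 2 / e))
    p = float(stats.chi2.sf(stat, df=1))
    obs = n_ab / n
    direction = "above" if obs > eh else ("below" if obs < eh else "equal")
    return stat, p, direction


def marker_segregation(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker counts, ratios and chi-square tests vs 1:1 and 5:1."""
    counts = matrix.counts()
    rows = []
    for mid, row in counts.iterrows():
        n_ab, n_aa = int(row["nAB"]), int(row["nAA"])
        if n_ab + n_aa == 0:
            continue
        ratio = n_ab / n_aa if n_aa > 0 else np.inf
        s11, p11, _ = chisq_ratio_test(n_ab, n_aa, (1.0, 1.0))
        s51, p51, d51 = chisq_ratio_test(n_ab, n_aa, (5.0, 1.0))
        rows.append(
            {
                "marker": mid,
                "chrom": matrix.chrom.loc[mid],
                "pos": matrix.pos.loc[mid],
                "nAA": n_aa,
                "nAB": n_ab,
                "ratio": ratio,
                "sqrt_ratio": np.sqrt(ratio),
                "chisq_1_1": s11,
                "p_1_1": p11,
                "chisq_5_1": s51,
                "p_5_1": p51,
                "direction_5_1": d51,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def classify_group(ratio: float, t_hi: float = 1.82, t_lo: float = 0.55) -> str:
    """Classify a group's average AB/AA ratio (strict inequalities; boundary
    values are balanced)."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if not t_hi > 1 > t_lo > 0:
        raise ValueError("thresholds must satisfy t_hi > 1 > t_lo > 0")
    if ratio > t_hi:
        return HALEPENSE_ENRICHED
    if ratio < t_lo:
        return BICOLOR_ENRICHED
    return BALANCED


def ratio_threshold_from_alpha(
    n: int, alpha: float, null_ratio: tuple[float, float] = (1.0, 1.0)
) -> tuple[float, float]:
    """Ratio thresholds equivalent to a chi-square test of a 1:1 null.

    Solves (nAB - nAA)^2 / n = chi2_1(1 - alpha) with nAB + nAA = n and
    returns the critical ratio and its reciprocal. Provided for sensitivity
    analysis around fixed published thresholds.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if null_ratio != (1.0, 1.0):
        raise NotImplementedError("only the 1:1 null is supported")
    c = stats.chi2.ppf(1.0 - alpha, df=1)
    q = 0.5 * (1.0 + np.sqrt(c / n))
    if q >= 1.0:
        return np.inf, 0.0
    t_hi = q / (1.0 - q)
    return float(t_hi), float(1.0 / t_hi)


def detect_distorted_markers(
    seg: pd.DataFrame,
    alpha: float = 0.05,
    direction: str = "above",
    p_col: str = "p_5_1",
    dir_col: str = "direction_5_1",
) -> set[str]:
    """Markers whose 5:1 test is significant in the requested direction."""
    if seg.empty:
        return set()
    mask = seg[p_col] < alpha
    if direction in ("above", "below"):
        mask &= seg[dir_col] == direction
    return set(seg.index[mask])


def cross_population_distortion(
    seg_a: pd.DataFrame,
    seg_b: pd.DataFrame,
    alpha: float = 0.05,
    expected: tuple[float, float] = (5.0, 1.0),
    direction: str = "above",
    method: str = "pool",
) -> tuple[set[str], set[str]]:
    """Distortion evidence across two populations sharing marker ids.

    Returns (intersection, pooled): markers flagged in both populations
    separately, and markers significant after combining the populations —
    by summing genotype counts before one chi-square test (``pool``), or by
    Fisher's method on the two p-values (``fisher``).
    """
    flagged_a = detect_distorted_markers(seg_a, alpha, direction)
    flagged_b = detect_distorted_markers(seg_b, alpha, direction)
    intersection = flagged_a & flagged_b

    shared = seg_a.index.intersection(seg_b.index)
    pooled: set[str] = set()
    for mid in shared:
        if method == "pool":
            n_ab = int(seg_a.loc[mid, "nAB"] + seg_b.loc[mid, "nAB"])
            n_aa = int(seg_a.loc[mid, "nAA"] + seg_b.loc[mid, "nAA"])
            _, p, d = chisq_ratio_test(n_ab, n_aa, expected)
        elif method == "fisher":
            stat = -2.0 * (
                np.log(max(seg_a.loc[mid, "p_5_1"], 1e-300))
                + np.log(max(seg_b.loc[mid, "p_5_1"], 1e-300))
            )
            p = float(stats.chi2.sf(stat, df=4))
            d = seg_a.loc[mid, "direction_5_1"]
        else:
            raise ValueError(f"unknown combination method {method!r}")
        if p < alpha and (direction not in ("above", "below") or d == direction):
            pooled.add(mid)
    return intersection, pooled


@dataclass(frozen=True)
class DistortionRegion:
    chrom: str
    start: int  # bp of first flagged marker, 1-based
    end: int  # bp of last flagged marker
    n_significant: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")


def detect_distortion_regions(
    flagged: pd.DataFrame,
    min_markers: int = 3,
    max_gap_bp: int = 5_000_000,
) -> list[DistortionRegion]:
    """Maximal chains of flagged markers with inter-marker gaps <= max_gap_bp
    and at least ``min_markers`` members. ``flagged`` needs chrom and pos."""
    regions: list[DistortionRegion] = []
    if flagged.empty:
        return regions
    for chrom, grp in flagged.sort_values(["chrom", "pos"]).groupby(
        "chrom", sort=True
    ):
        pos = grp["pos"].to_numpy()
        start = 0
        for k in range(1, len(pos) + 1):
            if k == len(pos) or pos[k] - pos[k - 1] > max_gap_bp:
                if k - start >= min_markers:
                    regions.append(
                        DistortionRegion(
                            str(chrom), int(pos[start]), int(pos[k - 1]), k - start
                        )
                    )
                start = k
    return regions


def regions_to_bed(regions: list[DistortionRegion], path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.n_significant}\n")
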