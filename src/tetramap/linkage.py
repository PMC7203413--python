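"""Linkage-map construction from presence/absence backcross genotypes.

The map pipeline mirrors a diploid-backcross treatment of tetraploid
presence/absence calls: two-point recombination fractions and LOD scores,
single-linkage clustering at a minimum LOD (default 10), 1-cM binning along
the physical order with genotype merging, de novo ordering by a greedy
nearest-neighbour chain refined with 2-opt moves, and per-interval
recombination re-estimation by EM under a two-state hidden chain that
allows a genotyping error probability (default 0.01). Distances use the
Kosambi mapping function d = 25 ln((1+2r)/(1-2r)).

Duplex markers make the two-point estimator a biased proxy (a shared donor
allele can descend from either of two homologs); the bias is accepted, as
in diploid-style mapping of polysomic data, and shows up as inflated map
length rather than wrong ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import xlogy

from .calling import GenotypeMatrix, HET, HOM, MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "kosambi",
    "kosambi_inverse",
    "PairLinkage",
    "LinkageGroup",
    "estimate_rf",
    "pairwise_linkage",
    "cluster_markers",
    "bin_markers",
    "order_markers",
    "estimate_map",
    "merge_repulsion",
    "group_summary_table",
]

_LN10 = np.log(10.0)
_RF_CAP = 0.4999  # keep Kosambi finite on unlinked pairs


def kosambi(r):
    """Kosambi map distance in cM for recombination fraction r in [0, 0.5)."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, _RF_CAP)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d):
    """Recombination fraction for a Kosambi distance d (cM)."""
    x = np.exp(np.asarray(d, dtype=float) / 25.0)
    return 0.5 * (x - 1.0) / (x + 1.0)


@dataclass(frozen=True)
class PairLinkage:
    marker_a: str
    marker_b: str
    rf: float
    lod: float
    n_informative: int
    phase_flipped: bool = False
    defined: bool = True


@dataclass
class LinkageGroup:
    """Ordered markers with cumulative cM positions and a summary row."""

    id: str
    marker_ids: list[str]
    positions_cm: np.ndarray
    rf: np.ndarray  # per-interval recombination fractions
    summary: dict = field(default_factory=dict)

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0


def _lod_from_rf(r, n):
    """LOD for linkage at rf estimate r vs the null r=0.5, n informative."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    return n * (xlogy(r, 2.0 * r) + xlogy(1.0 - r, 2.0 * (1.0 - r))) / _LN10


def estimate_rf(col_a: np.ndarray, col_b: np.ndarray,
                name_a: str = "A", name_b: str = "B") -> PairLinkage:
    """Two-point linkage between two call columns (backcross coding).

    An individual is informative when non-missing at both markers and
    recombinant when its calls differ. Estimates above 0.5 are phase-flipped
    (repulsion scored as coupling) and flagged.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    inf = (a != MISSING) & (b != MISSING)
    n = int(inf.sum())
    if n < 2:
        return PairLinkage(name_a, name_b, 0.5, 0.0, n, defined=False)
    rec = int((a[inf] != b[inf]).sum())
    r = rec / n
    flipped = r > 0.5
    if flipped:
        r = 1.0 - r
    return PairLinkage(name_a, name_b, r, float(_lod_from_rf(r, n)), n, flipped)


def pairwise_linkage(matrix: GenotypeMatrix):
    """All-pairs rf, LOD and informative counts as m x m arrays.

    Returns (rf, lod, n_informative, flipped) with rf already phase-flipped
    into [0, 0.5]. Pairs with fewer than 2 informative individuals get
    rf=0.5, lod=0.
    """
    x = matrix.calls.to_numpy().astype(np.float64)
    obs = (x != MISSING).astype(np.float64)
    v = np.where(x == HET, 1.0, 0.0) * obs
    n_inf = obs @ obs.T
    mismatch = v @ (obs - v).T + (obs - v) @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n_inf > 0, mismatch / np.maximum(n_inf, 1), 0.5)
    flipped = r > 0.5
    r = np.where(flipped, 1.0 - r, r)
    lod = _lod_from_rf(r, n_inf)
    undefined = n_inf < 2
    r[undefined] = 0.5
    lod[undefined] = 0.0
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod, n_inf.astype(int), flipped


def cluster_markers(
    matrix: GenotypeMatrix,
    min_lod: float = 10.0,
    per_chromosome: bool = True,
) -> list[list[str]]:
    """Single-linkage grouping: markers join one group when connected by a
    chain of pairs with LOD >= min_lod and rf < 0.5.

    By default only pairs on the same reference chromosome may link
    (clustering is run per chromosome): markers whose het frequency is far
    from 1/2 — duplex 5:1 segregants in particular — co-match by chance at
    a rate the 1:1 LOD null misstates, so unrestricted clustering can fuse
    unlinked duplex groups. Groups are returned in (chrom, pos) order of
    their first marker; singletons are kept.
    """
    ids = matrix.markers
    if not ids:
        return []
    r, lod, _, _ = pairwise_linkage(matrix)
    linked = (lod >= min_lod) & (r < 0.5)
    if per_chromosome:
        chrom = matrix.chrom.to_numpy()
        linked &= chrom[:, None] == chrom[None, :]
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    ii, jj = np.nonzero(np.triu(linked, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    order = {m: k for k, m in enumerate(ids)}
    phys = sorted(
        range(len(ids)),
        key=lambda k: (matrix.chrom.iloc[k], matrix.pos.iloc[k], k),
    )
    rank = {k: i for i, k in enumerate(phys)}
    comps = [sorted(c, key=lambda k: rank[k]) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: rank[c[0]])
    return [[ids[k] for k in c] for c in comps]


def _merge_calls(block: np.ndarray) -> np.ndarray:
    """Merge a bin's marker calls per individual: unanimous non-missing call,
    else majority, MISSING on tie or all-missing."""
    n_het = (block == HET).sum(axis=0)
    n_hom = (block == HOM).sum(axis=0)
    out = np.full(block.shape[1], MISSING, dtype=np.int8)
    out[n_het > n_hom] = HET
    out[n_hom > n_het] = HOM
    return out


def _deattenuate_rf(r_obs: float, error_prob: float) -> float:
    """Remove the mismatch inflation caused by genotyping error.

    With per-genotype error probability e, a non-recombinant pair shows a
    mismatch when exactly one call is flipped (probability 2e(1-e)), so
    p_obs = r(1 - 2e2) + e2 with e2 = 2e(1-e); invert and clip to [0, 0.5].
    """
    e2 = 2.0 * error_prob * (1.0 - error_prob)
    if e2 >= 0.5:
        return r_obs
    return float(np.clip((r_obs - e2) / (1.0 - 2.0 * e2), 0.0, 0.5))


def bin_markers(
    matrix: GenotypeMatrix,
    group_ids: list[str],
    bin_cm: float = 1.0,
    error_prob: float = 0.01,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse markers within ``bin_cm`` of each other into bins.

    Provisional cM positions come from cumulative Kosambi-transformed
    adjacent two-point rfs along the physical (chrom, pos) order, corrected
    for the genotyping-error probability (otherwise error alone pushes
    co-segregating markers beyond the bin width); a new bin starts when the
    provisional position exceeds the bin start by more than ``bin_cm`` (or
    the chromosome changes). The bin genotype minimises missing data: per
    individual the unanimous call if the bin agrees, majority on conflict,
    MISSING on ties.
    """
    sub = matrix.subset(markers=group_ids)
    order = sorted(
        group_ids, key=lambda m: (sub.chrom.loc[m], sub.pos.loc[m], m)
    )
    sub = sub.subset(markers=order)
    x = sub.calls.to_numpy()
    # adjacent provisional distances in physical order
    pos_cm = np.zeros(len(order))
    for k in range(1, len(order)):
        if sub.chrom.iloc[k] != sub.chrom.iloc[k - 1]:
            pos_cm[k] = pos_cm[k - 1] + 1e9  # force a bin break
            continue
        pl = estimate_rf(x[k - 1], x[k])
        r = _deattenuate_rf(pl.rf, error_prob)
        pos_cm[k] = pos_cm[k - 1] + float(kosambi(r))

    bins: list[list[int]] = []
    start = -np.inf
    for k in range(len(order)):
        if pos_cm[k] - start > bin_cm:
            bins.append([k])
            start = pos_cm[k]
        else:
            bins[-1].append(k)

    rows, ids, chroms, poss, bin_map = [], [], [], [], {}
    for members in bins:
        mids = [order[k] for k in members]
        rep = mids[0]
        rows.append(_merge_calls(x[members]))
        ids.append(rep)
        chroms.append(sub.chrom.loc[rep])
        poss.append(sub.pos.loc[rep])
        bin_map[rep] = mids
    calls = pd.DataFrame(
        np.vstack(rows), index=ids, columns=sub.individuals, dtype=np.int8
    )
    binned = GenotypeMatrix(
        calls, pd.Series(chroms, index=ids), pd.Series(poss, index=ids)
    )
    return binned, bin_map


def _path_length(order: list[int], dist: np.ndarray) -> float:
    idx = np.asarray(order)
    return float(dist[idx[:-1], idx[1:]].sum())


def order_markers(
    matrix: GenotypeMatrix, group_ids: list[str], clean_singletons: bool = True
) -> list[str]:
    """De novo seriation of one linkage group.

    Builds a chain greedily from the highest-LOD pair, repeatedly appending
    the unused marker closest (smallest rf, ties by LOD then physical rank)
    to either chain end, then applies 2-opt segment reversals and or-opt
    relocations until no move shortens the total adjacent Kosambi length.
    With ``clean_singletons`` the provisional order is used to blank
    apparent double recombinants spanning a single marker (the classic
    genotyping-error signature) and the seriation is repeated on the
    cleaned calls. The returned order is oriented so the physically first
    marker leads (orders are defined up to reversal).
    """
    if len(group_ids) <= 2:
        return sorted(
            group_ids,
            key=lambda m: (matrix.chrom.loc[m], matrix.pos.loc[m], m),
        )
    if clean_singletons:
        first = order_markers(matrix, group_ids, clean_singletons=False)
        x = matrix.calls.loc[first].to_numpy().copy()
        mid, up, dn = x[1:-1], x[:-2], x[2:]
        bad = (
            (mid != MISSING)
            & (up != MISSING)
            & (dn != MISSING)
            & (mid != up)
            & (mid != dn)
        )
        if not bad.any():
            return first
        x[1:-1][bad] = MISSING
        cleaned = GenotypeMatrix(
            pd.DataFrame(
                x, index=first, columns=matrix.individuals, dtype=np.int8
            ),
            matrix.chrom.loc[first],
            matrix.pos.loc[first],
        )
        return order_markers(cleaned, first, clean_singletons=False)
    sub = matrix.subset(markers=group_ids)
    r, lod, _, _ = pairwise_linkage(sub)
    m = len(group_ids)
    dist = kosambi(r)
    phys_rank = np.argsort(
        pd.DataFrame(
            {"c": sub.chrom.values, "p": sub.pos.values}
        ).apply(tuple, axis=1).values
    ).argsort()

    # greedy chain from the strongest pair
    triu = np.triu(lod, k=1)
    i0, j0 = np.unravel_index(np.argmax(triu), triu.shape)
    chain = [int(i0), int(j0)]
    used = set(chain)
    while len(chain) < m:
        best = None
        for end, at_front in ((chain[0], True), (chain[-1], False)):
            for k in range(m):
                if k in used:
                    continue
                cand = (r[end, k], -lod[end, k], phys_rank[k], at_front, k)
                if best is None or cand < best:
                    best = cand
        _, _, _, at_front, k = best
        (chain.insert(0, k) if at_front else chain.append(k))
        used.add(k)

    # local search: 2-opt segment reversals plus or-opt relocations of short
    # segments, repeated until neither shortens the path
    improved = True
    n_pass = 0
    while improved and n_pass < 50:
        improved = False
        n_pass += 1
        for i in range(m - 1):
            for j in range(i + 2, m + 1):
                if i == 0 and j == m:
                    continue
                new = chain[:i] + chain[i:j][::-1] + chain[j:]
                if _path_length(new, dist) < _path_length(chain, dist) - 1e-12:
                    chain = new
                    improved = True
        for seg in (1, 2, 3):
            for i in range(m - seg + 1):
                piece = chain[i : i + seg]
                rest = chain[:i] + chain[i + seg :]
                base = _path_length(chain, dist)
                for k in range(len(rest) + 1):
                    if k == i:
                        continue
                    new = rest[:k] + piece + rest[k:]
                    if _path_length(new, dist) < base - 1e-12:
                        chain = new
                        improved = True
                        break
                else:
                    continue
                break
    if phys_rank[chain[0]] > phys_rank[chain[-1]]:
        chain = chain[::-1]
    return [group_ids[k] for k in chain]


def _em_interval_rf(
    obs: np.ndarray, error_prob: float, r0: np.ndarray,
    max_iter: int = 100, tol: float = 1e-6
):
    """EM re-estimation of per-interval rfs under a 2-state hidden chain.

    States are the true HOM/HET classes; the observation equals the state
    with probability 1-error_prob, and MISSING is uninformative. Returns
    (rf array, converged flag).
    """
    m, n = obs.shape
    if m < 2:
        return np.zeros(0), True
    e = error_prob
    # emission[marker, individual, state]
    emis = np.ones((m, n, 2))
    for s, code in ((0, HOM), (1, HET)):
        emis[:, :, s] = np.where(
            obs == MISSING, 1.0, np.where(obs == code, 1.0 - e, e)
        )
    r = np.clip(np.asarray(r0, dtype=float), 1e-6, 0.5 - 1e-6)
    last_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # forward-backward with scaling, all individuals at once
        alpha = np.empty((m, n, 2))
        scale = np.empty((m, n))
        alpha[0] = 0.5 * emis[0]
        scale[0] = alpha[0].sum(axis=1)
        alpha[0] /= scale[0][:, None]
        for k in range(1, m):
            stay, move = 1.0 - r[k - 1], r[k - 1]
            trans = np.array([[stay, move], [move, stay]])
            alpha[k] = (alpha[k - 1] @ trans) * emis[k]
            scale[k] = alpha[k].sum(axis=1)
            alpha[k] /= scale[k][:, None]
        beta = np.empty((m, n, 2))
        beta[-1] = 1.0
        for k in range(m - 2, -1, -1):
            stay, move = 1.0 - r[k], r[k]
            trans = np.array([[stay, move], [move, stay]])
            beta[k] = (beta[k + 1] * emis[k + 1]) @ trans.T
            beta[k] /= scale[k + 1][:, None]
        ll = float(np.log(scale).sum())
        # expected recombination count per interval
        new_r = np.empty(m - 1)
        for k in range(m - 1):
            stay, move = 1.0 - r[k], r[k]
            trans = np.array([[stay, move], [move, stay]])
            xi = (
                alpha[k][:, :, None]
                * trans[None, :, :]
                * (emis[k + 1] * beta[k + 1])[:, None, :]
            )
            xi /= scale[k + 1][:, None, None]
            flips = xi[:, 0, 1] + xi[:, 1, 0]
            new_r[k] = float(np.clip(flips.mean(), 1e-6, 0.5 - 1e-6))
        if last_ll != -np.inf and abs(ll - last_ll) <= tol * abs(last_ll):
            r = new_r
            converged = True
            break
        r, last_ll = new_r, ll
    if not converged:
        logger.warning("EM map estimation stopped at max iterations")
    return r, converged


def estimate_map(
    matrix: GenotypeMatrix,
    ordered_ids: list[str],
    group_id: str = "LG",
    error_prob: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> LinkageGroup:
    """Estimate cM positions for an ordered group and fill its summary.

    Interval rfs are re-estimated by EM allowing a genotyping error
    probability, then converted by the Kosambi function and cumulated from
    0. The summary mirrors a map characteristics table: marker count,
    length, average/maximum spacing, average AA and AB counts and their
    ratio.
    """
    sub = matrix.subset(markers=ordered_ids)
    obs = sub.calls.to_numpy()
    m = len(ordered_ids)
    if m == 0:
        raise ValueError("empty group")
    if m == 1:
        rf = np.zeros(0)
    else:
        r0 = np.array(
            [estimate_rf(obs[k], obs[k + 1]).rf for k in range(m - 1)]
        )
        if error_prob == 0.0:
            rf = np.clip(r0, 0.0, 0.5 - 1e-9)
        else:
            rf, _ = _em_interval_rf(obs, error_prob, r0, max_iter, tol)
    steps = kosambi(rf) if m > 1 else np.zeros(0)
    positions = np.concatenate([[0.0], np.cumsum(steps)])
    counts = sub.counts()
    avg_aa = float(counts["nAA"].mean())
    avg_ab = float(counts["nAB"].mean())
    summary = {
        "n_markers": m,
        "length_cm": float(positions[-1]),
        "avg_spacing_cm": float(positions[-1] / (m - 1)) if m > 1 else 0.0,
        "max_spacing_cm": float(steps.max()) if m > 1 else 0.0,
        "avg_aa": avg_aa,
        "avg_ab": avg_ab,
        "ab_aa_ratio": avg_ab / avg_aa if avg_aa > 0 else np.inf,
    }
    return LinkageGroup(group_id, list(ordered_ids), positions, rf, summary)


@dataclass
class MergeReport:
    max_lod: float
    mean_lod: float
    coalesces: bool
    n_pairs: int


def merge_repulsion(
    matrix: GenotypeMatrix,
    group_a: list[str],
    group_b: list[str],
    min_lod: float = 10.0,
) -> MergeReport:
    """Test whether a 1:5-type group is the repulsion phase of a 5:1 group.

    Inverts group A's calls (AA <-> AB) and measures cross-group linkage; if
    any inverted-A/B pair reaches ``min_lod`` with rf < 0.5, single-linkage
    clustering would coalesce the two groups.
    """
    if not group_a or not group_b:
        raise ValueError("merge_repulsion requires two non-empty groups")
    a = matrix.subset(markers=group_a).calls.to_numpy().copy()
    b = matrix.subset(markers=group_b).calls.to_numpy()
    swap = a != MISSING
    a[swap] = 1 - a[swap]  # HOM<->HET
    lods, links = [], []
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            pl = estimate_rf(a[i], b[j])
            lods.append(pl.lod)
            links.append(pl.lod >= min_lod and pl.rf < 0.5)
    return MergeReport(
        max_lod=float(np.max(lods)),
        mean_lod=float(np.mean(lods)),
        coalesces=bool(np.any(links)),
        n_pairs=len(lods),
    )


def group_summary_table(groups: list[LinkageGroup]) -> pd.DataFrame:
    """Map characteristics table: one row per linkage group."""
    rows = []
    for g in groups:
        row = {"LG": g.id}
        row.update(
            {
                "Marker No.": g.summary["n_markers"],
                "Length (cM)": round(g.summary["length_cm"], 1),
                "Avg spacing (cM)": round(g.summary["avg_spacing_cm"], 2),
                "Max spacing (cM)": round(g.summary["max_spacing_cm"], 2),
                "Avg No. AA": round(g.summary["avg_aa"], 2),
                "Avg No. AB": round(g.summary["avg_ab"], 2),
                "AB/AA ratio": round(g.summary["ab_aa_ratio"], 2),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
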