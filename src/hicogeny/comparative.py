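"""Cross-stage and cross-sample machinery.

Quantile-normalized matrix subtraction (difference maps between stages),
sliding-window conserved-region detection on PC1 tracks, hierarchical
clustering of PC1 profiles across samples, interval-set overlap
bookkeeping, and Fisher-exact enrichment with Benjamini–Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core import (
    BALANCED,
    DIFFERENCE,
    BinTable,
    ContactMatrix,
    GenomicInterval,
    IntervalSet,
    ScalarTrack,
)

__all__ = [
    "ConservedRegion",
    "EnrichmentResult",
    "quantile_normalize_matrices",
    "deconvolve",
    "conserved_regions",
    "cluster_profiles",
    "linkage_to_newick",
    "region_overlap",
    "fisher_enrichment",
]


@dataclass(frozen=True)
class ConservedRegion:
    chrom: str
    start: int
    end: int
    mean_r: float


@dataclass
class EnrichmentResult:
    odds_ratio: float  # NaN when a margin is zero
    p: float
    p_adj: float
    table: np.ndarray  # 2x2 counts


# ---------------------------------------------------------------------------
# quantile normalization + subtraction

def quantile_normalize_matrices(
    matrices: list[ContactMatrix], include_zeros: bool = False
) -> list[ContactMatrix]:
    """Map each matrix's stored pixel values onto their common average
    distribution (rank-based, ties averaged).

    By default only nonzero upper-triangle pixels enter each matrix's
    distribution; masked bins never enter.  Distributions of unequal size
    are aligned by quantile interpolation.
    """
    first = matrices[0]
    for m in matrices[1:]:
        if not m.bins.same_table(first.bins):
            raise ValueError("matrices on different bin tables")
    n = first.n_bins
    iu = np.triu_indices(n, k=1)
    value_sets = []
    sels = []
    for m in matrices:
        v = m.values[iu]
        ok = np.isfinite(v) & ~m.mask[iu[0]] & ~m.mask[iu[1]]
        if not include_zeros:
            ok &= v != 0
        value_sets.append(np.sort(v[ok]))
        sels.append(ok)
    # common reference: mean of the sorted distributions on a shared grid
    grid = max(len(s) for s in value_sets)
    q = np.linspace(0, 1, grid)
    ref = np.mean(
        [np.quantile(s, q) if len(s) else np.zeros(grid) for s in value_sets],
        axis=0,
    )
    out = []
    for m, ok in zip(matrices, sels):
        v = m.values[iu].astype(float)
        x = v[ok]
        # average ranks for ties, then map through the reference quantiles
        ranks = stats.rankdata(x, method="average")
        pos = (ranks - 1) / max(len(x) - 1, 1)
        new = np.interp(pos, q, ref)
        v2 = v.copy()
        v2[ok] = new
        vals = np.zeros((n, n))
        vals[iu] = v2
        vals = vals + vals.T
        np.fill_diagonal(vals, np.diag(m.values))
        out.append(
            ContactMatrix(m.bins, vals, kind=m.kind, mask=m.mask.copy())
        )
    return out


def deconvolve(
    stages: list[ContactMatrix], pair: tuple[int, int],
    include_zeros: bool = False,
) -> ContactMatrix:
    """Quantile-normalize all stage matrices together, then subtract.

    Returns ``stages[pair[0]] - stages[pair[1]]`` as a difference matrix.
    """
    for m in stages:
        if m.kind not in (BALANCED,):
            raise ValueError("deconvolve expects balanced matrices")
    normed = quantile_normalize_matrices(stages, include_zeros=include_zeros)
    a, b = pair
    diff = normed[a].values - normed[b].values
    mask = normed[a].mask | normed[b].mask
    return ContactMatrix(normed[a].bins, diff, kind=DIFFERENCE, mask=mask)


# ---------------------------------------------------------------------------
# conserved regions

def conserved_regions(
    pc1_a: ScalarTrack,
    pc1_b: ScalarTrack,
    window: int = 2_000_000,
    step: int = 400_000,
    r_threshold: float = 0.6,
    min_bins: int = 3,
) -> list[ConservedRegion]:
    """Sliding-window Pearson correlation of two PC1 tracks.

    Windows of ``window`` bp advance by ``step`` bp along each chromosome;
    windows whose correlation over co-defined bins exceeds ``r_threshold``
    are merged into maximal regions annotated with the mean r of their
    contributing windows.  Windows with fewer than ``min_bins`` co-defined
    bins are skipped.
    """
    if not pc1_a.bins.same_table(pc1_b.bins):
        raise ValueError("tracks on different bin tables")
    bins = pc1_a.bins
    bin_size = bins.bin_size
    w = max(2, window // bin_size)
    st = max(1, step // bin_size)
    regions: list[ConservedRegion] = []
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        xa = pc1_a.values[sl]
        xb = pc1_b.values[sl]
        size = len(xa)
        starts = list(range(0, max(size - w, 0) + 1, st))
        if not starts:
            starts = [0]
        hits: list[tuple[int, int, float]] = []
        for s in starts:
            e = min(s + w, size)
            va, vb = xa[s:e], xb[s:e]
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < min_bins:
                continue
            va, vb = va[ok], vb[ok]
            if va.std() == 0 or vb.std() == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            if r > r_threshold:
                hits.append((s, e, r))
        # merge overlapping/adjacent qualifying windows into maximal regions
        cur = None
        start_bp_of = bins.df["start"].to_numpy()
        end_bp_of = bins.df["end"].to_numpy()
        for s, e, r in hits:
            if cur is not None and s <= cur[1]:
                cur = (cur[0], max(cur[1], e), cur[2] + [r])
            else:
                if cur is not None:
                    regions.append(
                        ConservedRegion(
                            chrom,
                            int(start_bp_of[sl.start + cur[0]]),
                            int(end_bp_of[sl.start + cur[1] - 1]),
                            float(np.mean(cur[2])),
                        )
                    )
                cur = (s, e, [r])
        if cur is not None:
            regions.append(
                ConservedRegion(
                    chrom,
                    int(start_bp_of[sl.start + cur[0]]),
                    int(end_bp_of[sl.start + cur[1] - 1]),
                    float(np.mean(cur[2])),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# clustering of PC1 profiles

def cluster_profiles(
    tracks: list[tuple[str, ScalarTrack]]
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over 1 - Pearson r distances between samples.

    Samples are ordered by name before linkage so the tree is independent
    of input order; returns the scipy linkage matrix and the label order.
    """
    if len(tracks) < 2:
        raise ValueError("need >= 2 samples")
    bins = tracks[0][1].bins
    for name, t in tracks:
        if not t.bins.same_table(bins):
            raise ValueError(f"sample {name} on a different bin table")
        ok = t.defined()
        if ok.sum() and np.std(t.values[ok]) == 0:
            raise ValueError(f"sample {name} has a constant track")
    items = sorted(tracks, key=lambda kv: kv[0])
    names = [n for n, _ in items]
    k = len(items)
    D = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            va, vb = items[a][1].values, items[b][1].values
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 3:
                raise ValueError("too few co-defined bins")
            r = np.corrcoef(va[ok], vb[ok])[0, 1]
            D[a, b] = D[b, a] = 1.0 - r
    Z = average(squareform(D, checks=False))
    return Z, names


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    n = len(names)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return names[i], 0.0
        a, b, height, _ = Z[i - n]
        sa, ha = node(int(a))
        sb, hb = node(int(b))
        return (
            f"({sa}:{height / 2 - ha:.6g},{sb}:{height / 2 - hb:.6g})",
            height / 2,
        )

    s, _ = node(n + len(Z) - 1)
    return s + ";"


# ---------------------------------------------------------------------------
# overlap and enrichment

def region_overlap(
    a: list[ConservedRegion], b: list[ConservedRegion]
) -> tuple[int, int, int]:
    """Base pairs unique to a, shared, and unique to b (interval sweep)."""

    def to_sets(regions):
        per: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            per.setdefault(r.chrom, []).append((r.start, r.end))
        for chrom, ivs in per.items():
            ivs.sort()
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping regions within one list on {chrom}")
        return per

    pa, pb = to_sets(a), to_sets(b)
    shared = 0
    for chrom in set(pa) & set(pb):
        ia, ib = pa[chrom], pb[chrom]
        x = y = 0
        while x < len(ia) and y < len(ib):
            lo = max(ia[x][0], ib[y][0])
            hi = min(ia[x][1], ib[y][1])
            if hi > lo:
                shared += hi - lo
            if ia[x][1] < ib[y][1]:
                x += 1
            else:
                y += 1
    total_a = sum(e - s for ivs in pa.values() for s, e in ivs)
    total_b = sum(e - s for ivs in pb.values() for s, e in ivs)
    return total_a - shared, shared, total_b - shared


def fisher_enrichment(
    regions: list[ConservedRegion] | IntervalSet,
    features: IntervalSet,
    universe: BinTable,
    batch_pvalues: list[float] | None = None,
) -> EnrichmentResult:
    """Two-sided Fisher exact test of feature-bearing bins inside regions.

    The 2x2 table counts universe bins by (inside/outside the regions) x
    (containing/not containing a feature); containment is any half-open
    overlap.  When ``batch_pvalues`` is given (tests over several feature
    sets), the adjusted p is the BH value of this test within that batch;
    otherwise ``p_adj == p``.
    """
    if universe.n_bins == 0:
        raise ValueError("empty universe")
    region_ivs = (
        [(r.chrom, r.start, r.end) for r in regions]
        if not isinstance(regions, IntervalSet)
        else [(iv.chrom, iv.start, iv.end) for iv in regions]
    )
    in_region = np.zeros(universe.n_bins, dtype=bool)
    has_feature = np.zeros(universe.n_bins, dtype=bool)
    df = universe.df
    for chrom, s, e in region_ivs:
        sel = (df["chrom"] == chrom) & (df["start"] < e) & (df["end"] > s)
        in_region |= sel.to_numpy()
    for iv in features:
        sel = (df["chrom"] == iv.chrom) & (df["start"] < iv.end) & (df["end"] > iv.start)
        has_feature |= sel.to_numpy()
    table = np.array(
        [
            [int((in_region & has_feature).sum()), int((in_region & ~has_feature).sum())],
            [int((~in_region & has_feature).sum()), int((~in_region & ~has_feature).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return EnrichmentResult(float("nan"), 1.0, 1.0, table)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if batch_pvalues is not None:
        all_p = np.array(list(batch_pvalues) + [p])
        p_adj = float(multipletests(all_p, method="fdr_bh")[1][-1])
    else:
        p_adj = float(p)
    return EnrichmentResult(float(odds), float(p), p_adj, table)
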