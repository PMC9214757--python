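"""Distance-dependent contact statistics.

Covers the contact-probability curve P(s), its LOWESS-smoothed log-log
slope, cis-short/cis-long partitioning at 2 Mb, per-chromosome trans/cis
fractions, chromosome-pair observed/expected enrichment and the
chromosome-length trend of trans contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import RAW, ContactMatrix

__all__ = [
    "DecayCurve",
    "contact_probability",
    "slope_curve",
    "cis_fractions",
    "trans_cis_partition",
    "chrom_pair_enrichment",
    "length_normalized_trend",
]


@dataclass
class DecayCurve:
    """P(s): contact probability per genomic separation.

    ``probability`` sums to 1 over the represented distances.  ``smoothed``
    and ``slope`` (d log10 p / d log10 s) are filled in by
    :func:`slope_curve`.
    """

    distances: np.ndarray  # bp, strictly increasing multiples of bin_size
    probability: np.ndarray
    smoothed: np.ndarray | None = None
    slope: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"distance": self.distances, "probability": self.probability})
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        if self.slope is not None:
            df["slope"] = self.slope
        return df


def contact_probability(m: ContactMatrix) -> DecayCurve:
    """Mean contact per valid pixel at each separation, normalized to sum 1.

    Pixels whose bins are unmasked count toward the denominator whether or
    not they carry signal; separations are pooled across chromosomes.
    """
    bin_size = m.bins.bin_size
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        v = m.values[sl, sl]
        ok = ~m.mask[sl]
        size = v.shape[0]
        for d in range(1, size):
            i = np.arange(size - d)
            valid = ok[i] & ok[i + d]
            if valid.any():
                sums[d] = sums.get(d, 0.0) + float(v[i[valid], i[valid] + d].sum())
                counts[d] = counts.get(d, 0) + int(valid.sum())
    if not sums:
        raise ValueError("matrix has no intra-chromosomal pixels")
    ds = np.array(sorted(sums))
    mean = np.array([sums[d] / counts[d] for d in ds])
    total = mean.sum()
    if total == 0:
        raise ValueError("matrix has no intra-chromosomal signal")
    return DecayCurve(distances=ds * bin_size, probability=mean / total)


def slope_curve(curve: DecayCurve, smooth_frac: float = 0.3) -> DecayCurve:
    """LOWESS-smooth log10 P(s) vs log10 s and differentiate.

    The slope track is the centred finite difference of the smoothed curve
    (one-sided at the ends); on an exact power law s^(-alpha) it equals
    -alpha everywhere.
    """
    keep = curve.probability > 0
    if keep.sum() < 10:
        raise ValueError("need >= 10 distances with nonzero probability")
    x = np.log10(curve.distances[keep].astype(float))
    y = np.log10(curve.probability[keep])
    sm = lowess(y, x, frac=smooth_frac, return_sorted=False)
    slope = np.gradient(sm, x)
    smoothed = np.full(curve.distances.shape, np.nan)
    slopes = np.full(curve.distances.shape, np.nan)
    smoothed[keep] = 10.0**sm
    slopes[keep] = slope
    return DecayCurve(
        distances=curve.distances,
        probability=curve.probability,
        smoothed=smoothed,
        slope=slopes,
    )


def cis_fractions(
    m: ContactMatrix, threshold: int = 2_000_000, ties_to_long: bool = True
) -> tuple[float, float]:
    """Fractions of cis counts at separations below / above ``threshold``.

    Separation is measured between bin start coordinates.  Counts landing
    exactly at the threshold go to the long fraction by default.
    """
    if m.kind != RAW:
        raise ValueError("cis_fractions expects raw counts")
    short = long = 0.0
    bin_size = m.bins.bin_size
    for chrom in m.bins.chroms:
        v = m.chrom_view(chrom)
        size = v.shape[0]
        for d in range(1, size):
            i = np.arange(size - d)
            s = float(v[i, i + d].sum())
            dist = d * bin_size
            if dist < threshold or (dist == threshold and not ties_to_long):
                short += s
            else:
                long += s
    total = short + long
    if total == 0:
        raise ValueError("no off-diagonal cis counts")
    return short / total, long / total


def trans_cis_partition(m: ContactMatrix) -> pd.DataFrame:
    """Per-chromosome trans and cis fractions of counts involving it."""
    if m.kind != RAW:
        raise ValueError("trans_cis_partition expects raw counts")
    chroms = m.bins.chroms
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes")
    rows = []
    for chrom in chroms:
        sl = m.bins.chrom_slice(chrom)
        inside = np.zeros(m.n_bins, dtype=bool)
        inside[sl] = True
        cis = float(np.triu(m.values[sl, sl]).sum())
        trans = float(m.values[np.ix_(inside, ~inside)].sum())
        total = cis + trans
        if total == 0:
            rows.append((chrom, np.nan, np.nan))
        else:
            rows.append((chrom, trans / total, cis / total))
    return pd.DataFrame(rows, columns=["chrom", "trans_frac", "cis_frac"])


def _trans_pair_counts(m: ContactMatrix) -> tuple[list[str], np.ndarray]:
    chroms = m.bins.chroms
    k = len(chroms)
    pair = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            sa = m.bins.chrom_slice(chroms[a])
            sb = m.bins.chrom_slice(chroms[b])
            pair[a, b] = pair[b, a] = float(m.values[sa, sb].sum())
    return chroms, pair


def chrom_pair_enrichment(m: ContactMatrix) -> pd.DataFrame:
    """Observed/expected trans contacts per chromosome pair.

    Expected is proportional to the product of the two chromosomes' trans
    margins, rescaled so the total expected over distinct pairs equals the
    total observed; a uniform background then gives enrichment exactly 1.
    """
    if m.kind != RAW:
        raise ValueError("chrom_pair_enrichment expects raw counts")
    chroms, pair = _trans_pair_counts(m)
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes")
    margins = pair.sum(axis=1)
    total = margins.sum() / 2.0
    if total == 0:
        raise ValueError("no trans contacts")
    product = np.outer(margins, margins)
    np.fill_diagonal(product, 0.0)
    expected = product / product.sum() * 2.0 * total
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(expected > 0, pair / expected, np.nan)
    np.fill_diagonal(enr, np.nan)
    return pd.DataFrame(enr, index=chroms, columns=chroms)


def length_normalized_trend(m: ContactMatrix) -> pd.DataFrame:
    """(log2 L_i/L_j with L_i > L_j, trans obs/exp) for every chrom pair."""
    enr = chrom_pair_enrichment(m)
    sizes = m.bins.chrom_sizes()
    chroms = list(enr.index)
    rows = []
    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            li, lj = sizes[chroms[a]], sizes[chroms[b]]
            big, small = max(li, lj), min(li, lj)
            rows.append(
                (chroms[a], chroms[b], np.log2(big / small),
                 enr.iloc[a, b])
            )
    return pd.DataFrame(
        rows, columns=["chrom_i", "chrom_j", "log2_length_ratio", "enrichment"]
    )
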