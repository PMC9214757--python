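"""A/B compartments: PC1 calling, switch accounting, saddle strength.

Compartments are called per chromosome as the first principal component of
the Pearson correlation matrix of the distance-normalized (O/E) map; the
sign is oriented against an external per-bin track (typically gene density
or mean expression) so that positive PC1 = A.  Compartment strength is the
(AA + BB) / (AB + BA) corner ratio of the PC1-ordered saddle matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import OBSERVED_EXPECTED, ContactMatrix, ScalarTrack

__all__ = [
    "CompartmentProfile",
    "SaddleResult",
    "pc1_compartments",
    "switch_table",
    "saddle_strength",
    "ab_composition",
]


@dataclass
class CompartmentProfile:
    pc1: ScalarTrack
    labels: np.ndarray  # per-bin "A" / "B" / "" (masked)
    orientation_evidence: float  # correlation(pc1, orientation), >= 0 after flip


@dataclass
class SaddleResult:
    saddle: np.ndarray  # Q x Q mean O/E by PC1-quantile pair
    strength: float


def _corr_pc1(oe_block: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the Pearson correlation matrix of O/E columns,
    over unmasked bins; NaN outside."""
    sub = oe_block[np.ix_(ok, ok)]
    sub = np.where(np.isfinite(sub), sub, np.nan)
    # column-pairwise correlation over the unmasked rows; NaNs (masked
    # distances) are rare here — replace by the column mean so corrcoef is
    # defined
    col_mean = np.nanmean(sub, axis=0)
    filled = np.where(np.isnan(sub), col_mean[None, :], sub)
    sd = filled.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("constant O/E block")
    keep = sd > 0
    corr = np.corrcoef(filled[:, keep], rowvar=False)
    w, v = np.linalg.eigh(corr)
    lead = v[:, -1]  # eigenvalues ascending
    pc1_sub = np.full(ok.sum(), np.nan)
    pc1_sub[keep] = lead
    out = np.full(oe_block.shape[0], np.nan)
    out[ok] = pc1_sub
    return out


def pc1_compartments(
    oe: ContactMatrix, orientation: ScalarTrack, min_bins: int = 10
) -> CompartmentProfile:
    """Per-chromosome PC1 of the O/E correlation matrix, sign-oriented.

    Chromosomes with fewer than ``min_bins`` unmasked bins are masked with
    a warning rather than failing the genome-wide call.
    """
    if oe.kind != OBSERVED_EXPECTED:
        raise ValueError("pc1_compartments requires an observed/expected matrix")
    if not orientation.bins.same_table(oe.bins):
        raise ValueError("orientation track not aligned to the matrix bins")
    n = oe.n_bins
    pc1 = np.full(n, np.nan)
    for chrom in oe.bins.chroms:
        sl = oe.bins.chrom_slice(chrom)
        ok = ~oe.mask[sl]
        if ok.sum() < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} unmasked bins; masked")
            continue
        try:
            pc1[sl] = _corr_pc1(oe.values[sl, sl], ok)
        except ValueError:
            warnings.warn(f"{chrom}: constant O/E; masked")
            continue
        # orient per chromosome: positive correlation with the orientation track
        o = orientation.values[sl]
        both = np.isfinite(pc1[sl]) & np.isfinite(o)
        if both.sum() >= 3 and np.std(pc1[sl][both]) > 0 and np.std(o[both]) > 0:
            r = np.corrcoef(pc1[sl][both], o[both])[0, 1]
            if r < 0:
                pc1[sl] = -pc1[sl]
    track = ScalarTrack(oe.bins, pc1, name="pc1")
    labels = np.where(
        ~np.isfinite(pc1), "", np.where(pc1 > 0, "A", np.where(pc1 < 0, "B", ""))
    ).astype(object)
    both = np.isfinite(pc1) & np.isfinite(orientation.values)
    if both.sum() >= 3 and np.std(pc1[both]) > 0 and np.std(orientation.values[both]) > 0:
        evidence = float(np.corrcoef(pc1[both], orientation.values[both])[0, 1])
    else:
        evidence = float("nan")
    return CompartmentProfile(pc1=track, labels=labels, orientation_evidence=evidence)


def switch_table(
    a: CompartmentProfile, b: CompartmentProfile
) -> tuple[dict[str, int], float]:
    """Joint A/B label counts over co-unmasked bins and the stable fraction.

    Keys are "AA", "AB", "BA", "BB" (first letter = state in ``a``);
    ``stable_fraction = (AA + BB) / total``.
    """
    if not a.pc1.bins.same_table(b.pc1.bins):
        raise ValueError("profiles on different bin tables")
    la, lb = a.labels, b.labels
    ok = (la != "") & (lb != "")
    if not ok.any():
        raise ValueError("no co-unmasked bins")
    counts = {
        key: int(((la == key[0]) & (lb == key[1]) & ok).sum())
        for key in ("AA", "AB", "BA", "BB")
    }
    total = sum(counts.values())
    stable = (counts["AA"] + counts["BB"]) / total
    return counts, stable


def saddle_strength(
    oe: ContactMatrix,
    pc1: ScalarTrack,
    n_quantiles: int = 5,
    corner_frac: float = 0.2,
) -> SaddleResult:
    """PC1-ordered saddle matrix and the (AA+BB)/(AB+BA) corner ratio.

    Bins are ranked genome-wide by PC1 and split into ``n_quantiles``
    equal-occupancy groups; saddle(q, r) is the mean O/E over cis pixel
    pairs with one bin in each group (diagonal excluded).  Corners are the
    extreme ``corner_frac`` of quantile pairs on each side.
    """
    if oe.kind != OBSERVED_EXPECTED:
        raise ValueError("saddle_strength requires an observed/expected matrix")
    vals = pc1.values
    ok = np.isfinite(vals) & ~oe.mask
    if ok.sum() < n_quantiles:
        raise ValueError("too few defined PC1 bins")
    if np.nanstd(vals[ok]) == 0:
        raise ValueError("constant PC1 track")
    # ascending PC1: quantile 0 = strongest B, quantile Q-1 = strongest A
    ranks = np.full(len(vals), -1)
    order = np.argsort(vals[ok], kind="stable")
    q = np.floor(np.arange(ok.sum()) * n_quantiles / ok.sum()).astype(int)
    tmp = np.empty(ok.sum(), dtype=int)
    tmp[order] = q
    ranks[ok] = tmp
    Q = n_quantiles
    sums = np.zeros((Q, Q))
    counts = np.zeros((Q, Q))
    cis = oe.cis_mask()
    d = oe.distance_bins()
    for chrom in oe.bins.chroms:
        sl = oe.bins.chrom_slice(chrom)
        block = oe.values[sl, sl]
        r = ranks[sl]
        size = block.shape[0]
        idx = np.arange(size)
        valid = (
            (idx[:, None] < idx[None, :])
            & np.isfinite(block)
            & (r[:, None] >= 0)
            & (r[None, :] >= 0)
        )
        ii, jj = np.nonzero(valid)
        np.add.at(sums, (r[ii], r[jj]), block[ii, jj])
        np.add.at(counts, (r[ii], r[jj]), 1)
    sums = sums + sums.T - np.diag(np.diag(sums))
    counts = counts + counts.T - np.diag(np.diag(counts))
    with np.errstate(invalid="ignore"):
        saddle = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    k = max(1, int(round(corner_frac * Q)))
    bb = np.nanmean(saddle[:k, :k])  # strongest-B corner
    aa = np.nanmean(saddle[Q - k :, Q - k :])  # strongest-A corner
    ab = np.nanmean(saddle[:k, Q - k :])
    ba = np.nanmean(saddle[Q - k :, :k])
    strength = float((aa + bb) / (ab + ba))
    return SaddleResult(saddle=saddle, strength=strength)


def ab_composition(
    profile: CompartmentProfile, chrom_subset: list[str] | None = None
) -> tuple[float, float, float]:
    """Percent A, percent B and the A-run/B-run count ratio over a subset.

    The ratio is NaN when the subset has no B runs.  Runs are maximal
    stretches of one label within a chromosome.
    """
    bins = profile.pc1.bins
    chroms = chrom_subset if chrom_subset is not None else bins.chroms
    labels = profile.labels
    n_a = n_b = 0
    runs_a = runs_b = 0
    for chrom in chroms:
        sl = bins.chrom_slice(chrom)
        lab = labels[sl]
        keep = lab != ""
        n_a += int((lab == "A").sum())
        n_b += int((lab == "B").sum())
        seq = [l for l in lab if l != ""]
        prev = None
        for l in seq:
            if l != prev:
                if l == "A":
                    runs_a += 1
                else:
                    runs_b += 1
            prev = l
    total = n_a + n_b
    if total == 0:
        raise ValueError("no unmasked bins in subset")
    pct_a = 100.0 * n_a / total
    pct_b = 100.0 * n_b / total
    ratio = runs_a / runs_b if runs_b else float("nan")
    return pct_a, pct_b, ratio
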