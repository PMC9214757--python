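"""Contact-matrix I/O, replicate handling, ICE balancing, O/E and coarsening.

File formats are plain text: matrices as whitespace-separated triplets
``bin_id_1  bin_id_2  value`` (upper triangle only on write), bin tables as
4-column BED (``chrom  start  end  bin_id``), per-bin vectors as bedGraph.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BALANCED,
    OBSERVED_EXPECTED,
    RAW,
    BinTable,
    ContactMatrix,
    ScalarTrack,
)

__all__ = [
    "read_bins",
    "write_bins",
    "read_matrix",
    "write_matrix",
    "read_bedgraph",
    "write_bedgraph",
    "merge_replicates",
    "replicate_correlation",
    "ice_normalize",
    "observed_expected",
    "coarsen",
]


# ---------------------------------------------------------------------------
# file I/O

def read_bins(path: str | Path) -> BinTable:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "bin_id"],
        dtype={"chrom": str},
    )
    if not (df["bin_id"].to_numpy() == np.arange(len(df))).all():
        raise ValueError(f"{path}: bin_id column must be dense 0..N-1 in order")
    return BinTable(df[["chrom", "start", "end"]])


def write_bins(bins: BinTable, path: str | Path) -> None:
    bins.df[["chrom", "start", "end", "bin_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_matrix(
    triplet_path: str | Path, bins_path: str | Path, kind: str = RAW
) -> ContactMatrix:
    """Read a triplet-format matrix; (j, i) rows are folded onto (i, j) and
    duplicates summed."""
    bins = read_bins(bins_path)
    n = bins.n_bins
    values = np.zeros((n, n), dtype=float)
    with open(triplet_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{triplet_path}:{lineno}: expected 3 fields")
            i, j = int(parts[0]), int(parts[1])
            v = float(parts[2])
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{triplet_path}:{lineno}: bin_id out of range")
            if kind == RAW and v < 0:
                raise ValueError(f"{triplet_path}:{lineno}: negative count")
            values[i, j] += v
            if i != j:
                values[j, i] += v
    if kind == RAW:
        values = values.astype(np.int64)
    return ContactMatrix(bins, values, kind=kind)


def write_matrix(m: ContactMatrix, path: str | Path) -> None:
    """Write the nonzero upper triangle, sorted by (i, j)."""
    i, j = np.nonzero(np.triu(m.values))
    vals = m.values[i, j]
    with open(path, "w") as fh:
        for a, b, v in zip(i, j, vals):
            if m.kind == RAW:
                fh.write(f"{a}\t{b}\t{int(v)}\n")
            else:
                fh.write(f"{a}\t{b}\t{float(v)!r}\n")


def read_bedgraph(path: str | Path, bins: BinTable) -> ScalarTrack:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    values = np.full(bins.n_bins, np.nan)
    key = {(c, s): k for k, (c, s) in enumerate(
        zip(bins.df["chrom"], bins.df["start"]))}
    for row in df.itertuples(index=False):
        k = key.get((row.chrom, row.start))
        if k is None:
            raise ValueError(f"{path}: interval {row.chrom}:{row.start} not a bin")
        values[k] = row.value
    return ScalarTrack(bins, values)


def write_bedgraph(track: ScalarTrack, path: str | Path) -> None:
    df = track.bins.df
    with open(path, "w") as fh:
        for chrom, start, end, v in zip(
            df["chrom"], df["start"], df["end"], track.values
        ):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{start}\t{end}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# replicate handling

def merge_replicates(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Entry-wise sum of raw replicate matrices on one bin table."""
    if not matrices:
        raise ValueError("no matrices to merge")
    first = matrices[0]
    for m in matrices[1:]:
        if not m.bins.same_table(first.bins):
            raise ValueError("replicates have mismatched bin tables")
        if m.kind != RAW:
            raise ValueError("merge_replicates expects raw counts")
    if first.kind != RAW:
        raise ValueError("merge_replicates expects raw counts")
    total = first.values.copy()
    for m in matrices[1:]:
        total = total + m.values
    return ContactMatrix(first.bins, total, kind=RAW)


def replicate_correlation(
    a: ContactMatrix, b: ContactMatrix, max_dist: int = 2_000_000
) -> float:
    """Pearson correlation of intra-chromosomal pixels within ``max_dist``.

    Every pixel position in the band enters, including shared zeros, one
    unordered pair each.
    """
    if not a.bins.same_table(b.bins):
        raise ValueError("bin tables differ")
    bin_size = a.bins.bin_size
    max_bins = max_dist // bin_size
    xs, ys = [], []
    for chrom in a.bins.chroms:
        va, vb = a.chrom_view(chrom), b.chrom_view(chrom)
        m = va.shape[0]
        idx = np.arange(m)
        d = np.abs(idx[:, None] - idx[None, :])
        band = (d <= max_bins) & (idx[:, None] <= idx[None, :])
        xs.append(va[band])
        ys.append(vb[band])
    x = np.concatenate(xs).astype(float)
    y = np.concatenate(ys).astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance band; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# ICE balancing

def ice_normalize(
    m: ContactMatrix,
    max_iter: int = 1000,
    tol: float = 1e-5,
    mask_low_frac: float = 0.02,
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: factor out multiplicative per-bin biases.

    Bins in the lowest ``mask_low_frac`` coverage quantile plus
    zero-coverage bins are masked before iterating.  The returned bias
    vector ``b`` satisfies ``balanced[i, j] == raw[i, j] / (b[i] * b[j])``
    exactly (the global scale is folded into ``b``); masked bins carry NaN.
    Convergence is max relative deviation of unmasked row sums from their
    mean below ``tol``; non-convergence sets ``converged=False`` on the
    result instead of raising.
    """
    if m.kind != RAW and m.kind != BALANCED:
        raise ValueError("ice_normalize expects a raw (or balanced) matrix")
    n = m.n_bins
    W = m.values.astype(float).copy()
    coverage = W.sum(axis=1)
    masked = m.mask.copy() | (coverage == 0)
    if mask_low_frac > 0:
        nz = coverage[~masked]
        if nz.size:
            cutoff = np.quantile(nz, mask_low_frac)
            masked |= coverage <= cutoff
    unmasked = ~masked
    if unmasked.sum() < 2:
        raise ValueError("fewer than 2 unmasked bins")
    W[masked, :] = 0.0
    W[:, masked] = 0.0
    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        s = W[unmasked][:, unmasked].sum(axis=1)
        mean_s = s.mean()
        if mean_s == 0:
            raise ValueError("all unmasked bins have zero coverage")
        dev = np.abs(s / mean_s - 1.0).max()
        if dev < tol:
            converged = True
            break
        f = np.ones(n)
        f[unmasked] = s / mean_s
        W /= f[:, None] * f[None, :]
        bias *= f
    if not converged:
        warnings.warn("ICE did not converge within max_iter", RuntimeWarning)
    # fold the leftover scale so that raw = b_i * b_j * balanced exactly
    out_bias = np.where(masked, np.nan, bias)
    balanced = ContactMatrix(m.bins, W, kind=BALANCED, mask=masked,
                             converged=converged)
    return balanced, out_bias


# ---------------------------------------------------------------------------
# observed / expected

def expected_by_distance(m: ContactMatrix) -> dict[str, np.ndarray]:
    """Per-chromosome mean value at each bin separation, zeros included,
    over pixels whose two bins are both unmasked."""
    out = {}
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        v = m.values[sl, sl]
        ok = ~m.mask[sl]
        size = v.shape[0]
        exp = np.full(size, np.nan)
        for d in range(size):
            i = np.arange(size - d)
            valid = ok[i] & ok[i + d]
            if valid.any():
                exp[d] = v[i[valid], i[valid] + d].mean()
        out[chrom] = exp
    return out


def observed_expected(m: ContactMatrix) -> ContactMatrix:
    """Divide each cis entry by the per-chromosome mean at its distance.

    Distances with zero expected value are masked (NaN); trans entries are
    left at 0 and play no part in downstream cis statistics.
    """
    if m.kind != BALANCED:
        raise ValueError("observed_expected requires a balanced matrix")
    n = m.n_bins
    out = np.zeros((n, n), dtype=float)
    exp = expected_by_distance(m)
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        v = m.values[sl, sl]
        size = v.shape[0]
        idx = np.arange(size)
        d = np.abs(idx[:, None] - idx[None, :])
        e = exp[chrom][d]
        with np.errstate(divide="ignore", invalid="ignore"):
            block = np.where((e > 0), v / e, np.nan)
        block[np.isnan(e)] = np.nan
        out[sl, sl] = block
    out[m.mask, :] = np.nan
    out[:, m.mask] = np.nan
    # keep trans at 0, not NaN, so the array stays finite off the diagonal blocks
    cis = m.cis_mask()
    out[~cis] = 0.0
    return ContactMatrix(m.bins, out, kind=OBSERVED_EXPECTED, mask=m.mask.copy())


# ---------------------------------------------------------------------------
# coarsening

def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum counts over ``factor`` x ``factor`` bin blocks per chromosome."""
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise ValueError("factor must be an integer >= 2")
    if m.kind != RAW:
        raise ValueError("coarsen expects raw counts")
    bin_size = m.bins.bin_size
    new_lengths = []
    groups = []  # global coarse id per fine bin
    next_id = 0
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        size = sl.stop - sl.start
        local = np.arange(size) // factor
        groups.append(local + next_id)
        next_id += int(local[-1]) + 1
        end_bp = int(m.bins.df["end"].iloc[sl.stop - 1])
        new_lengths.append((chrom, end_bp))
    group = np.concatenate(groups)
    n_new = next_id
    # sum each unordered fine pair exactly once: scatter the upper triangle,
    # then mirror (bin ids are sorted, so a cross-block pair always lands in
    # the upper coarse triangle)
    S = np.zeros((n_new, m.n_bins))
    S[group, np.arange(m.n_bins)] = 1.0
    upper = S @ np.triu(m.values.astype(float)) @ S.T
    coarse = upper + np.triu(upper, 1).T
    coarse = np.round(coarse).astype(np.int64)
    # build the coarse table directly (a short chromosome may end up with a
    # single coarse bin, which from_chrom_lengths would reject)
    rows = []
    new_size = bin_size * factor
    for chrom, end_bp in new_lengths:
        starts = np.arange(0, end_bp, new_size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + new_size, end_bp))))
    new_bins = BinTable(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    if new_bins.n_bins != n_new:  # guard against partition mismatch
        raise AssertionError("coarsen bin bookkeeping error")
    return ContactMatrix(new_bins, coarse, kind=RAW)
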