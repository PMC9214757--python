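"""Synthetic binned Hi-C contact maps with known planted structure.

The generator produces the statistical features that compartment, TAD and
loop analyses assume: a power-law distance decay, a log-symmetric A/B
checkerboard, block-enriched domains, focal loop peaks, multiplicative
per-bin biases and a flat trans background.  Observed counts are
independent Poisson draws around the noise-free expectation, which is kept
in the returned :class:`TruthSet` as an analytic oracle.

Model for the expected cis count between bins i and j of one chromosome::

    E_ij = depth_scale * (d_ij * bin_size)^(-alpha)        distance decay
         * exp(+g)  if label_i == label_j else exp(-g)     g = ln(1 + c)
         * tau      if i and j lie inside the same domain
         * lambda   at planted loop pixels
         * b_i b_j                                          ln b ~ N(0, sd^2)

with d_ij = |i - j| clipped below at 1 (the diagonal reuses the d=1
expectation; downstream statistics exclude it anyway).  Expected trans
counts are ``trans_background * depth_scale * b_i * b_j``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    RAW,
    BinTable,
    ContactMatrix,
    GenomicInterval,
    IntervalSet,
    ScalarTrack,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_contact_map",
    "simulate_pc1_pair",
    "simulate_expression_table",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic contact map.

    ``compartment_track`` is either an explicit per-bin array of ``"A"`` /
    ``"B"`` labels, the string ``"auto-blocks"`` (alternating blocks of
    ``block_size_bins``), ``"random"`` (i.i.d. fair labels, which keeps the
    label composition stationary in distance), or ``None`` for no
    compartment structure.
    """

    chrom_lengths: Sequence[tuple[str, int]]
    bin_size: int = 40_000
    decay_exponent: float = 1.0
    compartment_contrast: float = 0.0  # c; log-contrast g = ln(1 + c)
    compartment_track: object = "auto-blocks"
    block_size_bins: int = 10
    tad_intervals: Sequence[tuple[str, int, int]] = ()  # (chrom, start_bin, end_bin)
    tad_enrichment: float = 3.0  # tau
    loop_pixels: Sequence[tuple[str, int, int]] = ()  # (chrom, bin_i, bin_j)
    loop_enrichment: float = 8.0  # lambda
    bias_log_sd: float = 0.0
    trans_background: float = 0.0
    depth_scale: float = 2.0e7  # ~500 expected counts at one-bin separation (40 kb)
    seed: int = 0

    def validate(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")
        if self.compartment_contrast < 0:
            raise ValueError("compartment_contrast must be >= 0")
        if self.bias_log_sd < 0 or self.trans_background < 0:
            raise ValueError("bias_log_sd and trans_background must be >= 0")
        if self.tad_enrichment <= 0 or self.loop_enrichment <= 0:
            raise ValueError("enrichment factors must be positive")
        for chrom, length in self.chrom_lengths:
            if length < 2 * self.bin_size:
                raise ValueError(f"chromosome {chrom} must span >= 2 bins")
        sizes = {c: -(-l // self.bin_size) for c, l in self.chrom_lengths}
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.tad_intervals:
            if chrom not in sizes:
                raise ValueError(f"TAD on unknown chromosome {chrom}")
            if not (0 <= s < e <= sizes[chrom]):
                raise ValueError(f"TAD [{s},{e}) outside {chrom}")
            per_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping TADs on {chrom}")
        for chrom, i, j in self.loop_pixels:
            if chrom not in sizes:
                raise ValueError(f"loop on unknown chromosome {chrom}")
            if not (0 <= i < j < sizes[chrom]):
                raise ValueError(f"loop pixel ({i},{j}) invalid on {chrom}")


@dataclass
class TruthSet:
    """Planted structure and the noise-free expectation of a simulation."""

    compartment_labels: np.ndarray  # per-bin "A"/"B" ("" where none planted)
    tad_intervals: IntervalSet  # bp coordinates
    loop_pixels: list[tuple[str, int, int]]  # global bin ids on write, chrom-local here
    bias_vector: np.ndarray  # per-bin positive multiplier
    expected_matrix: np.ndarray  # noise-free expected counts


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent substreams so operations stay reproducible alone."""
    root = np.random.SeedSequence(seed)
    names = ["bias", "counts", "pc1", "expression"]
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _compartment_labels(config: SimulationConfig, bins: BinTable, rng) -> np.ndarray:
    track = config.compartment_track
    n = bins.n_bins
    if track is None:
        return np.full(n, "", dtype=object)
    if isinstance(track, str):
        if track == "auto-blocks":
            labels = np.empty(n, dtype=object)
            for chrom in bins.chroms:
                sl = bins.chrom_slice(chrom)
                local = np.arange(sl.stop - sl.start)
                labels[sl] = np.where(
                    (local // config.block_size_bins) % 2 == 0, "A", "B"
                )
            return labels
        if track == "random":
            return np.where(rng.random(n) < 0.5, "A", "B").astype(object)
        raise ValueError(f"unknown compartment_track {track!r}")
    labels = np.asarray(track, dtype=object)
    if labels.shape != (n,):
        raise ValueError("explicit compartment_track length must match bin count")
    if not set(np.unique(labels)) <= {"A", "B"}:
        raise ValueError("compartment labels must be 'A' or 'B'")
    return labels


def expected_contact_map(
    config: SimulationConfig, bins: BinTable, labels: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Noise-free expected count matrix under the generative model."""
    n = bins.n_bins
    E = np.zeros((n, n), dtype=float)
    g = np.log1p(config.compartment_contrast)
    chrom_of = {c: k for k, c in enumerate(bins.chroms)}
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        m = sl.stop - sl.start
        idx = np.arange(m)
        d = np.abs(idx[:, None] - idx[None, :])
        d_eff = np.maximum(d, 1)  # diagonal reuses the d=1 expectation
        block = config.depth_scale * (d_eff * config.bin_size) ** (
            -config.decay_exponent
        )
        if g > 0:
            lab = labels[sl]
            has = lab != ""
            same = (lab[:, None] == lab[None, :]) & has[:, None] & has[None, :]
            opposite = (lab[:, None] != lab[None, :]) & has[:, None] & has[None, :]
            block = block * np.where(same, np.exp(g), 1.0)
            block = block * np.where(opposite, np.exp(-g), 1.0)
        E[sl, sl] = block
    # TAD enrichment: both endpoints strictly inside [start_bin, end_bin)
    for chrom, s, e in config.tad_intervals:
        sl = bins.chrom_slice(chrom)
        lo, hi = sl.start + s, sl.start + e
        E[lo:hi, lo:hi] *= config.tad_enrichment
    for chrom, i, j in config.loop_pixels:
        sl = bins.chrom_slice(chrom)
        gi, gj = sl.start + i, sl.start + j
        E[gi, gj] *= config.loop_enrichment
        E[gj, gi] *= config.loop_enrichment
    if config.trans_background > 0:
        ci = bins.chrom_index
        trans = ci[:, None] != ci[None, :]
        E[trans] = config.trans_background * config.depth_scale
    E *= bias[:, None] * bias[None, :]
    return E


def simulate_contact_map(
    config: SimulationConfig,
) -> tuple[ContactMatrix, BinTable, TruthSet]:
    """Draw one Poisson contact map; returns matrix, bins and ground truth."""
    config.validate()
    bins = BinTable.from_chrom_lengths(config.chrom_lengths, config.bin_size)
    streams = _streams(config.seed)
    labels = _compartment_labels(config, bins, streams["bias"])
    n = bins.n_bins
    if config.bias_log_sd > 0:
        bias = np.exp(streams["bias"].normal(0.0, config.bias_log_sd, size=n))
    else:
        bias = np.ones(n)
    E = expected_contact_map(config, bins, labels, bias)
    # draw the upper triangle and mirror so the matrix is exactly symmetric
    iu = np.triu_indices(n)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu] = streams["counts"].poisson(E[iu])
    counts = counts + np.triu(counts, 1).T
    tads = IntervalSet(
        GenomicInterval(chrom, s * config.bin_size, e * config.bin_size, name="tad")
        for chrom, s, e in config.tad_intervals
    )
    truth = TruthSet(
        compartment_labels=labels,
        tad_intervals=tads,
        loop_pixels=list(config.loop_pixels),
        bias_vector=bias,
        expected_matrix=E,
    )
    return ContactMatrix(bins, counts, kind=RAW), bins, truth


def simulate_pc1_pair(
    n_bins: int,
    conserved_blocks: IntervalSet | Sequence[tuple[int, int]],
    r_in: float,
    r_out: float,
    seed: int = 0,
    bin_size: int = 400_000,
    chrom: str = "chr1",
) -> tuple[ScalarTrack, ScalarTrack]:
    """Two per-bin Gaussian tracks with block-dependent correlation.

    Inside ``conserved_blocks`` the per-bin bivariate correlation is
    ``r_in``, outside ``r_out``.  Blocks may be an :class:`IntervalSet` in
    bp or a list of ``(start_bin, end_bin)`` pairs on one chromosome.
    """
    if n_bins < 1:
        raise ValueError("empty track")
    if not (-1 <= r_out < r_in <= 1):
        raise ValueError("require -1 <= r_out < r_in <= 1")
    bins = BinTable.from_chrom_lengths([(chrom, n_bins * bin_size)], bin_size)
    inside = np.zeros(n_bins, dtype=bool)
    if isinstance(conserved_blocks, IntervalSet):
        for iv in conserved_blocks:
            if iv.chrom == chrom:
                inside[iv.start // bin_size : -(-iv.end // bin_size)] = True
    else:
        for s, e in conserved_blocks:
            inside[s:e] = True
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    z1 = rng.standard_normal(n_bins)
    z2 = rng.standard_normal(n_bins)
    r = np.where(inside, r_in, r_out)
    x = z1
    y = r * z1 + np.sqrt(1.0 - r**2) * z2
    return (
        ScalarTrack(bins, x, name="pc1_a"),
        ScalarTrack(bins, y, name="pc1_b"),
    )


def simulate_expression_table(
    genes: IntervalSet,
    high_set: set[str],
    effect: float,
    seed: int = 0,
    base_log_mean: float = 2.0,
    log_sd: float = 1.0,
):
    """Log-normal per-gene expression; genes in ``high_set`` get a mean
    shift of ``effect`` (in log-sd units) above baseline.

    Returns a DataFrame with columns ``gene_id`` and ``value``.
    """
    import pandas as pd

    if effect < 0:
        raise ValueError("effect must be >= 0")
    ids = [iv.name for iv in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    shift = np.array([effect * log_sd if g in high_set else 0.0 for g in ids])
    log_values = rng.normal(base_log_mean + shift, log_sd)
    return pd.DataFrame({"gene_id": ids, "value": np.exp(log_values)})
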