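"""TAD detection: directionality index, HMM domain calling, insulation.

The directionality index (DI) of a bin compares its contact mass to the
upstream window A and the downstream window B::

    E = (A + B) / 2
    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

Positive DI (downstream bias) marks a domain start, negative DI (upstream
bias) a domain end.  A 3-state Gaussian HMM over the DI track is decoded
with Viterbi; a domain runs from the start of a maximal downstream-bias
run to the end of the next upstream-bias run.  Gaps between adjacent
domains shorter than 400 kb are reported as boundaries.

The insulation score of a bin is the mean contact in the square window
just off the diagonal at that bin, reported as log2 over the chromosome
mean, with a loess-smoothed copy alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import (
    BALANCED,
    ContactMatrix,
    GenomicInterval,
    IntervalSet,
    ScalarTrack,
)

__all__ = [
    "DITrack",
    "TADSet",
    "InsulationTrack",
    "directionality_index",
    "hmm_call_tads",
    "insulation_score",
    "tad_profile",
    "tad_switch_class",
]

BOUNDARY_MAX_BP = 400_000  # inter-domain gaps below this are boundaries


@dataclass
class DITrack:
    track: ScalarTrack
    window: int  # bp


@dataclass
class TADSet:
    domains: IntervalSet
    boundaries: IntervalSet


@dataclass
class InsulationTrack:
    track: ScalarTrack  # log2(window mean / chromosome mean)
    smoothed: ScalarTrack
    window: int  # bp


def directionality_index(m: ContactMatrix, window: int = 2_000_000) -> DITrack:
    """Per-bin DI from a balanced matrix; NaN where A + B = 0."""
    if m.kind != BALANCED:
        raise ValueError("directionality_index expects a balanced matrix")
    bin_size = m.bins.bin_size
    w = window // bin_size
    if w < 2:
        raise ValueError("window must span >= 2 bins")
    di = np.full(m.n_bins, np.nan)
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        v = m.values[sl, sl]
        size = v.shape[0]
        for b in range(size):
            lo = max(0, b - w)
            hi = min(size, b + w + 1)
            A = float(v[b, lo:b].sum())  # upstream
            B = float(v[b, b + 1 : hi].sum())  # downstream
            s = A + B
            if s == 0:
                continue
            if A == B:
                di[sl.start + b] = 0.0
                continue
            E = s / 2.0
            stat = (A - E) ** 2 / E + (B - E) ** 2 / E
            di[sl.start + b] = np.sign(B - A) * stat
    di[m.mask] = np.nan
    return DITrack(track=ScalarTrack(m.bins, di, name="DI"), window=window)


def _fit_decode_hmm(x: np.ndarray, max_em_iter: int, seed: int) -> np.ndarray:
    """3-state Gaussian HMM states for one DI sequence.

    DI is chi-square-like and spans orders of magnitude, so emissions are
    modelled on the sign-preserving log scale sign(DI) * log1p(|DI|).
    Deterministic moment-based init: means at (-sd, 0, +sd), shared
    variance, sticky uniform-ish transitions.  Returns the Viterbi path
    with states ordered (0 = upstream bias, 1 = none, 2 = downstream bias).
    """
    x = np.sign(x) * np.log1p(np.abs(x))
    sd = x.std()
    if sd == 0:
        return np.ones(len(x), dtype=int)
    model = GaussianHMM(
        n_components=3,
        covariance_type="diag",
        n_iter=max_em_iter,
        init_params="",  # keep the moment-based initialization
        params="stmc",
        random_state=seed,
    )
    model.startprob_ = np.array([1 / 3, 1 / 3, 1 / 3])
    model.transmat_ = np.array(
        [[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]]
    )
    model.means_ = np.array([[-sd], [0.0], [sd]])
    model.covars_ = np.array([[sd**2], [sd**2], [sd**2]])
    X = x.reshape(-1, 1)
    try:
        model.fit(X)
    except Exception:
        warnings.warn("HMM fit failed; falling back to threshold segmentation")
        return np.digitize(x, [-sd / 2, sd / 2])
    states = model.predict(X)
    # reorder states by fitted mean so 0 < 1 < 2 in DI
    order = np.argsort(model.means_.ravel())
    remap = np.empty(3, dtype=int)
    remap[order] = np.arange(3)
    return remap[states]


def hmm_call_tads(
    di: DITrack, max_em_iter: int = 100, seed: int = 0
) -> TADSet:
    """Call TADs per chromosome from the DI track via a 3-state HMM.

    Domain grammar on the decoded state path: a domain opens at the start
    of a maximal downstream-bias run and closes at the end of the next
    upstream-bias run; no-bias stretches inside are absorbed.  Inter-domain
    gaps shorter than 400 kb become boundaries.
    """
    bins = di.track.bins
    bin_size = bins.bin_size
    domains: list[GenomicInterval] = []
    boundaries: list[GenomicInterval] = []
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        x = di.track.values[sl]
        ok = np.isfinite(x)
        if ok.sum() < 20:
            continue
        filled = np.where(ok, x, 0.0)
        if np.all(filled == 0):
            continue
        states = _fit_decode_hmm(filled, max_em_iter, seed)
        # walk runs: open on a downstream (2) run, close at end of the next
        # upstream (0) run
        size = len(states)
        chrom_domains: list[tuple[int, int]] = []
        b = 0
        while b < size:
            if states[b] == 2:
                start = b
                while b < size and states[b] == 2:
                    b += 1
                # advance through no-bias / downstream until an upstream run
                while b < size and states[b] != 0:
                    b += 1
                if b == size:
                    break
                while b < size and states[b] == 0:
                    b += 1
                end = b  # exclusive, end of the upstream run
                chrom_domains.append((start, end))
            else:
                b += 1
        start_bp_of = bins.df["start"].to_numpy()
        end_bp_of = bins.df["end"].to_numpy()
        prev_end = None
        for s, e in chrom_domains:
            d_start = int(start_bp_of[sl.start + s])
            d_end = int(end_bp_of[sl.start + e - 1])
            domains.append(GenomicInterval(chrom, d_start, d_end, name="tad"))
            if prev_end is not None:
                gap = d_start - prev_end
                if 0 < gap < BOUNDARY_MAX_BP:
                    boundaries.append(
                        GenomicInterval(chrom, prev_end, d_start, name="boundary")
                    )
            prev_end = d_end
    dom_set = IntervalSet(domains)
    dom_set.check_non_overlapping()
    return TADSet(domains=dom_set, boundaries=IntervalSet(boundaries))


def insulation_score(
    m: ContactMatrix, window: int = 400_000, loess_frac: float = 0.1
) -> InsulationTrack:
    """Sliding square-window mean contact along the diagonal.

    For bin b the window is the w x w square spanning (b-w, b] x (b, b+w]
    in bins; the reported track is log2 of the window mean over the
    chromosome mean of defined values, so it is scale-free and averages to
    about zero per chromosome.  Bins within ``window`` of a chromosome end
    are undefined; chromosomes shorter than twice the window are skipped.
    """
    if m.kind != BALANCED:
        raise ValueError("insulation_score expects a balanced matrix")
    bin_size = m.bins.bin_size
    w = window // bin_size
    if w < 1:
        raise ValueError("window shorter than one bin")
    raw = np.full(m.n_bins, np.nan)
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        size = sl.stop - sl.start
        if size < 2 * w:
            warnings.warn(f"{chrom}: shorter than twice the window; skipped")
            continue
        v = m.values[sl, sl]
        for b in range(w - 1, size - w):
            sq = v[b - w + 1 : b + 1, b + 1 : b + w + 1]
            raw[sl.start + b] = sq.mean()
        # log2 over the chromosome mean of defined window values
        chrom_vals = raw[sl]
        ok = np.isfinite(chrom_vals)
        mu = chrom_vals[ok].mean() if ok.any() else np.nan
        if mu and np.isfinite(mu) and mu > 0:
            with np.errstate(divide="ignore"):
                raw[sl] = np.where(ok, np.log2(chrom_vals / mu), np.nan)
        else:
            raw[sl] = np.nan
    smoothed = np.full(m.n_bins, np.nan)
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        ys = raw[sl]
        ok = np.isfinite(ys)
        if ok.sum() >= 10:
            xs = np.arange(sl.stop - sl.start, dtype=float)
            sm = lowess(ys[ok], xs[ok], frac=loess_frac, return_sorted=False)
            out = np.full(len(ys), np.nan)
            out[ok] = sm
            smoothed[sl] = out
    return InsulationTrack(
        track=ScalarTrack(m.bins, raw, name="insulation"),
        smoothed=ScalarTrack(m.bins, smoothed, name="insulation_loess"),
        window=window,
    )


def tad_profile(
    is_track: InsulationTrack,
    tads: TADSet,
    flank_frac: float = 0.5,
    n_points: int = 100,
    use_smoothed: bool = False,
) -> np.ndarray:
    """Average insulation over TADs rescaled to unit length with flanks.

    The shared coordinate runs from ``-flank_frac`` to ``1 + flank_frac``
    with the TAD occupying [0, 1]; each TAD's track is linearly
    interpolated onto ``n_points`` positions and averaged.  TADs whose
    flanked span leaves the defined part of the track are dropped; an
    error is raised if none remain.
    """
    src = is_track.smoothed if use_smoothed else is_track.track
    bins = src.bins
    bin_size = bins.bin_size
    coords = np.linspace(-flank_frac, 1.0 + flank_frac, n_points)
    profiles = []
    for tad in tads.domains:
        sl = bins.chrom_slice(tad.chrom)
        chrom_start_bp = int(bins.df["start"].iloc[sl.start])
        s = (tad.start - chrom_start_bp) // bin_size
        e = (tad.end - chrom_start_bp) // bin_size
        length = e - s
        if length < 2:
            continue
        flank = flank_frac * length
        lo = s - flank
        hi = e + flank
        positions = lo + (coords + flank_frac) / (1 + 2 * flank_frac) * (hi - lo)
        x = np.arange(sl.stop - sl.start, dtype=float)
        y = src.values[sl]
        ok = np.isfinite(y)
        if not ok.any():
            continue
        if positions[0] < x[ok].min() or positions[-1] > x[ok].max():
            continue
        prof = np.interp(positions, x[ok], y[ok])
        profiles.append(prof)
    if not profiles:
        raise ValueError("no TAD fully covered by the insulation track")
    return np.mean(profiles, axis=0)


def tad_switch_class(
    tads: TADSet, pc1_a: ScalarTrack, pc1_b: ScalarTrack
) -> dict[str, object]:
    """Classify each TAD's compartment transition between two stages.

    A TAD's label per stage is the sign of the mean PC1 over its span;
    transitions are counted over classified TADs and reported with the
    switched percentage.  TADs with fully masked PC1 in either stage land
    in an ``unclassified`` bucket.
    """
    if not pc1_a.bins.same_table(pc1_b.bins):
        raise ValueError("PC1 tracks on different bin tables")
    bins = pc1_a.bins
    bin_size = bins.bin_size
    counts = {"A->A": 0, "A->B": 0, "B->A": 0, "B->B": 0}
    per_tad = []
    unclassified = 0
    for tad in tads.domains:
        sl = bins.chrom_slice(tad.chrom)
        chrom_start_bp = int(bins.df["start"].iloc[sl.start])
        s = sl.start + (tad.start - chrom_start_bp) // bin_size
        e = sl.start + max(s - sl.start + 1, -(-(tad.end - chrom_start_bp) // bin_size))
        va = pc1_a.values[s:e]
        vb = pc1_b.values[s:e]
        ma = np.nanmean(va) if np.isfinite(va).any() else np.nan
        mb = np.nanmean(vb) if np.isfinite(vb).any() else np.nan
        if not (np.isfinite(ma) and np.isfinite(mb)) or ma == 0 or mb == 0:
            unclassified += 1
            per_tad.append((tad, "unclassified"))
            continue
        key = ("A" if ma > 0 else "B") + "->" + ("A" if mb > 0 else "B")
        counts[key] += 1
        per_tad.append((tad, key))
    classified = sum(counts.values())
    switched = counts["A->B"] + counts["B->A"]
    return {
        "counts": counts,
        "unclassified": unclassified,
        "switched_percent": 100.0 * switched / classified if classified else float("nan"),
        "per_tad": per_tad,
    }
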