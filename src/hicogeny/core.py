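"""Core data containers for binned Hi-C analysis.

The package works at the resolution of a genome-wide *bin table* (ordered,
dense 0-based bin ids over one or more chromosomes) and represents contact
maps as dense symmetric matrices over those bins.  Dense storage is the
right trade-off at the scales this package targets (hundreds to a few
thousand bins per chromosome); file I/O uses a sparse triplet text dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "ContactMatrix",
    "ScalarTrack",
    "GenomicInterval",
    "IntervalSet",
    "MatrixKind",
]

# matrix kinds; raw holds counts, the others reals
RAW = "raw"
BALANCED = "balanced"
OBSERVED_EXPECTED = "observed_expected"
DIFFERENCE = "difference"
MatrixKind = str
_KINDS = {RAW, BALANCED, OBSERVED_EXPECTED, DIFFERENCE}


class BinTable:
    """Ordered genomic bins with dense global 0-based ``bin_id``.

    Coordinates are 0-based half-open (BED convention).  Within each
    chromosome bins are contiguous and sorted; every bin has width
    ``bin_size`` except possibly the last bin of a chromosome.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["chrom", "start", "end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"bin table missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["bin_id"] = np.arange(len(df), dtype=int)
        self.df = df
        self._validate()
        # per-chromosome slices in table order
        self._chrom_slices: dict[str, slice] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            self._chrom_slices[str(chrom)] = slice(int(idx[0]), int(idx[-1]) + 1)

    @classmethod
    def from_chrom_lengths(
        cls, chrom_lengths: Sequence[tuple[str, int]], bin_size: int
    ) -> "BinTable":
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        rows = []
        for chrom, length in chrom_lengths:
            if length < 2 * bin_size:
                raise ValueError(
                    f"chromosome {chrom} shorter than two bins ({length} bp)"
                )
            starts = np.arange(0, length, bin_size)
            ends = np.minimum(starts + bin_size, length)
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(df)

    def _validate(self) -> None:
        for chrom, grp in self.df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"empty bin on {chrom}")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"bins on {chrom} not contiguous/sorted")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)

    @property
    def bin_size(self) -> int:
        """Modal bin width (the nominal resolution)."""
        widths = (self.df["end"] - self.df["start"]).to_numpy()
        return int(np.bincount(widths).argmax()) if len(widths) else 0

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def chrom_sizes(self) -> dict[str, int]:
        return {
            c: int(self.df["end"].iloc[self._chrom_slices[c]].max())
            for c in self.chroms
        }

    @property
    def chrom_index(self) -> np.ndarray:
        """Integer chromosome index per bin (order of appearance)."""
        codes = np.empty(len(self), dtype=int)
        for k, c in enumerate(self.chroms):
            codes[self._chrom_slices[c]] = k
        return codes

    def same_table(self, other: "BinTable") -> bool:
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        return bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinTable) and self.same_table(other)

    def __repr__(self) -> str:
        return f"BinTable({self.n_bins} bins, {len(self.chroms)} chroms, {self.bin_size} bp)"


@dataclass
class ContactMatrix:
    """Symmetric binned contact map over a :class:`BinTable`.

    ``values`` is a dense symmetric array aligned to ``bins``; ``mask`` marks
    excluded bins (their rows/columns are held at zero).  ``kind`` records
    the value semantics: ``raw`` counts, ``balanced`` reals,
    ``observed_expected`` ratios, or ``difference`` (may be negative).
    """

    bins: BinTable
    values: np.ndarray
    kind: MatrixKind = RAW
    mask: np.ndarray | None = None  # True where the bin is excluded
    converged: bool = True  # set False by a non-convergent balancing

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        v = np.asarray(self.values)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.kind == RAW:
            if np.any(v < 0):
                raise ValueError("raw matrix has negative counts")
        elif self.kind in (BALANCED, OBSERVED_EXPECTED):
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError(f"{self.kind} matrix has negative values")
        self.values = v.astype(float) if self.kind != RAW else v
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins, self.values.copy(), self.kind, self.mask.copy(), self.converged
        )

    def cis_mask(self) -> np.ndarray:
        """Boolean pixel matrix: True for intra-chromosomal pairs."""
        c = self.bins.chrom_index
        return c[:, None] == c[None, :]

    def distance_bins(self) -> np.ndarray:
        """|i - j| in bins (meaningful for cis pixels only)."""
        idx = np.arange(self.n_bins)
        return np.abs(idx[:, None] - idx[None, :])

    def chrom_view(self, chrom: str) -> np.ndarray:
        sl = self.bins.chrom_slice(chrom)
        return self.values[sl, sl]

    def total(self) -> float:
        """Genome-wide sum counting each unordered pair once."""
        return float(np.triu(self.values).sum())


@dataclass
class ScalarTrack:
    """Per-bin real-valued signal aligned to a BinTable; NaN marks undefined."""

    bins: BinTable
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.bins.n_bins,):
            raise ValueError("track length must match bin table")
        self.values = v

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self) -> "ScalarTrack":
        return ScalarTrack(self.bins, self.values.copy(), self.name)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    name: str = ""
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Labelled genomic intervals, sorted by (chrom, start)."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def check_non_overlapping(self) -> None:
        for chrom, ivs in self.by_chrom().items():
            for prev, cur in zip(ivs, ivs[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"overlapping intervals on {chrom}: "
                        f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                    )

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, iv.name, iv.score) for iv in self.intervals],
            columns=["chrom", "start", "end", "name", "score"],
        )
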