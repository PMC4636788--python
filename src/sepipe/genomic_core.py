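"""Coordinate conventions, domain types, and interval arithmetic.

Every coordinate inside the package is 0-based, half-open (BED convention).
Inputs that use other conventions are converted at the reader boundary
(:mod:`sepipe.io`). Adjacent (book-ended) intervals do **not** overlap —
overlap requires at least one shared base — but have gap 0.

Chromosome names are compared as exact strings; there is no silent "chr"
prefix normalisation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

VALID_STRANDS = ("+", "-", ".")
BIOTYPES = ("coding", "lncRNA", "miRNA")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end - start >= 1``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not isinstance(self.start, (int, np.integer)) or not isinstance(
            self.end, (int, np.integer)
        ):
            raise TypeError("interval coordinates must be integers")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base.

    Book-ended intervals ([100,200) vs [200,300)) do not overlap; intervals
    on different chromosomes never overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap in bp between two intervals; 0 if they overlap or are adjacent.

    Returns ``None`` (undefined) for intervals on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def extend(
    a: GenomicInterval,
    flank: int,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> GenomicInterval:
    """Extend an interval by ``flank`` bp on both sides, clipping at 0.

    Clipping at the chromosome end is applied only when ``chrom_sizes``
    is supplied.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start = max(0, a.start - flank)
    end = a.end + flank
    if chrom_sizes is not None and a.chrom in chrom_sizes:
        end = min(end, chrom_sizes[a.chrom])
    return GenomicInterval(a.chrom, start, end, a.strand)


def merge_overlapping(
    intervals: Iterable[GenomicInterval],
) -> List[GenomicInterval]:
    """Merge intervals that overlap by >= 1 bp into maximal loci.

    Book-ended intervals are kept separate (the ">= 1 bp" rule). Output is
    sorted by (chrom, start, end).
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict overlap, not book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval with its calling p-value and tag support."""

    interval: GenomicInterval
    pvalue: float
    tags: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")
        if self.tags is not None and self.tags < 0:
            raise ValueError("tags must be non-negative")


@dataclass(frozen=True)
class GeneAnnotation:
    """An annotated gene: id, biotype, body interval, strand-aware TSS.

    The TSS of a ``+``-strand gene is ``body.start``; for ``-`` strand it is
    ``body.end - 1`` (the last covered base).
    """

    gene_id: str
    biotype: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"biotype must be one of {BIOTYPES}, got {self.biotype!r}"
            )
        if self.body.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end - 1


@dataclass(frozen=True)
class LDRegion:
    """A linkage-disequilibrium block around a lead eQTL SNP."""

    snp_id: str
    region: GenomicInterval
    r2_cutoff: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_cutoff <= 1.0):
            raise ValueError("r2_cutoff must be in (0, 1]")


class SignalTrack:
    """Genome-placed tag signal queryable by interval.

    Two storage modes:

    * tag positions — one entry per mapped tag (``from_tags``); an interval
      query counts tags with ``start <= pos < end``;
    * bins — (interval, count) pairs, e.g. from bedGraph (``from_bins``);
      an interval query sums counts weighted by fractional bin overlap.

    ``library_size`` is the total mapped tags and is the tags-per-million
    denominator downstream.
    """

    def __init__(
        self,
        positions: Optional[Mapping[str, np.ndarray]] = None,
        bins: Optional[Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None,
        library_size: Optional[int] = None,
    ) -> None:
        if (positions is None) == (bins is None):
            raise ValueError("exactly one of positions/bins must be given")
        self._positions: Optional[Dict[str, np.ndarray]] = None
        self._bins = None
        if positions is not None:
            self._positions = {
                c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in positions.items()
            }
            total = sum(len(p) for p in self._positions.values())
        else:
            self._bins = {}
            total = 0.0
            for c, (starts, ends, counts) in bins.items():
                starts = np.asarray(starts, dtype=np.int64)
                ends = np.asarray(ends, dtype=np.int64)
                counts = np.asarray(counts, dtype=float)
                order = np.argsort(starts)
                if np.any(counts < 0):
                    raise ValueError("bin counts must be non-negative")
                self._bins[c] = (starts[order], ends[order], counts[order])
                total += float(counts.sum())
        if library_size is None:
            library_size = int(round(total))
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        if library_size < total - 1e-6:
            raise ValueError(
                f"library_size {library_size} smaller than total signal {total}"
            )
        self.library_size = int(library_size)

    @classmethod
    def from_tags(
        cls,
        positions: Mapping[str, Sequence[int]],
        library_size: Optional[int] = None,
    ) -> "SignalTrack":
        return cls(positions=positions, library_size=library_size)

    @classmethod
    def from_bins(
        cls,
        bins: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: Optional[int] = None,
    ) -> "SignalTrack":
        return cls(bins=bins, library_size=library_size)

    def count(self, region: GenomicInterval) -> float:
        """Tag count within ``region`` (fractional for bin-mode overlaps)."""
        if self._positions is not None:
            pos = self._positions.get(region.chrom)
            if pos is None:
                return 0.0
            lo = np.searchsorted(pos, region.start, side="left")
            hi = np.searchsorted(pos, region.end, side="left")
            return float(hi - lo)
        entry = self._bins.get(region.chrom)
        if entry is None:
            return 0.0
        starts, ends, counts = entry
        ov = np.minimum(ends, region.end) - np.maximum(starts, region.start)
        mask = ov > 0
        if not mask.any():
            return 0.0
        frac = ov[mask] / (ends[mask] - starts[mask])
        return float(np.sum(counts[mask] * frac))


class TSSIndex:
    """Sorted per-chromosome TSS positions for fast proximity queries."""

    def __init__(self, tss: Iterable[Tuple[str, int]]) -> None:
        by_chrom: Dict[str, List[int]] = {}
        for chrom, pos in tss:
            by_chrom.setdefault(chrom, []).append(int(pos))
        self._by_chrom = {c: sorted(v) for c, v in by_chrom.items()}

    @classmethod
    def from_genes(cls, genes: Iterable[GeneAnnotation]) -> "TSSIndex":
        return cls((g.body.chrom, g.tss) for g in genes)

    def any_within(self, region: GenomicInterval, window: int) -> bool:
        """True iff any TSS lies within ``window`` bp of any base of region.

        Equivalent to a TSS falling in ``[start - window, end + window)``.
        """
        positions = self._by_chrom.get(region.chrom)
        if not positions:
            return False
        lo = bisect.bisect_left(positions, region.start - window)
        hi = bisect.bisect_left(positions, region.end + window)
        return hi > lo

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())
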