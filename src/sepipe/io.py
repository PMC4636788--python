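"""Readers and writers for the plain-text formats the pipeline touches.

All files are tab-separated. Readers validate coordinates and raise
:class:`FormatError` naming the offending line. Writers emit deterministic
output: records sorted by (chrom, start, end) and floats formatted to six
decimals, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genomic_core import (
    BIOTYPES,
    GeneAnnotation,
    GenomicInterval,
    LDRegion,
    Peak,
    SignalTrack,
)

PathLike = Union[str, Path]

FLOAT_FMT = "{:.6f}"


class FormatError(ValueError):
    """A malformed record in an input file."""


def _lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _interval(path, lineno, chrom, start, end, strand=".") -> GenomicInterval:
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise FormatError(f"{path}, line {lineno}: non-integer coordinate") from exc
    try:
        return GenomicInterval(chrom, s, e, strand)
    except ValueError as exc:
        raise FormatError(f"{path}, line {lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: PathLike, format: str = "narrowPeak") -> List[Peak]:
    """Read peak calls.

    ``narrowPeak``: standard 10-column ENCODE narrowPeak; column 8 holds
    -log10(p) and is converted to ``pvalue = 10**(-value)``.

    ``bed6+pvalue``: chrom, start, end, pvalue [, tags] with the p-value as
    a plain probability in column 4.
    """
    peaks: List[Peak] = []
    if format == "narrowPeak":
        for lineno, f in _lines(path):
            if len(f) < 10:
                raise FormatError(
                    f"{path}, line {lineno}: narrowPeak needs 10 columns, got {len(f)}"
                )
            iv = _interval(path, lineno, f[0], f[1], f[2], f[5] if f[5] in "+-." else ".")
            try:
                neglog10p = float(f[7])
                signal = float(f[6])
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: bad numeric field") from exc
            pvalue = 10.0 ** (-neglog10p)
            tags = int(round(signal)) if signal >= 0 else None
            peaks.append(Peak(iv, pvalue=min(pvalue, 1.0), tags=tags, name=f[3]))
    elif format == "bed6+pvalue":
        for lineno, f in _lines(path):
            if len(f) < 4:
                raise FormatError(
                    f"{path}, line {lineno}: need chrom,start,end,pvalue"
                )
            iv = _interval(path, lineno, f[0], f[1], f[2])
            try:
                pvalue = float(f[3])
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: bad p-value") from exc
            tags = None
            if len(f) > 4 and f[4] not in (".", ""):
                tags = int(f[4])
            try:
                peaks.append(Peak(iv, pvalue=pvalue, tags=tags))
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown peak format {format!r}")
    return peaks


def write_peaks_narrowpeak(peaks: Sequence[Peak], path: PathLike) -> None:
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            neglog10p = -math.log10(p.pvalue) if p.pvalue > 0 else 999.0
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name or f"peak_{i + 1}",
                        "0",
                        p.interval.strand,
                        FLOAT_FMT.format(float(p.tags if p.tags is not None else -1)),
                        FLOAT_FMT.format(neglog10p),
                        "-1",
                        "-1",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: PathLike) -> List[Tuple[GenomicInterval, str, float]]:
    """Read BED3/BED6 records as (interval, name, score) tuples."""
    records = []
    for lineno, f in _lines(path):
        if len(f) < 3:
            raise FormatError(f"{path}, line {lineno}: need >= 3 columns")
        strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
        iv = _interval(path, lineno, f[0], f[1], f[2], strand)
        name = f[3] if len(f) > 3 else ""
        score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
        records.append((iv, name, score))
    return records


def write_bed(
    records: Iterable[Union[GenomicInterval, Tuple[GenomicInterval, str, float]]],
    path: PathLike,
) -> None:
    """Write BED records, sorted by (chrom, start, end). No header."""
    norm = []
    for rec in records:
        if isinstance(rec, GenomicInterval):
            norm.append((rec, "", 0.0))
        else:
            norm.append((rec[0], rec[1], float(rec[2])))
    norm.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for iv, name, score in norm:
            if name == "" and score == 0.0:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t"
                    + FLOAT_FMT.format(score)
                    + f"\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# signal


def read_tag_bed(path: PathLike, library_size: Optional[int] = None) -> SignalTrack:
    """Read one-tag-per-line BED (chrom, pos, pos+1) into a SignalTrack."""
    by_chrom: Dict[str, List[int]] = {}
    for lineno, f in _lines(path):
        if len(f) < 3:
            raise FormatError(f"{path}, line {lineno}: need >= 3 columns")
        iv = _interval(path, lineno, f[0], f[1], f[2])
        by_chrom.setdefault(iv.chrom, []).append(iv.start)
    return SignalTrack.from_tags(
        {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()},
        library_size=library_size,
    )


def write_tag_bed(track_positions: Dict[str, np.ndarray], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track_positions):
            for pos in np.sort(np.asarray(track_positions[chrom])):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def read_bedgraph(path: PathLike, library_size: Optional[int] = None) -> SignalTrack:
    """Read a bedGraph of (interval, count) signal bins."""
    by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    for lineno, f in _lines(path):
        if len(f) < 4:
            raise FormatError(f"{path}, line {lineno}: bedGraph needs 4 columns")
        iv = _interval(path, lineno, f[0], f[1], f[2])
        try:
            value = float(f[3])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: bad value") from exc
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
    bins = {}
    for chrom, rows in by_chrom.items():
        arr = np.array(rows, dtype=float)
        bins[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return SignalTrack.from_bins(bins, library_size=library_size)


# ---------------------------------------------------------------------------
# annotation / expression / LD


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for lineno, f in _lines(path):
        if len(f) < 2:
            raise FormatError(f"{path}, line {lineno}: need chrom<TAB>size")
        try:
            sizes[f[0]] = int(f[1])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: bad size") from exc
    return sizes


GENE_COLUMNS = ["gene_id", "biotype", "chrom", "start", "end", "strand"]


def read_genes(path: PathLike) -> List[GeneAnnotation]:
    """Read the gene annotation TSV (gene_id, biotype, chrom, start, end, strand).

    A header row matching the column names is allowed and skipped.
    """
    genes: List[GeneAnnotation] = []
    for lineno, f in _lines(path):
        if f[:2] == GENE_COLUMNS[:2]:
            continue
        if len(f) < 6:
            raise FormatError(f"{path}, line {lineno}: need 6 columns")
        iv = _interval(path, lineno, f[2], f[3], f[4], f[5])
        try:
            genes.append(GeneAnnotation(f[0], f[1], iv))
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return genes


def write_genes(genes: Sequence[GeneAnnotation], path: PathLike) -> None:
    rows = sorted(genes, key=lambda g: (g.body.chrom, g.body.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in rows:
            fh.write(
                f"{g.gene_id}\t{g.biotype}\t{g.body.chrom}\t{g.body.start}\t"
                f"{g.body.end}\t{g.body.strand}\n"
            )


def read_expression(path: PathLike) -> pd.DataFrame:
    """Read the expression TSV: gene_id index, one column per condition."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df


def write_expression(df: pd.DataFrame, path: PathLike) -> None:
    out = df.sort_index()
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_ld_regions(path: PathLike) -> List[LDRegion]:
    """Read LD-region BED; column 4 is the lead SNP id."""
    regions: List[LDRegion] = []
    for lineno, f in _lines(path):
        if len(f) < 4:
            raise FormatError(f"{path}, line {lineno}: need chrom,start,end,snp_id")
        iv = _interval(path, lineno, f[0], f[1], f[2])
        r2 = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.8
        regions.append(LDRegion(f[3], iv, r2_cutoff=r2))
    return regions


def write_ld_regions(regions: Sequence[LDRegion], path: PathLike) -> None:
    rows = sorted(regions, key=lambda r: (r.region.chrom, r.region.start, r.snp_id))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t{r.snp_id}\t"
                + FLOAT_FMT.format(r.r2_cutoff)
                + "\n"
            )
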