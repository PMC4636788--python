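"""Assignment of genes, non-coding RNAs and eQTL LD regions to enhancers.

The proximity rule: an element is assigned to an enhancer when the element's
genome coordinates overlap the enhancer extended by a flank (default 100 kb)
by at least 1 bp. "Directly transcribed from" an enhancer means the
transcript's TSS lies inside the unextended enhancer region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genomic_core import (
    GeneAnnotation,
    GenomicInterval,
    LDRegion,
    distance,
    extend,
    overlaps,
)
from .report import percent
from .se_caller import EnhancerCall

Element = Union[GeneAnnotation, LDRegion]


def _element_parts(el: Element) -> Tuple[str, str, GenomicInterval]:
    if isinstance(el, GeneAnnotation):
        return el.gene_id, el.biotype, el.body
    return el.snp_id, "eQTL", el.region


def assign_elements(
    enhancers: Sequence[EnhancerCall],
    elements: Sequence[Element],
    flank: int = 100_000,
    anchor: str = "body",
) -> pd.DataFrame:
    """Link elements to enhancers by the flank-extension 1-bp-overlap rule.

    An element is linked to an enhancer iff its body (or, with
    ``anchor="tss"``, its 1-bp TSS interval) overlaps the enhancer extended
    by ``flank`` bp. ``distance`` is the gap between the *unextended*
    enhancer and the element (0 when overlapping); ``relation`` is
    ``direct_overlap`` at distance 0, else ``within_100kb``-style flank
    containment. Links are many-to-many.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if anchor not in ("body", "tss"):
        raise ValueError("anchor must be 'body' or 'tss'")
    rows = []
    prepared = []
    for el in elements:
        el_id, el_class, iv = _element_parts(el)
        if anchor == "tss" and isinstance(el, GeneAnnotation):
            iv = GenomicInterval(iv.chrom, el.tss, el.tss + 1, iv.strand)
        prepared.append((el_id, el_class, iv))
    for enh in enhancers:
        ext = extend(enh.region, flank)
        for el_id, el_class, iv in prepared:
            if overlaps(ext, iv):
                d = distance(enh.region, iv)
                rows.append(
                    (
                        enh.enhancer_id,
                        enh.label,
                        el_id,
                        el_class,
                        int(d),
                        "direct_overlap" if d == 0 and overlaps(enh.region, iv) else "within_flank",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "enhancer_id",
            "enhancer_label",
            "element_id",
            "element_class",
            "distance",
            "relation",
        ],
    )


@dataclass
class TranscriptionFractions:
    """Fractions of SEs/CEs with an internally initiated transcript."""

    se_with_transcript: int
    se_total: int
    ce_with_transcript: int
    ce_total: int
    transcripts_from_se: int
    transcripts_from_ce: int
    n_transcripts: int
    degenerate: bool = False  # True when a denominator was 0

    @property
    def se_fraction(self) -> float:
        return self.se_with_transcript / self.se_total if self.se_total else 0.0

    @property
    def ce_fraction(self) -> float:
        return self.ce_with_transcript / self.ce_total if self.ce_total else 0.0


def transcribed_from(
    enhancers: Sequence[EnhancerCall],
    transcripts: Sequence[GeneAnnotation],
    rule: str = "tss_within",
) -> Tuple[pd.DataFrame, TranscriptionFractions]:
    """Call transcripts directly transcribed from enhancers.

    Default rule: the transcript TSS lies within the unextended enhancer
    region. ``rule="any_overlap"`` instead requires >= 1 bp body overlap.
    Returns a per-enhancer table and the SE/CE summary fractions.
    """
    if rule not in ("tss_within", "any_overlap"):
        raise ValueError("rule must be tss_within|any_overlap")
    per_enh = []
    from_se: set = set()
    from_ce: set = set()
    for enh in enhancers:
        hits = []
        for tr in transcripts:
            if rule == "tss_within":
                hit = (
                    tr.body.chrom == enh.region.chrom
                    and enh.region.start <= tr.tss < enh.region.end
                )
            else:
                hit = overlaps(enh.region, tr.body)
            if hit:
                hits.append(tr.gene_id)
                (from_se if enh.label == "SE" else from_ce).add(tr.gene_id)
        per_enh.append((enh.enhancer_id, enh.label, len(hits), ",".join(sorted(hits))))
    table = pd.DataFrame(
        per_enh, columns=["enhancer_id", "enhancer_label", "n_transcripts", "transcript_ids"]
    )
    se_total = int((table["enhancer_label"] == "SE").sum())
    ce_total = int((table["enhancer_label"] == "CE").sum())
    se_hit = int(((table["enhancer_label"] == "SE") & (table["n_transcripts"] > 0)).sum())
    ce_hit = int(((table["enhancer_label"] == "CE") & (table["n_transcripts"] > 0)).sum())
    fr = TranscriptionFractions(
        se_with_transcript=se_hit,
        se_total=se_total,
        ce_with_transcript=ce_hit,
        ce_total=ce_total,
        transcripts_from_se=len(from_se),
        transcripts_from_ce=len(from_ce),
        n_transcripts=len(transcripts),
        degenerate=(se_total == 0 or ce_total == 0 or len(transcripts) == 0),
    )
    return table, fr


@dataclass
class EQTLOverlap:
    """Per-class counts of enhancers overlapping >= 1 eQTL LD region."""

    se_overlapping: int
    se_total: int
    ce_overlapping: int
    ce_total: int

    @property
    def se_fraction(self) -> float:
        return self.se_overlapping / self.se_total if self.se_total else 0.0

    @property
    def ce_fraction(self) -> float:
        return self.ce_overlapping / self.ce_total if self.ce_total else 0.0

    @property
    def se_pct(self) -> int:
        return percent(self.se_overlapping, self.se_total) if self.se_total else 0

    @property
    def ce_pct(self) -> int:
        return percent(self.ce_overlapping, self.ce_total) if self.ce_total else 0

    def as_dict(self) -> Dict[str, float]:
        return {
            "se_overlapping": self.se_overlapping,
            "se_total": self.se_total,
            "ce_overlapping": self.ce_overlapping,
            "ce_total": self.ce_total,
            "se_fraction": self.se_fraction,
            "ce_fraction": self.ce_fraction,
            "se_pct": self.se_pct,
            "ce_pct": self.ce_pct,
        }


def eqtl_overlap(
    enhancers: Sequence[EnhancerCall],
    ld_regions: Sequence[LDRegion],
) -> EQTLOverlap:
    """Count SEs and CEs overlapping (>= 1 bp) at least one LD region."""
    se_hit = se_tot = ce_hit = ce_tot = 0
    by_chrom: Dict[str, List[LDRegion]] = {}
    for ld in ld_regions:
        by_chrom.setdefault(ld.region.chrom, []).append(ld)
    for enh in enhancers:
        hit = any(
            overlaps(enh.region, ld.region)
            for ld in by_chrom.get(enh.region.chrom, ())
        )
        if enh.label == "SE":
            se_tot += 1
            se_hit += int(hit)
        else:
            ce_tot += 1
            ce_hit += int(hit)
    return EQTLOverlap(se_hit, se_tot, ce_hit, ce_tot)


def nearest_se_distance(
    genes: Sequence[GeneAnnotation],
    se_regions: Sequence[GenomicInterval],
) -> Dict[str, Optional[int]]:
    """Distance from each gene TSS to the nearest SE edge (0 if inside).

    Genes on chromosomes without any SE map to ``None`` and should be
    excluded from downstream comparisons.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for r in se_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: Dict[str, Optional[int]] = {}
    for g in genes:
        ses = by_chrom.get(g.body.chrom)
        if not ses:
            out[g.gene_id] = None
            continue
        point = GenomicInterval(g.body.chrom, g.tss, g.tss + 1)
        out[g.gene_id] = int(min(distance(point, r) for r in ses))
    return out
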