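"""ROSE-style super-enhancer calling.

The procedure: keep peaks passing a significance threshold, drop peaks near
transcription start sites, transitively stitch the survivors into enhancer
regions, score each region by input-subtracted tags-per-million, rank the
regions by density, and split the ranked ("hockey-stick") curve at the
point where a line of slope one is tangent to the min-max-rescaled curve.
Regions with density strictly above the cutoff are super-enhancers (SEs);
the rest are conventional enhancers (CEs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_core import (
    GenomicInterval,
    Peak,
    SignalTrack,
    TSSIndex,
    merge_overlapping,
    overlaps,
)


class EmptyLandscapeError(RuntimeError):
    """All candidate peaks were removed by a filtering stage."""


@dataclass(frozen=True)
class SECallerConfig:
    """Thresholds of the SE-calling procedure.

    pvalue_max
        Keep peaks with calling p-value <= this (default 1e-9).
    stitch_distance
        Merge peaks separated by <= this many bp (default 12,500; the
        boundary is inclusive — a gap of exactly ``stitch_distance`` merges).
    tss_exclusion
        Drop peaks with any base within this many bp of a TSS (default 2,000).
    pseudocount
        Tags-per-million added in fold-change contexts downstream.
    tss_exclusion_stage
        ``pre_stitch`` (default) removes TSS-proximal peaks before stitching;
        ``post_stitch`` stitches first and removes TSS-proximal *regions*.
    """

    pvalue_max: float = 1e-9
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_000
    pseudocount: float = 1.0
    tss_exclusion_stage: str = "pre_stitch"

    def __post_init__(self) -> None:
        if not (0 < self.pvalue_max <= 1):
            raise ValueError("pvalue_max must be in (0, 1]")
        if self.stitch_distance <= 0 or self.tss_exclusion <= 0:
            raise ValueError("distances must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.tss_exclusion_stage not in ("pre_stitch", "post_stitch"):
            raise ValueError("tss_exclusion_stage must be pre_stitch|post_stitch")


@dataclass
class StitchedEnhancer:
    """A stitched enhancer region with its constituent peaks and density."""

    region: GenomicInterval
    constituents: List[Peak] = field(default_factory=list)
    density: Optional[float] = None


@dataclass(frozen=True)
class EnhancerCall:
    """One labeled enhancer in a finished ranking."""

    enhancer_id: str
    region: GenomicInterval
    density: float
    label: str  # "SE" or "CE"


@dataclass
class EnhancerRanking:
    """The ranked density curve with its cutoff and SE/CE labels.

    ``enhancers`` are sorted by ascending density; SEs are the (contiguous)
    suffix with density strictly above ``cutoff_density``.
    """

    enhancers: List[StitchedEnhancer]
    cutoff_rank: int
    cutoff_density: float
    labels: List[str]

    @property
    def n_se(self) -> int:
        return sum(1 for l in self.labels if l == "SE")

    @property
    def n_ce(self) -> int:
        return len(self.labels) - self.n_se

    def se_regions(self) -> List[GenomicInterval]:
        return [e.region for e, l in zip(self.enhancers, self.labels) if l == "SE"]

    def ce_regions(self) -> List[GenomicInterval]:
        return [e.region for e, l in zip(self.enhancers, self.labels) if l == "CE"]

    def to_calls(self) -> List[EnhancerCall]:
        return [
            EnhancerCall(str(e.region), e.region, float(e.density), l)
            for e, l in zip(self.enhancers, self.labels)
        ]

    def rank_curve(self) -> pd.DataFrame:
        """Rank-vs-density table (with min-max rescaled axes) for plotting."""
        dens = np.array([e.density for e in self.enhancers], dtype=float)
        n = len(dens)
        x = np.arange(n) / max(n - 1, 1)
        rng = dens[-1] - dens[0] if n else 0.0
        y = (dens - dens[0]) / rng if rng > 0 else np.zeros(n)
        return pd.DataFrame(
            {
                "rank": np.arange(1, n + 1),
                "chrom": [e.region.chrom for e in self.enhancers],
                "start": [e.region.start for e in self.enhancers],
                "end": [e.region.end for e in self.enhancers],
                "density": dens,
                "x_rescaled": x,
                "y_rescaled": y,
                "is_se": [l == "SE" for l in self.labels],
            }
        )


# ---------------------------------------------------------------------------
# stages


def filter_peaks(peaks: Sequence[Peak], pvalue_max: float) -> List[Peak]:
    """Keep peaks with calling p-value <= ``pvalue_max`` (inclusive)."""
    return [p for p in peaks if p.pvalue <= pvalue_max]


def exclude_tss_proximal(
    peaks: Sequence[Peak],
    tss_list: Iterable[Tuple[str, int]],
    window: int,
) -> List[Peak]:
    """Drop peaks with any base within ``window`` bp of a TSS.

    A peak is removed iff its interval overlaps ``[tss - window,
    tss + window + 1)`` for some TSS. An empty TSS list is the identity.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    index = tss_list if isinstance(tss_list, TSSIndex) else TSSIndex(tss_list)
    if len(index) == 0:
        return list(peaks)
    return [p for p in peaks if not index.any_within(p.interval, window)]


def stitch(peaks: Sequence[Peak], stitch_distance: int) -> List[StitchedEnhancer]:
    """Transitively merge peaks whose gap is <= ``stitch_distance``.

    Per chromosome, peaks sorted by start are merged while the gap between
    the running region end and the next peak start stays within the stitch
    distance (boundary inclusive). Each peak belongs to exactly one output
    region; regions are sorted and pairwise non-overlapping.
    """
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out: List[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        cur = [ps[0]]
        cur_end = ps[0].interval.end
        for p in ps[1:]:
            if p.interval.start - cur_end <= stitch_distance:
                cur.append(p)
                cur_end = max(cur_end, p.interval.end)
            else:
                out.append(_make_region(chrom, cur))
                cur = [p]
                cur_end = p.interval.end
        out.append(_make_region(chrom, cur))
    return out


def _make_region(chrom: str, peaks: List[Peak]) -> StitchedEnhancer:
    start = min(p.interval.start for p in peaks)
    end = max(p.interval.end for p in peaks)
    return StitchedEnhancer(GenomicInterval(chrom, start, end), constituents=peaks)


def compute_density(
    region: GenomicInterval,
    treatment: SignalTrack,
    control: Optional[SignalTrack] = None,
) -> float:
    """Input-subtracted tags-per-million in ``region``, clipped at zero.

    ``max(0, 1e6 * t/T - 1e6 * c/C)`` with t, c the tag counts in the region
    and T, C the library sizes; without a control simply ``1e6 * t/T``.
    """
    t = treatment.count(region)
    dens = 1e6 * t / treatment.library_size
    if control is not None:
        c = control.count(region)
        dens -= 1e6 * c / control.library_size
    return max(0.0, dens)


# ---------------------------------------------------------------------------
# inflection cutoff

_TIE_TOL = 1e-12
# a cutoff is only declared when the curve departs below the unit-slope
# tangent by more than this many rank-steps' worth of rise; a curve that
# hugs or stays above the diagonal has no super-enhancer tail
_MIN_DIP_STEPS = 2.0


def find_inflection_cutoff(densities: Sequence[float]) -> Tuple[int, float]:
    """Locate the SE cutoff on the ascending density curve.

    Rank and density are min-max rescaled to the unit square; the cutoff is
    where a line of slope one, slid up from below, first touches the curve
    (the index minimising ``y - x``; ties, within 1e-12, broken to the
    largest index). Returns ``(cutoff_rank, cutoff_density)`` with the
    density on the original scale. SEs are the entries with density strictly
    above ``cutoff_density``.

    Degenerate curves have no tail and yield zero SEs: all-equal input
    (with a warning), and curves that never dip below the unit-slope
    tangent by more than two rank steps — e.g. a linear ramp, or a bounded
    background with no high-density suffix — return the cutoff at the top.
    """
    d = np.asarray(densities, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 densities")
    if np.any(np.diff(d) < 0):
        raise ValueError("densities must be sorted ascending")
    span = d[-1] - d[0]
    if span == 0:
        warnings.warn("all densities equal; no inflection point, zero SEs")
        return n - 1, float(d[-1])
    x = np.arange(n) / (n - 1)
    y = (d - d[0]) / span
    gap = y - x
    m = gap.min()
    if m >= -_MIN_DIP_STEPS / (n - 1):
        # no elbow below the diagonal: flat, concave or near-linear curve
        return n - 1, float(d[-1])
    cutoff = int(np.nonzero(gap <= m + _TIE_TOL)[0][-1])
    return cutoff, float(d[cutoff])


# ---------------------------------------------------------------------------
# full procedure


def call_superenhancers(
    peaks: Sequence[Peak],
    tss_list: Iterable[Tuple[str, int]],
    treatment: SignalTrack,
    control: Optional[SignalTrack] = None,
    config: SECallerConfig = SECallerConfig(),
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> EnhancerRanking:
    """Run the full SE-calling procedure and return the labeled ranking.

    When ``regions`` is given (e.g. previously reported enhancer sites),
    stitching is skipped and the supplied regions are ranked directly.
    """
    if regions is not None:
        stitched = [StitchedEnhancer(r) for r in regions]
        if not stitched:
            raise EmptyLandscapeError("empty region list supplied")
    else:
        kept = filter_peaks(peaks, config.pvalue_max)
        if not kept:
            raise EmptyLandscapeError("empty after p-value filter")
        index = tss_list if isinstance(tss_list, TSSIndex) else TSSIndex(tss_list)
        if config.tss_exclusion_stage == "pre_stitch":
            kept = exclude_tss_proximal(kept, index, config.tss_exclusion)
            if not kept:
                raise EmptyLandscapeError("empty after TSS exclusion")
            stitched = stitch(kept, config.stitch_distance)
        else:
            stitched = stitch(kept, config.stitch_distance)
            stitched = [
                s
                for s in stitched
                if not index.any_within(s.region, config.tss_exclusion)
            ]
            if not stitched:
                raise EmptyLandscapeError("empty after TSS exclusion")
    for s in stitched:
        s.density = compute_density(s.region, treatment, control)
    # ascending density; coordinate tie-break keeps output deterministic
    stitched.sort(key=lambda s: (s.density, s.region.chrom, s.region.start))
    densities = [s.density for s in stitched]
    if len(stitched) == 1:
        warnings.warn("single enhancer region; no curve, labeling it CE")
        return EnhancerRanking(stitched, 0, densities[0], ["CE"])
    cutoff_rank, cutoff_density = find_inflection_cutoff(densities)
    labels = ["SE" if s.density > cutoff_density else "CE" for s in stitched]
    return EnhancerRanking(stitched, cutoff_rank, cutoff_density, labels)


# ---------------------------------------------------------------------------
# cross-condition comparison


@dataclass
class SEComparison:
    """Shared/unique structure of SE sets from several conditions.

    ``loci`` are the merged union loci (>= 1 bp overlap chains) across all
    conditions; ``membership[i]`` is the tuple of condition names whose SEs
    overlap locus i. Shared fractions use the merged loci as denominator.
    """

    conditions: List[str]
    loci: List[GenomicInterval]
    membership: List[Tuple[str, ...]]
    venn_counts: Dict[Tuple[str, ...], int]
    shared_all_fraction: float
    shared_two_plus_fraction: float
    pairwise_shared: Dict[Tuple[str, str], float]


def compare_se_sets(
    se_sets: Mapping[str, Sequence[GenomicInterval]],
) -> SEComparison:
    """Compare SE sets across >= 2 conditions by 1-bp overlap.

    SE regions from all conditions are merged into union loci; each locus is
    assigned the set of conditions with at least one overlapping SE. Returns
    Venn counts over those membership sets, the fraction of loci present in
    all (and in >= 2) conditions, and for each ordered pair (a, b) the
    fraction of b's merged SE loci that overlap an SE of a.
    """
    names = list(se_sets)
    if len(names) < 2:
        raise ValueError("need >= 2 conditions")
    non_empty = [n for n in names if len(se_sets[n])]
    all_regions = [r for n in non_empty for r in se_sets[n]]
    loci = merge_overlapping(all_regions) if all_regions else []
    membership: List[Tuple[str, ...]] = []
    for locus in loci:
        members = tuple(
            n for n in names if any(overlaps(locus, r) for r in se_sets[n])
        )
        membership.append(members)
    venn: Dict[Tuple[str, ...], int] = {}
    for m in membership:
        venn[m] = venn.get(m, 0) + 1
    n_loci = len(loci)
    shared_all = sum(1 for m in membership if len(m) == len(names))
    shared_two = sum(1 for m in membership if len(m) >= 2)
    pairwise: Dict[Tuple[str, str], float] = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            b_loci = merge_overlapping(se_sets[b]) if len(se_sets[b]) else []
            if not b_loci:
                pairwise[(a, b)] = 0.0
                continue
            hit = sum(
                1
                for locus in b_loci
                if any(overlaps(locus, r) for r in se_sets[a])
            )
            pairwise[(a, b)] = hit / len(b_loci)
    return SEComparison(
        conditions=names,
        loci=loci,
        membership=membership,
        venn_counts=venn,
        shared_all_fraction=shared_all / n_loci if n_loci else 0.0,
        shared_two_plus_fraction=shared_two / n_loci if n_loci else 0.0,
        pairwise_shared=pairwise,
    )


def recovery(
    reference: Sequence[GenomicInterval],
    query: Sequence[GenomicInterval],
) -> Tuple[int, int]:
    """Count reference SEs overlapped (>= 1 bp) by any query SE.

    Returns ``(n_recovered, n_reference)`` — e.g. how many SEs called with
    one mark are recovered by another mark.
    """
    n_hit = sum(1 for r in reference if any(overlaps(r, q) for q in query))
    return n_hit, len(reference)
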