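"""Synthetic enhancer landscapes with a ground-truth manifest.

The generator emulates the statistical structure the analysis assumes:

* a heavy-tailed enhancer-density distribution — a clipped-lognormal bulk of
  background (CE) sites plus a small high-density tail of planted SE
  clusters whose total tag count is ``se_multiplier`` times the bulk mean;
* constituent peaks clustered within the stitching distance;
* shared and condition-unique SEs across conditions, following a
  seven-module plan;
* elevated expression of genes within 100 kb of an active SE;
* eQTL LD blocks planted inside SEs at a higher rate than inside CEs.

Loci are laid out on a slot grid so that distinct loci can never stitch
together and no planted peak falls within the TSS-exclusion window of a
coding gene: every landscape is exactly recoverable by construction when the
planted contrast is large. The bulk distribution is clipped at a ceiling
(``exp(mu + ce_ceiling_sigma * sigma)``) so the background rank curve has a
bounded upper edge — without a ceiling, bulk upper order statistics would
straddle any rank-curve cutoff and exact planted recovery would be
impossible. Identical config + seed gives byte-identical serialized output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as sio
from .genomic_core import (
    GeneAnnotation,
    GenomicInterval,
    LDRegion,
    Peak,
    SignalTrack,
    extend,
    overlaps,
)
from .specificity import module_label

# default seven-module mix across three conditions: ~44 % shared by all
# three, ~31 % pairwise, ~25 % condition-unique
DEFAULT_MODULE_PROBS: Dict[Tuple[int, ...], float] = {
    (0,): 0.084,
    (1,): 0.083,
    (2,): 0.083,
    (0, 1): 0.103,
    (0, 2): 0.103,
    (1, 2): 0.104,
    (0, 1, 2): 0.440,
}


@dataclass
class SimulationConfig:
    """Shape and planted effect sizes of a synthetic landscape."""

    n_chromosomes: int = 3
    chrom_length: int = 20_000_000
    n_coding: int = 400
    n_lncrna: int = 120
    n_mirna: int = 50
    n_ce: int = 1000
    n_se: int = 10
    se_peaks_per_cluster: Tuple[int, int] = (4, 8)
    se_cluster_span: int = 14_000
    ce_mu: float = math.log(50.0)  # bulk tag count, lognormal location
    ce_sigma: float = 0.5
    ce_ceiling_sigma: float = 0.8  # bulk clipped at exp(mu + this * sigma)
    se_multiplier: float = 20.0
    conditions: Tuple[str, ...] = ("A", "B", "C")
    module_probs: Optional[Dict[Tuple[int, ...], float]] = None
    expression_effect: float = 4.0
    eqtl_rate_se: float = 0.6
    eqtl_rate_ce: float = 0.1
    input_library_size: int = 30_000
    n_weak_peaks: int = 40
    n_tss_decoy_peaks: int = 30
    lnc_in_se_rate: float = 0.3
    lnc_in_ce_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.se_multiplier <= 1:
            raise ValueError("se_multiplier must exceed 1")
        for name in ("n_ce", "n_se", "n_coding", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("eqtl_rate_se", "eqtl_rate_ce", "lnc_in_se_rate", "lnc_in_ce_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        lo, hi = self.se_peaks_per_cluster
        if lo < 2 or hi < lo:
            raise ValueError("se_peaks_per_cluster must be a range with lo >= 2")
        # worst-case intra-cluster gap must stay within the stitch distance
        if self.se_cluster_span - lo * 800 > 12_500:
            raise ValueError(
                "se_cluster_span too large: constituent gaps could exceed the stitch distance"
            )
        if self.n_coding < self.n_se:
            raise ValueError("need at least one coding gene per planted SE")

    @property
    def ce_ceiling(self) -> float:
        return math.exp(self.ce_mu + self.ce_ceiling_sigma * self.ce_sigma)

    @property
    def ce_mean(self) -> float:
        return math.exp(self.ce_mu + 0.5 * self.ce_sigma**2)

    @property
    def slot_width(self) -> int:
        # locus occupies <= 2 kb jitter + cluster span; 16 kb of clearance
        # guarantees > 12.5 kb between occupants of adjacent slots
        return self.se_cluster_span + 16_000


@dataclass
class LocusTruth:
    """Ground truth for one planted locus."""

    locus_id: str
    chrom: str
    start: int
    end: int
    kind: str  # "SE" or "CE"
    module: Optional[str]
    members: Tuple[str, ...]
    tags: Dict[str, int]
    companion_genes: Tuple[str, ...]
    has_eqtl: bool
    direction: Optional[str] = None  # induced/repressed/stable for dynamics


@dataclass
class GroundTruthManifest:
    loci: List[LocusTruth]

    def se_loci(self) -> List[LocusTruth]:
        return [l for l in self.loci if l.kind == "SE"]

    def ce_loci(self) -> List[LocusTruth]:
        return [l for l in self.loci if l.kind == "CE"]

    def se_regions(self, member_of: Optional[str] = None) -> List[GenomicInterval]:
        return [
            GenomicInterval(l.chrom, l.start, l.end)
            for l in self.se_loci()
            if member_of is None or member_of in l.members
        ]

    def to_json(self) -> str:
        return json.dumps([asdict(l) for l in self.loci], indent=1, sort_keys=True)


@dataclass
class Landscape:
    """A complete synthetic input set plus its ground truth."""

    config: SimulationConfig
    seed: int
    conditions: Tuple[str, ...]
    peaks: Dict[str, List[Peak]]
    signals: Dict[str, SignalTrack]
    signal_positions: Dict[str, Dict[str, np.ndarray]]
    control: SignalTrack
    control_positions: Dict[str, np.ndarray]
    genes: List[GeneAnnotation]
    expression: pd.DataFrame
    ld_regions: List[LDRegion]
    manifest: GroundTruthManifest

    def coding_tss(self) -> List[Tuple[str, int]]:
        return [(g.body.chrom, g.tss) for g in self.genes if g.biotype == "coding"]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for cond in self.conditions:
            cdir = out / cond
            cdir.mkdir(exist_ok=True)
            sio.write_peaks_narrowpeak(self.peaks[cond], cdir / "peaks.narrowPeak")
            sio.write_tag_bed(self.signal_positions[cond], cdir / "tags.bed")
        sio.write_tag_bed(self.control_positions, out / "input_tags.bed")
        sio.write_genes(self.genes, out / "genes.tsv")
        sio.write_expression(self.expression, out / "expression.tsv")
        sio.write_ld_regions(self.ld_regions, out / "ld.bed")
        (out / "truth.json").write_text(self.manifest.to_json())


# ---------------------------------------------------------------------------
# internals


def _ce_tags(rng: np.random.Generator, cfg: SimulationConfig, size: int) -> np.ndarray:
    draw = rng.lognormal(cfg.ce_mu, cfg.ce_sigma, size)
    return np.maximum(1, np.round(np.minimum(draw, cfg.ce_ceiling))).astype(int)


def _se_total(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return int(round(cfg.se_multiplier * cfg.ce_mean * rng.uniform(0.9, 1.1)))


def _split_tags(
    rng: np.random.Generator, total: int, widths: np.ndarray
) -> np.ndarray:
    probs = widths / widths.sum()
    return rng.multinomial(total, probs)


def _build(
    cfg: SimulationConfig,
    seed: int,
    conditions: Tuple[str, ...],
    se_members: List[FrozenSet[int]],
    directions: Optional[List[str]] = None,
) -> Landscape:
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    slot_w = cfg.slot_width
    slots_per_chrom = cfg.chrom_length // slot_w
    all_slots = [(c, int(k * slot_w)) for c in chroms for k in range(slots_per_chrom)]

    n_free_coding = cfg.n_coding - cfg.n_se
    n_lnc_in_se = min(int(round(cfg.lnc_in_se_rate * cfg.n_se)), cfg.n_lncrna)
    n_lnc_in_ce = min(
        int(round(cfg.lnc_in_ce_rate * cfg.n_ce)), cfg.n_lncrna - n_lnc_in_se
    )
    n_lnc_free = cfg.n_lncrna - n_lnc_in_se - n_lnc_in_ce
    needed = (
        cfg.n_se
        + cfg.n_ce
        + cfg.n_weak_peaks
        + n_free_coding
        + n_lnc_free
        + cfg.n_mirna
    )
    if needed > len(all_slots):
        raise ValueError(
            f"infeasible packing: {needed} loci/genes need slots but the genome "
            f"({cfg.n_chromosomes} x {cfg.chrom_length} bp) provides {len(all_slots)}"
        )
    order = rng.permutation(len(all_slots))[:needed]
    cursor = 0

    def take(n: int) -> List[Tuple[str, int]]:
        nonlocal cursor
        picked = [all_slots[i] for i in order[cursor : cursor + n]]
        cursor += n
        return picked

    se_slots = take(cfg.n_se)
    ce_slots = take(cfg.n_ce)
    weak_slots = take(cfg.n_weak_peaks)
    coding_slots = take(n_free_coding)
    lnc_slots = take(n_lnc_free)
    mir_slots = take(cfg.n_mirna)

    # --- planted loci -----------------------------------------------------
    lo_k, hi_k = cfg.se_peaks_per_cluster
    se_peak_ivs: List[List[GenomicInterval]] = []
    se_regions: List[GenomicInterval] = []
    for chrom, s0 in se_slots:
        off = int(rng.integers(0, 2001))
        k = int(rng.integers(lo_k, hi_k + 1))
        widths = rng.integers(800, 1501, size=k)
        free = cfg.se_cluster_span - int(widths.sum())
        raw = rng.random(k - 1)
        gaps = np.floor(raw / raw.sum() * free * rng.uniform(0.6, 1.0)).astype(int)
        pos = s0 + off
        ivs = []
        for j in range(k):
            ivs.append(GenomicInterval(chrom, pos, pos + int(widths[j])))
            pos += int(widths[j]) + (int(gaps[j]) if j < k - 1 else 0)
        se_peak_ivs.append(ivs)
        se_regions.append(GenomicInterval(chrom, ivs[0].start, ivs[-1].end))

    ce_ivs: List[GenomicInterval] = []
    for chrom, s0 in ce_slots:
        off = int(rng.integers(0, 2001))
        w = int(rng.integers(800, 1501))
        ce_ivs.append(GenomicInterval(chrom, s0 + off, s0 + off + w))

    weak_ivs: List[GenomicInterval] = []
    for chrom, s0 in weak_slots:
        off = int(rng.integers(0, 2001))
        w = int(rng.integers(800, 1501))
        weak_ivs.append(GenomicInterval(chrom, s0 + off, s0 + off + w))

    # --- genes ------------------------------------------------------------
    genes: List[GeneAnnotation] = []
    companion_ids: List[str] = []
    for i, (chrom, s0) in enumerate(se_slots):
        tss = s0 + 20_000 + int(rng.integers(0, 2001))
        L = int(rng.integers(5_000, 15_001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            body = GenomicInterval(chrom, tss, tss + L, "+")
        else:
            body = GenomicInterval(chrom, max(0, tss - L + 1), tss + 1, "-")
        gid = f"gene_se_{i + 1:04d}"
        genes.append(GeneAnnotation(gid, "coding", body))
        companion_ids.append(gid)
    free_coding_ids: List[str] = []
    for i, (chrom, s0) in enumerate(coding_slots):
        start = s0 + 4_000 + int(rng.integers(0, 2001))
        L = int(rng.integers(5_000, 20_001))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{i + 1:04d}"
        genes.append(GeneAnnotation(gid, "coding", GenomicInterval(chrom, start, start + L, strand)))
        free_coding_ids.append(gid)

    lnc_genes: List[GeneAnnotation] = []
    lnc_in_se_idx = sorted(
        rng.permutation(cfg.n_se)[:n_lnc_in_se].tolist()
    ) if cfg.n_se else []
    for j, idx in enumerate(lnc_in_se_idx):
        region = se_regions[idx]
        tss = (region.start + region.end) // 2
        L = int(rng.integers(2_000, 5_001))
        lnc_genes.append(
            GeneAnnotation(
                f"lnc_se_{j + 1:04d}", "lncRNA", GenomicInterval(region.chrom, tss, tss + L, "+")
            )
        )
    lnc_in_ce_idx = sorted(
        rng.permutation(cfg.n_ce)[:n_lnc_in_ce].tolist()
    ) if cfg.n_ce else []
    for j, idx in enumerate(lnc_in_ce_idx):
        iv = ce_ivs[idx]
        tss = (iv.start + iv.end) // 2
        L = int(rng.integers(2_000, 5_001))
        lnc_genes.append(
            GeneAnnotation(
                f"lnc_ce_{j + 1:04d}", "lncRNA", GenomicInterval(iv.chrom, tss, tss + L, "+")
            )
        )
    for i, (chrom, s0) in enumerate(lnc_slots):
        start = s0 + 4_000 + int(rng.integers(0, 2001))
        L = int(rng.integers(2_000, 8_001))
        strand = "+" if rng.random() < 0.5 else "-"
        lnc_genes.append(
            GeneAnnotation(f"lnc_{i + 1:04d}", "lncRNA", GenomicInterval(chrom, start, start + L, strand))
        )
    genes.extend(lnc_genes)
    for i, (chrom, s0) in enumerate(mir_slots):
        start = s0 + 4_000 + int(rng.integers(0, 2001))
        L = int(rng.integers(80, 121))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(f"mir_{i + 1:04d}", "miRNA", GenomicInterval(chrom, start, start + L, strand))
        )

    # TSS-proximal decoy peaks next to free coding genes (removed by the
    # TSS-exclusion stage downstream)
    decoy_ivs: List[GenomicInterval] = []
    n_decoy = min(cfg.n_tss_decoy_peaks, len(free_coding_ids))
    for gid in free_coding_ids[:n_decoy]:
        g = next(g for g in genes if g.gene_id == gid)
        decoy_ivs.append(
            GenomicInterval(g.body.chrom, g.tss + 200, g.tss + 1_200)
        )

    # --- per-condition tags and peaks --------------------------------------
    peaks: Dict[str, List[Peak]] = {c: [] for c in conditions}
    positions: Dict[str, Dict[str, List[np.ndarray]]] = {
        c: {ch: [] for ch in chroms} for c in conditions
    }
    se_tags: List[Dict[str, int]] = [dict() for _ in range(cfg.n_se)]

    def strong_pvalue() -> float:
        return 10.0 ** (-float(rng.uniform(9.0, 15.0)))

    def weak_pvalue() -> float:
        return 10.0 ** (-float(rng.uniform(4.0, 8.0)))

    def place(cond: str, iv: GenomicInterval, count: int) -> None:
        if count > 0:
            positions[cond][iv.chrom].append(
                rng.integers(iv.start, iv.end, size=count)
            )

    for i, ivs in enumerate(se_peak_ivs):
        widths = np.array([iv.length for iv in ivs], dtype=float)
        pvals = [strong_pvalue() for _ in ivs]
        for cond_idx, cond in enumerate(conditions):
            total = (
                _se_total(rng, cfg)
                if cond_idx in se_members[i]
                else int(_ce_tags(rng, cfg, 1)[0])
            )
            se_tags[i][cond] = total
            alloc = _split_tags(rng, total, widths)
            for iv, p, t in zip(ivs, pvals, alloc):
                peaks[cond].append(Peak(iv, pvalue=p, tags=int(t)))
                place(cond, iv, int(t))

    ce_tags_by_cond: Dict[str, np.ndarray] = {}
    ce_pvals = [strong_pvalue() for _ in ce_ivs]
    for cond in conditions:
        tags = _ce_tags(rng, cfg, len(ce_ivs))
        ce_tags_by_cond[cond] = tags
        for iv, p, t in zip(ce_ivs, ce_pvals, tags):
            peaks[cond].append(Peak(iv, pvalue=p, tags=int(t)))
            place(cond, iv, int(t))

    for group, pfun in ((weak_ivs, weak_pvalue), (decoy_ivs, strong_pvalue)):
        pvals = [pfun() for _ in group]
        for cond in conditions:
            tags = _ce_tags(rng, cfg, len(group))
            for iv, p, t in zip(group, pvals, tags):
                peaks[cond].append(Peak(iv, pvalue=p, tags=int(t)))
                place(cond, iv, int(t))

    signal_positions: Dict[str, Dict[str, np.ndarray]] = {}
    signals: Dict[str, SignalTrack] = {}
    for cond in conditions:
        merged = {
            ch: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
            for ch, v in positions[cond].items()
        }
        signal_positions[cond] = merged
        signals[cond] = SignalTrack.from_tags(merged)

    # uniform input background
    chrom_probs = np.full(len(chroms), 1.0 / len(chroms))
    per_chrom = rng.multinomial(cfg.input_library_size, chrom_probs)
    control_positions = {
        ch: np.sort(rng.integers(0, cfg.chrom_length, size=int(n)))
        for ch, n in zip(chroms, per_chrom)
    }
    control = SignalTrack.from_tags(control_positions)

    # --- expression --------------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    base = rng.lognormal(math.log(10.0), 1.0, len(genes))
    silent = rng.random(len(genes)) < 0.10
    expr = pd.DataFrame(
        {cond: base.copy() for cond in conditions}, index=pd.Index(gene_ids, name="gene_id")
    )
    near_se: Dict[str, List[int]] = {g.gene_id: [] for g in genes}
    for i, region in enumerate(se_regions):
        ext = extend(region, 100_000)
        for g in genes:
            if overlaps(ext, g.body):
                near_se[g.gene_id].append(i)
    for gi, g in enumerate(genes):
        hits = near_se[g.gene_id]
        if hits:
            member_conds = set()
            for i in hits:
                member_conds.update(conditions[c] for c in se_members[i])
            for cond in member_conds:
                expr.loc[g.gene_id, cond] *= cfg.expression_effect
        elif silent[gi]:
            expr.loc[g.gene_id, :] = 0.0
    expr = expr.round(6)

    # --- eQTL LD regions ----------------------------------------------------
    ld_regions: List[LDRegion] = []
    se_has_eqtl = rng.random(cfg.n_se) < cfg.eqtl_rate_se
    ce_has_eqtl = rng.random(cfg.n_ce) < cfg.eqtl_rate_ce
    snp_n = 0
    for i, region in enumerate(se_regions):
        if se_has_eqtl[i]:
            snp_n += 1
            w = int(rng.integers(2_000, 6_001))
            mid = (region.start + region.end) // 2
            ld_regions.append(
                LDRegion(f"rs_sim_{snp_n:05d}", GenomicInterval(region.chrom, max(0, mid - w // 2), mid - w // 2 + w))
            )
    for j, iv in enumerate(ce_ivs):
        if ce_has_eqtl[j]:
            snp_n += 1
            w = int(rng.integers(1_500, 4_001))
            mid = (iv.start + iv.end) // 2
            ld_regions.append(
                LDRegion(f"rs_sim_{snp_n:05d}", GenomicInterval(iv.chrom, max(0, mid - w // 2), mid - w // 2 + w))
            )

    # --- manifest -----------------------------------------------------------
    loci: List[LocusTruth] = []
    for i, region in enumerate(se_regions):
        members = tuple(conditions[c] for c in sorted(se_members[i]))
        companions = tuple(
            sorted(g for g, hits in near_se.items() if i in hits)
        )
        loci.append(
            LocusTruth(
                locus_id=f"se_{i + 1:04d}",
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                kind="SE",
                module=module_label(list(members)),
                members=members,
                tags=dict(se_tags[i]),
                companion_genes=companions,
                has_eqtl=bool(se_has_eqtl[i]),
                direction=directions[i] if directions else None,
            )
        )
    for j, iv in enumerate(ce_ivs):
        loci.append(
            LocusTruth(
                locus_id=f"ce_{j + 1:05d}",
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                kind="CE",
                module=None,
                members=tuple(conditions),
                tags={c: int(ce_tags_by_cond[c][j]) for c in conditions},
                companion_genes=(),
                has_eqtl=bool(ce_has_eqtl[j]),
            )
        )
    return Landscape(
        config=cfg,
        seed=seed,
        conditions=conditions,
        peaks=peaks,
        signals=signals,
        signal_positions=signal_positions,
        control=control,
        control_positions=control_positions,
        genes=genes,
        expression=expr,
        ld_regions=ld_regions,
        manifest=GroundTruthManifest(loci),
    )


# ---------------------------------------------------------------------------
# public entry points


def simulate_landscape(
    config: Optional[SimulationConfig] = None, seed: int = 0
) -> Landscape:
    """Generate a multi-condition landscape with planted SEs and truth.

    Condition membership of each planted SE is drawn from the config's
    seven-module plan (default: the realistic mostly-shared mix).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    probs = cfg.module_probs or DEFAULT_MODULE_PROBS
    if len(cfg.conditions) != 3 and cfg.module_probs is None:
        raise ValueError("default module plan requires exactly 3 conditions")
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    choice = rng.choice(len(keys), size=cfg.n_se, p=p)
    members = [frozenset(keys[c]) for c in choice]
    # the membership draw consumes from the same stream as _build; derive a
    # child seed so file-level determinism only depends on (config, seed)
    child_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    return _build(cfg, child_seed, tuple(cfg.conditions), members)


def simulate_state_transition(
    config: Optional[SimulationConfig] = None,
    induced_fraction: float = 0.4,
    repressed_fraction: float = 0.3,
    seed: int = 0,
) -> Landscape:
    """Two-state (rest vs stim) landscape with induced/repressed SE loci.

    A fraction of planted SE loci is active only in the stimulated state
    (induced: resting signal at bulk level, so each induced SE overlaps a
    resting conventional enhancer by construction), a disjoint fraction only
    at rest (repressed), and the remainder in both states (stable).
    """
    cfg = config or SimulationConfig(conditions=("rest", "stim"))
    if not (0 <= induced_fraction <= 1 and 0 <= repressed_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if induced_fraction + repressed_fraction > 1:
        raise ValueError("induced_fraction + repressed_fraction must be <= 1")
    conditions = ("rest", "stim")
    rng = np.random.default_rng(seed)
    n_ind = int(round(induced_fraction * cfg.n_se))
    n_rep = int(round(repressed_fraction * cfg.n_se))
    perm = rng.permutation(cfg.n_se)
    directions = ["stable"] * cfg.n_se
    members: List[FrozenSet[int]] = [frozenset((0, 1))] * cfg.n_se
    for idx in perm[:n_ind]:
        directions[idx] = "induced"
        members[idx] = frozenset((1,))  # stim only
    for idx in perm[n_ind : n_ind + n_rep]:
        directions[idx] = "repressed"
        members[idx] = frozenset((0,))  # rest only
    child_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    return _build(cfg, child_seed, conditions, members, directions=directions)


def simulate_module_values(
    n_entities: int,
    contrast: float = 4.0,
    noise_sigma: float = 0.15,
    names: Tuple[str, str, str] = ("A", "B", "C"),
    module_probs: Optional[Dict[Tuple[int, ...], float]] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Planted three-condition signal values with known module labels.

    Member conditions carry ``contrast`` times the non-member baseline;
    every value gets multiplicative lognormal noise of ``noise_sigma``.
    Returns (values DataFrame, true module labels).
    """
    if contrast <= 1:
        raise ValueError("contrast must exceed 1")
    rng = np.random.default_rng(seed)
    probs = module_probs or DEFAULT_MODULE_PROBS
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    choice = rng.choice(len(keys), size=n_entities, p=p)
    base = rng.lognormal(math.log(10.0), 0.5, n_entities)
    values = np.empty((n_entities, 3))
    labels = []
    for row, c in enumerate(choice):
        members = keys[c]
        noise = rng.lognormal(0.0, noise_sigma, 3)
        for col in range(3):
            level = contrast if col in members else 1.0
            values[row, col] = base[row] * level * noise[col]
        labels.append(module_label([names[m] for m in members]))
    df = pd.DataFrame(values, columns=list(names))
    df.index = [f"entity_{i + 1:05d}" for i in range(n_entities)]
    return df, pd.Series(labels, index=df.index, name="module")
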