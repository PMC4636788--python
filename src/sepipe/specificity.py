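"""Cell-type specificity and cell-state dynamics of enhancer landscapes.

Three-condition specificity: each SE locus (or gene) is placed in ternary
coordinates — its per-condition signal divided by the three-condition sum —
and assigned to one of seven modules (three condition-unique, three
pairwise-shared, one all-shared) by a dominance rule: a condition is a
member when its value reaches ``dominance`` times the maximum value.

Two-state dynamics: SE loci are merged across states, density is recomputed
per state over the merged locus, and loci are ranked by log2 fold change
(with a pseudocount) to pick the most induced and most repressed SEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_core import (
    GeneAnnotation,
    GenomicInterval,
    SignalTrack,
    extend,
    merge_overlapping,
    overlaps,
)
from .se_caller import EnhancerRanking, compute_density

DEFAULT_STABLE_BAND = 0.263  # |log2 FC| below this (~1.2x) counts as stable


# ---------------------------------------------------------------------------
# ternary coordinates and module labels


def ternary_coordinates(values: pd.DataFrame) -> pd.DataFrame:
    """Per-entity fractions of signal across three conditions.

    ``values`` has one row per entity and exactly three condition columns,
    all non-negative. Returns fractional columns summing to 1 per row plus
    a ``defined`` flag; zero-sum entities are flagged undefined (their
    fractions are NaN) and should be excluded from plots.
    """
    if values.shape[1] != 3:
        raise ValueError("need exactly three condition columns")
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("values must be non-negative")
    totals = arr.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = arr / totals[:, None]
    out = pd.DataFrame(fracs, index=values.index, columns=list(values.columns))
    out["defined"] = totals > 0
    out.loc[~out["defined"], values.columns] = np.nan
    return out


def module_label(members: Sequence[str]) -> str:
    """Canonical label for a member set: ``X_only`` or ``X+Y`` / ``X+Y+Z``."""
    if not members:
        raise ValueError("member set must be non-empty")
    if len(members) == 1:
        return f"{members[0]}_only"
    return "+".join(members)


def assign_module(
    values: Sequence[float],
    names: Sequence[str] = ("A", "B", "C"),
    dominance: float = 0.5,
) -> str:
    """Module label for one entity from its three condition values.

    A condition is a member iff its value is >= ``dominance`` times the
    maximum of the three. Singleton member sets give ``X_only`` labels,
    pairs and the full set give joined labels.
    """
    v = np.asarray(values, dtype=float)
    if v.size != 3 or len(names) != 3:
        raise ValueError("need three values and three condition names")
    if (v < 0).any():
        raise ValueError("values must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("zero total signal; module undefined")
    vmax = v.max()
    members = [n for n, x in zip(names, v) if x >= dominance * vmax]
    return module_label(members)


def assign_modules(
    values: pd.DataFrame,
    dominance: float = 0.5,
) -> pd.Series:
    """Vectorised :func:`assign_module` over a 3-column DataFrame."""
    if values.shape[1] != 3:
        raise ValueError("need exactly three condition columns")
    names = list(values.columns)
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("values must be non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("entities with zero total signal; filter them first")
    member = arr >= dominance * arr.max(axis=1, keepdims=True)
    labels = [
        module_label([n for n, m in zip(names, row) if m]) for row in member
    ]
    return pd.Series(labels, index=values.index, name="module")


# ---------------------------------------------------------------------------
# cross-condition locus matching


def match_se_loci(
    rankings: Mapping[str, EnhancerRanking],
    signals: Mapping[str, SignalTrack],
    controls: Optional[Mapping[str, Optional[SignalTrack]]] = None,
    source: str = "se",
) -> pd.DataFrame:
    """Merge SE (or all enhancer) regions across conditions into union loci.

    Regions overlapping by >= 1 bp are chained into a single locus; density
    is then recomputed per condition over the merged interval from that
    condition's signal, so per-condition densities share identical support.
    Returns one row per locus with ``density_<cond>`` columns.
    """
    if len(rankings) < 2:
        raise ValueError("need >= 2 conditions")
    if source not in ("se", "all"):
        raise ValueError("source must be 'se' or 'all'")
    regions: List[GenomicInterval] = []
    for cond, ranking in rankings.items():
        regions.extend(
            ranking.se_regions() if source == "se" else [e.region for e in ranking.enhancers]
        )
    loci = merge_overlapping(regions)
    rows = []
    for locus in loci:
        row: Dict[str, object] = {
            "locus_id": str(locus),
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
        }
        for cond in rankings:
            control = controls.get(cond) if controls else None
            row[f"density_{cond}"] = compute_density(locus, signals[cond], control)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dynamics


def build_dynamic_records(
    loci: pd.DataFrame,
    rest: str,
    stim: str,
    pseudocount: float = 1.0,
    stable_band: float = DEFAULT_STABLE_BAND,
) -> pd.DataFrame:
    """Annotate matched loci with log2 fold change and direction.

    ``log2_fold_change = log2((density_stim + pc) / (density_rest + pc))``;
    the direction is induced/repressed outside the +/- ``stable_band``
    (used for scatter colouring only, not for top-k ranking).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive for finite fold changes")
    df = loci.copy()
    dr = df[f"density_{rest}"].to_numpy(dtype=float)
    ds = df[f"density_{stim}"].to_numpy(dtype=float)
    lfc = np.log2((ds + pseudocount) / (dr + pseudocount))
    df["density_rest"] = dr
    df["density_stim"] = ds
    df["log2_fold_change"] = lfc
    df["direction"] = np.where(
        lfc > stable_band, "induced", np.where(lfc < -stable_band, "repressed", "stable")
    )
    return df


def rank_dynamic_ses(
    records: pd.DataFrame,
    k: int = 25,
    genes: Optional[Sequence[GeneAnnotation]] = None,
    expression: Optional[pd.DataFrame] = None,
    conditions: Tuple[str, str] = ("rest", "stim"),
    flank: int = 100_000,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k most induced and most repressed loci by log2 fold change.

    Ties are broken by (chrom, start) for determinism. When genes (and
    optionally an expression table) are supplied, each locus is annotated
    with the coding genes within ``flank`` bp and their expression fold
    change between the two conditions.
    """
    if k > len(records):
        raise ValueError(f"k={k} exceeds number of loci {len(records)}")
    induced = records.sort_values(
        ["log2_fold_change", "chrom", "start"], ascending=[False, True, True]
    ).head(k)
    repressed = records.sort_values(
        ["log2_fold_change", "chrom", "start"], ascending=[True, True, True]
    ).head(k)

    def annotate(df: pd.DataFrame) -> pd.DataFrame:
        if genes is None:
            return df.reset_index(drop=True)
        names, fcs = [], []
        for _, row in df.iterrows():
            locus = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            ext = extend(locus, flank)
            near = [g for g in genes if g.biotype == "coding" and overlaps(ext, g.body)]
            names.append(",".join(sorted(g.gene_id for g in near)))
            if expression is not None and near:
                vals = []
                for g in near:
                    if g.gene_id in expression.index:
                        r = expression.loc[g.gene_id, conditions[0]]
                        s = expression.loc[g.gene_id, conditions[1]]
                        vals.append((s + 1.0) / (r + 1.0))
                fcs.append(",".join(f"{v:.2f}" for v in vals))
            else:
                fcs.append("")
        out = df.reset_index(drop=True)
        out["nearby_genes"] = names
        out["expression_fold_change"] = fcs
        return out

    return annotate(induced), annotate(repressed)


def seed_enhancer_report(
    induced_loci: Sequence[GenomicInterval],
    resting_enhancers: Sequence[GenomicInterval],
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Classify induced SEs as arising from a resting seed enhancer or de novo.

    An induced SE originates ``from_low_density_enhancer`` iff it overlaps
    (>= 1 bp) at least one enhancer called in the resting state; otherwise
    it is ``de_novo``. Fractions sum to 1 over the induced set.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for r in resting_enhancers:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for locus in induced_loci:
        hit = any(overlaps(locus, r) for r in by_chrom.get(locus.chrom, ()))
        rows.append(
            (str(locus), "from_low_density_enhancer" if hit else "de_novo")
        )
    table = pd.DataFrame(rows, columns=["locus_id", "origin"])
    n = len(table)
    seeded = int((table["origin"] == "from_low_density_enhancer").sum())
    fractions = {
        "from_low_density_enhancer": seeded / n if n else 0.0,
        "de_novo": (n - seeded) / n if n else 0.0,
        "n_induced": float(n),
    }
    return table, fractions
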