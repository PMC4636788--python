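"""Count-derived report arithmetic: integer percentages and Venn summaries.

Percentages are rounded half-up to the integer (54 % style); the raw
fractions are always kept alongside in tabular output.
"""

from __future__ import annotations

import math
from typing import Dict


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half-up (e.g. 28.75 % -> 29 %)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def recovery_summary(n_reference: int, n_recovered: int) -> Dict[str, int]:
    """Summarise how many reference SEs a second mark recovers.

    Returns the recovered percentage and the count of reference-only SEs
    (those the query mark missed).
    """
    if n_recovered > n_reference:
        raise ValueError("recovered count exceeds reference total")
    return {
        "recovered": n_recovered,
        "reference_total": n_reference,
        "recovered_pct": percent(n_recovered, n_reference),
        "reference_only": n_reference - n_recovered,
    }


def sharing_summary(n_shared: int, n_total: int) -> Dict[str, int]:
    """Shared-locus percentage from printed or computed counts."""
    if n_shared > n_total:
        raise ValueError("shared count exceeds total")
    return {
        "shared": n_shared,
        "total": n_total,
        "shared_pct": percent(n_shared, n_total),
    }


def overlap_enrichment_summary(
    se_hit: int, se_total: int, ce_hit: int, ce_total: int
) -> Dict[str, int]:
    """SE-vs-CE overlap percentages from per-class hit counts."""
    return {
        "se_overlapping": se_hit,
        "se_total": se_total,
        "ce_overlapping": ce_hit,
        "ce_total": ce_total,
        "se_pct": percent(se_hit, se_total),
        "ce_pct": percent(ce_hit, ce_total),
    }
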