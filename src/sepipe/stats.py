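"""Statistical tests for enhancer-class comparisons.

Two-sample t-tests (pooled-variance "Student" by default, Welch on request),
Pearson chi-squared on 2x2 overlap tables (no continuity correction by
default), the SE-vs-CE expression comparison on log2(x+1), and per-module
distance enrichment on log10(d+1). Raw p-values are reported; a
Benjamini-Hochberg column is offered for convenience where tables of tests
are emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    df: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "student_pooled",
) -> TestResult:
    """Two-sided two-sample t-test.

    ``student_pooled`` (default) uses the classical pooled-variance
    statistic with df = n1 + n2 - 2; ``welch`` uses unequal variances with
    Welch-Satterthwaite df. Constant samples with zero pooled variance are
    an error (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if variant not in ("student_pooled", "welch"):
        raise ValueError("variant must be student_pooled|welch")
    equal_var = variant == "student_pooled"
    if equal_var and x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            # identical constants: no evidence of difference
            return TestResult(0.0, 1.0, x.size + y.size - 2, x.size, y.size, variant)
        raise ValueError("zero pooled variance; t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        df=df,
        n1=int(x.size),
        n2=int(y.size),
        method=variant,
    )


def chi_squared_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> TestResult:
    """Pearson chi-squared test on the 2x2 table [[a, b], [c, d]], df = 1.

    Continuity (Yates) correction is off by default. A zero row or column
    marginal is an error.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; test undefined")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        df=float(res.dof),
        n1=int(a + b),
        n2=int(c + d),
        method="pearson_chi2" + ("_yates" if correction else ""),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return sps.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def expression_by_enhancer_class(
    expression: pd.DataFrame,
    associations: pd.DataFrame,
    condition: Optional[str] = None,
) -> Tuple[pd.DataFrame, Dict[str, TestResult]]:
    """Compare expression of SE-proximal, CE-only, and all expressed genes.

    Groups: genes linked (within the flank) to >= 1 SE; genes linked to a CE
    but to no SE; all genes with expression > 0. A gene near both an SE and
    a CE counts in the SE group only. Tests are two-sided pooled t-tests on
    log2(expression + 1): SE vs CE-only and SE vs all-expressed.
    """
    if condition is None:
        condition = expression.columns[0]
    expr = expression[condition]
    gene_links = associations[associations["element_class"] == "coding"]
    se_genes = set(gene_links.loc[gene_links["enhancer_label"] == "SE", "element_id"])
    ce_genes = (
        set(gene_links.loc[gene_links["enhancer_label"] == "CE", "element_id"])
        - se_genes
    )
    all_expressed = expr[expr > 0]
    groups = {
        "SE": expr[expr.index.isin(se_genes)],
        "CE_only": expr[expr.index.isin(ce_genes)],
        "all_expressed": all_expressed,
    }
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 genes")
    summary = pd.DataFrame(
        {
            "group": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean": [float(v.mean()) for v in groups.values()],
            "median": [float(v.median()) for v in groups.values()],
            "mean_log2": [float(np.log2(v + 1).mean()) for v in groups.values()],
        }
    )
    tests = {
        "SE_vs_CE": two_sample_t(
            np.log2(groups["SE"] + 1), np.log2(groups["CE_only"] + 1)
        ),
        "SE_vs_all": two_sample_t(
            np.log2(groups["SE"] + 1), np.log2(groups["all_expressed"] + 1)
        ),
    }
    return summary, tests


def module_distance_enrichment(
    gene_distances: Mapping[str, Mapping[str, Optional[float]]],
    gene_modules: Mapping[str, str],
    conditions: Sequence[str] = ("A", "B", "C"),
) -> Dict[str, TestResult]:
    """Are module-X genes closer to X-unique SEs than other genes?

    ``gene_distances[cond][gene]`` is the distance from the gene TSS to the
    nearest ``cond``-unique SE (``None`` when undefined). For each
    condition, genes labeled ``<cond>_only`` are compared with all other
    genes by a pooled t-test on log10(distance + 1). Conditions whose
    module is empty are skipped with a warning.
    """
    results: Dict[str, TestResult] = {}
    for cond in conditions:
        dist = gene_distances[cond]
        label = f"{cond}_only"
        in_mod, out_mod = [], []
        for gene, d in dist.items():
            if d is None or gene not in gene_modules:
                continue
            (in_mod if gene_modules[gene] == label else out_mod).append(
                np.log10(d + 1.0)
            )
        if len(in_mod) < 2 or len(out_mod) < 2:
            warnings.warn(f"module {label} empty or too small; skipped")
            continue
        results[cond] = two_sample_t(in_mod, out_mod)
    return results
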