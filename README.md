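# sepipe

Super-enhancer (SE) analysis for ChIP-seq enhancer landscapes: calling,
element association, cell-type-specificity modules, cell-state dynamics,
and the matching statistics — plus a synthetic-data generator with ground
truth so every stage can be exercised and validated without external data.

## The problem

Transcriptional co-activators (P300/CBP, Med1, Brd4) and the H3K27ac mark
concentrate at a small subset of enhancer clusters — super-enhancers — that
sit near cell-identity genes, are enriched for disease-associated
non-coding variation, and are remodelled during differentiation and
activation (e.g. T helper lineage commitment, TLR4 stimulation of
macrophages). `sepipe` implements the ROSE-style identification procedure
and the downstream comparative analyses around it.

## The method

Starting from peak calls and genome-placed tag signal:

1. **Filter** — keep peaks with calling p-value ≤ 1e-9.
2. **TSS exclusion** — drop peaks with any base within 2,000 bp of a
   transcription start site.
3. **Stitch** — transitively merge peaks within 12,500 bp of each other
   into enhancer regions.
4. **Density** — score each region by input-subtracted tags per million:
   `max(0, 10⁶·t/T − 10⁶·c/C)` for treatment and control counts t, c and
   library sizes T, C.
5. **Rank & cut** — sort regions by density, min–max rescale rank (x) and
   density (y) to the unit square, and slide a line of slope 1 up from
   below until it touches the curve (the index minimising y − x). Regions
   with density strictly above the touch point are super-enhancers; the
   rest are conventional enhancers (CEs).

Downstream: genes/lncRNAs/miRNAs and eQTL linkage-disequilibrium regions
are assigned to enhancers when they overlap the enhancer extended by
100 kb by ≥ 1 bp; SE loci and expressed genes are placed in ternary
coordinates across three conditions and assigned to seven specificity
modules by a dominance rule; resting-vs-stimulated landscapes are compared
on merged loci by log2 density fold change to rank induced and repressed
SEs; and group comparisons use Student t-tests (expression on log2(x+1),
distances on log10(d+1)) and Pearson chi-squared tests on overlap counts.

## Worked example

Generate a three-condition landscape (10 planted SE clusters among 1,000
background enhancers on a 3 × 20 Mb genome), call SEs in condition A, and
run the association and expression analyses:

```python
from sepipe import (SimulationConfig, simulate_landscape, TSSIndex,
                    call_superenhancers, assign_elements, eqtl_overlap,
                    expression_by_enhancer_class)

land = simulate_landscape(SimulationConfig(), seed=7)
tss = TSSIndex(land.coding_tss())
ranking = call_superenhancers(land.peaks["A"], tss, land.signals["A"], land.control)
print(f"{ranking.n_se} super-enhancers among {len(ranking.enhancers)} enhancers "
      f"(cutoff density {ranking.cutoff_density:.1f} TPM)")

calls = ranking.to_calls()
genes = [g for g in land.genes if g.biotype == "coding"]
links = assign_elements(calls, genes, flank=100_000)
summary, tests = expression_by_enhancer_class(land.expression, links, condition="A")
print(summary.to_string(index=False))
res = tests["SE_vs_CE"]
print(f"SE vs CE expression: t = {res.statistic:.2f}, p = {res.pvalue:.3g}")
ov = eqtl_overlap(calls, land.ld_regions)
print(f"eQTL LD overlap: {ov.se_overlapping}/{ov.se_total} SEs ({ov.se_pct} %) "
      f"vs {ov.ce_overlapping}/{ov.ce_total} CEs ({ov.ce_pct} %)")
```

Output:

```
5 super-enhancers among 1010 enhancers (cutoff density 1247.3 TPM)
        group   n      mean    median  mean_log2
           SE   6 31.912035 23.974006   4.716083
      CE_only 393 15.360620  8.124042   3.107381
all_expressed 506 17.219709 10.132158   3.547084
SE vs CE expression: t = 2.30, p = 0.0217
eQTL LD overlap: 3/5 SEs (60 %) vs 108/1005 CEs (11 %)
```

Five SEs are called in condition A because, under the default mostly-shared
module plan, only the planted clusters active in A rise above the rank-curve
cutoff — and those five are exactly the planted condition-A clusters. Genes
within 100 kb of an SE are expressed above CE-proximal genes (the generator
plants a 4× effect), and eQTL LD blocks overlap SEs far more often than CEs
(planted 60 % vs 10 % rates).

The same pipeline is available from the shell:

```bash
sepipe simulate --seed 7 -o simdir
sepipe call-se --peaks simdir/A/peaks.narrowPeak --signal simdir/A/tags.bed \
       --control simdir/input_tags.bed --tss simdir/genes.tsv -o se_A
sepipe associate --enhancers se_A/enhancers.bed --se se_A/superenhancers.bed \
       --genes simdir/genes.tsv --eqtl simdir/ld.bed -o assoc_A
```

## Layout

- `sepipe.genomic_core`, `sepipe.io` — coordinate types, interval
  arithmetic, readers/writers (BED, narrowPeak, bedGraph, tag BED, TSVs).
- `sepipe.se_caller` — the calling procedure and cross-condition SE
  comparison.
- `sepipe.association` — gene/ncRNA/eQTL assignment, transcribed-from
  calls, nearest-SE distances.
- `sepipe.specificity` — ternary coordinates, module assignment, SE-locus
  matching, dynamics ranking, seed-enhancer classification.
- `sepipe.stats` — t-tests, chi-squared, expression-by-class and
  module-distance comparisons, BH adjustment.
- `sepipe.synthetic_data` — landscape/state-transition/module-value
  generators with ground-truth manifests.
- `docs/methods.md` — model assumptions, parameter defaults, and design
  notes.
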