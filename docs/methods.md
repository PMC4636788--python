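# Methods

## Coordinates and conventions

All coordinates are 0-based half-open (BED). Book-ended intervals do not
overlap — assignment and sharing rules require at least one shared base —
but have gap 0. The TSS of a −strand gene is `body.end − 1`. Chromosome
names match as exact strings. GTF-style 1-based inputs must be converted
at the reader boundary; all bundled readers consume 0-based formats.

## Super-enhancer calling

The caller composes five stages (`se_caller.call_superenhancers`):
p-value filter (≤ 1e-9, inclusive) → TSS exclusion (any peak base within
2,000 bp of a TSS; applied before stitching by default, after it with
`tss_exclusion_stage="post_stitch"`) → stitching (transitive merge at gap
≤ 12,500 bp, boundary inclusive) → input-subtracted density → rank-curve
cutoff. A `regions` argument ranks user-supplied regions (e.g. previously
published enhancer sites) instead of stitching.

**Density.** The total input-subtracted tags-per-million in the region,
`max(0, 10⁶·t/T − 10⁶·c/C)`, not a per-bp rate: ranking follows the
normalized read count of the region. Negative background-subtracted values
are clipped to zero so the min–max rescaling below is well defined.
Bin-mode signal (bedGraph) contributes fractional counts by bin overlap.

**Cutoff.** On the ascending density curve, rank and density are min–max
rescaled to the unit square and the cutoff is the unit-slope tangency from
below: the index minimising `y − x`, ties (within 1e-12) broken to the
largest index. SEs are the entries with density strictly above the cutoff
density, so ties at the cutoff are CEs. Two degenerate families yield zero
SEs: all-equal densities (warned), and curves that never dip below the
unit-slope tangent by more than two rank-steps' rise (`min(y − x) ≥
−2/(n−1)`). The guard matters in practice: integer tag counts produce
exact ties among the lowest densities, a one-step flat start puts the
curve marginally below the diagonal, and without the guard the tangent
would touch at the bottom and label essentially everything an SE on a
background-only landscape. A linear ramp (slope ≡ 1) likewise has no
tail. The implementation is checked against an exhaustive tangent-line
scan (every candidate line tested against every point) with exact index
agreement on random curves.

We use the tangency form rather than a local finite-difference slope scan
because the two disagree on non-convex curves, and only the tangency
cleanly separates a planted high-density tail from a bounded background:
a central-difference rule always spends its last in-bounds index one step
below the background/tail junction and mislabels the top background site.

**Cross-condition comparison.** SE regions from all conditions are merged
into union loci (≥ 1 bp overlap chains); a locus is "shared" by the
conditions whose SEs overlap it. Venn counts and shared fractions use the
merged loci as denominator. Directional recovery (how many of one mark's
SEs another mark finds) counts reference SEs overlapped by ≥ 1 query SE.

## Element association

An element (gene body, lncRNA, miRNA, or eQTL LD region) is assigned to an
enhancer when it overlaps the enhancer extended by 100 kb by ≥ 1 bp; the
element's full body is used (a `anchor="tss"` switch restricts to the TSS).
Distances are gaps to the unextended enhancer. "Directly transcribed from"
an enhancer means the transcript's TSS lies inside the unextended region
(default; `any_overlap` is available because body-overlap is a defensible
alternative reading). eQTL overlap reports per-class hit counts, raw
fractions, and integer percentages rounded half-up (54 % style).

## Specificity modules and dynamics

**Ternary coordinates** divide each entity's per-condition signal by its
three-condition sum; zero-sum entities are flagged undefined. **Module
assignment** uses a dominance rule: a condition is a member when its value
is ≥ `dominance` (default 0.5) × the maximum of the three, giving exactly
seven classes (three unique, three pairwise, one shared). This rule is a
documented reconstruction — it is simple, scale-invariant, and equivariant
under condition permutation — not a published definition.

**Dynamics.** SE regions from the two states are merged into union loci
and density is recomputed per state over the merged interval, so fold
changes compare identical genomic support. `log2 FC = log2((d_stim + pc) /
(d_rest + pc))` with pseudocount 1 TPM keeps fold changes finite for
de-novo SEs. Top-k induced/repressed loci are ranked by fold change with
(chrom, start) tie-breaks; a ±0.263 (≈1.2×) band colours "stable" loci in
scatter output but does not affect the ranking. Induced SEs overlapping
any resting enhancer call are classed as arising from a low-density "seed"
enhancer, otherwise de novo.

## Statistics

"Student" t-tests are pooled-variance two-sided (Welch by flag); expression
is compared on log2(x+1) and distances on log10(d+1), both documented
reconstructions since the measurement scale is rarely stated alongside the
test. Chi-squared on 2×2 overlap tables is Pearson without continuity
correction (toggleable). Genes near both an SE and a CE count in the SE
group only. Raw p-values are reported; Benjamini–Hochberg q-values are
emitted as a clearly-labelled convenience column. Computations go through
scipy (`ttest_ind`, `chi2_contingency`, `false_discovery_control`); the
test suite verifies them against closed-form and permutation oracles.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, on
a slot grid that makes recovery properties hold by construction: loci are
placed in 30-kb slots (slot width = cluster span + 16 kb) so distinct loci
can never stitch together, and coding TSSs are placed ≥ 4 kb from planted
peaks so TSS exclusion never removes planted signal. Decoy peaks exercise
the filters: weak-p-value peaks (p ~ 1e-4..1e-8) and TSS-proximal peaks
near free coding genes.

**Background (CE) density**: one peak per locus with tag count drawn from
lognormal(μ = log 50, σ = 0.5) clipped at a ceiling `exp(μ + 0.8σ)` and
floored at 1. The ceiling is the generator's definition of the bounded
background the cutoff needs: it was set so the clipped bulk's rescaled
quantile curve lies on/above the unit diagonal (analytically true for
ceiling exponents ≤ 1.0σ at σ = 0.5; 0.8σ leaves margin for sampling and
input-subtraction noise), which makes a background-only landscape yield
zero SEs. Real ChIP backgrounds are not hard-bounded; passing tests on
this generator therefore demonstrate correctness of the procedure, not
SE-calling specificity on unbounded real-data tails.

**Planted SEs**: 4–8 constituent peaks within a 14-kb span (intra-cluster
gaps are ≤ 10.8 kb by construction, under the 12.5-kb stitch distance);
the cluster's total tag count in a member condition is `se_multiplier`
(default 20) × the unclipped bulk mean × U(0.9, 1.1), split across peaks
by width-weighted multinomial; non-member conditions receive one bulk-level
draw split the same way, so a condition-inactive SE locus appears as a
conventional enhancer there — and every induced SE in a state transition
overlaps a resting CE by construction. Membership follows a seven-module
plan (default mix: 44 % all-shared, ~31 % pairwise, ~25 % unique).

**Signal** is emitted as one-tag-per-line BED positions (uniform within
peaks) so density computation exercises real counting; the input control
is uniform background (30k tags). **Expression**: lognormal(log 10, 1)
baseline, 10 % silent genes, ×4 (`expression_effect`) for genes within
100 kb of an SE in its member conditions; each SE slot carries a companion
coding gene ~20 kb away so association is never degenerate. **eQTL LD
blocks** (2–6 kb) are planted in 60 % of SEs and 10 % of CEs (1.5–4 kb),
centred inside the locus so they cannot touch a neighbouring slot.
**lncRNAs**: 30 % of SEs (and 2 % of CEs) carry an internal lncRNA TSS;
TSS exclusion uses coding TSSs only, so enhancer-internal non-coding
transcripts do not erase their own enhancer.

`simulate_module_values` plants seven-module ternary entities with a 4×
member contrast and lognormal noise σ = 0.15 (CV ~15 %, a realistic
density-measurement spread under which a 4× contrast is resolvable by the
dominance rule: the member/maximum ratio falls below 0.5 with probability
Φ(−0.69/(σ√2)) ≈ 6e-4 per pair).

Determinism: identical config + seed gives byte-identical serialized
trees (sorted records, fixed 6-decimal float format, sorted JSON keys).

## Problem sizes

Validation runs use desk-scale genomes chosen as the package's own study
conditions: 3 × 20 Mb chromosomes, 1,000 background sites, 10 planted SE
clusters (20 seeds); dynamics on 20 SE loci at 10× contrast (20 seeds);
module recovery on 2,000 entities; eQTL enrichment on 200 SEs / 2,000 CEs
(3 × 40 Mb genome, all-shared plan so per-condition calls coincide with
the classes the rates were planted on); calibration on 5,000 null
replicates (t on two N(0,1) samples of 30; chi-squared on Binomial(300,
0.4) margins, whose exact Pearson size is ≈ 0.0502).

## Known limitations

- The rank-curve cutoff is a global geometric rule; on curves with several
  comparable elbows the chosen tangency point can jump between them under
  small perturbations (inherent to the method, not the implementation).
- The seven-module dominance rule and the statistical-test scales are
  reconstructions of under-specified conventions; both are configurable
  and recorded in output metadata.
- The generator does not model fragment-length smearing, GC bias,
  copy-number variation, or unbounded background tails; recovery results
  quantify procedure correctness under the stated planted conditions.
- Tag-position signal assumes single-base tag placement; extended-fragment
  pileups should be reduced to positions (or bedGraph bins) upstream.
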