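# Methods

## The statistical model

The design is three unreplicated DGE libraries — V1 and V2 sampled at the
vegetative stage from a single- and a double-flowering sub-group, F2 at the
flowering stage from the double-flowering sub-group — compared pairwise
(V1F2, V1V2, V2F2). With one library per condition there is no estimate of
biological dispersion, so differential expression is judged under the
Poisson sampling model of tag counting: given x tags for a gene in a
library of N₁ total mapped tags, the count y in a second library of N₂
tags follows the conditional law

    P(y | x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1+N₂/N₁)^(x+y+1) ),

equivalently a negative binomial with r = x+1 and success probability
N₁/(N₁+N₂). This is an exact test of proportions, not a replicate-aware
model; its calls mean "incompatible with equal relative abundance given
Poisson counting noise" and will overstate certainty in the presence of
real biological variation. That limitation is inherent to the design being
reproduced and is deliberately not patched with a dispersion term.

### p-values and numerics

The two-sided p-value is the doubled smaller tail, capped at 1:
p = min(1, 2·min(P(Y≤y), P(Y≥y))). The smaller tail is summed directly in
log space (log-gamma terms, log-sum-exp accumulation), so x+y up to 10⁶
neither overflows nor loses the tiny tails to cancellation; the larger
tail comes from the complement plus the point mass, where cancellation is
harmless. Infinite upper tails are extended in blocks of 512 terms and
truncated once the running term has fallen 60 nats below the largest term
seen *and* the terms are decreasing (i.e. past the mode); beyond the mode
the terms decay at least geometrically, so the discarded mass is below
~1e-20 of the tail. Agreement with a plain-arithmetic enumeration oracle
is at the 1e-13 level over all x, y ≤ 30 and size ratios 0.5–2.

Two conventions worth making explicit:

- The p-value conditions on whichever count is labelled x. The two
  orientations of a comparison are therefore not bit-identical for small
  or strongly size-imbalanced counts (the conditional pmfs differ by a
  factor N₁/N₂), though they agree in magnitude for informative counts.
  The pipeline always conditions on the reference library of a comparison.
- The log2 ratio is computed on pseudocounted (pc = 1 tag),
  library-size-normalized counts: log2(((y+1)/N₂)/((x+1)/N₁)). This keeps
  zero-count genes finite and leaves genuine ≥2-fold changes above the
  screen threshold. Raw-count and RPKM-based ratios differ only by the
  pseudocount and a constant per-gene length factor respectively.

Significance requires both FDR ≤ 0.001 (Benjamini–Hochberg step-up across
all genes tested in the comparison; genes with zero tags in both libraries
are removed first, since they carry no information and would only dilate
the BH denominator) and |log2 ratio| ≥ 1. Both thresholds are parameters
(`ScreenThresholds`).

## Set logic

A gene is "in" a comparison set if called DE in either direction. The
flowering-exclusive set defaults to `(V1F2 & V2F2) - V1V2`: DE against the
flowering-stage material from both vegetative baselines, but not DE
between the vegetative samples themselves. The published figure this
mirrors never states its formula, so the expression is a configurable
string over the three labels (grammar: `&` intersection, `-` difference,
`|` union, parentheses; `|` binds loosest) rather than a hard-coded rule.

## Enrichment

Exact hypergeometric upper tails per term, corrected per namespace (BH by
default, Bonferroni available), enriched ⇔ q ≤ α = 0.05. The population
defaults to genes with at least one mapped tag across the libraries — the
expressed background — rather than the whole genome; a genome background
can be supplied explicitly. Terms with zero study hits are still tested
(k = 0, p = 1) so corrected values do not depend on the study set through
the test count. Term maps are flat tables; no GO-DAG propagation is
performed, matching the upstream analysis convention. The three-category
GO breakdown counts (gene, term) assignments, not distinct genes, and
reports one-decimal percentages of total assignments.

## miRNA–mRNA integration

An antagonistic pair is a DE miRNA and a predicted target whose DE
direction is opposite in the same comparison (V1F2 in the pipeline).
Target prediction is an input, not a computation. Grouping preserves the
target map's entry order and duplicates; marginal counts count target
*entries* (with duplicates), the only convention under which the packaged
pair table's own 27/66 split is internally consistent. The DEG input may
contain a gene listed under both directions — this occurs in merged
published tables — and is tolerated with a logged warning rather than
rejected, the pair logic then honouring either direction. The
flowering filter is an annotation flag supplied with the gene table, not
an ontology query, because the upstream retrieval criterion is unstated.

## qPCR arithmetic

Standard curves regress mean CT on log10(input amount) (least squares);
efficiency = 10^(−1/slope) − 1, undefined (error) for a flat series. ΔΔCT
folds use base 2 regardless of measured efficiency, with an
efficiency-corrected variant (base 1+E) available; technical replicates
are averaged on the CT scale before differencing. Concordance between
qPCR and sequencing log2 folds is plain Pearson correlation, with zero
variance reported as an error rather than NaN.

## The synthetic-data generator

The generator emulates the real study's scale: three libraries whose sizes
default to the published total mapped reads (~5.8–6.0 × 10⁶ tags) over
27 000 genes. Choices and what they mean:

- **Counts**: independent Poisson draws per gene × library — the exact
  test's own sampling model. No biological replicates exist in the design,
  so no extra-Poisson dispersion is simulated; recovery results therefore
  show correctness of the chain under its stated model, not robustness to
  overdispersed real tissue.
- **Baseline rates**: log-normal in log10 (mean −4.5, sd 1.0), normalized
  so profiled genes absorb 75% of a library's tags (the rest standing for
  multi-mapping and unassigned tags). This gives a realistic dynamic range
  in which a sizeable minority of genes sit below the exact test's
  detection limit at these depths, as in real DGE libraries.
- **Planted DE**: disjoint random gene subsets per comparison
  (defaults 5% / 10% / 5% for V1F2 / V1V2 / V2F2, in the range of the
  published per-comparison DE fractions), each gene's rate multiplied by
  2^(±f), f uniform in [1.5, 3], in the *test* library of its comparison.
  A fold planted in F2 genuinely perturbs both stage comparisons, and the
  recorded truth is computed from the true rate ratios, so cross-comparison
  effects are represented honestly. The top 5% of genes by baseline rate
  are never planted: very high-abundance transcripts are left unperturbed
  (this also keeps expected library totals within the library size).
- **miRNA tables**: 44 miRNAs (17 up-regulated, 38 previously known —
  the published composition), 1–8 targets each, 60% of targets sign-opposed
  (true pairs) and the rest same-direction or null decoys; 30% of genes
  flowering-annotated. These last two fractions are unstated upstream and
  were fixed once at values that exercise both branches of the pair and
  flowering filters.
- **Determinism**: every routine derives its generator from the config
  seed through named seed sequences, so identical configs give
  bit-identical outputs.

## Evaluation conventions and problem sizes

Calibration and recovery runs (shared by the test suite and
`scripts/acceptance.py`) use deliberately desk-sized studies:

- Null calibration: 2000 genes × 3 libraries of 10⁶ tags, nothing planted,
  10 seeds; the fraction of DE calls is compared with the nominal FDR of
  10⁻³.
- Recovery: 1000 genes × 10⁶ tags, 10% planted DE per comparison, folds in
  [1.5, 3], 10 seeds. Recall is reported both over all planted genes and
  over the *adequately expressed* stratum — expected reference count ≥ 30,
  the depth at which a 2.8-fold change is detectable at FDR 10⁻³ with
  single libraries. Genes below that limit are undetectable by any method
  at these depths; overall recall (~0.7 under these conditions) quantifies
  that censoring rather than a defect of the screen. The
  flowering-exclusive set is scored by Jaccard similarity against the
  planted truth over the same stratum.
- Pair recovery: 30 miRNAs × 5 targets, 60% opposed, scored against the
  planted pair truth with the screen's power factored out (the DE input is
  the exact truth), isolating the join logic.
- Concordance: 25 gene pairs, 100 seeds, noise calibrated so the
  population correlation is 0.90.

The demo (`make_demo`) scales further down (2000 genes, 5 × 10⁵ tags) so
documentation examples run in seconds.

## Known limitations

- Poisson-only noise: calls on real replicated tissue would need a
  negative-binomial framework; this package reproduces a single-library
  design faithfully instead.
- The flowering-exclusive formula and several upstream conventions
  (correction method, log-ratio definition, flowering retrieval) are not
  stated by the analysis being reproduced; defaults are documented choices
  and all are configurable.
- Term maps, target maps and annotations are trusted inputs; no retrieval,
  propagation or prediction is performed.
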