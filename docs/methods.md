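# Methods

`teescape` implements the downstream statistical pipeline used to link
transposable-element (TE) derepression to the downregulation of nearby
(immune) genes. It consumes differential-expression (DE) summary tables —
DESeq2-style rows for canonical genes and for TE subfamilies quantified at
the RepeatMasker name:family:class level — together with TE locus
annotation, gene models, Hi-C contact pairs and GMT gene sets. Count-level
quantification and model fitting (alignment, TE-aware counting, DESeq2) are
upstream of this package and are not re-implemented.

## Coordinate and identity conventions

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based, closed) is converted at the I/O boundary in both directions, so
interval joins never mix conventions. TE subfamilies are identified by the
colon-separated name:family:class triplet (the TEtranscripts convention); the
delimiter is configurable for other quantifiers. DE rows with a missing
p-value (DESeq2 independent filtering) are dropped on read and counted in the
log: every downstream stage ranks or thresholds on p, so such rows can enter
no stage.

## DETE/DEG calling and attribution

Significance defaults to unadjusted P < 0.05 (the descriptive DEG/DETE sets);
the Hi-C-facing DETE set instead recomputes Benjamini–Hochberg over the
table's TE rows and keeps adjusted p < 0.1 (a flag switches to joint
correction over genes + TEs). Rows with log2FC = 0 are counted but excluded
from up/down labels.

TE classes collapse to LTR / non-LTR / DNA / other, with LINE and SINE
aggregated as non-LTR and everything else (Satellite, Simple_repeat, RC,
Unknown, ...) as other. Class shares are reported both over the three
canonical classes (default, 'other' excluded from the denominator) and over
all four buckets, since either reading of published percentages is possible.

The class-composition shift between conditions is a Pearson chi-square
goodness-of-fit test of the observed DETE class counts against expected
proportions taken from the reference condition's own breakdown (the WT-like
condition by default). Cells with expected count < 1 are pooled into
'other'. The reference proportions are treated as fixed, which mildly
understates the variance when the reference set is small; this matches the
usual goodness-of-fit usage.

Genomic-feature attribution assigns each *unique* DETE locus (identical
intervals de-duplicated) exactly one label with precedence
promoter > exon > intron > distal_enhancer > intergenic. Promoters are
[TSS − w, TSS + w) with w = 1,000 bp by default (a common convention; no
single standard exists, so w is a config field). Exon models are optional:
without them, any non-promoter gene-body overlap counts as intron. Enhancers
are a user-supplied BED; no specific enhancer atlas is assumed.

## Rank–rank hypergeometric overlap (RRHO)

Features are ranked by −log10(p) · sign(log2FC), strongest upregulation
first; TE rows are excluded by default so the comparison covers canonical
genes. Ties break lexicographically by feature id, and p is floored at
1e−300, so maps are finite and platform-independent. For every pair of rank
thresholds on a step grid (default step ⌊N/100⌋, about a 100 × 100 grid),
the overlap k of the two top-lists is scored by the exact hypergeometric
tail — upper when k exceeds its expectation ij/N, lower otherwise — and the
map stores signed −log10(p).

The map's lower-left corner (small thresholds on both axes) captures
coupregulation and the upper-right codownregulation; by the tail identity
P[bottom-overlap ≥ i − k] = P[top-overlap ≤ k], anti-regulation appears as
*depletion* in the mixed quadrants. The summary's concordance score is
therefore mean(signed values over the concordant quadrants) minus
mean(negated values over the discordant quadrants); identical rankings
maximize it, independent rankings give ≈ 0, and reversed rankings make it
negative. No numeric RRHO statistic beyond this ordering is claimed: the
score is used to order pairwise condition comparisons. A map-wide Bonferroni
bar (−log10(α / #cells)) is reported for single-cell significance.

## Gene-set enrichment

**ORA** is the upper-tail hypergeometric test: population = all features with
a tested p-value in the relevant DE table (no external reference set is
assumed), successes = category ∩ universe, draws = query.

**GSEA** operates on the signed ranking. The running sum increments at set
members proportionally to |score|^w (w = 1 by default) and decrements
uniformly at non-members; ES is the signed maximal deviation. Because the
pipeline consumes DE summary tables rather than per-sample expression, the
permutation null resamples gene labels into random same-size member sets
(1,000 by default, seeded) — phenotype permutation is impossible at this
layer. The empirical p is the sign-matched null fraction with the +1
correction, NES divides ES by the mean |null ES| of matching sign, and FDR
is Benjamini–Hochberg over the reported terms (a deliberate, documented
simplification of the original NES-bucketed GSEA FDR). Category sizes are
capped to [5, 300] after intersection with the ranked universe, and the
significance cutoff is a config field (default FDR < 0.01; 0.05 is also
reported by the pipeline since both conventions are in circulation).
Under a fully null generator the empirical p is uniform (checked by KS over
200 seeded runs). Note the sign-matched convention means the smallest
attainable p is ≈ 2/(n_permutations + 1), since only the same-sign half of
the null is compared.

## Hi-C contact proximity

Contacts are consumed as BEDPE anchor pairs (optional cell-type and support
columns), filtered to one cell type (default "excitatory"). A contact is
DETE-anchored when any locus of an FDR-surviving DETE subfamily overlaps one
of its anchors; under the default distal-anchor rule, candidate genes are
sought within 20 kb of the *other* anchor — the cis-regulatory looping
reading — with either-anchor available as a sensitivity switch. Distance is
the boundary gap between the anchor and the gene body (0 when overlapping);
a TSS mode is provided since published descriptions rarely pin the gene
reference point. A zero chromosome-name overlap between contacts and genes
raises a hard error rather than returning an empty result, because it almost
always signals mismatched naming schemes. Results equal a brute-force triple
loop over (DETE locus, contact, gene) on every tested fixture.

DETE-proximal genes intersected with the condition's DEGs give the
DETE-proximal DEG set and its fraction_down = down/(up + down).

## Resampling empirical-null percentile

To ask whether the DETE-proximal DEGs are more enriched for a target set
than equally sized random subsets of all DETE-proximal genes, the observed
ORA p is placed within an empirical distribution of ORA p-values from
n_subsets (default 100) random subsets drawn uniformly without replacement
from the pool (independently across subsets). The reported percentile is
100 · rank/(N + 1) with rank = |{null ≤ observed}| + 1 — ties count toward
the rank, the conservative choice consistent with the +1 empirical-p
convention. Under this convention one tied-or-smaller null among 100 gives
exactly 100 · 2/101 = 1.98. The plain rank/N convention is available via a
flag. Under exchangeability the percentile is uniform on (0, 100].

## The synthetic cohort generator

The generator plants effects directly on summary statistics, emulating the
output distribution of an upstream DESeq2/TEtranscripts fit:

- **Null features**: p uniform on (0, 1], log2FC ~ Normal(0, noise_sd)
  (noise_sd = 0.3).
- **Perturbed TEs**: p ~ Beta(a, 1) with a = ln(power)/ln(α) so that
  P(p < α) equals the detection power (0.9 at α = 0.05 by default; a is
  computed at run time), and |log2FC| from a shifted exponential
  (shift 0.5, mean per condition).
- **Genes**: a latent-effect z-model — z = scale_c · e_g / noise_sd + N(0,1),
  log2FC = z · noise_sd, p the two-sided normal tail — keeps p and log2FC
  mutually consistent and exactly uniform for null genes. A latent program
  (15% of genes, effect sd 1.2) shared across conditions and scaled
  0.15 / 0.6 / 1.0 for WT-/NFD-/VPR-like conditions drives the graded
  transcriptome concordance that RRHO must recover. Every immune gene also
  receives a latent downshift of 1.5 (implied z-shifts −0.75 / −3 / −5),
  reproducing a gradient from non-significant to moderate to strongest
  immune downregulation.
- **TE perturbation**: per-condition fractions of a 1,500-subfamily universe
  pushed up: 0.04 / 0.17 / 0.34 (≈ 60 / 255 / 510 planted upregulated
  DETEs), small down fractions (0.01 / 0.01 / 0.02). Up-sets are nested
  across conditions (one shared per-class permutation), matching a graded
  derepression reading.
- **Class mixture**: the TE universe is 50% LTR / 30% non-LTR / 20% DNA.
  The planted upregulated draw uses per-condition class proportions derived
  by *inverting the null-false-positive dilution*: called DETEs are planted
  hits (at the detection power) plus ≈ α of the null TEs, and the nulls
  arrive at the universe mix, so planted proportions p must satisfy
  realized = (detected_up · p + (detected_down + α·n_null) · mix) / total.
  Solving for realized non-LTR shares on a graded ~0.20 / 0.26 / 0.33
  trajectory gives planted non-LTR proportions 0.05 / 0.247 / 0.335. A
  realized share much below ≈ 0.19 is unreachable in the weakest condition:
  with honestly calibrated null p-values, false positives at the universe
  mix put a floor under the weakest condition's realized share. This is a
  known difference from real datasets, where null p-values are typically
  conservative and the weakest condition can show lower shares.
- **TE loci** are placed inside gene introns (outside the promoter margin),
  inside enhancer blocks carved into intergenic gaps, or in deep intergenic
  slots, at a 0.45 / 0.35 / 0.20 mix, on a 2 × 50 Mb toy genome (small
  enough for seconds-scale tests, large enough that random 20-kb proximity
  is rare). Placement containers are margin-separated, so the generator's
  per-locus truth labels are exactly recoverable by the annotation stage.
- **Contacts**: each planted proximal immune gene (70% of a 100-gene immune
  set) gets one "excitatory" contact pair linking a 5-kb anchor on an
  upregulated TE locus to a 5-kb anchor within 0–12 kb of the gene body;
  300 background contacts link uniform random anchors with a mixed cell-type
  label. No droplet noise model beyond this; contacts are sparse
  support-1 pairs.
- **Planted proximal DEGs**: every planted proximal immune gene receives a
  DEG-strength effect; a planted_down_frac = 0.71 share is down and the
  complement up, so the proximal-DEG fraction_down is a recoverable
  parameter. (Making the complement non-significant instead would push the
  recovered fraction toward 1 and leave no planted value to recover.) A side
  effect: the strongly upregulated complement weakens the immune GSEA signal
  in the VPR-like condition relative to NFD-like — a deliberate trade-off,
  so the strongest-condition immune GSEA ordering should not be read as a
  generator guarantee.

One `numpy` Generator seeded from `config.seed` drives every draw in fixed
order, so identical configs give byte-identical fixture bundles. `padj` is
filled by the package's own BH implementation per table.

What the generator does *not* emulate: count-level mean–variance structure,
p-value conservatism and inter-feature correlation of real RNA-seq,
multi-mapping ambiguity of TE quantification, binned/normalized Hi-C contact
matrices, and GO-style nested gene-set redundancy. Passing recovery tests
therefore demonstrate correctness of the downstream statistics under a
clean, calibrated input distribution — not robustness to those upstream
artifacts.

## Numerical choices and degenerate inputs

p-values are floored at 1e−300 before logs; hypergeometric tails come from
`scipy.stats.hypergeom`; BH is `statsmodels`' step-up implementation (checked
against a quadratic-time definition-based reference in the tests). Ranking
ties break by feature id. GSEA's running-sum extrema are evaluated only at
hit positions (where the path's extrema provably occur); all-zero hit
weights fall back to unweighted increments. An empty DETE set yields
all-zero breakdowns with shares reported as missing rather than NaN
arithmetic; an all-zero chi-square reference, an empty ranked universe, and
a subset larger than its pool raise typed errors.

## Problem sizes used by the test suite and acceptance script

The default cohort is 2,000 genes / 1,500 TE subfamilies / ~370 contacts;
recovery properties are evaluated over 100 replicate cohorts, null
calibration over 200 seeded runs, and GSEA defaults to 1,000 permutations
(500 in replicate loops). These sizes keep the full suite under a minute
while leaving every binomial/KS acceptance band well-resolved.
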