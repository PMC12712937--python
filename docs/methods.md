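# Methods

## The di-motif model

A PRE di-motif configuration is an orientation in {H-H, H-T, T-T} plus a
spacer length *s* in 0..100, giving 303 configurations.  The top-strand
templates are H-T: `TGAAACA·N^s·TGAAACA`, T-T: `TGTTTCA·N^s·TGAAACA`, and
H-H: `TGAAACA·N^s·TGTTTCA`.  T-H is not a separate orientation: it is H-T
read on the bottom strand.  The H-H and T-T templates are their own reverse
complements as patterns, so they are scanned once and reported on the plus
strand; H-T is genuinely stranded and scanned on both strands.  Overlapping
matches are all reported; the two PRE slots of one match can never overlap
because the spacer is non-negative.

A placement matches when each 7-mer slot has at most `max_mm_per_pre`
mismatches against its expected slot sequence (default 2, configurable up
to 3).  `N` in a slot counts as a mismatch; spacer content is ignored
entirely, including `N`.

### Match significance

Each match carries the probability that iid background sequence matches the
14 constrained positions at least as well as observed:

p(m) = P( X ≥ 14 − m ),  X = Σ_j Bernoulli(π_j),  π_j = background(template_j)

with m = m1 + m2 the total mismatch count, computed by exact convolution of
the 14 per-position match indicators.  Under a non-uniform background the
p-value depends on the orientation's base composition (H-T templates have
eight A's; T-T/H-H have five), but not on the spacer length.  This
match-count tail is a deliberately transparent significance model: it is
fully specified by the background, it makes matches with fewer mismatches
strictly more significant, and it is exactly checkable against enumeration.
A log-odds scoring model (FIMO-style) would order matches with equal
mismatch counts differently in principle; since every downstream decision
here ranks on q-value and then mismatch count, the rankings coincide where
it matters.  Absolute p/q magnitudes from other scanners will differ.

q-values are Benjamini–Hochberg over all matches of one region-set scan
(one scan invocation defines the family).  A region's best match is the
minimum-q match among those with p ≤ 0.01; ties break by fewer total
mismatches, then smaller spacing, then leftmost start, then plus strand.
The tie-break chain is a package convention (only "lowest q" is inherent to
the problem); note it prefers T-T 3 over H-T 4 when both are perfect, since
3 < 4.

## Regions, curation, and spectra

Binding sites arrive as point coordinates with occupancy and log2 Q-value
statistics from any peak caller.  Each point expands to `point ±
half_width` inclusive (241 bp at the default half_width 120); runs of sites
within `merge_gap` (60 bp) merge into one region from half_width upstream
of the first to half_width downstream of the last, clamped to chromosome
bounds.  Regions whose scan yields no surviving match keep `best = None`
and remain in denominators of "fraction of regions with best = C"
summaries.

Top-k membership ranks one entry per configuration (that configuration's
best match in the region) and asks whether a query configuration is among
the k lowest-q entries (default k = 5).  Curated H-T 4 lists keep, per
site, the best-ranked H-T 4 match with both slots ≤ 2 mismatches whose
template center lies within 100 bp of the site point, and emit the 18-mer
oriented so both PREs read in consensus direction.  Mismatch categories are
order-invariant sorted pairs ("1_2" means one slot with 1 and one with 2
mismatches); per-class category spectra normalize within class.

## Gene classification

Inputs are five contrast tables (gene, shrunk log2 fold-change, BH-adjusted
p-value): the wild-type pheromone response (t60 vs t0), the ste12Δ and
kar4Δ effects at t60, the kar4Δ internal response, and a mock-treatment
control.  Thresholds are inclusive: "at least 2-fold" means |lfc| ≥ 1.
Genes significant (padj < 0.05) and ≥ 2-fold in the *same* direction in
both the pheromone response and the mock control are flagged as
t60 artifacts and drop out of classification.  Then, with padj < 0.01:

* **pheromone-induced, Ste12-dependent**: wt lfc ≥ 1 and ste12Δ contrast
  lfc ≤ −1, both significant;
* **Kar4-dependent** additionally has kar4Δ contrast lfc ≤ −1 significant;
  the remaining induced Ste12-dependent genes are **Kar4-independent**;
* **kar4Δ-only (up)**: kar4Δ contrast ≥ 1 and kar4Δ internal response ≥ 1,
  both significant (down mirrored).  This label can co-occur with
  Kar4-independent induction and is carried as a separate boolean.
* everything else is **pheromone_down** (wt ≤ −1 significant) or
  **all_other**.

Genes missing from a contrast are non-significant there (DE tools drop
low-count genes); an exclusion list (default `KAR4`, whose own dependence
is undecidable from a kar4 deletion) flags genes out of set counts without
relabeling them.  The per-sample log2 fold-change matrix for clustering
adds a pseudocount of 0.5 to every TPM *before* averaging the reference
samples: entry = log2((tpm + 0.5) / mean_ref(tpm_ref + 0.5)).

## Peak association and occupancy

A peak point associates with every gene or LTR start within 500 bp in
either direction — deliberately strand-blind, so bidirectional promoters
yield two associations.  A peak whose nearest start is an LTR (or that lies
inside a supplied LTR interval) is LTR-flagged, and any gene sharing a peak
with an LTR is flagged for exclusion from gene-level analyses.  When
several peaks map to one gene the gene takes the statistics of its
minimum-Q peak; ties break by higher occupancy then leftmost coordinate, so
the result is input-order invariant.  Occupancy is the tag count over a
region summed across strands (and replicates, before scaling) divided by
total tags / 1e6.  Group comparisons use two-sided Mann–Whitney U: exact
for ≤ 20 pooled observations (midrank enumeration; a tie-free
dynamic-programming path covers larger exact requests), otherwise the
tie-corrected normal approximation; pairwise category tests are BH-corrected.

## Motif activity inference

Promoter affinity of motif *m* for gene *g* sums window products over both
strands: N_mg = Σ_windows Π_j A_j(base), with PSAM affinities A_j ∈ (0, 1]
and per-position maximum exactly 1.  PSPMs convert to PSAMs by
A_j(b) = (p_j(b) + ε) / max_b (p_j(b) + ε).  A window position reading `N`
contributes the background-weighted mean affinity of its column (an
unbiased placeholder; a "skip window" policy is available).  Promoters
shorter than a motif score 0 with a warning.  Both-strand scoring is a
package choice; tools that score one strand will produce different absolute
N values, which the regression's scale-free p-values largely absorb.

Activities come from one joint OLS fit of the response on all motif
affinities with intercept.  Collinear columns are dropped with a warning; a
zero-variance response returns zero coefficients with p = 1.  Reported
quantities: β, t, two-sided p, signed −log10 p (sign of β attached; p = 0
clamps to the smallest positive float), and per-family rescaling by the
maximum absolute coefficient (default family: all samples for one motif).
Nested-model F-tests compare fits with and without a motif subset.  The
"most significant activity motif for an induced response" is read as the
largest *positive* signed −log10 p: a motif can also acquire a strong
negative association (its targets flat while the rest of the universe
responds), which is informative but is not "driving" that response.

## The synthetic study

The generator builds one chromosome of iid background (default composition
A/T 0.31, C/G 0.19 — AT-rich like yeast intergenic sequence) tiled with
gene units of a 600 bp promoter plus 400 bp body, and plants exactly one
di-motif per non-background promoter at a uniform position (H-T planted on
a random strand; a dual-motif mode adds a perfect T-T 3 beside the H-T 4
for promoters carrying both).  Defaults, which define the study conditions
for all recovery tests:

| parameter | default | meaning |
|---|---|---|
| n_genes / proportions | 800, ¼ each | Kar4-independent, Kar4-dependent, kar4Δ-only, background |
| planted configs | H-T 4, H-T 4, T-T 3 | per the three non-background classes |
| mismatch pairs | {0_0,0_1,1_1} / {0_1,1_1,1_2,2_2} / {0_0,0_1} | Kar4-dependent sites are the most degenerate |
| occ_base, occ_lambda | 300 RPM, 0.5 | occupancy = base·exp(−λ·(m1+m2))·lognormal(σ) |
| occ_penalty | 1.5 / 4.0 / 0.5 | kar4Δ occupancy divisor per class (0.5 = gain) |
| occ_sigma, lfc_sigma | 0.3, 0.3 | lognormal occupancy noise; gaussian fold-change noise |
| effects | see `SimConfig` | per-class true lfc per contrast; validated to classify exactly at σ = 0 |

Mismatch positions are uniform over the 7 PRE positions; an optional
position-weighted mode favors the first two positions, mimicking the
preferential 5'-end degradation seen at Kar4-dependent sites.  Tags are
spread with a triangular kernel (±40 bp) around each site and each
genotype's library is padded on a chromosome tail to exactly one million
tags, so region RPM recovers the drawn occupancy to well within 1%.
Differential-expression p-values come from the z-score of the observed lfc
against the noise scale, BH-adjusted per contrast; at σ = 0 planted effects
get padj 0 and everything else 1, making classification exact by
construction.  The effect-size table is validated at config load by running
the classifier on one archetype gene per class.

What the simulation does *not* emulate: linked genes and operative
chromatin (sites are independent and evenly spaced), peak-caller noise
(site points sit exactly on motif centers), read-level artifacts,
replicate structure in the DE tables (noise is injected at the lfc level),
and realistic class proportions (a quarter of genes per class, against a
few percent in a real genome — chosen so every class is well sampled at
800 genes).  Passing recovery tests therefore demonstrate correctness of
the pipeline's logic under its own model assumptions, not performance on
real ChIP-exo data.  One visible consequence of the inflated kar4Δ-only
proportion: in the wild-type-response activity fit the T-T 3 motif shows a
strong negative association (its many planted genes are flat in wild type),
which a realistically small class would not produce at that magnitude.

## Numerical and testing notes

Problem sizes in the default test run: 600 scanned regions of 241 bp
against all 303 configurations (~1 s), 100 activity-recovery replicates of
2000 promoters x 6 PSAMs (~2 min, via log-space window accumulation), and
exhaustive oracles at width ≤ 8 (p-values), N ≤ 12 (hypergeometric), and
n ≤ 8 (Mann–Whitney).  All stochastic steps take explicit integer seeds;
the same seed reproduces byte-identical simulator output.  Internal
coordinates are 0-based half-open everywhere; GFF3 converts at the
boundary, and minus-strand feature starts use the rightmost coordinate.
IUPAC ambiguity codes other than N collapse to N with a warning rather
than being dropped.  Benjamini–Hochberg adjustment is order-invariant and
monotone but not idempotent — re-adjusting adjusted values inflates them —
so q-values are computed exactly once per family.

Known limitations: the hypergeometric population convention (pooled union
of compared sets vs. a full annotated universe) changes Table-style
enrichment p-values and is a caller choice, not a package judgment; the
match p-value model is not FIMO's, so absolute q-values are not comparable
across tools; and the curated-site filter assumes the caller's point
estimate is within ~100 bp of the true binding center.
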