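# dimotif

Regulatory-genomics toolkit for analyzing how the yeast transcription factor
**Ste12** binds **dimeric pheromone response elements (PREs)**, and how the
methyltransferase-family protein **Kar4** redirects that binding during the
mating pheromone response.

Ste12 binds the 7-mer consensus PRE, 5'-TGAAACA-3', and can bind
cooperatively to a *pair* of PREs.  A PRE **di-motif** is an ordered pair of
PRE slots with a relative orientation — head-to-head (H-H), head-to-tail
(H-T), or tail-to-tail (T-T) — and an unconstrained spacer of *s*
nucleotides.  On the top strand:

```
H-T s:  TGAAACA · N^s · TGAAACA      (stranded; scanned on both strands)
T-T s:  TGTTTCA · N^s · TGAAACA      (reverse-complement invariant)
H-H s:  TGAAACA · N^s · TGTTTCA      (reverse-complement invariant)
```

The package implements the downstream analysis around this model, for
computational biologists working from peak-caller and differential-expression
output rather than raw reads:

* **`motif_core`** — enumerate all configurations (3 orientations x spacers
  0–100), scan sequences with per-PRE mismatch accounting (at most 2
  mismatches per 7-mer slot by default), attach an exact match-count
  p-value, Benjamini–Hochberg q-values, and best-match ranking.
* **`region_pipeline`** — expand ChIP-exo binding points to 241 bp windows,
  merge nearby sites, assign each region its best di-motif, and summarize
  configuration histograms, top-k membership, curated H-T 4 site lists, and
  per-class mismatch spectra.
* **`geneset_classify`** — threshold classification of genes into
  Kar4-independent / Kar4-dependent / kar4Δ-only / background classes from
  five differential-expression contrasts, plus promoter perfect-PRE
  summaries with hypergeometric enrichment.
* **`peak_assoc`** — peak-to-gene association within 500 bp, LTR flagging,
  minimum-Q peak selection, tag-based occupancy in reads per million, and
  Mann–Whitney occupancy comparisons.
* **`activity_inference`** — REDUCE-style motif activity: promoter
  affinities from position-specific affinity matrices (PSAMs), a joint
  ordinary-least-squares fit `y_g = C + Σ_m β_m N_mg`, signed −log10 p, and
  coefficient rescaling.
* **`stat_tests`** — exact hypergeometric upper tail, BH adjustment, and
  Mann–Whitney U with an exact midrank path.
* **`synthetic`** — seeded generators for every input the pipeline consumes
  (genome, sites, annotation, contrast tables, TPMs, tag tracks) with a
  ground-truth table for parameter-recovery testing.

## Worked example

```python
from dimotif import Sequence, assign_qvalues, best_match, enumerate_configs, scan_dimotifs

frag = Sequence("FIG1_fragment", "TGACACATACATGAAACC")
matches = assign_qvalues(scan_dimotifs(frag, enumerate_configs(100)))
m = best_match(matches)
print(m.config.label(), m.m1, m.m2, f"{m.p:.2e}")
```

prints

```
H-T 4 1 1 3.21e-06
```

i.e. the fragment's best match is a head-to-tail di-motif with a 4 nt
spacer in which each PRE slot carries one mismatch from the consensus — a
suboptimal H-T 4 motif of the kind associated with Kar4-dependent
transcription.  The p-value is the chance that iid background sequence
matches the 14 constrained positions at least this well.

A full simulated study (`python examples/02_simulate_and_recover.py`)
plants H-T 4 motifs in Kar4-independent/-dependent promoters and T-T 3
motifs in kar4Δ-only promoters, then re-discovers them:

```
modal best di-motif configuration per planted class:
  kar4_dependent     -> H-T 4 (25/50 regions)
  kar4_independent   -> H-T 4 (44/50 regions)
  kar4_only          -> T-T 3 (50/50 regions)
gene-class recovery at noise sigma=0.3: 99.5%
```

The `examples/` directory has one short script per capability; the
`dimotif` command exposes the same stages as shell subcommands
(`simulate`, `scan-dimotifs`, `classify-genesets`, `associate-peaks`,
`occupancy`, `enrich`, `activity`, `report`).

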