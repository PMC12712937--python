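"""Simulate a synthetic study and recover its planted structure.

The generator plants one PRE di-motif per non-background promoter (H-T 4
for Kar4-independent/-dependent genes, T-T 3 for kar4-delta-only genes),
draws ChIP occupancy decaying with mismatch count, and emits
differential-expression tables.  The pipeline then re-discovers the modal
configuration per class and the gene classes themselves.
"""

import collections

from dimotif import (
    SimConfig,
    classify_genesets,
    enumerate_configs,
    prepare_regions,
    scan_region_set,
    simulate_de_tables,
    simulate_occupancy,
    simulate_promoters,
)

cfg = SimConfig(n_genes=200, seed=42)
genome, promoters, truth, features = simulate_promoters(cfg)
truth, peaks, sites, tracks = simulate_occupancy(truth, cfg)
contrasts = simulate_de_tables(truth, cfg)

regions = prepare_regions(sites, cfg.region_half_width, genome=genome)
bests = scan_region_set(regions, genome, enumerate_configs(100))

cls_of = truth["class"].to_dict()
modal = collections.defaultdict(collections.Counter)
for rb in bests:
    if rb.best is None:
        continue
    for sid in rb.region_id.split("+"):
        cls = cls_of[sid.removeprefix("site_")]
        modal[cls][rb.best.config.label()] += 1

print("modal best di-motif configuration per planted class:")
for cls, counter in sorted(modal.items()):
    config, n = counter.most_common(1)[0]
    print(f"  {cls:18s} -> {config} ({n}/{sum(counter.values())} regions)")

labels = classify_genesets(contrasts, exclude=())
expected = truth["class"].map({
    "kar4_independent": "pheromone_up_kar4_independent",
    "kar4_dependent": "pheromone_up_kar4_dependent",
    "kar4_only": "kar4_only_up",
    "background": "all_other",
})
acc = (labels["label"].loc[expected.index] == expected).mean()
print(f"gene-class recovery at noise sigma={cfg.lfc_sigma}: {acc:.1%}")

# The modal configurations should match what was planted (H-T 4 / H-T 4 /
# T-T 3), and recovery should exceed 95% at the default noise level.
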