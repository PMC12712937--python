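"""Infer motif activities by regressing expression changes on PSAM affinities.

Every promoter is scored against each position-specific affinity matrix
(window products summed over both strands); the per-gene wild-type response
is then fit on all affinities jointly by ordinary least squares.  The sign
of a coefficient says whether the motif is associated with up- or
down-regulated genes; its -log10 p measures confidence.
"""

from dimotif import (
    SimConfig,
    default_psams,
    fit_activity,
    promoter_affinity,
    simulate_de_tables,
    simulate_promoters,
)

cfg = SimConfig(n_genes=400, seed=3)
genome, promoters, truth, _ = simulate_promoters(cfg)
contrasts = simulate_de_tables(truth, cfg)

psams = default_psams(seed=0)  # PRE mono-motif, H-T 4, T-T 3, three decoys
N = promoter_affinity(psams, promoters)
y = contrasts.wt_t60_vs_t0.set_index("gene")["lfc"].loc[N.index]

print("motif activities for the wild-type pheromone response:")
for fit in sorted(fit_activity(N, y), key=lambda f: -f.signed_logp):
    print(f"  {fit.motif_id:22s} beta={fit.beta:+.3f}  "
          f"signed -log10 p = {fit.signed_logp:+.1f}")

# The H-T 4 di-motif shows the strongest positive activity (it drives the
# planted induction); the T-T 3 motif is negatively associated in wild type
# because its genes respond only in the kar4 deletion.
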