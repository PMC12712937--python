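import numpy as np
import pandas as pd
import pytest

from dimotif import SimConfig, simulate_de_tables, simulate_occupancy, simulate_promoters


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study (80 genes) shared across tests."""
    cfg = SimConfig(n_genes=80, seed=7)
    genome, promoters, truth, features = simulate_promoters(cfg)
    truth, peaks, sites, tracks = simulate_occupancy(truth, cfg)
    contrasts = simulate_de_tables(truth, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "promoters": promoters,
        "truth": truth,
        "features": features,
        "peaks": peaks,
        "sites": sites,
        "tracks": tracks,
        "contrasts": contrasts,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


def random_dna(rng, n, comp=(0.25, 0.25, 0.25, 0.25)):
    """Random iid DNA string; shared helper for the scanning tests."""
    return "".join(rng.choice(list("ACGT"), size=n, p=list(comp)))


@pytest.fixture()
def noise_free_contrasts():
    """Hand-built contrast tables with one archetype gene per class."""
    from dimotif.geneset_classify import CONTRAST_NAMES, ContrastSet

    effects = {
        "gInd": {"wt_t60_vs_t0": 2.0, "ste12_t60_vs_wt_t60": -2.5,
                 "kar4_t60_vs_wt_t60": -0.2, "kar4_t60_vs_kar4_t0": 2.0,
                 "wt_t60ctrl_vs_t0": 0.0},
        "gDep": {"wt_t60_vs_t0": 3.0, "ste12_t60_vs_wt_t60": -3.0,
                 "kar4_t60_vs_wt_t60": -1.5, "kar4_t60_vs_kar4_t0": 1.0,
                 "wt_t60ctrl_vs_t0": 0.0},
        "gOnly": {"wt_t60_vs_t0": 0.1, "ste12_t60_vs_wt_t60": 0.0,
                  "kar4_t60_vs_wt_t60": 2.2, "kar4_t60_vs_kar4_t0": 2.5,
                  "wt_t60ctrl_vs_t0": 0.0},
        "gDown": {"wt_t60_vs_t0": -2.0, "ste12_t60_vs_wt_t60": 0.5,
                  "kar4_t60_vs_wt_t60": 0.0, "kar4_t60_vs_kar4_t0": -0.3,
                  "wt_t60ctrl_vs_t0": 0.0},
        "gArtifact": {"wt_t60_vs_t0": 2.5, "ste12_t60_vs_wt_t60": 0.0,
                      "kar4_t60_vs_wt_t60": 0.0, "kar4_t60_vs_kar4_t0": 0.0,
                      "wt_t60ctrl_vs_t0": 2.4},
        "gFlat": {n: 0.0 for n in CONTRAST_NAMES},
    }
    tables = {}
    for name in CONTRAST_NAMES:
        rows = [
            {"gene": g, "lfc": eff[name],
             "padj": 0.001 if abs(eff[name]) >= 1 else 0.9}
            for g, eff in effects.items()
        ]
        tables[name] = pd.DataFrame(rows)
    return ContrastSet(**tables)
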