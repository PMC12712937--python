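"""Threshold-based gene-set classification from differential-expression tables.

Five contrasts drive the classification (all shrunk log2 fold-changes with
BH-adjusted p-values, consumed as input):

* ``wt_t60_vs_t0``        - wild-type pheromone response (60 min vs 0 min)
* ``ste12_t60_vs_wt_t60`` - ste12 deletion vs wild-type, both at 60 min
* ``kar4_t60_vs_wt_t60``  - kar4 deletion vs wild-type, both at 60 min
* ``kar4_t60_vs_kar4_t0`` - pheromone response within the kar4 deletion
* ``wt_t60ctrl_vs_t0``    - 60 min mock treatment vs 0 min (artifact control)

A gene is *pheromone-induced* when significantly up at least 2-fold in
wild-type and not a t60 artifact; it is *Ste12-dependent* when that induction
is significantly lost in ste12-delta, and within those, *Kar4-dependent* when
it is also significantly at least 2-fold lower in kar4-delta.  *kar4-delta-only*
genes respond at least 2-fold more in the deletion than in wild-type and at
least 2-fold within the deletion's own response; they may co-occur with the
Kar4-independent label.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .io_formats import Sequence
from .motif_core import find_perfect_pre
from .stat_tests import HypergeomSpec, hypergeom_tail

CONTRAST_NAMES = (
    "wt_t60_vs_t0",
    "ste12_t60_vs_wt_t60",
    "kar4_t60_vs_wt_t60",
    "kar4_t60_vs_kar4_t0",
    "wt_t60ctrl_vs_t0",
)

PRIMARY_LABELS = (
    "pheromone_up_kar4_independent",
    "pheromone_up_kar4_dependent",
    "kar4_only_up",
    "kar4_only_down",
    "pheromone_down",
    "all_other",
)

__all__ = [
    "CONTRAST_NAMES",
    "PRIMARY_LABELS",
    "ContrastSet",
    "logfc_matrix",
    "flag_t60_artifacts",
    "classify_genesets",
    "promoter_perfect_pre_fraction",
    "set_induction_fraction",
]


@dataclass
class ContrastSet:
    """The five differential-expression tables, each with columns
    gene / lfc / padj.  Genes absent from a contrast are non-significant
    there; a missing padj is non-significant."""

    wt_t60_vs_t0: pd.DataFrame
    ste12_t60_vs_wt_t60: pd.DataFrame
    kar4_t60_vs_wt_t60: pd.DataFrame
    kar4_t60_vs_kar4_t0: pd.DataFrame
    wt_t60ctrl_vs_t0: pd.DataFrame

    def __post_init__(self) -> None:
        for f in fields(self):
            df = getattr(self, f.name)
            missing = {"gene", "lfc", "padj"} - set(df.columns)
            if missing:
                raise ValueError(f"contrast {f.name} lacks columns {missing}")
            if df["gene"].duplicated().any():
                dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
                raise ValueError(f"duplicate gene ids in {f.name}: {dups[:5]}")

    def universe(self) -> list[str]:
        genes: set[str] = set()
        for f in fields(self):
            genes |= set(getattr(self, f.name)["gene"])
        return sorted(genes)

    def aligned(self) -> dict[str, pd.DataFrame]:
        """Each contrast reindexed on the shared gene universe; genes missing
        from a contrast get lfc=0, padj=1 (non-significant)."""
        genes = self.universe()
        out = {}
        for f in fields(self):
            df = getattr(self, f.name).set_index("gene").reindex(genes)
            df["lfc"] = df["lfc"].fillna(0.0)
            df["padj"] = df["padj"].fillna(1.0)
            out[f.name] = df
        return out


def logfc_matrix(
    tpm: pd.DataFrame,
    reference_sample_ids: TypingSequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Genes x samples log2 fold-change matrix against the reference mean.

    A pseudocount is added to every TPM first, then the per-gene reference
    mean is taken over the pseudocounted values:
    entry = log2((tpm + c) / mean_ref(tpm_ref + c)).
    """
    if len(reference_sample_ids) == 0:
        raise ValueError("empty reference sample set")
    missing = set(reference_sample_ids) - set(tpm.columns)
    if missing:
        raise ValueError(f"reference samples absent from table: {missing}")
    shifted = tpm + pseudocount
    ref_mean = shifted[list(reference_sample_ids)].mean(axis=1)
    return np.log2(shifted.div(ref_mean, axis=0))


def _sig(df: pd.DataFrame, padj_thresh: float) -> pd.Series:
    return df["padj"].fillna(1.0) < padj_thresh


def flag_t60_artifacts(
    contrasts: ContrastSet,
    lfc_thresh: float = 1.0,
    padj_thresh: float = 0.05,
) -> set[str]:
    """Genes significantly changed at least 2-fold in the SAME direction in
    both the pheromone response and the mock t60 control; such genes are
    potential false positives of the 60-minute treatment itself."""
    al = contrasts.aligned()
    phe, ctrl = al["wt_t60_vs_t0"], al["wt_t60ctrl_vs_t0"]
    up = (
        (phe["lfc"] >= lfc_thresh) & _sig(phe, padj_thresh)
        & (ctrl["lfc"] >= lfc_thresh) & _sig(ctrl, padj_thresh)
    )
    dn = (
        (phe["lfc"] <= -lfc_thresh) & _sig(phe, padj_thresh)
        & (ctrl["lfc"] <= -lfc_thresh) & _sig(ctrl, padj_thresh)
    )
    return set(phe.index[up | dn])


def classify_genesets(
    contrasts: ContrastSet,
    lfc_thresh: float = 1.0,
    padj_thresh: float = 0.01,
    artifact_padj_thresh: float = 0.05,
    exclude: Iterable[str] = ("KAR4",),
) -> pd.DataFrame:
    """Classify every gene in the contrast universe.

    Returns a frame indexed by gene with a primary ``label``, boolean
    ``kar4_only_up`` / ``kar4_only_down`` co-labels, and ``excluded`` /
    ``t60_artifact`` flags.  Thresholds are inclusive (lfc >= lfc_thresh:
    "at least 2-fold").  Excluded genes keep their computed label but are
    flagged for removal from set counts.
    """
    al = contrasts.aligned()
    wt = al["wt_t60_vs_t0"]
    st = al["ste12_t60_vs_wt_t60"]
    k4 = al["kar4_t60_vs_wt_t60"]
    k4self = al["kar4_t60_vs_kar4_t0"]
    genes = wt.index

    artifacts = flag_t60_artifacts(contrasts, lfc_thresh, artifact_padj_thresh)
    is_artifact = genes.isin(sorted(artifacts))

    t = lfc_thresh
    induced = (wt["lfc"] >= t) & _sig(wt, padj_thresh) & ~is_artifact
    repressed = (wt["lfc"] <= -t) & _sig(wt, padj_thresh) & ~is_artifact
    ste12_dep_up = induced & (st["lfc"] <= -t) & _sig(st, padj_thresh)
    kar4_dep_up = ste12_dep_up & (k4["lfc"] <= -t) & _sig(k4, padj_thresh)
    kar4_ind_up = ste12_dep_up & ~kar4_dep_up

    kar4_only_up = (
        (k4["lfc"] >= t) & _sig(k4, padj_thresh)
        & (k4self["lfc"] >= t) & _sig(k4self, padj_thresh)
    )
    kar4_only_down = (
        (k4["lfc"] <= -t) & _sig(k4, padj_thresh)
        & (k4self["lfc"] <= -t) & _sig(k4self, padj_thresh)
    )

    label = pd.Series("all_other", index=genes, name="label")
    label[repressed] = "pheromone_down"
    label[kar4_only_down & ~(induced | repressed)] = "kar4_only_down"
    label[kar4_only_up & ~ste12_dep_up] = "kar4_only_up"
    label[kar4_ind_up] = "pheromone_up_kar4_independent"
    label[kar4_dep_up] = "pheromone_up_kar4_dependent"

    out = pd.DataFrame(
        {
            "label": label,
            "kar4_only_up": kar4_only_up,
            "kar4_only_down": kar4_only_down,
            "excluded": genes.isin(list(exclude)),
            "t60_artifact": is_artifact,
        },
        index=genes,
    )
    out.index.name = "gene"
    return out.sort_index()


def _set_members(labels: pd.DataFrame, label: str) -> list[str]:
    keep = (labels["label"] == label) & ~labels["excluded"]
    return list(labels.index[keep])


def promoter_perfect_pre_fraction(
    gene_sets: Mapping[str, TypingSequence[str]],
    promoters: Mapping[str, Sequence | str],
    background_set: str = "all_other",
) -> pd.DataFrame:
    """Per gene set: count and fraction of members whose promoter contains at
    least one exact PRE (TGAAACA, either strand), with a hypergeometric
    upper-tail enrichment p against the pooled population.

    Genes without a promoter sequence are dropped with a warning.  The
    population is the union of all supplied sets.
    """
    import warnings

    has_pre: dict[str, bool] = {}
    for gene, seq in promoters.items():
        bases = seq.bases if isinstance(seq, Sequence) else seq
        has_pre[gene] = len(find_perfect_pre(bases)) > 0

    filtered: dict[str, list[str]] = {}
    for name, members in gene_sets.items():
        kept = [g for g in members if g in has_pre]
        dropped = len(members) - len(kept)
        if dropped:
            warnings.warn(f"set {name!r}: {dropped} genes without promoter dropped")
        filtered[name] = kept

    pop = sorted(set().union(*filtered.values())) if filtered else []
    N = len(pop)
    K = sum(has_pre[g] for g in pop)
    rows = []
    for name, members in filtered.items():
        n = len(members)
        k = sum(has_pre[g] for g in members)
        p = hypergeom_tail(HypergeomSpec(N, K, n, k)) if n else float("nan")
        rows.append(
            {"set": name, "size": n, "count": k,
             "fraction": k / n if n else float("nan"), "p": p}
        )
    return pd.DataFrame(rows).set_index("set")


def set_induction_fraction(
    gene_set: TypingSequence[str],
    fc_table: Mapping[str, float] | pd.Series,
    threshold: float,
    population: TypingSequence[str] | None = None,
) -> tuple[float, float]:
    """Fraction of set members whose external fold-change value is >= the
    threshold, plus a hypergeometric enrichment p against the population
    (default: all genes in the table)."""
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    fc = pd.Series(fc_table)
    pop = list(population) if population is not None else list(fc.index)
    members = [g for g in gene_set if g in fc.index]
    k = int((fc[members] >= threshold).sum())
    K = int((fc[pop] >= threshold).sum())
    frac = k / len(members)
    p = hypergeom_tail(HypergeomSpec(len(pop), K, len(members), k))
    return frac, p
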