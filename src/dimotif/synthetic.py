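"""Seeded generators for every input the pipeline consumes.

The simulator emulates the statistical structure the downstream analysis
assumes, with a ground-truth table enabling parameter-recovery tests:

* iid-background promoters with one planted PRE di-motif per non-background
  gene, whose configuration and mismatch spectrum differ by gene class
  (Kar4-independent and Kar4-dependent genes carry H-T 4 motifs with few and
  many mismatches respectively; kar4-delta-only genes carry T-T 3 motifs);
* ChIP occupancy decreasing exponentially with total mismatch count, with a
  per-class genotype penalty in the kar4 deletion and lognormal noise;
* differential-expression tables for the five contrasts with per-class effect
  sizes chosen so the classifier recovers every class exactly at zero noise.

All generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .io_formats import FeatureStart, Sequence, write_bedgraph, write_fasta
from .geneset_classify import CONTRAST_NAMES, ContrastSet
from .motif_core import PRE, PRE_RC, PSAM, DiMotifConfig, mismatches, revcomp
from .peak_assoc import PeakRecord
from .region_pipeline import SiteRecord
from .stat_tests import bh_adjust

__all__ = [
    "ClassMotifSpec",
    "SimConfig",
    "simulate_promoters",
    "simulate_occupancy",
    "simulate_de_tables",
    "simulate_tpm",
    "make_fixture_bundle",
    "default_psams",
]

CLASSES = ("kar4_independent", "kar4_dependent", "kar4_only", "background")
GENE_BODY = 400  # bp of transcribed sequence after each promoter
TAIL = 5000  # chromosome tail used to pad tag libraries


@dataclass(frozen=True)
class ClassMotifSpec:
    """Planted di-motif for one gene class: configuration plus the mismatch
    pairs its sites are drawn from (uniformly)."""

    orientation: str
    spacing: int
    categories: tuple[tuple[int, int], ...]

    @property
    def config(self) -> DiMotifConfig:
        return DiMotifConfig(self.orientation, self.spacing)


def _default_motif_specs() -> dict[str, ClassMotifSpec]:
    return {
        "kar4_independent": ClassMotifSpec("HT", 4, ((0, 0), (0, 1), (1, 1))),
        "kar4_dependent": ClassMotifSpec("HT", 4, ((0, 1), (1, 1), (1, 2), (2, 2))),
        "kar4_only": ClassMotifSpec("TT", 3, ((0, 0), (0, 1))),
    }


def _default_effects() -> dict[str, dict[str, float]]:
    # Per-class true shrunk log2 fold-changes for the five contrasts, chosen
    # so threshold classification (|lfc| >= 1, significant) is exact at
    # sigma = 0: Kar4-independent genes induce in wild-type and in the kar4
    # deletion; Kar4-dependent genes lose >= 2-fold of their induction in the
    # deletion; kar4-delta-only genes respond only in the deletion.
    return {
        "kar4_independent": {
            "wt_t60_vs_t0": 2.0, "ste12_t60_vs_wt_t60": -2.0,
            "kar4_t60_vs_wt_t60": 0.0, "kar4_t60_vs_kar4_t0": 2.0,
            "wt_t60ctrl_vs_t0": 0.0,
        },
        "kar4_dependent": {
            "wt_t60_vs_t0": 2.0, "ste12_t60_vs_wt_t60": -2.0,
            "kar4_t60_vs_wt_t60": -1.5, "kar4_t60_vs_kar4_t0": 0.5,
            "wt_t60ctrl_vs_t0": 0.0,
        },
        "kar4_only": {
            "wt_t60_vs_t0": 0.0, "ste12_t60_vs_wt_t60": 0.0,
            "kar4_t60_vs_wt_t60": 2.0, "kar4_t60_vs_kar4_t0": 2.5,
            "wt_t60ctrl_vs_t0": 0.0,
        },
        "background": {name: 0.0 for name in CONTRAST_NAMES},
    }


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults: 200 genes per class; yeast-like AT-rich background; occupancy
    base level 300 RPM decaying as exp(-0.5 * total mismatches) with
    kar4-deletion penalties of 1.5x (Kar4-independent), 4x (Kar4-dependent)
    and 0.5x, i.e. a gain, for kar4-delta-only sites; lognormal occupancy
    noise and gaussian fold-change noise both at sigma 0.3.
    """

    n_genes: int = 800
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in CLASSES}
    )
    motif_specs: dict[str, ClassMotifSpec] = field(default_factory=_default_motif_specs)
    background_comp: tuple[float, float, float, float] = (0.31, 0.19, 0.19, 0.31)
    promoter_len: int = 600
    region_half_width: int = 120
    # occupancy model
    occ_base: float = 300.0
    occ_lambda: float = 0.5
    occ_penalty: dict[str, float] = field(
        default_factory=lambda: {
            "kar4_independent": 1.5, "kar4_dependent": 4.0, "kar4_only": 0.5,
        }
    )
    occ_sigma: float = 0.3
    # expression model
    effects: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    lfc_sigma: float = 0.3
    base_tpm: float = 20.0
    n_replicates: int = 4
    # optional modes
    position_weighted_mismatches: bool = False
    dual_motif_classes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be >= 0")
        if min(self.occ_base, self.occ_lambda, self.occ_sigma, self.lfc_sigma) < 0:
            raise ValueError("rates and noise scales must be >= 0")
        if abs(sum(self.background_comp) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        for cls, spec in self.motif_specs.items():
            if spec.config.width > self.promoter_len:
                raise ValueError(f"promoter too short for {cls} template")
        self.validate_effects()

    def class_counts(self) -> dict[str, int]:
        counts = {
            c: int(self.n_genes * self.class_proportions.get(c, 0.0))
            for c in CLASSES
        }
        counts["background"] += self.n_genes - sum(counts.values())
        return counts

    def validate_effects(self) -> None:
        """Check the noise-free effect vectors reproduce each class label."""
        from .geneset_classify import classify_genesets

        rows = {name: [] for name in CONTRAST_NAMES}
        genes = []
        for cls in CLASSES:
            genes.append(f"_probe_{cls}")
            for name in CONTRAST_NAMES:
                lfc = self.effects[cls][name]
                rows[name].append(
                    {"gene": f"_probe_{cls}", "lfc": lfc,
                     "padj": 0.0 if lfc != 0 else 1.0}
                )
        cs = ContrastSet(**{n: pd.DataFrame(rows[n]) for n in CONTRAST_NAMES})
        labels = classify_genesets(cs, exclude=())
        expected = {
            "kar4_independent": "pheromone_up_kar4_independent",
            "kar4_dependent": "pheromone_up_kar4_dependent",
            "kar4_only": "kar4_only_up",
            "background": "all_other",
        }
        for cls, want in expected.items():
            got = labels.loc[f"_probe_{cls}", "label"]
            if got != want:
                raise ValueError(
                    f"effect sizes for class {cls!r} classify as {got!r}, "
                    f"not {want!r}"
                )


_BASES = np.array(list("ACGT"))


def _mutate_slot(slot: str, n_mm: int, rng: np.random.Generator,
                 weighted: bool) -> str:
    """Introduce n_mm mismatches at distinct positions, each to a random
    non-consensus base.  The weighted mode favors the first two positions,
    mimicking the preferential degradation seen at PRE 5' ends."""
    if n_mm == 0:
        return slot
    if weighted:
        w = np.array([3.0, 3.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        pos = rng.choice(7, size=n_mm, replace=False, p=w / w.sum())
    else:
        pos = rng.choice(7, size=n_mm, replace=False)
    out = list(slot)
    for j in pos:
        out[j] = rng.choice([b for b in "ACGT" if b != slot[j]])
    return "".join(out)


def _planted_template(spec: ClassMotifSpec, m1: int, m2: int,
                      rng: np.random.Generator, weighted: bool) -> str:
    up, dn = spec.config.slots
    spacer = "".join(rng.choice(_BASES, size=spec.spacing))
    return (
        _mutate_slot(up, m1, rng, weighted)
        + spacer
        + _mutate_slot(dn, m2, rng, weighted)
    )


def simulate_promoters(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, Sequence], pd.DataFrame, list[FeatureStart]]:
    """Build the synthetic genome: one chromosome of iid background with one
    gene unit (promoter + body) per gene, one di-motif planted per
    non-background promoter.

    Returns (genome, promoters, truth, feature_starts).  The truth table
    records the planted configuration, actual per-slot mismatch counts,
    strand, and top-strand template start for every gene.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.class_counts()
    classes: list[str] = sum(([c] * counts[c] for c in CLASSES), [])
    rng.shuffle(classes)

    unit = config.promoter_len + GENE_BODY
    chrom_len = config.n_genes * unit + TAIL
    chrom = rng.choice(_BASES, size=chrom_len, p=list(config.background_comp))

    rows = []
    features: list[FeatureStart] = []
    for gi, cls in enumerate(classes):
        gene = f"g{gi:04d}"
        prom_start = gi * unit
        gene_start = prom_start + config.promoter_len
        features.append(FeatureStart("chr_sim", gene_start, "+", gene, "gene"))
        row = {
            "gene": gene, "class": cls, "orientation": "", "spacing": -1,
            "m1": -1, "m2": -1, "strand": "", "motif_start": -1,
            "motif_center": -1, "prom_start": prom_start,
            "gene_start": gene_start,
        }
        if cls != "background":
            spec = config.motif_specs[cls]
            m_lo, m_hi = spec.categories[rng.integers(len(spec.categories))]
            m1, m2 = (m_lo, m_hi) if rng.random() < 0.5 else (m_hi, m_lo)
            template = _planted_template(
                spec, m1, m2, rng, config.position_weighted_mismatches
            )
            strand = "+"
            if spec.orientation == "HT" and rng.random() < 0.5:
                strand = "-"
            planted = template if strand == "+" else revcomp(template)
            width = len(template)
            margin = 10
            offset = int(
                rng.integers(margin, config.promoter_len - width - margin + 1)
            )
            start = prom_start + offset
            chrom[start:start + width] = list(planted)
            row.update(
                orientation=spec.orientation, spacing=spec.spacing,
                m1=m1, m2=m2, strand=strand, motif_start=start,
                motif_center=start + width // 2,
            )
            if cls in config.dual_motif_classes and spec.orientation == "HT":
                extra = PRE_RC + "".join(rng.choice(_BASES, size=3)) + PRE
                eoff = margin if offset > config.promoter_len // 2 else (
                    config.promoter_len - len(extra) - margin
                )
                chrom[prom_start + eoff:prom_start + eoff + len(extra)] = list(extra)
        rows.append(row)

    # a few LTR starts in the tail so the annotation exercises both types
    tail_start = config.n_genes * unit
    for li in range(3):
        features.append(
            FeatureStart("chr_sim", tail_start + 500 + 800 * li, "+",
                         f"ltr{li}", "LTR")
        )

    genome = {"chr_sim": "".join(chrom)}
    truth = pd.DataFrame(rows).set_index("gene")
    promoters = {
        g: Sequence(g, genome["chr_sim"][r.prom_start:r.gene_start])
        for g, r in truth.iterrows()
    }
    return genome, promoters, truth, features


def simulate_occupancy(
    truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, list[PeakRecord], list[SiteRecord],
           dict[tuple[str, str], pd.DataFrame]]:
    """Draw per-site occupancy and scatter tags around each motif center.

    occupancy_wt = base * exp(-lambda * (m1 + m2)) * lognormal(sigma);
    occupancy_kar4 = occupancy_wt / penalty(class).  Tags are spread with a
    triangular kernel within +/-40 bp of the site point and each genotype's
    library is padded on the chromosome tail to exactly 1e6 tags, so RPM over
    the site region recovers the drawn occupancy.

    Returns (truth with occupancy columns, peaks, sites, tag tracks keyed by
    (genotype, strand)).
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = truth.copy()
    planted = truth[truth["class"] != "background"]
    total_mm = planted["m1"] + planted["m2"]
    noise = (
        rng.lognormal(mean=0.0, sigma=config.occ_sigma, size=len(planted))
        if config.occ_sigma > 0 else np.ones(len(planted))
    )
    occ_wt = config.occ_base * np.exp(-config.occ_lambda * total_mm) * noise
    penalty = planted["class"].map(config.occ_penalty).to_numpy(float)
    occ_kar4 = occ_wt / penalty

    truth["occ_wt"] = 0.0
    truth["occ_kar4"] = 0.0
    truth.loc[planted.index, "occ_wt"] = occ_wt
    truth.loc[planted.index, "occ_kar4"] = occ_kar4

    peaks, sites = [], []
    for (gene, row), o_wt, o_k4 in zip(planted.iterrows(), occ_wt, occ_kar4):
        point = int(row["motif_center"])
        peaks.append(
            PeakRecord(
                peak_id=f"peak_{gene}", chrom="chr_sim", point=point,
                occupancy_rpm={"wt": float(o_wt), "kar4": float(o_k4)},
                logQ=-float(o_wt) / 10.0,
                log2_occ_fc=float(np.log2(o_k4 / o_wt)),
            )
        )
        sites.append(
            SiteRecord("chr_sim", point, f"site_{gene}",
                       occupancy_rpm=float(o_wt), logQ=-float(o_wt) / 10.0)
        )

    kernel_hw = 40
    offsets = np.arange(-kernel_hw, kernel_hw + 1)
    weights = (kernel_hw + 1 - np.abs(offsets)).astype(float)
    weights /= weights.sum()

    chrom_len = int(truth["gene_start"].max()) + GENE_BODY + TAIL
    tail_start = chrom_len - TAIL
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    for genotype, occs in (("wt", occ_wt), ("kar4", occ_kar4)):
        cover = {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)}
        for point, occ in zip(planted["motif_center"].astype(int), occs):
            pos = point + offsets
            cover["+"][pos] += occ * weights / 2.0
            cover["-"][pos] += occ * weights / 2.0
        pad = 1e6 - sum(c.sum() for c in cover.values())
        if pad < 0:
            raise ValueError("site tags exceed library size; lower occ_base")
        cover["+"][tail_start:] += pad / 2.0 / TAIL
        cover["-"][tail_start:] += pad / 2.0 / TAIL
        for strand in "+-":
            tracks[(genotype, strand)] = _coverage_to_bedgraph(
                cover[strand], "chr_sim"
            )
    return truth, peaks, sites, tracks


def _coverage_to_bedgraph(cover: np.ndarray, chrom: str) -> pd.DataFrame:
    """Run-length encode a per-base coverage vector, dropping zero runs."""
    change = np.nonzero(np.diff(cover))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(cover)]])
    values = cover[starts]
    keep = values != 0
    return pd.DataFrame(
        {"chrom": chrom, "start": starts[keep], "end": ends[keep],
         "value": values[keep]}
    )


def simulate_de_tables(
    truth: pd.DataFrame,
    config: SimConfig,
) -> ContrastSet:
    """Differential-expression tables for the five contrasts.

    Observed lfc = class effect + N(0, sigma); p-values come from the z-score
    of the observed lfc against the noise scale and are BH-adjusted within
    each contrast.  At sigma = 0 planted effects get padj 0 and everything
    else padj 1, so classification is exact by construction.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = truth.index.to_list()
    cls = truth["class"]
    tables = {}
    for name in CONTRAST_NAMES:
        true_lfc = cls.map(lambda c: config.effects[c][name]).to_numpy(float)
        if config.lfc_sigma > 0:
            obs = true_lfc + rng.normal(0.0, config.lfc_sigma, size=len(genes))
            z = obs / config.lfc_sigma
            p = 2.0 * sps.norm.sf(np.abs(z))
            padj = bh_adjust(p)
        else:
            obs = true_lfc
            padj = np.where(true_lfc != 0.0, 0.0, 1.0)
        tables[name] = pd.DataFrame(
            {"gene": genes, "lfc": obs, "padj": padj}
        )
    return ContrastSet(**tables)


def simulate_tpm(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-gene TPM table for all samples (replicated), consistent with the
    per-class contrast effects."""
    rng = np.random.default_rng(config.seed + 3)
    cls = truth["class"]

    def eff(name: str) -> pd.Series:
        return cls.map(lambda c: config.effects[c][name]).astype(float)

    wt_t60 = eff("wt_t60_vs_t0")
    means = {
        "wt_t0": 0.0 * wt_t60,
        "wt_t60": wt_t60,
        "ste12_t60": wt_t60 + eff("ste12_t60_vs_wt_t60"),
        "kar4_t60": wt_t60 + eff("kar4_t60_vs_wt_t60"),
        "kar4_t0": wt_t60 + eff("kar4_t60_vs_wt_t60") - eff("kar4_t60_vs_kar4_t0"),
        "wt_t60ctrl": eff("wt_t60ctrl_vs_t0"),
    }
    cols = {}
    log_base = np.log2(config.base_tpm)
    for sample, mu in means.items():
        for rep in range(1, config.n_replicates + 1):
            noise = (
                rng.normal(0.0, config.lfc_sigma / 2.0, size=len(truth))
                if config.lfc_sigma > 0 else 0.0
            )
            cols[f"{sample}_r{rep}"] = 2.0 ** (log_base + mu.to_numpy() + noise)
    return pd.DataFrame(cols, index=truth.index)


def default_psams(seed: int = 0, mismatch_affinity: float = 0.1) -> list[PSAM]:
    """The bundle's motif set: PRE mono-motif, H-T 4 and T-T 3 di-motif PSAMs
    (consensus base affinity 1, others ``mismatch_affinity``; spacer columns
    uniform), plus three random consensus 8-mer decoys."""
    rng = np.random.default_rng(seed)

    def consensus_psam(name: str, consensus: str, spacer: str = "") -> PSAM:
        rows = []
        for c in consensus:
            if c == ".":
                rows.append([1.0, 1.0, 1.0, 1.0])
            else:
                row = [mismatch_affinity] * 4
                row["ACGT".index(c)] = 1.0
                rows.append(row)
        return PSAM(name, np.array(rows))

    psams = [
        consensus_psam("PRE_mono", PRE),
        consensus_psam("HT_4", PRE + "." * 4 + PRE),
        consensus_psam("TT_3", PRE_RC + "." * 3 + PRE),
    ]
    for i in range(3):
        decoy = "".join(rng.choice(_BASES, size=8))
        psams.append(consensus_psam(f"decoy_{i}_{decoy}", decoy))
    return psams


def _crosscheck_truth(genome: dict[str, str], truth: pd.DataFrame) -> None:
    """Verify every planted template is present with its recorded mismatches."""
    chrom = genome["chr_sim"]
    for gene, row in truth[truth["class"] != "background"].iterrows():
        spec_cfg = DiMotifConfig(row["orientation"], int(row["spacing"]))
        width = spec_cfg.width
        sub = chrom[int(row["motif_start"]):int(row["motif_start"]) + width]
        if row["strand"] == "-":
            sub = revcomp(sub)
        up, dn = spec_cfg.slots
        got = (mismatches(sub[:7], up), mismatches(sub[-7:], dn))
        if got != (int(row["m1"]), int(row["m2"])):
            raise AssertionError(
                f"truth/genome mismatch for {gene}: recorded "
                f"({row['m1']},{row['m2']}), found {got}"
            )


def make_fixture_bundle(
    outdir: str | Path,
    seed: int = 0,
    config: SimConfig | None = None,
) -> SimConfig:
    """Generate and write the full input bundle: genome FASTA, sites BED,
    feature-start GFF3, five contrast TSVs, TPM TSV, per-genotype/strand tag
    bedGraphs, the truth table, and the configuration used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimConfig(seed=seed)
    elif config.seed != seed:
        config = SimConfig(**{**asdict_config(config), "seed": seed})

    genome, promoters, truth, features = simulate_promoters(config)
    _crosscheck_truth(genome, truth)
    truth, peaks, sites, tracks = simulate_occupancy(truth, config)
    contrasts = simulate_de_tables(truth, config)
    tpm = simulate_tpm(truth, config)

    write_fasta([Sequence(c, s) for c, s in genome.items()], outdir / "genome.fa")
    with open(outdir / "sites.bed", "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.point}\t{s.point + 1}\t{s.region_id}\t"
                     f"{s.occupancy_rpm:.4f}\t{s.logQ:.4f}\n")
    with open(outdir / "features.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            gff_type = "gene" if f.feature_type == "gene" else "long_terminal_repeat"
            fh.write(
                f"{f.chrom}\tsim\t{gff_type}\t{f.pos + 1}\t"
                f"{f.pos + 1 + GENE_BODY}\t.\t{f.strand}\t.\tID={f.feature_id}\n"
            )
    for name in CONTRAST_NAMES:
        getattr(contrasts, name).to_csv(
            outdir / f"contrast_{name}.tsv", sep="\t", index=False
        )
    tpm.to_csv(outdir / "tpm.tsv", sep="\t")
    for (genotype, strand), track in tracks.items():
        tag = "plus" if strand == "+" else "minus"
        write_bedgraph(track, outdir / f"tags_{genotype}_{tag}.bedgraph")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(asdict_config(config), fh, sort_keys=False)
    return config


def asdict_config(config: SimConfig) -> dict:
    d = asdict(config)
    d["motif_specs"] = {
        k: {"orientation": v.orientation, "spacing": v.spacing,
            "categories": [list(c) for c in v.categories]}
        for k, v in config.motif_specs.items()
    }
    d["background_comp"] = list(config.background_comp)
    d["dual_motif_classes"] = list(config.dual_motif_classes)
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "motif_specs" in d:
        d["motif_specs"] = {
            k: ClassMotifSpec(
                v["orientation"], v["spacing"],
                tuple(tuple(c) for c in v["categories"]),
            )
            for k, v in d["motif_specs"].items()
        }
    if "background_comp" in d:
        d["background_comp"] = tuple(d["background_comp"])
    if "dual_motif_classes" in d:
        d["dual_motif_classes"] = tuple(d["dual_motif_classes"])
    return SimConfig(**d)
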