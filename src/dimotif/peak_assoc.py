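"""Peak-to-gene association, tag-based occupancy, and occupancy comparisons.

A peak point is associated with every annotated feature start (gene or LTR)
within a fixed window in either direction; peaks nearest to an LTR start are
flagged so LTR-driven binding can be excluded from gene-level analyses.  When
several peaks map to one gene, the gene inherits the statistics of its most
significant (lowest Q) peak.  Occupancy is the per-region tag count on both
strands scaled to reads per million.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import FeatureStart, GenomicRegion
from .stat_tests import bh_adjust, mann_whitney

__all__ = [
    "PeakRecord",
    "Association",
    "associate_peaks",
    "gene_peak_stats",
    "occupancy_rpm",
    "compare_occupancy",
    "occupancy_vs_mismatch",
]


@dataclass(frozen=True)
class PeakRecord:
    """A called binding peak (consumed from a peak caller).

    ``occupancy_rpm`` maps condition name -> RPM; ``logQ`` is the caller's
    log2 Q-value (more negative = more significant).
    """

    peak_id: str
    chrom: str
    point: int
    occupancy_rpm: Mapping[str, float] = field(default_factory=dict)
    logQ: float = 0.0
    log2_occ_fc: float | None = None
    region: GenomicRegion | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.occupancy_rpm.values()):
            raise ValueError(f"peak {self.peak_id!r}: negative occupancy")

    @classmethod
    def from_interval(cls, peak_id, chrom, start, end, **kw) -> "PeakRecord":
        """Peaks given as intervals use the interval midpoint as the point."""
        return cls(
            peak_id, chrom, (start + end) // 2,
            region=GenomicRegion(chrom, start, end, peak_id), **kw,
        )


@dataclass(frozen=True)
class Association:
    peak_id: str
    feature_id: str
    feature_type: str
    distance: int
    ltr_flag: bool


def associate_peaks(
    peaks: TypingSequence[PeakRecord],
    feature_starts: TypingSequence[FeatureStart],
    window: int = 500,
    ltr_intervals: TypingSequence[GenomicRegion] = (),
) -> list[Association]:
    """Associate every peak with all feature starts within ``window`` bp in
    either direction (multiple associations allowed, e.g. bidirectional
    promoters).  A peak whose nearest start is an LTR, or that lies inside an
    LTR interval, is LTR-flagged, and the flag propagates to all of its gene
    associations for downstream filtering."""
    by_chrom: dict[str, list[FeatureStart]] = {}
    for f in feature_starts:
        by_chrom.setdefault(f.chrom, []).append(f)

    out: list[Association] = []
    for peak in peaks:
        nearby = [
            (abs(peak.point - f.pos), f)
            for f in by_chrom.get(peak.chrom, [])
            if abs(peak.point - f.pos) <= window
        ]
        if not nearby:
            continue
        nearest = min(nearby, key=lambda t: (t[0], t[1].feature_type))
        inside_ltr = any(
            r.chrom == peak.chrom and r.start <= peak.point < r.end
            for r in ltr_intervals
        )
        ltr = nearest[1].feature_type == "LTR" or inside_ltr
        for dist, f in sorted(nearby, key=lambda t: (t[0], t[1].feature_id)):
            out.append(Association(peak.peak_id, f.feature_id, f.feature_type, dist, ltr))
    return out


def gene_peak_stats(
    associations: TypingSequence[Association],
    peaks: TypingSequence[PeakRecord],
) -> pd.DataFrame:
    """Per-gene statistics from each gene's most significant peak.

    The minimum-logQ peak wins; ties break by higher total occupancy, then by
    leftmost coordinate, so the result is invariant to input order.  Genes
    with any LTR-flagged association are marked ``ltr_flag`` for filtering.
    """
    by_id = {p.peak_id: p for p in peaks}
    gene_peaks: dict[str, set[str]] = {}
    gene_ltr: dict[str, bool] = {}
    for a in associations:
        if a.feature_type != "gene":
            continue
        gene_peaks.setdefault(a.feature_id, set()).add(a.peak_id)
        gene_ltr[a.feature_id] = gene_ltr.get(a.feature_id, False) or a.ltr_flag

    rows = []
    for gene in sorted(gene_peaks):
        cands = [by_id[pid] for pid in gene_peaks[gene]]
        win = min(
            cands,
            key=lambda p: (p.logQ, -sum(p.occupancy_rpm.values()), p.point, p.peak_id),
        )
        row = {
            "gene": gene,
            "peak_id": win.peak_id,
            "chrom": win.chrom,
            "point": win.point,
            "logQ": win.logQ,
            "n_peaks": len(cands),
            "ltr_flag": gene_ltr[gene],
            "log2_occ_fc": win.log2_occ_fc,
        }
        for cond, v in win.occupancy_rpm.items():
            row[f"occ_{cond}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()


def occupancy_rpm(
    tag_coverage: pd.DataFrame | TypingSequence[pd.DataFrame],
    region: GenomicRegion,
    library_scale: float,
) -> float:
    """Tag count over ``region`` summed across the supplied per-strand tracks,
    divided by ``library_scale`` (total tags / 1e6).

    Tracks are bedGraph frames (chrom/start/end/value).  When replicates are
    pooled their tracks are summed before a single scaling.
    """
    if library_scale <= 0:
        raise ValueError("library scale must be > 0")
    tracks = [tag_coverage] if isinstance(tag_coverage, pd.DataFrame) else list(tag_coverage)
    total = 0.0
    for track in tracks:
        sel = track[track["chrom"] == region.chrom]
        if sel.empty:
            continue
        overlap = (
            np.minimum(sel["end"], region.end) - np.maximum(sel["start"], region.start)
        ).clip(lower=0)
        total += float((sel["value"] * overlap).sum())
    return total / library_scale


def compare_occupancy(
    group_a: TypingSequence[float],
    group_b: TypingSequence[float],
    ci_method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Group means with 95% CIs and a two-sided Mann-Whitney test.

    The exact enumeration path is used for n_a + n_b <= 20, otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = mann_whitney(a, b, mode="auto")
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "ci95_a": _ci95(a, ci_method, n_boot, seed),
        "ci95_b": _ci95(b, ci_method, n_boot, seed + 1),
        "U": u,
        "p": p,
    }


def _ci95(x: np.ndarray, method: str, n_boot: int, seed: int) -> tuple[float, float]:
    if x.size == 1:
        return (float(x[0]), float(x[0]))
    if method == "t":
        sem = x.std(ddof=1) / np.sqrt(x.size)
        half = sps.t.ppf(0.975, x.size - 1) * sem
        return (float(x.mean() - half), float(x.mean() + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


def occupancy_vs_mismatch(
    occupancies: TypingSequence[float],
    categories: TypingSequence[str],
) -> tuple[dict[str, list[float]], pd.DataFrame]:
    """Occupancy distributions keyed by mismatch category, with pairwise
    Mann-Whitney tests BH-corrected across all category pairs.

    Returns (distributions, tests) where tests has one row per category pair
    with U, raw p, and BH-adjusted q; with fewer than two categories the test
    table is empty.
    """
    if len(occupancies) != len(categories):
        raise ValueError("occupancies and categories must align")
    dists: dict[str, list[float]] = {}
    for occ, cat in zip(occupancies, categories):
        dists.setdefault(cat, []).append(float(occ))

    cats = sorted(dists)
    rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            u, p = mann_whitney(dists[cats[i]], dists[cats[j]], mode="auto")
            rows.append({"cat_a": cats[i], "cat_b": cats[j], "U": u, "p": p})
    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["q"] = bh_adjust(tests["p"].to_numpy())
    return dists, tests
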