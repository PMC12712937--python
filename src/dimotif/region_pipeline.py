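"""Region preparation around binding sites and per-region di-motif summaries.

Binding sites called from ChIP-exo come in as point coordinates.  Each point
is expanded to a symmetric window (point +/- half_width, 241 bp at the
default half_width of 120); nearby sites are merged into one region to avoid
scanning duplicated sequence.  Every region is scanned for all PRE di-motif
configurations, matches are pooled for one Benjamini-Hochberg family, and
each region is assigned a best match by lowest q-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TypingSequence

import pandas as pd

from .io_formats import GenomicRegion, Sequence
from .motif_core import (
    DiMotifConfig,
    DiMotifMatch,
    PAIR_WIDTH,
    assign_qvalues,
    best_match,
    revcomp,
    _rank_key,
)

__all__ = [
    "SiteRecord",
    "RegionBest",
    "prepare_regions",
    "extract_sequence",
    "scan_region_set",
    "config_histogram",
    "topk_contains",
    "curated_ht4_filter",
    "mismatch_spectrum",
]


@dataclass(frozen=True)
class SiteRecord:
    """A called binding site: a point coordinate with occupancy and
    significance statistics from the peak caller (consumed, not computed)."""

    chrom: str
    point: int
    region_id: str
    occupancy_rpm: float = 0.0
    logQ: float = 0.0  # log2 Q-value; more negative = more significant

    def __post_init__(self) -> None:
        if self.occupancy_rpm < 0:
            raise ValueError("occupancy must be >= 0")


@dataclass
class RegionBest:
    """Scan summary for one region: its best match, the per-configuration
    ranking (one entry per configuration, that configuration's best match),
    and all matches surviving the p filter."""

    region_id: str
    best: DiMotifMatch | None
    ranked_configs: list[tuple[DiMotifConfig, float]]
    matches: list[DiMotifMatch] = field(default_factory=list)


def prepare_regions(
    sites: TypingSequence[SiteRecord],
    half_width: int,
    merge_gap: int = 60,
    genome: Mapping[str, str] | Mapping[str, int] | None = None,
) -> list[GenomicRegion]:
    """Expand site points to [point - half_width, point + half_width + 1) and
    merge runs of sites within ``merge_gap`` of each other on one chromosome
    into a single region (half_width upstream of the first to half_width
    downstream of the last).  Regions are clamped to chromosome bounds."""
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    lengths = _chrom_lengths(genome)
    ordered = sorted(sites, key=lambda s: (s.chrom, s.point))
    regions: list[GenomicRegion] = []
    i = 0
    while i < len(ordered):
        j = i
        while (
            j + 1 < len(ordered)
            and ordered[j + 1].chrom == ordered[j].chrom
            and ordered[j + 1].point - ordered[j].point <= merge_gap
        ):
            j += 1
        first, last = ordered[i], ordered[j]
        chrom_len = lengths.get(first.chrom)
        if chrom_len is not None and last.point >= chrom_len:
            raise ValueError(
                f"site {last.region_id!r} at {last.point} beyond end of "
                f"{first.chrom} (length {chrom_len})"
            )
        start = max(0, first.point - half_width)
        end = last.point + half_width + 1
        if chrom_len is not None:
            end = min(end, chrom_len)
        rid = first.region_id if i == j else "+".join(
            s.region_id for s in ordered[i:j + 1]
        )
        regions.append(GenomicRegion(first.chrom, start, end, rid))
        i = j + 1
    return regions


def _chrom_lengths(genome) -> dict[str, int]:
    if genome is None:
        return {}
    out = {}
    for chrom, v in genome.items():
        out[chrom] = v if isinstance(v, int) else len(v)
    return out


def extract_sequence(region: GenomicRegion, genome: Mapping[str, str]) -> Sequence:
    chrom = genome[region.chrom]
    bases = chrom.bases if isinstance(chrom, Sequence) else chrom
    return Sequence(region.id, bases[region.start:region.end].upper())


def scan_region_set(
    regions: TypingSequence[GenomicRegion],
    genome: Mapping[str, str],
    configs: TypingSequence[DiMotifConfig],
    max_mm_per_pre: int = 2,
    match_p_threshold: float = 0.01,
    background: TypingSequence[float] | None = None,
) -> list[RegionBest]:
    """Scan every region, pool all matches into one BH family, and assign each
    region its best match.  Regions with no surviving match keep
    ``best=None`` and stay in downstream denominators."""
    from .motif_core import scan_dimotifs

    per_region: dict[str, list[DiMotifMatch]] = {r.id: [] for r in regions}
    pooled: list[DiMotifMatch] = []
    for region in regions:
        if len(region) < PAIR_WIDTH:
            raise ValueError(f"region {region.id!r} shorter than 14 bp template")
        seq = extract_sequence(region, genome)
        pooled.extend(
            scan_dimotifs(seq, configs, max_mm_per_pre, background, region.id)
        )
    if pooled:
        pooled = assign_qvalues(pooled)
    for m in pooled:
        per_region[m.region_id].append(m)

    out = []
    for region in regions:
        matches = [
            m for m in per_region[region.id] if m.p <= match_p_threshold
        ]
        per_config: dict[DiMotifConfig, DiMotifMatch] = {}
        for m in matches:
            cur = per_config.get(m.config)
            if cur is None or _rank_key(m) < _rank_key(cur):
                per_config[m.config] = m
        ranked = sorted(per_config.values(), key=_rank_key)
        out.append(
            RegionBest(
                region_id=region.id,
                best=best_match(matches, match_p_threshold) if matches else None,
                ranked_configs=[(m.config, m.q) for m in ranked],
                matches=matches,
            )
        )
    return out


def config_histogram(
    region_bests: Iterable[RegionBest],
) -> dict[DiMotifConfig, int]:
    """Counts of best-match configurations over regions with a best match."""
    counts: dict[DiMotifConfig, int] = {}
    for rb in region_bests:
        if rb.best is not None:
            counts[rb.best.config] = counts.get(rb.best.config, 0) + 1
    return counts


def topk_contains(region_best: RegionBest, config: DiMotifConfig, k: int = 5) -> bool:
    """True iff ``config`` is among the k lowest-q configurations of the
    region (one entry per configuration)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return config in {c for c, _ in region_best.ranked_configs[:k]}


HT4 = DiMotifConfig("HT", 4)


def curated_ht4_filter(
    region_bests: TypingSequence[RegionBest],
    sites: TypingSequence[SiteRecord],
    regions: TypingSequence[GenomicRegion],
    genome: Mapping[str, str],
    max_mm_per_pre: int = 2,
    max_center_dist: int = 100,
) -> list[tuple[str, str, DiMotifMatch]]:
    """One curated 18-mer H-T 4 match per site.

    Among a site's H-T 4 matches whose template center lies within
    ``max_center_dist`` of the site point and whose PREs each carry at most
    ``max_mm_per_pre`` mismatches, the best-ranked one is kept; sites with no
    qualifying match contribute nothing.  Returned sequences are oriented so
    both PRE slots read in consensus direction.
    """
    by_id = {rb.region_id: rb for rb in region_bests}
    region_by_id = {r.id: r for r in regions}
    out = []
    for site in sites:
        region = _region_of(site, regions)
        if region is None or region.id not in by_id:
            continue
        rb = by_id[region.id]
        width = HT4.width  # 18
        candidates = []
        for m in rb.matches:
            if m.config != HT4 or m.m1 > max_mm_per_pre or m.m2 > max_mm_per_pre:
                continue
            g_start = _top_strand_start(m, region)
            center = g_start + width / 2.0
            if abs(center - (site.point + 0.5)) <= max_center_dist:
                candidates.append((m, g_start))
        if not candidates:
            continue
        m, g_start = min(candidates, key=lambda t: _rank_key(t[0]))
        chrom = genome[region.chrom]
        bases = chrom.bases if isinstance(chrom, Sequence) else chrom
        sub = bases[g_start:g_start + width].upper()
        if m.strand == "-":
            sub = revcomp(sub)
        out.append((site.region_id, sub, m))
    return out


def _region_of(site: SiteRecord, regions) -> GenomicRegion | None:
    for r in regions:
        if r.chrom == site.chrom and r.start <= site.point < r.end:
            return r
    return None


def _top_strand_start(m: DiMotifMatch, region: GenomicRegion) -> int:
    """Genomic top-strand start coordinate of a match template."""
    width = m.config.width
    if m.strand == "+":
        return region.start + m.start
    return region.start + (len(region) - m.start - width)


def mismatch_spectrum(
    categories: TypingSequence[str],
    class_labels: TypingSequence[str],
) -> pd.DataFrame:
    """Fraction of sites per mismatch category, normalized independently
    within each class (rows are classes and sum to 1)."""
    if len(categories) != len(class_labels):
        raise ValueError("categories and class labels must align")
    if any(lbl is None or lbl == "" for lbl in class_labels):
        raise ValueError("every match needs a class label")
    df = pd.DataFrame({"category": categories, "label": class_labels})
    counts = df.groupby(["label", "category"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
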