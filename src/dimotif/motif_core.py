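"""The PRE di-motif model.

Ste12 binds the pheromone response element (PRE), optimally the 7-mer
5'-TGAAACA-3', and can bind cooperatively to a pair of PREs.  A *di-motif
configuration* is an orientation (head-to-head, head-to-tail, tail-to-tail)
plus an unconstrained spacer of s nucleotides between the two 7-mer slots.
On the top strand the templates are

    HT: TGAAACA . N^s . TGAAACA      (genuinely stranded)
    TT: TGTTTCA . N^s . TGAAACA      (reverse-complement invariant)
    HH: TGAAACA . N^s . TGTTTCA      (reverse-complement invariant)

This module enumerates configurations, scans sequences for di-motif matches
with per-PRE mismatch accounting, attaches match significance, ranks matches,
and provides the PSPM/PSAM motif-matrix utilities used downstream.

Match significance is an exact match-count tail probability: the chance that
an iid-background 14-position slot pair matches the template in at least as
many positions as the observed match, computed by convolving the per-position
Bernoulli match indicators.  This preserves the mismatch-count ranking that
drives best-match assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import Sequence

PRE = "TGAAACA"
PRE_RC = "TGTTTCA"
PRE_WIDTH = 7
PAIR_WIDTH = 2 * PRE_WIDTH

_COMP = str.maketrans("ACGTN", "TGCAN")
_ENCODE = {c: i for i, c in enumerate("ACGTN")}

# upstream-slot / downstream-slot 7-mers on the scanned strand, per orientation
ORIENT_SLOTS = {
    "HH": (PRE, PRE_RC),
    "HT": (PRE, PRE),
    "TT": (PRE_RC, PRE),
}

__all__ = [
    "PRE", "PRE_RC", "DiMotifConfig", "DiMotifMatch", "PSPM", "PSAM",
    "revcomp", "enumerate_configs", "mismatches", "scan_dimotifs",
    "match_pvalue", "assign_qvalues", "best_match", "mismatch_category",
    "find_perfect_pre", "build_count_matrix", "pspm_to_psam",
    "read_meme", "write_meme",
]


@dataclass(frozen=True, order=True)
class DiMotifConfig:
    """One PRE-pair configuration: orientation plus spacer length."""

    orientation: str
    spacing: int

    def __post_init__(self) -> None:
        if self.orientation not in ORIENT_SLOTS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")

    @property
    def width(self) -> int:
        return PAIR_WIDTH + self.spacing

    @property
    def slots(self) -> tuple[str, str]:
        return ORIENT_SLOTS[self.orientation]

    def label(self) -> str:
        return f"{self.orientation[0]}-{self.orientation[1]} {self.spacing}"


@dataclass(frozen=True)
class DiMotifMatch:
    """A scored occurrence of a di-motif configuration in one region.

    ``start`` is the 0-based offset of the template on the match strand;
    ``m1``/``m2`` count consensus mismatches of the upstream/downstream PRE
    slot (N counts as a mismatch; spacer bases are unconstrained).
    """

    region_id: str
    strand: str
    start: int
    config: DiMotifConfig
    m1: int
    m2: int
    p: float
    q: float = math.nan

    @property
    def total_mm(self) -> int:
        return self.m1 + self.m2

    def category(self) -> str:
        return mismatch_category(self.m1, self.m2)


def revcomp(seq: str | Sequence) -> str | Sequence:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    if isinstance(seq, Sequence):
        return Sequence(seq.id, revcomp(seq.bases))
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.upper().translate(_COMP)[::-1]


def enumerate_configs(max_spacing: int = 100) -> list[DiMotifConfig]:
    """All 3 * (max_spacing + 1) configurations, HH < HT < TT then spacing."""
    if max_spacing < 0:
        raise ValueError("max_spacing must be >= 0")
    return [
        DiMotifConfig(o, s)
        for o in ("HH", "HT", "TT")
        for s in range(max_spacing + 1)
    ]


def mismatches(window: str, expected: str = PRE) -> int:
    """Hamming distance between a 7-mer window and an expected 7-mer; N mismatches."""
    if len(window) != PRE_WIDTH or len(expected) != PRE_WIDTH:
        raise ValueError("mismatches() compares 7-mers")
    return sum(a != b or a == "N" for a, b in zip(window.upper(), expected))


def _encode(bases: str) -> np.ndarray:
    return np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()


_CODE = np.full(256, -1, dtype=np.int8)
for _c, _i in _ENCODE.items():
    _CODE[ord(_c)] = _i
_N_CODE = _ENCODE["N"]


def _mismatch_profile(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Per-offset Hamming distance of every 7-mer window to ``pattern``."""
    if len(codes) < PRE_WIDTH:
        return np.zeros(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, PRE_WIDTH)
    pat = np.array([_ENCODE[c] for c in pattern], dtype=np.int8)
    return ((win != pat) | (win == _N_CODE)).sum(axis=1)


def scan_dimotifs(
    seq: Sequence,
    configs: TypingSequence[DiMotifConfig],
    max_mm_per_pre: int = 2,
    background: TypingSequence[float] | None = None,
    region_id: str | None = None,
) -> list[DiMotifMatch]:
    """Report every (config, offset, strand) whose two PRE slots each carry at
    most ``max_mm_per_pre`` mismatches.

    HT is scanned on both strands; HH and TT templates are reverse-complement
    invariant and are scanned once, reported on '+'.  Spacer content is
    ignored.  Each match carries the exact match-count p-value for its
    orientation and mismatch total under ``background`` (uniform by default).
    """
    if len(seq.bases) < PAIR_WIDTH:
        raise ValueError("sequence shorter than the minimal 14 bp template")
    if not configs:
        raise ValueError("no configurations supplied")
    if not 0 <= max_mm_per_pre <= 3:
        raise ValueError("max_mm_per_pre must be in [0, 3]")
    bg = _check_background(background)
    rid = region_id if region_id is not None else seq.id

    strands = {"+": seq.bases, "-": revcomp(seq.bases)}
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for strand, bases in strands.items():
        codes = _CODE[_encode(bases)]
        profiles[(strand, PRE)] = _mismatch_profile(codes, PRE)
        profiles[(strand, PRE_RC)] = _mismatch_profile(codes, PRE_RC)

    out: list[DiMotifMatch] = []
    pcache: dict[tuple[str, int], float] = {}
    for config in configs:
        up_pat, dn_pat = config.slots
        scan_strands = ("+", "-") if config.orientation == "HT" else ("+",)
        for strand in scan_strands:
            up = profiles[(strand, up_pat)]
            dn = profiles[(strand, dn_pat)]
            shift = PRE_WIDTH + config.spacing
            n_off = len(up) - shift
            if n_off <= 0:
                continue
            m1 = up[:n_off]
            m2 = dn[shift:shift + n_off]
            hits = np.nonzero((m1 <= max_mm_per_pre) & (m2 <= max_mm_per_pre))[0]
            for i in hits:
                a, b = int(m1[i]), int(m2[i])
                key = (config.orientation, a + b)
                if key not in pcache:
                    pcache[key] = match_pvalue(
                        a, b, background=bg, template=up_pat + dn_pat
                    )
                out.append(
                    DiMotifMatch(rid, strand, int(i), config, a, b, pcache[key])
                )
    return out


def _check_background(background: TypingSequence[float] | None) -> tuple[float, ...]:
    if background is None:
        return (0.25, 0.25, 0.25, 0.25)
    bg = tuple(float(x) for x in background)
    if len(bg) != 4 or any(x < 0 for x in bg) or abs(sum(bg) - 1.0) > 1e-9:
        raise ValueError("background must be 4 probabilities summing to 1")
    return bg


@lru_cache(maxsize=4096)
def _match_count_tail(pis: tuple[float, ...], min_matches: int) -> float:
    """P(#matching positions >= min_matches) for independent Bernoulli(pi_j)."""
    dist = np.array([1.0])
    for pi in pis:
        dist = np.convolve(dist, [1.0 - pi, pi])
    return float(dist[min_matches:].sum())


def match_pvalue(
    m1: int,
    m2: int,
    background: TypingSequence[float] | None = None,
    template: str = PRE + PRE,
) -> float:
    """Tail probability that a random slot pair matches ``template`` in at
    least ``len(template) - m1 - m2`` positions under an iid background.

    The spacer is excluded: only the two 7-mer slots (concatenated into
    ``template``) are scored.  Computed by exact convolution of the
    per-position match indicators pi_j = background[template_j].
    """
    if m1 < 0 or m2 < 0:
        raise ValueError("mismatch counts must be >= 0")
    if m1 + m2 > len(template):
        raise ValueError("total mismatches exceed template width")
    bg = _check_background(background)
    pis = tuple(bg[_ENCODE[c]] for c in template.upper())
    return _match_count_tail(pis, len(template) - (m1 + m2))


def assign_qvalues(matches: list[DiMotifMatch]) -> list[DiMotifMatch]:
    """Benjamini-Hochberg adjust the p-values of one region-set scan.

    The family is all matches passed in one call (one scan invocation).
    """
    if not matches:
        raise ValueError("no matches to adjust")
    ps = np.array([m.p for m in matches])
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    return [replace(m, q=float(q)) for m, q in zip(matches, qs)]


_STRAND_ORDER = {"+": 0, "-": 1}


def _rank_key(m: DiMotifMatch):
    return (m.q, m.total_mm, m.config.spacing, m.start, _STRAND_ORDER[m.strand])


def best_match(
    matches: Iterable[DiMotifMatch], p_threshold: float = 0.01
) -> DiMotifMatch | None:
    """The minimum-q match among those with p <= p_threshold, or None.

    Ties on q break by smaller total mismatches, then smaller spacing, then
    leftmost start, then '+' before '-'.
    """
    surviving = [m for m in matches if m.p <= p_threshold]
    if not surviving:
        return None
    if any(math.isnan(m.q) for m in surviving):
        raise ValueError("q-values missing; run assign_qvalues first")
    return min(surviving, key=_rank_key)


def mismatch_category(m1: int, m2: int) -> str:
    """Order-invariant mismatch-pair label, e.g. (2, 1) -> '1_2'."""
    if m1 < 0 or m2 < 0:
        raise ValueError("mismatch counts must be >= 0")
    lo, hi = sorted((m1, m2))
    return f"{lo}_{hi}"


def find_perfect_pre(seq: str | Sequence) -> list[tuple[int, str]]:
    """All exact TGAAACA occurrences on both strands.

    Minus-strand occurrences (TGTTTCA on the top strand) are reported at
    their top-strand coordinates.
    """
    bases = seq.bases if isinstance(seq, Sequence) else seq.upper()
    hits = [(i, "+") for i in _find_all(bases, PRE)]
    hits += [(i, "-") for i in _find_all(bases, PRE_RC)]
    return sorted(hits)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


@dataclass(frozen=True)
class PSPM:
    """Position-specific probability matrix: W x 4 columns over A, C, G, T."""

    name: str
    probs: np.ndarray  # shape (W, 4), rows sum to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("PSPM must be a W x 4 matrix")
        if not 1 <= p.shape[0] <= 24:
            raise ValueError("PSPM width must be in [1, 24]")
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PSPM rows must be probabilities summing to 1")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray,
                    pseudocount: float = 0.0) -> "PSPM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, c / c.sum(axis=1, keepdims=True))


@dataclass(frozen=True)
class PSAM:
    """Position-specific affinity matrix: per-position max affinity is 1."""

    name: str
    affinities: np.ndarray  # shape (W, 4), entries in [0, 1], row max == 1

    def __post_init__(self) -> None:
        a = np.asarray(self.affinities, dtype=float)
        if a.ndim != 2 or a.shape[1] != 4:
            raise ValueError("PSAM must be a W x 4 matrix")
        if np.any(a < 0) or np.any(a > 1 + 1e-12):
            raise ValueError("PSAM affinities must lie in [0, 1]")
        if np.any(np.abs(a.max(axis=1) - 1.0) > 1e-9):
            raise ValueError("each PSAM position must have max affinity 1")
        object.__setattr__(self, "affinities", a)

    @property
    def width(self) -> int:
        return self.affinities.shape[0]


def build_count_matrix(aligned: TypingSequence[str]) -> np.ndarray:
    """Per-position base counts (L x 4, A/C/G/T) for equal-length aligned sites.

    Inputs must already be oriented so both PRE slots read in consensus
    direction; column sums equal the number of input sequences.
    """
    if not aligned:
        raise ValueError("no sequences")
    L = len(aligned[0])
    if any(len(s) != L for s in aligned):
        raise ValueError("aligned sequences must be equal length")
    counts = np.zeros((L, 4), dtype=np.int64)
    for s in aligned:
        codes = _CODE[_encode(s.upper())]
        if np.any(codes < 0):
            raise ValueError(f"illegal character in {s!r}")
        for j, c in enumerate(codes):
            if c < 4:  # N contributes to no base column
                counts[j, c] += 1
    return counts


def pspm_to_psam(pspm: PSPM, epsilon: float = 0.0) -> PSAM:
    """Convert probabilities to relative affinities:
    A_j(b) = (p_j(b) + eps) / max_b (p_j(b) + eps)."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    p = pspm.probs + epsilon
    mx = p.max(axis=1, keepdims=True)
    if np.any(mx == 0):
        raise ValueError("zero column; use epsilon > 0")
    a = p / mx
    if epsilon == 0 and np.any(a == 0):
        import warnings

        warnings.warn(f"PSAM {pspm.name!r} has zero affinities (epsilon=0)")
    return PSAM(pspm.name, a)


def write_meme(motifs: TypingSequence[PSPM], path, background=None) -> None:
    """Write PSPMs in MEME minimal motif format."""
    bg = _check_background(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            # large nsites: readers that reconstruct counts keep full precision
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in m.probs:
                fh.write(" " + "  ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PSPM]:
    """Read PSPMs from a MEME minimal motif file (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        pwm = rec.counts.normalize()
        mat = np.array([[pwm[b][j] for b in "ACGT"] for j in range(rec.length)])
        out.append(PSPM(rec.name, mat))
    return out
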