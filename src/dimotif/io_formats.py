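"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are held 0-based half-open internally.  GFF3 input
(1-based, closed) is converted at the boundary; BED passes through unchanged.
Sequences are normalized to uppercase over the alphabet {A, C, G, T, N};
IUPAC ambiguity codes other than N are collapsed to N with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
# IUPAC one-letter codes that legally appear in DNA FASTA but that we collapse.
_AMBIGUITY = frozenset("RYSWKMBDHVU")

__all__ = [
    "Sequence",
    "GenomicRegion",
    "FeatureStart",
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "write_intervals",
    "read_feature_starts",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A, C, G, T, N}, uppercase."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.id!r}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region {self.id!r}: end {self.end} must exceed start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureStart:
    """An annotated feature start point (gene or LTR), 0-based.

    For minus-strand features the start is the rightmost genomic coordinate,
    i.e. the transcription start in promoter-facing orientation.
    """

    chrom: str
    pos: int
    strand: str
    feature_id: str
    feature_type: str  # "gene" or "LTR"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"feature {self.feature_id!r}: unknown strand {self.strand!r}"
            )
        if self.feature_type not in ("gene", "LTR"):
            raise ValueError(
                f"feature {self.feature_id!r}: unknown type {self.feature_type!r}"
            )


def _normalize_bases(raw: str, label: str) -> str:
    up = raw.upper()
    if set(up) <= ALPHABET:
        return up
    ambig = set(up) & _AMBIGUITY
    if ambig:
        warnings.warn(
            f"sequence {label!r}: ambiguity codes {sorted(ambig)} collapsed to N",
            stacklevel=3,
        )
        up = "".join("N" if c in _AMBIGUITY else c for c in up)
    return up  # Sequence.__post_init__ rejects anything still illegal


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into normalized :class:`Sequence` records, in order."""
    with open(path) as fh:
        records = [
            Sequence(rec.id, _normalize_bases(str(rec.seq), rec.id))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs),
        str(path),
        "fasta",
    )


def read_intervals(path: str | Path, dialect: str = "bed") -> list[GenomicRegion]:
    """Read an interval table.

    ``bed``: 0-based half-open, columns chrom/start/end[/name], no header.
    ``tsv``: header row ``chrom  start  end  [id]``; an optional first line
    ``#coords=1-closed`` (or ``0-half-open``, the default) declares the base.
    """
    path = Path(path)
    if dialect == "bed":
        ncols = _ncols(path)
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "id", "score", "strand"][:ncols],
        )
    elif dialect == "tsv":
        with open(path) as fh:
            first = fh.readline().strip()
        one_based = False
        skip = 0
        if first.startswith("#coords="):
            one_based = "1-closed" in first
            skip = 1
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        offset = 1 if one_based else 0
        if one_based:
            # 1-based closed [start, end] -> 0-based half-open [start-1, end)
            df["start"] = df["start"] - offset
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    regions = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(getattr(row, "id", "")) if hasattr(row, "id") else ""
        if name in ("", "nan"):
            name = f"region_{i}"
        regions.append(GenomicRegion(str(row.chrom), int(row.start), int(row.end), name))
    return regions


def _ncols(path: Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.rstrip("\n").split("\t")), 6)
    raise ValueError(f"no data lines in {path}")


def write_intervals(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


_GFF_LTR_TYPES = {"long_terminal_repeat", "LTR_retrotransposon", "LTR"}


def read_feature_starts(path: str | Path) -> list[FeatureStart]:
    """Read gene and LTR start points from a GFF3 subset or a tabular file.

    GFF3 rows are 1-based closed; the returned positions are 0-based, and for
    minus-strand features the start is the rightmost coordinate.  A tabular
    file (header ``chrom  pos  strand  feature_id  feature_type``) is taken as
    already 0-based.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or len(head.rstrip("\n").split("\t")) == 9:
        return _read_gff_starts(path)
    df = pd.read_csv(path, sep="\t")
    return [
        FeatureStart(str(r.chrom), int(r.pos), str(r.strand),
                     str(r.feature_id), str(r.feature_type))
        for r in df.itertuples(index=False)
    ]


def _read_gff_starts(path: Path) -> list[FeatureStart]:
    out: list[FeatureStart] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF row: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype == "gene":
                feature_type = "gene"
            elif ftype in _GFF_LTR_TYPES:
                feature_type = "LTR"
            else:
                continue
            fid = _gff_attr(attrs, "ID") or _gff_attr(attrs, "Name") or f"{ftype}:{start}"
            pos = int(start) - 1 if strand == "+" else int(end) - 1
            out.append(FeatureStart(chrom, pos, strand, fid, feature_type))
    return out


def _gff_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        if item.startswith(f"{key}="):
            return item[len(key) + 1:]
    return None


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph track into columns chrom/start/end/value (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError(f"invalid intervals in bedGraph {path}")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )
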