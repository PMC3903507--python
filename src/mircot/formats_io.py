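"""Readers/writers for the standard formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open; GFF3/BED
boundaries convert to/from their native conventions at read/write time.
Sequences are stored DNA-style (T, never U); ``normalize_seq`` folds U->T.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

VALID_CATEGORIES = frozenset(
    {"known_mirna", "rrna", "trna", "repeat", "coding", "other"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and fold RNA U into internal T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Display form: internal T shown as U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Malformed FASTQ/FASTA record; message names the offending line."""


@dataclass
class RawRead:
    """A single sequencing read as it comes off the instrument."""

    sequence: str
    library_id: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("read sequence must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length differs from sequence length")


@dataclass
class CollapsedRead:
    """A unique small-RNA species with per-library read counts.

    The atomic unit of all downstream accounting: every count reported by
    the pipeline is a sum over CollapsedRead counts, never a re-count of
    raw reads.
    """

    sequence: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if "N" in self.sequence:
            raise ValueError("collapsed reads must not contain N")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative library count")
        if self.total_count < 1:
            raise ValueError("total_count must be >= 1")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def n_libraries(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    category: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class AnnotationTrack:
    """Genomic intervals with a category, plus optional mature sequences
    (exact known-miRNA identity is sequence-based, not positional)."""

    intervals: list[Interval] = field(default_factory=list)
    mature_sequences: Optional[dict[str, str]] = None

    def validate_against(self, lengths: dict[str, int]) -> None:
        for iv in self.intervals:
            if iv.chrom not in lengths:
                raise ValueError(f"interval on unknown chromosome {iv.chrom}")
            if iv.end > lengths[iv.chrom]:
                raise ValueError(f"interval {iv} exceeds chromosome length")

    def by_category(self, category: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.category == category]


# ---------------------------------------------------------------------------
# FASTQ / FASTA reading


def _read_fastq_records(path, library_id: str) -> Iterator[RawRead]:
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.strip():
                continue  # tolerate trailing blank lines
            if not header.startswith("@"):
                raise FastqParseError(
                    f"line {lineno}: expected '@' header, got {header.strip()[:30]!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError(
                    f"line {lineno}: truncated FASTQ record starting here"
                )
            lineno += 3
            seq = seq.strip().upper()
            qual = qual.strip()
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield RawRead(sequence=normalize_seq(seq), library_id=library_id, quality=qual)


def _read_fasta_records(path, library_id: str) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield RawRead(sequence=normalize_seq(str(rec.seq)), library_id=library_id)


def read_fastq(path, library_id: str) -> Iterator[RawRead]:
    """Stream RawReads from a FASTQ (4-line records) or FASTA file.

    The format is sniffed from the first non-blank character ('>' means
    FASTA). Records are yielded in file order with library_id attached.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
    if not first:
        return iter(())
    if first == ">":
        return _read_fasta_records(path, library_id)
    return _read_fastq_records(path, library_id)


# ---------------------------------------------------------------------------
# Read collapsing


def collapse_reads(reads: Iterable[RawRead]) -> list[CollapsedRead]:
    """Collapse raw reads into unique species with per-library counts.

    Output is ordered by descending total count, ties broken
    lexicographically by sequence, so the result is deterministic for a
    fixed input multiset regardless of input order.
    """
    table: dict[str, Counter] = {}
    for read in reads:
        if "N" in read.sequence:
            raise ValueError(
                "read containing N reached collapse_reads; run QC first"
            )
        table.setdefault(read.sequence, Counter())[read.library_id] += 1
    collapsed = [
        CollapsedRead(sequence=seq, counts=dict(cnt)) for seq, cnt in table.items()
    ]
    collapsed.sort(key=lambda cr: (-cr.total_count, cr.sequence))
    return collapsed


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path) -> None:
    """Write species as FASTA; header carries counts as
    ``sp000001 total=N lib1=a lib2=b``."""
    with open(path, "w") as fh:
        for i, cr in enumerate(collapsed, start=1):
            libs = " ".join(f"{lib}={n}" for lib, n in sorted(cr.counts.items()))
            fh.write(f">sp{i:06d} total={cr.total_count} {libs}\n{cr.sequence}\n")


def read_collapsed_fasta(path) -> list[CollapsedRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        counts = {}
        for tok in rec.description.split()[1:]:
            key, _, val = tok.partition("=")
            if key != "total":
                counts[key] = int(val)
        out.append(CollapsedRead(sequence=normalize_seq(str(rec.seq)), counts=counts))
    return out


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffFeature:
    """One GFF3 feature, held with 0-based half-open coordinates."""

    chrom: str
    type: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"
    source: str = "mircot"
    score: Optional[float] = None
    phase: Optional[int] = None
    attributes: dict[str, str] = field(default_factory=dict)


def _esc(value: str) -> str:
    return re.sub(r"[;=&,\t\n]", lambda m: "%%%02X" % ord(m.group()), str(value))


def _unesc(value: str) -> str:
    return re.sub(r"%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), value)


def write_gff3(
    features: Iterable[GffFeature],
    path,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write GFF3 (1-based inclusive on disk). If ``chrom_lengths`` is
    given, coordinates are validated against it and sequence-region
    pragmas are emitted."""
    features = list(features)
    if chrom_lengths is not None:
        for f in features:
            if f.chrom not in chrom_lengths:
                raise ValueError(f"feature on unknown chromosome {f.chrom}")
            if f.end > chrom_lengths[f.chrom]:
                raise ValueError(f"feature end {f.end} beyond {f.chrom} length")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths is not None:
            for chrom, length in sorted(chrom_lengths.items()):
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for f in features:
            attrs = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        f.source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        "." if f.score is None else f"{f.score:g}",
                        f.strand,
                        "." if f.phase is None else str(f.phase),
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GffFeature]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
            attrs = {}
            if cols[8] not in (".", ""):
                for pair in cols[8].split(";"):
                    if not pair:
                        continue
                    key, _, val = pair.partition("=")
                    attrs[_unesc(key)] = _unesc(val)
            out.append(
                GffFeature(
                    chrom=cols[0],
                    source=cols[1],
                    type=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    score=None if cols[5] == "." else float(cols[5]),
                    phase=None if cols[7] == "." else int(cols[7]),
                    attributes=attrs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED6 annotation tracks


def read_bed6(path, category: str = "other") -> AnnotationTrack:
    """Read a BED6 file as an AnnotationTrack. The feature name column may
    carry a category override as ``name|category``."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"line {lineno}: BED6 needs 6 columns")
            name, _, cat = cols[3].partition("|")
            intervals.append(
                Interval(
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5],
                    category=cat or category,
                    name=name,
                )
            )
    return AnnotationTrack(intervals=intervals)


def track_from_gff3(path, category_map: Optional[dict[str, str]] = None) -> AnnotationTrack:
    """Build an AnnotationTrack from GFF3; feature types are mapped to
    categories via ``category_map`` (defaults to identity for valid
    categories, 'other' otherwise)."""
    intervals = []
    for f in read_gff3(path):
        if category_map and f.type in category_map:
            cat = category_map[f.type]
        elif f.type in VALID_CATEGORIES:
            cat = f.type
        else:
            cat = "other"
        intervals.append(
            Interval(
                chrom=f.chrom,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                category=cat,
                name=f.attributes.get("Name", f.attributes.get("ID", "")),
            )
        )
    return AnnotationTrack(intervals=intervals)
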