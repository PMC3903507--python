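"""Exact (0-mismatch) read mapping and small-RNA classification.

The mapper is a contract, not an aligner choice: every exact occurrence of
each read on either genome strand is reported, deterministically. Multi-
mapping reads keep all hits and contribute their full count at every locus
(``n_hits`` lets downstream consumers exclude multi-mapped signal).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .formats_io import (
    AnnotationTrack,
    CollapsedRead,
    normalize_seq,
    revcomp,
)


@dataclass
class Genome:
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        self.chromosomes = {
            name: normalize_seq(seq) for name, seq in self.chromosomes.items()
        }

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.chromosomes[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        chroms = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
        if not chroms:
            raise ValueError(f"no sequences in {path}")
        return cls(chromosomes=chroms)

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class ReadAlignment:
    read: CollapsedRead
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.read.sequence):
            raise ValueError("alignment span does not match read length")

    def verify(self, genome: Genome) -> bool:
        """Exactness audit: the genomic substring (reverse-complemented for
        the minus strand) equals the read sequence."""
        return (
            genome.fetch(self.chrom, self.start, self.end, self.strand)
            == self.read.sequence
        )


class ExactIndex:
    """Exact-match index over both genome strands for query lengths 17-30.

    Per-length hash tables over forward-strand windows are built lazily;
    minus-strand hits are found by querying the reverse complement.
    """

    MIN_LEN, MAX_LEN = 17, 30

    def __init__(self, genome: Genome):
        if not genome.chromosomes or all(
            len(s) == 0 for s in genome.chromosomes.values()
        ):
            raise ValueError("empty genome")
        self.genome = genome
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _table(self, length: int) -> dict[str, list[tuple[str, int]]]:
        if length not in self._tables:
            table: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for chrom, seq in self.genome.chromosomes.items():
                for start in range(0, len(seq) - length + 1):
                    table[seq[start : start + length]].append((chrom, start))
            self._tables[length] = dict(table)
        return self._tables[length]

    def find(self, pattern: str) -> list[tuple[str, int, str]]:
        """All exact hits of ``pattern`` as (chrom, start, strand), sorted."""
        if not (self.MIN_LEN <= len(pattern) <= self.MAX_LEN):
            raise ValueError(
                f"pattern length {len(pattern)} outside [{self.MIN_LEN}, {self.MAX_LEN}]"
            )
        pattern = normalize_seq(pattern)
        table = self._table(len(pattern))
        hits = [(c, s, "+") for c, s in table.get(pattern, ())]
        rc = revcomp(pattern)
        hits += [(c, s, "-") for c, s in table.get(rc, ())]
        if pattern == rc:  # palindromic read: one physical site, both strands
            hits = sorted(set(hits))
        hits.sort()
        return hits


def build_exact_index(genome: Genome) -> ExactIndex:
    return ExactIndex(genome)


@dataclass
class MappingResult:
    alignments: list[ReadAlignment]
    unmapped: list[CollapsedRead]
    mapped_reads: list[CollapsedRead] = field(default_factory=list)

    @property
    def mapped_read_fraction(self) -> float:
        """Fraction of read counts (not species) that mapped."""
        mapped = sum(cr.total_count for cr in self.mapped_reads)
        total = mapped + sum(cr.total_count for cr in self.unmapped)
        return mapped / total if total else 0.0


def map_reads(index: ExactIndex, collapsed: Iterable[CollapsedRead]) -> MappingResult:
    """Map collapsed reads with 0 mismatches; all hits on both strands are
    reported and ``n_hits`` records each read's total genomic hit count."""
    alignments: list[ReadAlignment] = []
    unmapped: list[CollapsedRead] = []
    mapped: list[CollapsedRead] = []
    for cr in collapsed:
        hits = index.find(cr.sequence)
        if not hits:
            unmapped.append(cr)
            continue
        mapped.append(cr)
        for chrom, start, strand in hits:
            alignments.append(
                ReadAlignment(
                    read=cr,
                    chrom=chrom,
                    start=start,
                    end=start + len(cr.sequence),
                    strand=strand,
                    n_hits=len(hits),
                )
            )
    return MappingResult(alignments=alignments, unmapped=unmapped, mapped_reads=mapped)


def classify_small_rnas(
    alignments: list[ReadAlignment],
    track: AnnotationTrack,
    mature_sequences: Optional[dict[str, str]] = None,
    categories: Iterable[str] = ("known_mirna", "rrna", "trna", "repeat", "coding"),
) -> dict[str, set[str]]:
    """Tag each mapped read sequence with annotation categories.

    ``known_mirna`` is assigned only by exact sequence identity to a mature
    miRNA (iso-reads, offset by a few nt, are deliberately not tagged);
    all other categories require >= 1 bp overlap between any alignment of
    the read and a track interval of that category, strand-agnostically.
    """
    categories = list(categories)
    if "known_mirna" in categories:
        if mature_sequences is None:
            if track.mature_sequences is None:
                raise ValueError(
                    "known_mirna classification requires mature sequences"
                )
            mature_sequences = track.mature_sequences
        mature_set = {normalize_seq(s) for s in mature_sequences.values()}
    else:
        mature_set = set()

    by_chrom: dict[tuple[str, str], list] = defaultdict(list)
    for iv in track.intervals:
        if iv.category in categories and iv.category != "known_mirna":
            by_chrom[(iv.chrom, iv.category)].append((iv.start, iv.end))

    result: dict[str, set[str]] = defaultdict(set)
    for aln in alignments:
        if aln.read.sequence in mature_set:
            result[aln.read.sequence].add("known_mirna")
        for cat in categories:
            if cat == "known_mirna":
                continue
            for start, end in by_chrom.get((aln.chrom, cat), ()):
                if aln.start < end and start < aln.end:
                    result[aln.read.sequence].add(cat)
                    break
    # sequence-identity tagging also applies to unaligned positions of the
    # same species; callers pass alignments, so every mapped species is seen
    return dict(result)


def classification_summary(
    classification: dict[str, set[str]],
    collapsed: list[CollapsedRead],
) -> pd.DataFrame:
    """Per-category read/species counts and read-count fractions over the
    given collapsed set (multi-tagged reads count in every category)."""
    total_reads = sum(cr.total_count for cr in collapsed)
    rows = []
    cats = sorted({c for tags in classification.values() for c in tags})
    by_seq = {cr.sequence: cr for cr in collapsed}
    for cat in cats:
        seqs = [s for s, tags in classification.items() if cat in tags and s in by_seq]
        read_count = sum(by_seq[s].total_count for s in seqs)
        rows.append(
            {
                "category": cat,
                "read_count": read_count,
                "species_count": len(seqs),
                "fraction": read_count / total_reads if total_reads else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["category", "read_count", "species_count", "fraction"])


def alignments_to_bed6(alignments: list[ReadAlignment], path) -> None:
    """Export alignments as BED6: name = read sequence, score = total count."""
    with open(path, "w") as fh:
        for a in sorted(alignments, key=lambda a: (a.chrom, a.start, a.strand)):
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.read.sequence}\t"
                f"{a.read.total_count}\t{a.strand}\n"
            )
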