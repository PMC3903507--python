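"""Adaptor trimming, qualified-read filtering and descriptive read profiles.

Small-RNA libraries ligate a 3' adaptor to each insert; the insert is
recovered by locating the longest substring of the adaptor within the read
and trimming from its leftmost occurrence to the read's 3' end. Reads whose
longest shared adaptor substring is <= 6 nt are treated as adaptor-less and
discarded, as are reads shorter than 17 nt or longer than 30 nt after
trimming, reads containing N, and (when qualities are present) reads with
any base below Q20.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .formats_io import CollapsedRead, RawRead

MIN_ADAPTOR_MATCH = 7  # matches of <= 6 nt do not count as an adaptor
DEFAULT_MIN_LEN = 17
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_QUALITY = 20


@dataclass
class TrimResult:
    trimmed_sequence: str
    adaptor_found: bool
    matched_length: int

    def __post_init__(self) -> None:
        assert self.adaptor_found == (self.matched_length >= MIN_ADAPTOR_MATCH)


def trim_adaptor(sequence: str, adaptor: str) -> TrimResult:
    """Trim the 3' adaptor off a read.

    Finds the longest substring of ``adaptor`` occurring anywhere in
    ``sequence`` and trims from the leftmost occurrence of that longest
    match to the 3' end. If no shared substring longer than 6 nt exists the
    read is returned untrimmed with ``adaptor_found=False``.
    """
    if not sequence or not adaptor:
        raise ValueError("sequence and adaptor must be non-empty")
    max_len = min(len(sequence), len(adaptor))
    for length in range(max_len, 0, -1):
        best_pos = None
        for a0 in range(len(adaptor) - length + 1):
            pos = sequence.find(adaptor[a0 : a0 + length])
            if pos != -1 and (best_pos is None or pos < best_pos):
                best_pos = pos
        if best_pos is not None:
            if length < MIN_ADAPTOR_MATCH:
                return TrimResult(sequence, False, length)
            return TrimResult(sequence[:best_pos], True, length)
    return TrimResult(sequence, False, 0)


def qc_filter(
    reads: Iterable[RawRead],
    adaptor: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_quality: int | None = DEFAULT_MIN_QUALITY,
) -> tuple[list[RawRead], Counter]:
    """Trim adaptors and keep qualified reads.

    Returns the kept (trimmed) reads and a tally of discards by reason
    (``no_adaptor``, ``too_short``, ``too_long``, ``ambiguous``,
    ``low_quality``). kept + sum(tally) equals the input read count.
    """
    kept: list[RawRead] = []
    tally: Counter = Counter()
    for read in reads:
        trim = trim_adaptor(read.sequence, adaptor)
        if not trim.adaptor_found:
            tally["no_adaptor"] += 1
            continue
        seq = trim.trimmed_sequence
        if len(seq) < min_len:
            tally["too_short"] += 1
            continue
        if len(seq) > max_len:
            tally["too_long"] += 1
            continue
        if "N" in seq:
            tally["ambiguous"] += 1
            continue
        if min_quality is not None and read.quality is not None:
            quals = read.quality[: len(seq)]
            if any(ord(q) - 33 < min_quality for q in quals):
                tally["low_quality"] += 1
                continue
        kept.append(
            RawRead(
                sequence=seq,
                library_id=read.library_id,
                quality=read.quality[: len(seq)] if read.quality else None,
            )
        )
    return kept, tally


@dataclass
class ReadProfile:
    """Size and 5'-nucleotide composition of a qualified read set.

    ``by_size`` maps length -> (read_fraction, species_fraction);
    ``five_prime`` maps nucleotide (RNA display, U not T) -> proportion;
    ``mean_count_per_species_by_size`` is reads-per-species at each size.
    """

    by_size: dict[int, tuple[float, float]]
    five_prime: dict[str, float]
    mean_count_per_species_by_size: dict[int, float]


def size_complexity_profile(collapsed: list[CollapsedRead]) -> ReadProfile:
    """Per-size abundance (read fraction) and complexity (species fraction)
    plus the mean read count per species at each size."""
    if not collapsed:
        raise ValueError("empty read set")
    reads_by_size: Counter = Counter()
    species_by_size: Counter = Counter()
    for cr in collapsed:
        reads_by_size[len(cr)] += cr.total_count
        species_by_size[len(cr)] += 1
    total_reads = sum(reads_by_size.values())
    total_species = sum(species_by_size.values())
    by_size = {
        size: (
            reads_by_size[size] / total_reads,
            species_by_size[size] / total_species,
        )
        for size in sorted(reads_by_size)
    }
    mean_count = {
        size: reads_by_size[size] / species_by_size[size]
        for size in sorted(reads_by_size)
    }
    return ReadProfile(
        by_size=by_size,
        five_prime=five_prime_composition(collapsed, weighting="by_read"),
        mean_count_per_species_by_size=mean_count,
    )


def five_prime_composition(
    collapsed: list[CollapsedRead], weighting: str = "by_read"
) -> dict[str, float]:
    """Proportion of A/C/G/U at read 5' ends, count-weighted (``by_read``)
    or per unique species (``by_species``)."""
    if not collapsed:
        raise ValueError("empty read set")
    if weighting not in ("by_read", "by_species"):
        raise ValueError(f"unknown weighting {weighting!r}")
    tally: Counter = Counter()
    for cr in collapsed:
        first = "U" if cr.sequence[0] == "T" else cr.sequence[0]
        tally[first] += cr.total_count if weighting == "by_read" else 1
    total = sum(tally.values())
    return {nt: n / total for nt, n in sorted(tally.items())}


def write_profile_tsv(profile: ReadProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("size\tread_fraction\tspecies_fraction\tmean_count\n")
        for size, (rf, sf) in profile.by_size.items():
            mc = profile.mean_count_per_species_by_size[size]
            fh.write(f"{size}\t{rf:.6f}\t{sf:.6f}\t{mc:.4f}\n")
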