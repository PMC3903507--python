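"""Candidate pre-miRNA hairpins from mapped reads.

Read alignments are merged into loci wherever read intervals overlap;
each locus is scanned with 250-nt windows (step 10) reaching 220 nt beyond
the reads on both sides; windows are folded on the read strand and kept if
they carry a hairpin stem of >= 18 paired positions, free energy no greater
than -18 kcal/mol, at least one read on a stem arm, and at most 5 unpaired
positions under the read-covered arm region. Structurally equivalent
windows are collapsed to one representative per locus.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .formats_io import CollapsedRead, GffFeature
from .genome_map import Genome, ReadAlignment

# pipeline configuration defaults
WINDOW_LEN = 250
STEP = 10
FLANK = 220
ENERGY_MAX = -18.0
STEM_MIN = 18
MAX_STEM_MISMATCHES = 5
SUBOPT_DELTA = 2.0  # kcal/mol above MFE for the suboptimal ensemble
MAX_STRUCTURES = 5


@dataclass
class ReadLocus:
    """Envelope of a connected set of overlapping read alignments."""

    chrom: str
    strand: str
    start: int
    end: int
    reads: list[ReadAlignment]

    @property
    def max_read_count(self) -> int:
        return max(a.read.total_count for a in self.reads)

    @property
    def width(self) -> int:
        return self.end - self.start


def merge_read_loci(alignments: Iterable[ReadAlignment]) -> list[ReadLocus]:
    """Merge alignments into loci: two loci merge iff some read interval of
    one overlaps (>= 1 bp) some read interval of the other, transitively.

    Because a locus is a union of read intervals, connected components of
    the read-overlap graph are exactly the runs found by a coordinate
    sweep per (chrom, strand).
    """
    loci: list[ReadLocus] = []
    ordered = sorted(
        alignments, key=lambda a: (a.chrom, a.strand, a.start, a.end, a.read.sequence)
    )
    current: Optional[ReadLocus] = None
    for aln in ordered:
        if (
            current is not None
            and aln.chrom == current.chrom
            and aln.strand == current.strand
            and aln.start < current.end  # half-open: abutting reads do not merge
        ):
            current.reads.append(aln)
            current.end = max(current.end, aln.end)
        else:
            current = ReadLocus(
                chrom=aln.chrom,
                strand=aln.strand,
                start=aln.start,
                end=aln.end,
                reads=[aln],
            )
            loci.append(current)
    return loci


def extract_candidate_windows(
    locus: ReadLocus,
    chrom_length: int,
    window_len: int = WINDOW_LEN,
    step: int = STEP,
    flank: int = FLANK,
) -> list[tuple[int, int]]:
    """Sliding precursor windows over a locus.

    The first window starts ``flank`` nt upstream of the reads; windows of
    ``window_len`` advance by ``step`` until one ends at or beyond
    ``flank`` nt downstream of the reads. Windows are clipped to the
    chromosome.
    """
    windows: list[tuple[int, int]] = []
    start = locus.start - flank
    target_end = locus.end + flank
    while True:
        # clamp the window start at the chromosome edge, keeping the
        # window length where possible, then truncate the end
        s = max(start, 0)
        e = min(s + window_len, chrom_length)
        if e - s > 0 and (not windows or windows[-1] != (s, e)):
            windows.append((s, e))
        if start + window_len >= target_end:
            break
        start += step
    return windows


def window_count_closed_form(locus_width: int, window_len: int = WINDOW_LEN,
                             step: int = STEP, flank: int = FLANK) -> int:
    """Number of unclipped windows for a locus of the given read span:
    ceil((w + 2*flank - window_len)/step) + 1."""
    overhang = locus_width + 2 * flank - window_len
    if overhang <= 0:
        return 1
    return -(-overhang // step) + 1


# ---------------------------------------------------------------------------
# Folding backends


class FoldBackendError(RuntimeError):
    pass


def _fold_vienna(sequence: str, delta: float) -> list[tuple[str, float]]:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise FoldBackendError(
            "ViennaRNA python bindings unavailable; use backend='rnafold'"
        ) from exc
    rna = sequence.replace("T", "U")
    fc = RNA.fold_compound(rna)
    solutions = fc.subopt(int(round(delta * 100)))
    out = [(s.structure, s.energy) for s in solutions if s.structure]
    out.sort(key=lambda se: (se[1], se[0]))
    return out


def _fold_rnafold_cli(sequence: str, delta: float) -> list[tuple[str, float]]:
    if shutil.which("RNAsubopt") is None:
        raise FoldBackendError(
            "RNAsubopt executable not found; use backend='vienna'"
        )
    rna = sequence.replace("T", "U")
    proc = subprocess.run(
        ["RNAsubopt", "-e", f"{delta:.2f}", "-s"],
        input=rna + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    out = []
    for line in proc.stdout.splitlines()[1:]:
        parts = line.split()
        if len(parts) == 2 and set(parts[0]) <= set("()."):
            out.append((parts[0], float(parts[1])))
    out.sort(key=lambda se: (se[1], se[0]))
    return out


_BACKENDS = {"vienna": _fold_vienna, "rnafold": _fold_rnafold_cli}


# ---------------------------------------------------------------------------
# Structure parsing


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return table


@dataclass
class HairpinStem:
    """The stem (helix chain through bulges/interior loops) that closes a
    terminal loop, with the arm spans it defines."""

    arm5: tuple[int, int]  # 0-based half-open span of the 5' arm
    arm3: tuple[int, int]
    loop: tuple[int, int]
    pairs: list[tuple[int, int]]  # stem base pairs, innermost first

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def find_hairpin_stems(structure: str) -> list[HairpinStem]:
    """Locate every terminal loop and walk its closing stem outward.

    The walk continues through bulges and interior loops (unpaired
    positions between consecutive stem pairs) and stops at multiloop
    junctions, i.e. when another paired position intervenes.
    """
    table = pair_table(structure)
    n = len(structure)
    stems = []
    i = 0
    while i < n:
        if structure[i] == "(" and table[i] != -1:
            j = table[i]
            # terminal loop iff no paired position strictly inside (i, j)
            if all(table[k] == -1 for k in range(i + 1, j)):
                pairs = [(i, j)]
                p, q = i, j
                while True:
                    p2 = p - 1
                    while p2 >= 0 and table[p2] == -1:
                        p2 -= 1
                    if p2 < 0 or table[p2] <= q:
                        break
                    q2 = table[p2]
                    # stop at multiloop junctions: a paired position between
                    # q and q2 would belong to another helix
                    if any(table[k] != -1 for k in range(q + 1, q2)):
                        break
                    pairs.append((p2, q2))
                    p, q = p2, q2
                outer5, outer3 = pairs[-1]
                stems.append(
                    HairpinStem(
                        arm5=(outer5, i + 1),
                        arm3=(j, outer3 + 1),
                        loop=(i + 1, j),
                        pairs=pairs,
                    )
                )
        i += 1
    stems.sort(key=lambda s: (-s.n_pairs, s.arm5[0]))
    return stems


@dataclass
class FoldedSegment:
    """A folded genomic window. ``sequence`` is the read-strand sequence;
    position 0 of the structure is ``seg_start`` on '+' loci and
    ``seg_end - 1`` on '-' loci."""

    chrom: str
    strand: str
    seg_start: int
    seg_end: int
    sequence: str
    structure: str
    mfe: float
    stem: Optional[HairpinStem]

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")

    def to_genomic(self, pos: int) -> int:
        """Map a structure position to a genomic coordinate."""
        if self.strand == "+":
            return self.seg_start + pos
        return self.seg_end - 1 - pos

    def from_genomic(self, gpos: int) -> int:
        if self.strand == "+":
            return gpos - self.seg_start
        return self.seg_end - 1 - gpos


def fold_segment(
    sequence: str,
    chrom: str = "",
    strand: str = "+",
    seg_start: int = 0,
    backend: str = "vienna",
    energy_max: float = ENERGY_MAX,
    max_structures: int = MAX_STRUCTURES,
    subopt_delta: float = SUBOPT_DELTA,
) -> list[FoldedSegment]:
    """Fold one window and return up to ``max_structures`` structures with
    free energy <= ``energy_max`` kcal/mol (empty list if none qualify).

    Structures come from the backend's suboptimal ensemble within
    ``subopt_delta`` kcal/mol of the MFE, ranked by energy.
    """
    if not 40 <= len(sequence) <= WINDOW_LEN:
        raise ValueError(f"segment length {len(sequence)} outside [40, {WINDOW_LEN}]")
    if backend not in _BACKENDS:
        raise FoldBackendError(f"unknown backend {backend!r}; use one of {sorted(_BACKENDS)}")
    structures = _BACKENDS[backend](sequence, subopt_delta)
    out = []
    for struct, energy in structures[: max_structures * 4]:
        if energy > energy_max:
            continue
        stems = find_hairpin_stems(struct)
        out.append(
            FoldedSegment(
                chrom=chrom,
                strand=strand,
                seg_start=seg_start,
                seg_end=seg_start + len(sequence),
                sequence=sequence,
                structure=struct,
                mfe=energy,
                stem=stems[0] if stems else None,
            )
        )
        if len(out) == max_structures:
            break
    return out


# ---------------------------------------------------------------------------
# Filtering


FILTER_NAMES = ("stem18", "energy", "reads_on_stem", "structure_mismatches")


@dataclass
class HairpinCandidate:
    segment: FoldedSegment
    stem_paired_length: int
    reads_on_arms: list[tuple[tuple[int, int], CollapsedRead]]  # (struct span, read)
    max_read: Optional[tuple[str, int]]
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.passes.get(name, False) for name in FILTER_NAMES)

    def revalidate(self) -> dict[str, bool]:
        """Independently recompute the four filters from the stored fold."""
        return _compute_filters(self.segment, self.reads_on_arms)


def _arm_spans(segment: FoldedSegment) -> list[tuple[int, int]]:
    if segment.stem is None:
        return []
    return [segment.stem.arm5, segment.stem.arm3]


def _compute_filters(
    segment: FoldedSegment,
    reads_on_arms: list[tuple[tuple[int, int], CollapsedRead]],
) -> dict[str, bool]:
    stem = segment.stem
    passes = {
        "stem18": stem is not None and stem.n_pairs >= STEM_MIN,
        "energy": segment.mfe <= ENERGY_MAX,
        "reads_on_stem": len(reads_on_arms) > 0,
    }
    if stem is None or not reads_on_arms:
        passes["structure_mismatches"] = False
        return passes
    table = pair_table(segment.structure)
    covered: set[int] = set()
    for (s, e), _read in reads_on_arms:
        for arm in (stem.arm5, stem.arm3):
            lo, hi = max(s, arm[0]), min(e, arm[1])
            covered.update(range(lo, hi))
    mismatches = sum(1 for pos in covered if table[pos] == -1)
    passes["structure_mismatches"] = mismatches <= MAX_STEM_MISMATCHES
    return passes


def place_reads(
    segment: FoldedSegment, alignments: Sequence[ReadAlignment]
) -> list[tuple[tuple[int, int], CollapsedRead]]:
    """Structure-coordinate spans of the alignments fully inside the
    segment (same chrom and strand)."""
    placed = []
    for aln in alignments:
        if aln.chrom != segment.chrom or aln.strand != segment.strand:
            continue
        if aln.start < segment.seg_start or aln.end > segment.seg_end:
            continue
        a = segment.from_genomic(aln.start)
        b = segment.from_genomic(aln.end - 1)
        lo, hi = min(a, b), max(a, b) + 1
        placed.append(((lo, hi), aln.read))
    placed.sort(key=lambda pr: (pr[0], pr[1].sequence))
    return placed


def filter_hairpin_segments(
    segment: FoldedSegment, alignments: Sequence[ReadAlignment]
) -> HairpinCandidate:
    """Apply the four structural filters to one folded window.

    * stem18 — the hairpin stem has >= 18 paired positions on an arm
      (bulges allowed, unpaired positions not counted);
    * energy — free energy <= -18 kcal/mol;
    * reads_on_stem — at least one read lies within an arm span;
    * structure_mismatches — <= 5 unpaired positions within the
      read-covered arm region.
    """
    placed = place_reads(segment, alignments)
    arm_spans = _arm_spans(segment)
    on_arms = [
        ((s, e), read)
        for (s, e), read in placed
        if any(s >= lo and e <= hi for lo, hi in arm_spans)
    ]
    passes = _compute_filters(segment, on_arms)
    max_read = None
    if on_arms:
        best = max(on_arms, key=lambda pr: (pr[1].total_count, pr[1].sequence))
        max_read = (best[1].sequence, best[1].total_count)
    return HairpinCandidate(
        segment=segment,
        stem_paired_length=segment.stem.n_pairs if segment.stem else 0,
        reads_on_arms=on_arms,
        max_read=max_read,
        passes=passes,
    )


# ---------------------------------------------------------------------------
# Representative selection


def _read_span_paired_positions(candidate: HairpinCandidate) -> frozenset[int]:
    """Genomic positions that are paired within the read-covered region —
    the structural signature used to decide whether two windows describe
    the same hairpin."""
    table = pair_table(candidate.segment.structure)
    sig = set()
    for (s, e), _read in candidate.reads_on_arms:
        for pos in range(s, e):
            if table[pos] != -1:
                sig.add(candidate.segment.to_genomic(pos))
    return frozenset(sig)


def select_representatives(
    candidates: list[HairpinCandidate],
) -> list[HairpinCandidate]:
    """Group passing candidates of one locus whose read-span paired-position
    sets agree on >= 90% of positions (Jaccard, single linkage) and keep,
    per group, the candidate with the most reads on arms, then the lowest
    free energy, then the leftmost window start."""
    passing = [c for c in candidates if c.passed]
    if not passing:
        return []
    sigs = [_read_span_paired_positions(c) for c in passing]
    parent = list(range(len(passing)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(passing)):
        for j in range(i + 1, len(passing)):
            union = sigs[i] | sigs[j]
            if not union:
                continue
            if len(sigs[i] & sigs[j]) / len(union) >= 0.9:
                parent[find(i)] = find(j)

    groups: dict[int, list[HairpinCandidate]] = {}
    for i, cand in enumerate(passing):
        groups.setdefault(find(i), []).append(cand)
    reps = []
    for members in groups.values():
        members.sort(
            key=lambda c: (
                -sum(r.total_count for _s, r in c.reads_on_arms),
                c.segment.mfe,
                c.segment.seg_start,
            )
        )
        reps.append(members[0])
    reps.sort(key=lambda c: (c.segment.chrom, c.segment.seg_start))
    return reps


def candidates_to_gff(candidates: Iterable[HairpinCandidate]) -> list[GffFeature]:
    feats = []
    for i, cand in enumerate(candidates, start=1):
        seg = cand.segment
        feats.append(
            GffFeature(
                chrom=seg.chrom,
                type="pre_miRNA",
                start=seg.seg_start,
                end=seg.seg_end,
                strand=seg.strand,
                attributes={
                    "ID": f"hairpin{i:04d}",
                    "mfe": f"{seg.mfe:.2f}",
                    "stem_paired_length": str(cand.stem_paired_length),
                    "filters": ",".join(k for k, v in cand.passes.items() if v),
                },
            )
        )
    return feats


def write_structure_file(candidates: Iterable[HairpinCandidate], path) -> None:
    """Vienna-style structure dump: header, sequence, dot-bracket+energy."""
    with open(path, "w") as fh:
        for i, cand in enumerate(candidates, start=1):
            seg = cand.segment
            fh.write(
                f">hairpin{i:04d} {seg.chrom}:{seg.seg_start}-{seg.seg_end}({seg.strand})\n"
                f"{seg.sequence.replace('T', 'U')}\n"
                f"{seg.structure} ({seg.mfe:.2f})\n"
            )
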