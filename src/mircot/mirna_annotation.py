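"""miRNA annotation: mature/star calling, duplex validation, processing
precision, acceptance rules, overlap resolution, family grouping and
miRNA/miRNA* ratio accounting.

A candidate hairpin is annotated as a miRNA when (a) its mature read lies
on a stem arm, (b) the mature species has >= 10 cumulative reads, (c) it is
detected in >= 2 libraries, and (d) either a star read is observed with a
valid duplex (2-3 nt 3' overhangs on both ends, <= 5 duplex mismatches,
neither strand in the loop) and processing precision >= 10%, or no star is
observed and precision >= 45%. Counts are exact-sequence counts only:
iso-reads (offset variants) never contribute to a mature or star count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import edlib

from .formats_io import CollapsedRead, GffFeature, normalize_seq
from .hairpin_discovery import HairpinCandidate, pair_table

MIN_MATURE_READS = 10
MIN_LIBRARIES = 2
PRECISION_WITH_STAR = 10.0
PRECISION_NO_STAR = 45.0
MAX_DUPLEX_MISMATCHES = 5
VALID_OVERHANGS = (2, 3)
STAR_REGISTER_SHIFT = 2  # +/- nt slack when locating the star read
FAMILY_EDIT_DISTANCE = 2


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class ArmRead:
    sequence: str
    arm: str  # {5p, 3p}
    count: int
    span: tuple[int, int]  # structure coordinates on the hairpin segment
    counts_by_library: dict[str, int]


@dataclass
class DuplexCheck:
    overhang_3p_mature: int
    overhang_3p_star: int
    duplex_mismatches: int
    in_loop: bool

    @property
    def passed(self) -> bool:
        return (
            self.overhang_3p_mature in VALID_OVERHANGS
            and self.overhang_3p_star in VALID_OVERHANGS
            and self.duplex_mismatches <= MAX_DUPLEX_MISMATCHES
            and not self.in_loop
        )


@dataclass
class MirnaAnnotation:
    hairpin: HairpinCandidate
    mature: ArmRead
    star: Optional[ArmRead]
    n_libraries_detected: int
    precision: float
    duplex: Optional[DuplexCheck]
    status: str = "candidate"  # accepted | rejected_<reason> | candidate
    family_id: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def chrom(self) -> str:
        return self.hairpin.segment.chrom

    @property
    def strand(self) -> str:
        return self.hairpin.segment.strand

    @property
    def span(self) -> tuple[int, int]:
        return self.hairpin.segment.seg_start, self.hairpin.segment.seg_end


@dataclass
class FamilyAssignment:
    family_id: str
    members: list[MirnaAnnotation] = field(default_factory=list)
    conserved: bool = False


# ---------------------------------------------------------------------------
# Mature / star calling


def _which_arm(span: tuple[int, int], candidate: HairpinCandidate) -> Optional[str]:
    stem = candidate.segment.stem
    if stem is None:
        return None
    if span[0] >= stem.arm5[0] and span[1] <= stem.arm5[1]:
        return "5p"
    if span[0] >= stem.arm3[0] and span[1] <= stem.arm3[1]:
        return "3p"
    return None


def _partner_of(table: list[int], span: tuple[int, int]) -> Optional[tuple[int, int]]:
    """Span on the opposite arm pairing with ``span``, from the pair table."""
    partners = [table[i] for i in range(*span) if table[i] != -1]
    if not partners:
        return None
    return min(partners), max(partners) + 1


def call_mature_and_star(candidate: HairpinCandidate) -> MirnaAnnotation:
    """Select the mature miRNA (highest cumulative exact-read count on an
    arm; ties prefer a 5'-U read, then the leftmost) and, if observed, the
    star read: the opposite-arm read positioned to pair with the mature
    (within a +/- 2 nt register shift)."""
    if not candidate.reads_on_arms:
        raise ValueError("candidate has no reads on arms; filter first")
    seg = candidate.segment

    def tie_key(item: tuple[tuple[int, int], CollapsedRead]):
        (s, _e), read = item
        five_prime_u = read.sequence.startswith("T")
        return (-read.total_count, 0 if five_prime_u else 1, s, read.sequence)

    (m_span, m_read) = min(candidate.reads_on_arms, key=tie_key)
    m_arm = _which_arm(m_span, candidate)
    mature = ArmRead(
        sequence=m_read.sequence,
        arm=m_arm or "?",
        count=m_read.total_count,
        span=m_span,
        counts_by_library=dict(m_read.counts),
    )

    star = None
    table = pair_table(seg.structure)
    expected = _partner_of(table, m_span)
    if expected is not None and m_arm is not None:
        opposite = "3p" if m_arm == "5p" else "5p"
        best = None
        for span, read in candidate.reads_on_arms:
            if _which_arm(span, candidate) != opposite:
                continue
            # the canonical star 5' end sits 2 nt inward of the mature
            # partner span on the 3' side; allow a small register shift
            if abs(span[0] - expected[0]) > STAR_REGISTER_SHIFT + 2:
                continue
            key = (-read.total_count, abs(span[0] - expected[0]), read.sequence)
            if best is None or key < best[0]:
                best = (key, span, read)
        if best is not None:
            _key, s_span, s_read = best
            star = ArmRead(
                sequence=s_read.sequence,
                arm=opposite,
                count=s_read.total_count,
                span=s_span,
                counts_by_library=dict(s_read.counts),
            )

    return MirnaAnnotation(
        hairpin=candidate,
        mature=mature,
        star=star,
        n_libraries_detected=sum(1 for c in mature.counts_by_library.values() if c > 0),
        precision=0.0,
        duplex=None,
    )


# ---------------------------------------------------------------------------
# Duplex validation


def _three_prime_overhang(
    table: list[int], x_span: tuple[int, int], y_span: tuple[int, int]
) -> int:
    """3' overhang of strand x over its duplex with strand y: how far x's
    3' end extends past the position pairing y's 5'-most (paired) base.
    Unpaired bases at y's 5' end are bridged by offsetting the first
    paired partner."""
    for k in range(y_span[0], y_span[1]):
        if table[k] != -1:
            partner = table[k] - (k - y_span[0])
            return max(0, (x_span[1] - 1) - partner)
    return 0


def validate_duplex(annotation: MirnaAnnotation) -> DuplexCheck:
    """Compute 3' overhangs, duplex mismatches and loop intrusion for a
    called mature/star pair (requires an observed star)."""
    if annotation.star is None:
        raise ValueError("duplex validation requires an observed star read")
    seg = annotation.hairpin.segment
    stem = seg.stem
    table = pair_table(seg.structure)
    m_span = annotation.mature.span
    s_span = annotation.star.span

    oh_m = _three_prime_overhang(table, m_span, s_span)
    oh_s = _three_prime_overhang(table, s_span, m_span)

    # mismatches: unpaired mature positions within the duplex region (the
    # mature span minus its 3' overhang; structure coordinates follow the
    # transcript 5'->3', so the overhang is always at the span's high end)
    lo, hi = m_span[0], m_span[1] - oh_m
    mismatches = sum(1 for pos in range(lo, hi) if table[pos] == -1)

    in_loop = False
    if stem is not None:
        loop_lo, loop_hi = stem.loop
        for span in (m_span, s_span):
            if span[0] < loop_hi and loop_lo < span[1]:
                in_loop = True
    check = DuplexCheck(
        overhang_3p_mature=oh_m,
        overhang_3p_star=oh_s,
        duplex_mismatches=mismatches,
        in_loop=in_loop,
    )
    annotation.duplex = check
    return check


# ---------------------------------------------------------------------------
# Processing precision


def compute_precision(total_hairpin_count: int, mature_count: int, star_count: int = 0) -> float:
    """Processing precision: 100 * (mature + star) / total reads aligned to
    the hairpin. Always in [0, 100]."""
    if total_hairpin_count == 0:
        raise ValueError("no reads aligned to hairpin")
    if mature_count + star_count > total_hairpin_count:
        raise ValueError("mature+star exceeds total hairpin-aligned count")
    return 100.0 * (mature_count + star_count) / total_hairpin_count


def hairpin_total_count(candidate: HairpinCandidate, placed_reads=None) -> int:
    """Total read count aligned to the hairpin segment. When the full
    placement (including loop/flank reads) is not supplied, arm reads are
    used."""
    reads = placed_reads if placed_reads is not None else candidate.reads_on_arms
    return sum(read.total_count for _span, read in reads)


# ---------------------------------------------------------------------------
# Acceptance rules


def apply_annotation_rules(
    annotation: MirnaAnnotation,
    min_reads: int = MIN_MATURE_READS,
    min_libraries: int = MIN_LIBRARIES,
    precision_with_star: float = PRECISION_WITH_STAR,
    precision_no_star: float = PRECISION_NO_STAR,
) -> MirnaAnnotation:
    """Apply the annotation criteria and set ``status``; the first failing
    rule is recorded as the rejection reason."""
    if annotation.mature.arm not in ("5p", "3p"):
        annotation.status = "rejected_not_on_arm"
    elif annotation.mature.count < min_reads:
        annotation.status = "rejected_min_reads"
    elif annotation.n_libraries_detected < min_libraries:
        annotation.status = "rejected_min_libraries"
    elif annotation.star is not None:
        duplex = annotation.duplex or validate_duplex(annotation)
        if not duplex.passed:
            annotation.status = "rejected_duplex"
        elif annotation.precision < precision_with_star:
            annotation.status = "rejected_precision"
        else:
            annotation.status = "accepted"
    else:
        if annotation.precision < precision_no_star:
            annotation.status = "rejected_precision_no_star"
        else:
            annotation.status = "accepted"
    return annotation


def annotate_mirnas(
    annotations: Iterable[MirnaAnnotation],
    known_mature: Optional[dict[str, str]] = None,
    **rule_kwargs,
) -> tuple[list[MirnaAnnotation], list[MirnaAnnotation]]:
    """Apply the acceptance rules to all candidates; returns
    (accepted novel, rejected). Candidates whose mature sequence exactly
    matches a known mature miRNA are labelled via ``family_id`` but still
    processed under the same rules."""
    known_by_seq = (
        {normalize_seq(s): name for name, s in known_mature.items()}
        if known_mature
        else {}
    )
    accepted, rejected = [], []
    for ann in annotations:
        if ann.mature.sequence in known_by_seq:
            ann.family_id = known_by_seq[ann.mature.sequence]
        apply_annotation_rules(ann, **rule_kwargs)
        (accepted if ann.accepted else rejected).append(ann)
    return accepted, rejected


def expressed_known_mirnas(
    collapsed: Iterable[CollapsedRead],
    mature_sequences: dict[str, str],
    min_reads: int = MIN_MATURE_READS,
) -> dict[str, int]:
    """Known-miRNA expression calls: name -> cumulative exact-read count,
    keeping only miRNAs with >= ``min_reads`` exact reads (iso-reads are
    not counted)."""
    by_seq: dict[str, int] = {}
    for cr in collapsed:
        by_seq[cr.sequence] = by_seq.get(cr.sequence, 0) + cr.total_count
    calls = {}
    for name, seq in mature_sequences.items():
        count = by_seq.get(normalize_seq(seq), 0)
        if count >= min_reads:
            calls[name] = count
    return calls


# ---------------------------------------------------------------------------
# Overlap resolution, families, ratios


def resolve_locus_overlaps(annotations: list[MirnaAnnotation]) -> list[MirnaAnnotation]:
    """Among accepted hairpins overlapping >= 1 bp on the same strand, keep
    the one with the highest mature count, then the greatest precision,
    then the leftmost; the rest are re-labelled ``rejected_overlap``."""
    order = sorted(
        annotations,
        key=lambda a: (-a.mature.count, -a.precision, a.chrom, a.span[0]),
    )
    kept: list[MirnaAnnotation] = []
    for ann in order:
        clash = any(
            k.chrom == ann.chrom
            and k.strand == ann.strand
            and k.span[0] < ann.span[1]
            and ann.span[0] < k.span[1]
            for k in kept
        )
        if clash:
            ann.status = "rejected_overlap"
        else:
            kept.append(ann)
    kept.sort(key=lambda a: (a.chrom, a.span[0]))
    return kept


def group_families(
    annotations: list[MirnaAnnotation],
    known_families: Optional[dict[str, str]] = None,
    max_edit: int = FAMILY_EDIT_DISTANCE,
) -> list[FamilyAssignment]:
    """Single-linkage clustering of mature sequences at edit distance <=
    ``max_edit``. Clusters whose mature matches a known family's mature
    sequence (same threshold) inherit its name and conserved flag; the
    rest get fresh sequential ids.

    ``known_families`` maps family name -> representative mature sequence.
    """
    anns = sorted(annotations, key=lambda a: (a.chrom, a.span[0], a.mature.sequence))
    n = len(anns)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if edit_distance(anns[i].mature.sequence, anns[j].mature.sequence) <= max_edit:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[MirnaAnnotation]] = {}
    for i, ann in enumerate(anns):
        clusters.setdefault(find(i), []).append(ann)

    known = {
        name: normalize_seq(seq) for name, seq in (known_families or {}).items()
    }
    families = []
    fresh = 0
    for root in sorted(clusters):
        members = clusters[root]
        name, conserved = None, False
        for fam_name, fam_seq in sorted(known.items()):
            if any(
                edit_distance(m.mature.sequence, fam_seq) <= max_edit for m in members
            ):
                name, conserved = fam_name, True
                break
        if name is None:
            fresh += 1
            name = f"fam{fresh:03d}"
        fam = FamilyAssignment(family_id=name, members=members, conserved=conserved)
        for m in members:
            m.family_id = name
        families.append(fam)
    return families


def mirna_star_ratio(mature_count: int, star_count: int) -> Optional[float]:
    """miRNA/miRNA* count ratio, rounded half-up to 2 decimals; undefined
    (None) when no star reads were detected."""
    if mature_count < 0 or star_count < 0:
        raise ValueError("counts must be non-negative")
    if mature_count == 0 and star_count == 0:
        raise ValueError("both counts are zero")
    if star_count == 0:
        return None
    ratio = Decimal(mature_count) / Decimal(star_count)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_ratio(ratio: Optional[float]) -> str:
    """Display form with thousands separators; blank when undefined."""
    return "" if ratio is None else f"{ratio:,.2f}"


# ---------------------------------------------------------------------------
# Catalog summary (genes/families by conservation status)


def catalog_summary(records) -> dict:
    """Summarise a miRNA catalog into per-conservation-status counts with
    totals computed by summation.

    ``records``: iterable of dicts with keys ``family_id``, ``conserved``
    (bool), ``known`` (bool) and optionally ``expression`` and
    ``precision`` — one record per miRNA gene.
    """
    import statistics

    out: dict = {}
    records = list(records)
    for label, keep in (
        ("conserved", lambda r: r["conserved"]),
        ("non_conserved", lambda r: not r["conserved"]),
    ):
        sub = [r for r in records if keep(r)]
        fams: dict[str, int] = {}
        for r in sub:
            fams[r["family_id"]] = fams.get(r["family_id"], 0) + 1
        entry = {
            "n_genes": len(sub),
            "n_families": len(fams),
            "n_known_genes": sum(1 for r in sub if r.get("known")),
            "n_novel_genes": sum(1 for r in sub if not r.get("known")),
        }
        if fams:
            entry["median_family_size"] = statistics.median(fams.values())
        if any("expression" in r for r in sub):
            entry["median_expression"] = statistics.median(
                r["expression"] for r in sub if "expression" in r
            )
        if any("precision" in r for r in sub):
            entry["median_precision"] = statistics.median(
                r["precision"] for r in sub if "precision" in r
            )
        out[label] = entry
    out["total"] = {
        "n_genes": out["conserved"]["n_genes"] + out["non_conserved"]["n_genes"],
        "n_families": out["conserved"]["n_families"] + out["non_conserved"]["n_families"],
        "n_known_genes": out["conserved"]["n_known_genes"]
        + out["non_conserved"]["n_known_genes"],
        "n_novel_genes": out["conserved"]["n_novel_genes"]
        + out["non_conserved"]["n_novel_genes"],
    }
    return out


# ---------------------------------------------------------------------------
# Exports


def annotations_to_gff(annotations: Iterable[MirnaAnnotation]) -> list[GffFeature]:
    feats = []
    for i, ann in enumerate(annotations, start=1):
        seg = ann.hairpin.segment
        mir_id = ann.family_id or f"mir{i:04d}"
        feats.append(
            GffFeature(
                chrom=seg.chrom,
                type="miRNA_primary_transcript",
                start=seg.seg_start,
                end=seg.seg_end,
                strand=seg.strand,
                attributes={"ID": f"{mir_id}_hairpin", "Name": mir_id},
            )
        )
        m_lo = min(seg.to_genomic(ann.mature.span[0]), seg.to_genomic(ann.mature.span[1] - 1))
        feats.append(
            GffFeature(
                chrom=seg.chrom,
                type="miRNA",
                start=m_lo,
                end=m_lo + (ann.mature.span[1] - ann.mature.span[0]),
                strand=seg.strand,
                attributes={
                    "ID": f"{mir_id}_{ann.mature.arm}",
                    "Derives_from": f"{mir_id}_hairpin",
                },
            )
        )
    return feats


def annotations_to_table(annotations: Iterable[MirnaAnnotation]):
    import pandas as pd

    rows = []
    for i, ann in enumerate(annotations, start=1):
        star_count = ann.star.count if ann.star else 0
        rows.append(
            {
                "id": ann.family_id or f"mir{i:04d}",
                "chrom": ann.chrom,
                "start": ann.span[0],
                "end": ann.span[1],
                "strand": ann.strand,
                "arm": ann.mature.arm,
                "mature_seq": ann.mature.sequence.replace("T", "U"),
                "mature_count": ann.mature.count,
                "star_count": star_count,
                "ratio": format_ratio(
                    mirna_star_ratio(ann.mature.count, star_count)
                    if (ann.mature.count or star_count)
                    else None
                ),
                "precision": round(ann.precision, 2),
                "n_libraries": ann.n_libraries_detected,
                "status": ann.status,
            }
        )
    return pd.DataFrame(rows)
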