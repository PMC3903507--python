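"""End-to-end discovery: raw reads -> accepted miRNA annotations.

Chains QC, collapsing, exact mapping, optional known/structural-RNA
exclusion, locus merging, window folding, structural filtering, mature/
star calling, duplex validation, precision thresholds, overlap resolution
and family grouping. Loci whose most abundant species falls below the
minimum mature-read count are skipped before folding (no such locus can
yield an accepted miRNA, so this changes nothing but runtime).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import hairpin_discovery as hd
from . import mirna_annotation as ann
from .formats_io import AnnotationTrack, CollapsedRead, RawRead, collapse_reads
from .genome_map import Genome, MappingResult, build_exact_index, classify_small_rnas, map_reads
from .mirna_annotation import FamilyAssignment, MirnaAnnotation
from .preprocess import qc_filter


@dataclass
class DiscoveryParams:
    window_len: int = hd.WINDOW_LEN
    step: int = hd.STEP
    flank: int = hd.FLANK
    energy_max: float = hd.ENERGY_MAX
    stem_min: int = hd.STEM_MIN
    max_stem_mismatches: int = hd.MAX_STEM_MISMATCHES
    min_reads: int = ann.MIN_MATURE_READS
    min_libraries: int = ann.MIN_LIBRARIES
    precision_with_star: float = ann.PRECISION_WITH_STAR
    precision_no_star: float = ann.PRECISION_NO_STAR
    backend: str = "vienna"
    max_structures: int = hd.MAX_STRUCTURES
    exclude_categories: tuple[str, ...] = ("known_mirna", "rrna", "trna")


@dataclass
class DiscoveryResult:
    accepted: list[MirnaAnnotation]
    rejected: list[MirnaAnnotation]
    families: list[FamilyAssignment]
    mapping: MappingResult
    n_loci: int
    n_loci_folded: int
    dropped_loci: list[str] = field(default_factory=list)

    @property
    def five_prime_u_fraction(self) -> float:
        """Fraction of accepted miRNAs with a 5' terminal uracil."""
        if not self.accepted:
            return 0.0
        n_u = sum(1 for a in self.accepted if a.mature.sequence.startswith("T"))
        return n_u / len(self.accepted)


def discover_mirnas(
    genome: Genome,
    collapsed: list[CollapsedRead],
    params: Optional[DiscoveryParams] = None,
    exclusion_track: Optional[AnnotationTrack] = None,
    known_mature: Optional[dict[str, str]] = None,
) -> DiscoveryResult:
    """Run the discovery pipeline on qualified, collapsed reads."""
    params = params or DiscoveryParams()
    index = build_exact_index(genome)
    mapping = map_reads(index, collapsed)

    alignments = mapping.alignments
    if exclusion_track is not None:
        tags = classify_small_rnas(
            alignments,
            exclusion_track,
            mature_sequences=known_mature,
            categories=params.exclude_categories,
        )
        excluded = {
            seq for seq, cats in tags.items() if cats & set(params.exclude_categories)
        }
        alignments = [a for a in alignments if a.read.sequence not in excluded]

    loci = hd.merge_read_loci(alignments)
    # windows are seeded by a locus but annotated against every alignment
    # falling inside them (mature and star often sit in disjoint loci)
    by_chrom_strand: dict[tuple[str, str], list] = {}
    for a in alignments:
        by_chrom_strand.setdefault((a.chrom, a.strand), []).append(a)
    annotations: list[MirnaAnnotation] = []
    dropped: list[str] = []
    n_folded = 0
    for locus in loci:
        label = f"{locus.chrom}:{locus.start}-{locus.end}({locus.strand})"
        if locus.max_read_count < params.min_reads:
            dropped.append(f"{label} below_min_reads")
            continue
        n_folded += 1
        chrom_len = genome.lengths[locus.chrom]
        window_reads = by_chrom_strand[(locus.chrom, locus.strand)]
        candidates = []
        for seg_start, seg_end in hd.extract_candidate_windows(
            locus, chrom_len, params.window_len, params.step, params.flank
        ):
            if seg_end - seg_start < 40:
                continue
            seq = genome.fetch(locus.chrom, seg_start, seg_end, locus.strand)
            for segment in hd.fold_segment(
                seq,
                chrom=locus.chrom,
                strand=locus.strand,
                seg_start=seg_start,
                backend=params.backend,
                energy_max=params.energy_max,
                max_structures=params.max_structures,
            ):
                cand = hd.filter_hairpin_segments(segment, window_reads)
                if cand.passed:
                    candidates.append(cand)
        reps = hd.select_representatives(candidates)
        if not reps:
            dropped.append(f"{label} no_passing_candidate")
            continue
        for rep in reps:
            annotation = ann.call_mature_and_star(rep)
            placed = hd.place_reads(rep.segment, window_reads)
            total = sum(read.total_count for _s, read in placed)
            star_count = annotation.star.count if annotation.star else 0
            annotation.precision = ann.compute_precision(
                total, annotation.mature.count, star_count
            )
            if annotation.star is not None:
                ann.validate_duplex(annotation)
            annotations.append(annotation)

    accepted, rejected = ann.annotate_mirnas(
        annotations,
        known_mature=known_mature,
        min_reads=params.min_reads,
        min_libraries=params.min_libraries,
        precision_with_star=params.precision_with_star,
        precision_no_star=params.precision_no_star,
    )
    kept = ann.resolve_locus_overlaps(accepted)
    overlap_rejected = [a for a in accepted if a.status == "rejected_overlap"]
    families = ann.group_families(kept)
    return DiscoveryResult(
        accepted=kept,
        rejected=rejected + overlap_rejected,
        families=families,
        mapping=mapping,
        n_loci=len(loci),
        n_loci_folded=n_folded,
        dropped_loci=dropped,
    )


def run_from_raw_reads(
    genome: Genome,
    raw_reads: Iterable[RawRead],
    adaptor: str,
    params: Optional[DiscoveryParams] = None,
    **kwargs,
) -> tuple[DiscoveryResult, list[CollapsedRead], dict]:
    """QC + collapse + discover, returning the result, the qualified
    collapsed reads and the QC discard tally."""
    qualified, tally = qc_filter(raw_reads, adaptor)
    collapsed = collapse_reads(qualified)
    result = discover_mirnas(genome, collapsed, params=params, **kwargs)
    return result, collapsed, dict(tally)
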