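"""Mature/star calling, duplex checks, precision, rules and ratios."""

import random

import pytest

from mircot.formats_io import CollapsedRead, revcomp
from mircot.genome_map import ReadAlignment
from mircot.hairpin_discovery import filter_hairpin_segments, fold_segment
from mircot.mirna_annotation import (
    MirnaAnnotation,
    ArmRead,
    annotate_mirnas,
    apply_annotation_rules,
    call_mature_and_star,
    catalog_summary,
    compute_precision,
    expressed_known_mirnas,
    format_ratio,
    group_families,
    mirna_star_ratio,
    resolve_locus_overlaps,
    validate_duplex,
)


def build_candidate(mature_counts=None, star_count=10, iso_count=0,
                    mature_len=21, pad=8, seed=0, mature_prefix="T"):
    """Fold a constructed hairpin and attach synthetic arm reads."""
    rng = random.Random(seed)
    mature = mature_prefix + "".join(rng.choice("ACGT") for _ in range(mature_len - 1))
    arm5 = "".join(rng.choice("ACGT") for _ in range(pad)) + mature + "".join(
        rng.choice("ACGT") for _ in range(pad)
    )
    loop = "AACAACAA"
    hairpin = arm5 + loop + revcomp(arm5)
    n = len(hairpin)
    a = pad
    star_start = n - a - mature_len + 2
    star = hairpin[star_start : star_start + mature_len]

    segs = fold_segment(hairpin)
    assert segs, "constructed hairpin failed to fold"
    seg = segs[0]

    reads = []
    if mature_counts is None:
        mature_counts = {"lib1": 30, "lib2": 25}
    reads.append(
        ReadAlignment(
            read=CollapsedRead(sequence=mature, counts=dict(mature_counts)),
            chrom="", start=a, end=a + mature_len, strand="+",
        )
    )
    if star_count:
        reads.append(
            ReadAlignment(
                read=CollapsedRead(sequence=star, counts={"lib1": star_count}),
                chrom="", start=star_start, end=star_start + mature_len, strand="+",
            )
        )
    if iso_count:
        reads.append(
            ReadAlignment(
                read=CollapsedRead(
                    sequence=hairpin[a + 1 : a + 1 + mature_len],
                    counts={"lib1": iso_count},
                ),
                chrom="", start=a + 1, end=a + 1 + mature_len, strand="+",
            )
        )
    cand = filter_hairpin_segments(seg, reads)
    assert cand.passed
    return cand, mature, star


class TestCallMatureAndStar:
    def test_highest_count_read_is_mature_iso_excluded(self):
        cand, mature, _star = build_candidate(
            mature_counts={"lib1": 300, "lib2": 200}, iso_count=40
        )
        ann = call_mature_and_star(cand)
        assert ann.mature.sequence == mature
        assert ann.mature.count == 500  # iso reads not pooled into the count
        assert ann.n_libraries_detected == 2

    def test_star_absent_when_not_observed(self):
        cand, _m, _s = build_candidate(star_count=0)
        ann = call_mature_and_star(cand)
        assert ann.star is None

    def test_star_read_found_on_opposite_arm(self):
        cand, _m, star = build_candidate(star_count=7)
        ann = call_mature_and_star(cand)
        assert ann.star is not None
        assert ann.star.sequence == star
        assert ann.star.count == 7
        assert {ann.mature.arm, ann.star.arm} == {"5p", "3p"}

    def test_five_prime_u_tiebreak(self):
        cand, _m, _s = build_candidate(star_count=0, seed=3)
        # add an equal-count 5'-A read elsewhere on the same arm
        seg = cand.segment
        mature_total = sum(
            r.total_count for _sp, r in cand.reads_on_arms
        )
        span, u_read = cand.reads_on_arms[0]
        a_seq = "A" + u_read.sequence[1:]
        cand.reads_on_arms.append(
            ((span[0], span[1]), CollapsedRead(sequence=a_seq,
                                               counts={"lib1": u_read.total_count}))
        )
        ann = call_mature_and_star(cand)
        assert ann.mature.sequence.startswith("T")


class TestDuplex:
    def test_canonical_duplex_passes(self):
        cand, _m, _s = build_candidate()
        ann = call_mature_and_star(cand)
        check = validate_duplex(ann)
        assert check.overhang_3p_mature == 2
        assert check.overhang_3p_star == 2
        assert check.duplex_mismatches <= 5
        assert not check.in_loop
        assert check.passed

    def test_blunt_duplex_fails(self):
        cand, _m, _s = build_candidate()
        ann = call_mature_and_star(cand)
        # shift the star span to simulate blunt-end processing
        s0, s1 = ann.star.span
        ann.star = ArmRead(
            sequence=ann.star.sequence, arm=ann.star.arm, count=ann.star.count,
            span=(s0 + 2, s1 + 2), counts_by_library=ann.star.counts_by_library,
        )
        check = validate_duplex(ann)
        assert check.overhang_3p_mature not in (2, 3)
        assert not check.passed

    def test_mature_straddling_loop_fails(self):
        cand, _m, _s = build_candidate()
        ann = call_mature_and_star(cand)
        loop = cand.segment.stem.loop
        ann.mature = ArmRead(
            sequence=ann.mature.sequence, arm=ann.mature.arm,
            count=ann.mature.count,
            span=(loop[0] - 20, loop[0] + 1),  # one base into the loop
            counts_by_library=ann.mature.counts_by_library,
        )
        check = validate_duplex(ann)
        assert check.in_loop and not check.passed


class TestPrecision:
    def test_arithmetic(self):
        assert compute_precision(100, 45, 5) == 50.0

    def test_upper_bound(self):
        assert compute_precision(55, 50, 5) == 100.0

    def test_mature_only_boundary(self):
        assert compute_precision(100, 10, 0) == 10.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            compute_precision(0, 0, 0)

    def test_bounded(self):
        rng = random.Random(1)
        for _ in range(200):
            total = rng.randint(1, 10_000)
            mature = rng.randint(0, total)
            star = rng.randint(0, total - mature)
            assert 0.0 <= compute_precision(total, mature, star) <= 100.0


def make_annotation(count=50, libs=2, precision=50.0, with_star=True,
                    star_count=5, chrom="c", span=(0, 250), strand="+"):
    """Rule-level fixture that bypasses folding."""

    class _Seg:
        pass

    class _Cand:
        pass

    seg = _Seg()
    seg.chrom, seg.strand = chrom, strand
    seg.seg_start, seg.seg_end = span
    cand = _Cand()
    cand.segment = seg
    counts_by_library = {f"lib{i+1}": count // libs or 1 for i in range(libs)}
    mature = ArmRead("T" + "A" * 20, "5p", count, (10, 31), counts_by_library)
    star = (
        ArmRead("C" + "G" * 20, "3p", star_count, (40, 61), {"lib1": star_count})
        if with_star
        else None
    )
    ann = MirnaAnnotation(
        hairpin=cand, mature=mature, star=star,
        n_libraries_detected=libs, precision=precision, duplex=None,
    )
    if with_star:
        ann.duplex = __import__("mircot.mirna_annotation", fromlist=["DuplexCheck"]).DuplexCheck(2, 2, 1, False)
    return ann


class TestAnnotationRules:
    def test_min_reads_boundary(self):
        assert apply_annotation_rules(make_annotation(count=9)).status == "rejected_min_reads"
        assert apply_annotation_rules(make_annotation(count=10)).accepted

    def test_min_libraries(self):
        ann = make_annotation(libs=1)
        assert apply_annotation_rules(ann).status == "rejected_min_libraries"

    def test_no_star_precision_boundary(self):
        assert (
            apply_annotation_rules(make_annotation(with_star=False, precision=44.9)).status
            == "rejected_precision_no_star"
        )
        assert apply_annotation_rules(make_annotation(with_star=False, precision=45.0)).accepted

    def test_with_star_precision_boundary(self):
        assert (
            apply_annotation_rules(make_annotation(precision=9.99)).status
            == "rejected_precision"
        )
        assert apply_annotation_rules(make_annotation(precision=10.0)).accepted

    def test_bad_duplex_rejected(self):
        from mircot.mirna_annotation import DuplexCheck

        ann = make_annotation()
        ann.duplex = DuplexCheck(0, 2, 1, False)
        assert apply_annotation_rules(ann).status == "rejected_duplex"

    def test_accepted_reaudit(self):
        ann = apply_annotation_rules(make_annotation(count=100, precision=80.0))
        assert ann.accepted
        assert ann.mature.count >= 10
        assert ann.n_libraries_detected >= 2
        assert ann.duplex.passed and ann.precision >= 10.0


class TestKnownExpression:
    def test_ten_read_cutoff(self):
        mature = {"mir-a": "T" + "G" * 20, "mir-b": "A" + "C" * 20}
        collapsed = [
            CollapsedRead("T" + "G" * 20, {"l1": 6, "l2": 4}),
            CollapsedRead("A" + "C" * 20, {"l1": 9}),
        ]
        calls = expressed_known_mirnas(collapsed, mature)
        assert calls == {"mir-a": 10}


class TestOverlapResolution:
    def test_higher_count_wins(self):
        a = make_annotation(count=100, span=(0, 250))
        b = make_annotation(count=50, span=(100, 350))
        kept = resolve_locus_overlaps([a, b])
        assert kept == [a] and b.status == "rejected_overlap"

    def test_precision_breaks_count_tie(self):
        a = make_annotation(count=50, precision=90.0, span=(0, 250))
        b = make_annotation(count=50, precision=60.0, span=(100, 350))
        assert resolve_locus_overlaps([a, b]) == [a]

    def test_disjoint_and_opposite_strand_kept(self):
        a = make_annotation(span=(0, 250))
        b = make_annotation(span=(300, 550))
        c = make_annotation(span=(0, 250), strand="-")
        kept = resolve_locus_overlaps([a, b, c])
        assert len(kept) == 3

    def test_no_overlaps_remain(self):
        rng = random.Random(2)
        anns = [
            make_annotation(count=rng.randint(10, 500),
                            span=(s := rng.randrange(2000), s + 250))
            for _ in range(30)
        ]
        kept = resolve_locus_overlaps(anns)
        for i, x in enumerate(kept):
            for y in kept[i + 1:]:
                assert not (
                    x.strand == y.strand
                    and x.span[0] < y.span[1]
                    and y.span[0] < x.span[1]
                )


class TestFamilies:
    def mk(self, seq, span=(0, 100), chrom="c"):
        ann = make_annotation(span=span, chrom=chrom)
        ann.mature = ArmRead(seq, "5p", 50, (10, 10 + len(seq)), {"lib1": 50})
        return ann

    def test_one_edit_groups(self):
        base = "TGGAGCTCCTTGAAGTCGATC"
        one_off = "TGGAGCTCCTTGAAGTCGATG"
        fams = group_families([self.mk(base), self.mk(one_off, span=(200, 300))])
        assert len(fams) == 1 and len(fams[0].members) == 2

    def test_five_edits_split(self):
        a = "TGGAGCTCCTTGAAGTCGATC"
        b = "TGGAGAAACTTGAAGTCTTTC"
        fams = group_families([self.mk(a), self.mk(b, span=(200, 300))])
        assert len(fams) == 2

    def test_known_family_name_inherited(self):
        seq = "TGGAGCTCCTTGAAGTCGATC"
        fams = group_families([self.mk(seq)], known_families={"miR-x": seq})
        assert fams[0].family_id == "miR-x" and fams[0].conserved

    def test_order_invariance(self):
        rng = random.Random(7)
        seqs = ["".join(rng.choice("ACGT") for _ in range(21)) for _ in range(10)]
        anns = [self.mk(s, span=(i * 300, i * 300 + 100)) for i, s in enumerate(seqs)]
        f1 = group_families(list(anns))
        f2 = group_families(list(reversed(anns)))
        sig = lambda fams: sorted(
            tuple(sorted(m.mature.sequence for m in f.members)) for f in fams
        )
        assert sig(f1) == sig(f2)


class TestRatios:
    @pytest.mark.parametrize(
        "mature,star,expected",
        [
            (30656, 1688, 18.16),
            (3476, 0, None),
            (1088, 1, 1088.00),
            (37449, 23, 1628.22),
            (234260, 84, 2788.81),
            (980289, 28181, 34.79),
            (16954526, 10467, 1619.81),
            (1088, 2, 544.00),
        ],
    )
    def test_duplex_accounting(self, mature, star, expected):
        assert mirna_star_ratio(mature, star) == expected

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            mirna_star_ratio(0, 0)

    def test_display_formats_with_thousands_separator(self):
        assert format_ratio(1628.22) == "1,628.22"
        assert format_ratio(None) == ""


class TestCatalogSummary:
    def test_totals_by_summation(self):
        records = []
        # 3 conserved genes in 2 families, 2 non-conserved in 2 families
        records += [
            {"family_id": "f1", "conserved": True, "known": True},
            {"family_id": "f1", "conserved": True, "known": False},
            {"family_id": "f2", "conserved": True, "known": True},
            {"family_id": "g1", "conserved": False, "known": False},
            {"family_id": "g2", "conserved": False, "known": False},
        ]
        summary = catalog_summary(records)
        assert summary["total"]["n_genes"] == 5
        assert summary["total"]["n_families"] == 4
        assert summary["conserved"]["median_family_size"] == 1.5
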