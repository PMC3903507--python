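"""Locus merging, window arithmetic, folding and structural filters."""

import random

import pytest

from mircot.formats_io import CollapsedRead, revcomp
from mircot.genome_map import ReadAlignment
from mircot.hairpin_discovery import (
    FoldedSegment,
    ReadLocus,
    extract_candidate_windows,
    filter_hairpin_segments,
    find_hairpin_stems,
    fold_segment,
    merge_read_loci,
    pair_table,
    select_representatives,
    window_count_closed_form,
)


def aln(start, length=21, chrom="c", strand="+", count=1, lib="lib1", seq=None):
    seq = seq or "".join(random.Random(start).choice("ACGT") for _ in range(length))
    return ReadAlignment(
        read=CollapsedRead(sequence=seq, counts={lib: count}),
        chrom=chrom,
        start=start,
        end=start + length,
        strand=strand,
    )


class TestMergeLoci:
    def test_overlapping_reads_merge(self):
        loci = merge_read_loci([aln(100), aln(110)])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 131)

    def test_abutting_reads_do_not_merge(self):
        loci = merge_read_loci([aln(100), aln(121)])
        assert len(loci) == 2

    def test_strands_kept_separate(self):
        loci = merge_read_loci([aln(100, strand="+"), aln(100, strand="-")])
        assert len(loci) == 2

    def test_matches_union_find_oracle(self):
        rng = random.Random(11)
        for _trial in range(20):
            alignments = [aln(rng.randrange(500), length=rng.randint(17, 24))
                          for _ in range(30)]
            # union-find over the pairwise overlap graph
            n = len(alignments)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = alignments[i], alignments[j]
                    if a.start < b.end and b.start < a.end:
                        parent[find(i)] = find(j)
            components = {}
            for i, a in enumerate(alignments):
                components.setdefault(find(i), []).append((a.start, a.end))
            expected = sorted(
                (min(s for s, _ in grp), max(e for _, e in grp))
                for grp in components.values()
            )
            got = sorted((l.start, l.end) for l in merge_read_loci(alignments))
            assert got == expected


class TestWindows:
    def locus(self, start, end, chrom="c"):
        return ReadLocus(chrom=chrom, strand="+", start=start, end=end,
                         reads=[aln(start, length=end - start)])

    def test_enumerated_windows_for_21nt_locus(self):
        wins = extract_candidate_windows(self.locus(1000, 1021), chrom_length=10_000)
        assert wins[0] == (780, 1030)
        assert wins[-1] == (1000, 1250)
        assert len(wins) == 23
        assert all(b - a == 250 for a, b in wins)
        assert all(wins[i + 1][0] - wins[i][0] == 10 for i in range(len(wins) - 1))

    def test_stopping_rule(self):
        # the last window is the first whose end reaches end + flank
        wins = extract_candidate_windows(self.locus(1000, 1021), chrom_length=10_000)
        assert wins[-1][1] >= 1021 + 220
        assert wins[-2][1] < 1021 + 220

    def test_edge_clipping(self):
        wins = extract_candidate_windows(self.locus(5, 26), chrom_length=10_000)
        assert wins[0] == (0, 250)

    def test_window_set_covers_flanked_locus(self):
        locus = self.locus(2000, 2100)
        wins = extract_candidate_windows(locus, chrom_length=10_000)
        covered = set()
        for a, b in wins:
            covered.update(range(a, b))
        assert covered >= set(range(2000 - 220, 2100 + 220))

    def test_closed_form_matches_enumeration(self):
        rng = random.Random(4)
        for _ in range(100):
            width = rng.randint(17, 400)
            locus = self.locus(5000, 5000 + width)
            wins = extract_candidate_windows(locus, chrom_length=100_000)
            assert len(wins) == window_count_closed_form(width), width


class TestPairTableAndStems:
    def test_pair_table_roundtrip(self):
        s = "((((...))))"
        t = pair_table(s)
        assert t[0] == 10 and t[10] == 0 and t[4] == -1

    def test_unbalanced_raises(self):
        with pytest.raises(ValueError):
            pair_table("(((..")

    def test_single_hairpin_stem(self):
        s = "((((((....))))))"
        (stem,) = find_hairpin_stems(s)
        assert stem.n_pairs == 6
        assert stem.loop == (6, 10)
        assert stem.arm5 == (0, 6) and stem.arm3 == (10, 16)

    def test_stem_walk_crosses_bulge(self):
        s = "(((.(((....))))))"
        (stem,) = find_hairpin_stems(s)
        assert stem.n_pairs == 6  # bulge does not break the helix chain

    def test_multiloop_yields_two_stems(self):
        s = "((.((((...)))).((((...)))).))"
        stems = find_hairpin_stems(s)
        assert len(stems) == 2
        assert all(stem.n_pairs == 4 for stem in stems)


class TestFolding:
    def test_poly_a_has_no_qualifying_structure(self):
        assert fold_segment("A" * 250) == []

    def test_perfect_inverted_repeat_folds_to_hairpin(self):
        rng = random.Random(6)
        arm = "".join(rng.choice("ACGT") for _ in range(30))
        hairpin = arm + "AACAAC" + revcomp(arm)
        segs = fold_segment(hairpin)
        assert segs
        top = segs[0]
        assert top.mfe <= -18
        assert top.stem is not None and top.stem.n_pairs >= 25
        lo, hi = top.stem.loop
        assert 4 <= hi - lo <= 8

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            fold_segment("ACGT" * 5)  # 20 nt < 40

    def test_backends_agree_on_mfe(self):
        rng = random.Random(13)
        for _ in range(10):
            arm = "".join(rng.choice("ACGT") for _ in range(40))
            seq = (
                "".join(rng.choice("ACGT") for _ in range(30))
                + arm + "AACCAA" + revcomp(arm)
                + "".join(rng.choice("ACGT") for _ in range(30))
            )
            a = fold_segment(seq, backend="vienna")
            b = fold_segment(seq, backend="rnafold")
            assert a and b
            assert a[0].mfe == pytest.approx(b[0].mfe, rel=0.10)

    def test_unknown_backend_names_alternatives(self):
        from mircot.hairpin_discovery import FoldBackendError

        with pytest.raises(FoldBackendError, match="vienna"):
            fold_segment("A" * 50, backend="nonsense")


def synthetic_candidate(n_pairs=22, read_span=None, counts=(50,), mfe=-30.0,
                        unpaired_under_read=0):
    """Hand-built folded segment: n_pairs stem with a 6-nt loop, optionally
    forcing unpaired positions inside the read span."""
    arm = n_pairs
    struct = list("(" * arm + "." * 6 + ")" * arm)
    seq = "G" * arm + "AACAAC" + "C" * arm
    if unpaired_under_read and read_span:
        # break pairs starting mid-read (both partners become dots)
        s, _e = read_span
        for k in range(unpaired_under_read):
            pos = s + 2 + k
            struct[pos] = "."
            struct[2 * arm + 6 - 1 - pos] = "."
    segment = FoldedSegment(
        chrom="c", strand="+", seg_start=0, seg_end=2 * arm + 6,
        sequence=seq, structure="".join(struct), mfe=mfe,
        stem=find_hairpin_stems("".join(struct))[0] if "(" in struct else None,
    )
    reads = []
    if read_span:
        s, e = read_span
        reads.append(
            ReadAlignment(
                read=CollapsedRead(sequence=seq[s:e], counts={"lib1": counts[0]}),
                chrom="c", start=s, end=e, strand="+",
            )
        )
    return segment, reads


class TestFilters:
    def test_stem18_boundary(self):
        seg17, reads = synthetic_candidate(n_pairs=17, read_span=(0, 17))
        assert not filter_hairpin_segments(seg17, reads).passes["stem18"]
        seg18, reads = synthetic_candidate(n_pairs=18, read_span=(0, 18))
        assert filter_hairpin_segments(seg18, reads).passes["stem18"]

    def test_reads_in_loop_fail_reads_on_stem(self):
        seg, _ = synthetic_candidate(n_pairs=22)
        loop_read = ReadAlignment(
            read=CollapsedRead(sequence=seg.sequence[14:35], counts={"l": 5}),
            chrom="c", start=14, end=35, strand="+",
        )  # straddles the loop: not fully within an arm
        cand = filter_hairpin_segments(seg, [loop_read])
        assert not cand.passes["reads_on_stem"]

    def test_mismatch_boundary_five_passes_six_fails(self):
        seg5, reads5 = synthetic_candidate(
            n_pairs=30, read_span=(0, 21), unpaired_under_read=5
        )
        assert filter_hairpin_segments(seg5, reads5).passes["structure_mismatches"]
        seg6, reads6 = synthetic_candidate(
            n_pairs=30, read_span=(0, 21), unpaired_under_read=6
        )
        assert not filter_hairpin_segments(seg6, reads6).passes["structure_mismatches"]

    def test_energy_boundary_sign_sensitive(self):
        seg_pass, reads = synthetic_candidate(read_span=(0, 20), mfe=-18.0)
        assert filter_hairpin_segments(seg_pass, reads).passes["energy"]
        seg_fail, reads = synthetic_candidate(read_span=(0, 20), mfe=-17.9)
        assert not filter_hairpin_segments(seg_fail, reads).passes["energy"]

    def test_candidate_revalidates(self):
        seg, reads = synthetic_candidate(read_span=(0, 20))
        cand = filter_hairpin_segments(seg, reads)
        assert cand.revalidate() == cand.passes


class TestRepresentatives:
    def test_shifted_identical_windows_collapse(self):
        rng = random.Random(21)
        arm = "".join(rng.choice("ACGT") for _ in range(30))
        hairpin = arm + "AACAAC" + revcomp(arm)
        flank = "".join(rng.choice("ACGT") for _ in range(60))
        genome_seq = flank + hairpin + flank
        read = ReadAlignment(
            read=CollapsedRead(sequence=genome_seq[62:83], counts={"l": 40}),
            chrom="c", start=62, end=83, strand="+",
        )
        cands = []
        for shift in (0, 10, 20):
            seq = genome_seq[shift : shift + 150]
            for seg in fold_segment(seq, chrom="c", seg_start=shift):
                cand = filter_hairpin_segments(seg, [read])
                if cand.passed:
                    cands.append(cand)
        assert len(cands) >= 2
        reps = select_representatives(cands)
        assert len(reps) == 1

    def test_tie_breaks_leftmost(self):
        seg_a, reads = synthetic_candidate(read_span=(0, 20))
        cand_a = filter_hairpin_segments(seg_a, reads)
        seg_b, _ = synthetic_candidate(read_span=(0, 20))
        seg_b.seg_start += 100  # same structure, placed to the right
        seg_b.seg_end += 100
        shifted = [
            ReadAlignment(read=r.read, chrom="c", start=r.start + 100,
                          end=r.end + 100, strand="+")
            for r in reads
        ]
        cand_b = filter_hairpin_segments(seg_b, shifted)
        reps = select_representatives([cand_b, cand_a])
        # disjoint signatures: both survive as distinct hairpins
        assert len(reps) == 2
        assert reps[0].segment.seg_start == 0
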