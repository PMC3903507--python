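# Methods

## Discovery pipeline

**Read QC.** The 3' adaptor is located as the longest substring of the
adaptor occurring anywhere in the read; the read is trimmed from the
leftmost occurrence of that longest match. Matches of ≤ 6 nt do not count
as an adaptor and such reads are discarded. Ties between equal-length
matches are broken leftmost, which yields the shortest insert — the
conservative choice, since the 3' adaptor follows the insert. "Low
quality" is operationalised as any base below Q20 when qualities are
present; FASTA input skips the check. Inserts are kept at 17–30 nt (the
gel-excised library range) with no ambiguous bases. U and T are one
symbol: storage uses T, display uses U.

**Collapsing and mapping.** Unique sequences carry per-library counts;
every downstream number is a sum over these species. Mapping is an exact
(0-mismatch) contract over both strands: every hit is reported, and a
multi-mapping read contributes its full count at every locus (`n_hits`
lets consumers exclude multi-mapped signal); no fractional apportioning is
invented. Known-miRNA expression calls use exact sequence identity to the
mature sequence, never positional overlap, and require ≥ 10 exact reads.

**Hairpin candidates.** Alignments merge into loci wherever read intervals
overlap by ≥ 1 bp (transitively); abutting reads do not merge (half-open
intervals). Each locus is scanned with 250-nt windows stepping 10 nt from
220 nt upstream of the reads until a window reaches 220 nt downstream; the
closed-form window count for a read span *w* is ⌈(w + 190)/10⌉ + 1.
Windows are folded on the read strand only. Up to five structures with
free energy ≤ −18 kcal/mol are taken from the suboptimal ensemble within
2 kcal/mol of the MFE; the energy gate is sign-sensitive (−18.0 passes,
−17.9 fails). The hairpin stem is the helix chain that closes a terminal
loop, walked outward through bulges and interior loops and stopped at
multiloop junctions; "stem of ≥ 18 nt" counts *paired* positions on one
arm, since requiring 18 contiguous pairs would reject most real
precursors. Windows describing the same hairpin (read-span paired-position
sets agreeing at Jaccard ≥ 0.9 in genomic coordinates) collapse to one
representative (most arm reads, then lowest energy, then leftmost).
Because a mature and its star often fall in disjoint read loci, windows
are annotated against every alignment they contain, not only the seeding
locus's reads.

**Annotation rules.** The mature is the arm read with the highest
cumulative count (ties prefer 5'-U, then leftmost). The star is the
opposite-arm read positioned to pair with the mature, with ± 2 nt register
slack for imprecise processing. Duplex diagnostics (3' overhangs on both
ends, unpaired mature positions inside the duplex, loop intrusion) are
computed from the pair table. Precision = 100·(mature + star)/(all reads
on the hairpin window); the formula is normalised so precision ∈ [0, 100].
Acceptance requires mature count ≥ 10, detection in ≥ 2 libraries (≥ 1
exact mature read each), and either a passing duplex with precision ≥ 10%
or, with no star observed, precision ≥ 45%. Same-strand overlapping
hairpins resolve by count, then precision, then leftmost. Families are
single-linkage clusters of mature sequences at edit distance ≤ 2 (the
1-nt-apart family precedent generalised; the threshold is exposed).
The ≥ 10-read rule is applied to the mature species alone, not
mature+star combined; users who prefer the combined reading can lower
`min_reads` and filter on the reported counts.

**Runtime.** Loci whose most abundant species is below the 10-read
threshold are skipped before folding. No such locus can produce an
accepted miRNA, so the output is unchanged, but the dominant cost —
folding windows around thousands of single-copy background reads —
disappears.

## Evolutionary analyses

A duplicated-segment locus is *retained* iff the partner segment carries a
locus whose mature is within edit distance 2 (configurable; the criterion
is this package's own, stated outcome-first sources give no rule).
Summaries report integer percentages overall and per category. K2P uses
pairwise gap deletion and raises on saturation rather than returning NaN.
Neighbor joining is implemented directly so that Q-matrix ties break on
the smallest taxon-index pair, making tree output deterministic; the final
three clusters join at a trifurcation (unrooted tree). Conservation age is
the class of the deepest-diverging plant order where a family is present,
over a configurable order→age map; a family absent outside (and inside)
the fabales order is species-specific.

## Enrichment

Bins are hierarchical dotted labels with prefix-closure (membership in a
child counts toward every ancestor). Per bin, the 2×2 table of
target/non-target × in/out-of-bin is tested with a two-sided Fisher's
exact test (both over- and under-representation are of interest); the
sample odds ratio is (a·d)/(b·c). The universe defaults to the genes in
the bin table — the binned-gene background, not the whole genome — and can
be overridden. No multiple-testing correction is applied by default (raw
p-values are the reporting convention here); Benjamini–Hochberg is
available as an option.

## Synthetic data generator

The generator emulates the statistical structure of a cotyledon-style
small-RNA study at desk scale:

* **Hairpins** are inverted repeats of a sampled mature sequence (8-nt
  pads each side, 8-nt A/C loop), with 0–3 point mutations on the 3' arm
  to exercise the mismatch filters near their boundary; duplex ends are
  spared so overhangs stay canonical. Constructs are verified to fold
  below −25 kcal/mol and redrawn otherwise. Mature lengths follow the
  plant-typical distribution (mode 21 nt, mass on 20–24), and the 5' base
  is U with probability 0.92 — the observed 5'-U bias of genuine miRNAs.
* **Reads**: mature counts are Poisson with mean 100/hairpin, split
  uniformly over 3 libraries; star counts follow a log-normal
  miRNA/miRNA\* ratio (median 10, σ = 1, spanning the ~1.5–2800 range seen
  in real duplex tables); iso-reads (±1–2 nt offsets) appear at 0.1 per
  mature read; 24-nt background reads make up 40% of all reads (the
  dominant heterochromatic class), 85% drawn from the genome and 15%
  random, echoing the mapped fraction of real libraries. Each insert gets
  the TruSeq small-RNA 3' adaptor appended and is truncated to a 50-nt
  instrument read.
* **Duplications**: a window around half the hairpins is copied to a fresh
  region; with probability 0.45 the copy keeps the hairpin with 1–2
  mutations in mature and star (within the retention-homology threshold
  but mapping distinctly), otherwise the hairpin is replaced by random
  sequence. An IR-cluster mode plants tandem near-copies of one hairpin
  (mutated on both arms per copy) for family-grouping tests.
* **Determinism**: one global seed drives a named substream per stage
  (genome, hairpins, segments, reads, background), so the same config
  reproduces a bundle byte for byte and stages can be regenerated
  independently.

**Problem sizes.** The real study's 292M reads across 18 libraries are
emulated at 12 hairpins on 2×60-kb chromosomes with ~2,500 reads in 3
libraries (the default config, used by `scripts/acceptance.py`); the
five-seed recovery tests use 8 hairpins on 2×40-kb chromosomes. The
retention analysis, which needs no reads, uses 60 loci. These sizes keep a
full run around a minute while leaving every rule boundary exercised.

**What passing tests do and do not show.** The generator reproduces the
pileup *shape* of Dicer products (dominant mature, 2-nt-overhang star,
iso-read halo, background) but not sequencing error, ligation bias,
heterochromatic siRNA clustering, or genome-scale repeat structure; all
planted hairpins sit on the plus strand (minus-strand mapping and folding
are unit-tested directly). Perfect recovery on synthetic bundles therefore
validates the pipeline's logic and thresholds, not its behaviour on noisy
genome-scale data. One deliberate artefact: a perfect inverted repeat is
the same hairpin read off either strand, so discovery can legitimately
report a minus-strand twin of a planted plus-strand hairpin; truth-ledger
evaluation counts these as the same planted locus, never as false
discoveries.

## Known limitations

No mismatch-tolerant or spliced alignment; no phasiRNA/tasiRNA detection;
no multi-loop precursors or pseudoknots; alignments for dating are
consumed, never computed; no bootstrap support on trees; target
prediction is consumed as a table, never computed.
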