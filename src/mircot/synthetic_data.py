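"""Synthetic small-RNA study generator.

Builds a toy genome with planted miRNA hairpins (inverted repeats of a
sampled mature sequence around a short loop), duplicated segment pairs
with controlled retention, and Dicer-like read pileups: a dominant mature
species, a star species positioned for 2-nt 3' overhangs, low-frequency
iso-reads offset by 1-2 nt, and background 24-nt reads emulating
heterochromatic siRNAs. Reads get a 3' adaptor appended and truncated to
the instrument read length, so the full trimming/QC path is exercised.

Every quantity is driven by a single seed through named substreams; the
same config reproduces the same bundle byte for byte. The ground-truth
ledger records every planted hairpin, segment pair and read provenance so
parameter-recovery tests can compare pipeline output against truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .formats_io import GffFeature, RawRead, revcomp, write_gff3
from .genome_map import Genome

DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adaptor

_STAGES = ("genome", "hairpins", "segments", "reads", "background")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_hairpins: int = 12
    # mature length distribution: the 21-nt mode of plant miRNAs with mass
    # on 20-24 nt
    mature_len_probs: dict[int, float] = field(
        default_factory=lambda: {20: 0.10, 21: 0.60, 22: 0.15, 23: 0.10, 24: 0.05}
    )
    mature_5prime_U_prob: float = 0.92
    reads_per_mature: float = 100.0  # Poisson mean per hairpin
    # log-normal miRNA/miRNA* ratio: median ~10, spanning the 1.5-2800
    # range seen in real duplex accounting
    star_ratio_log_mean: float = float(np.log(10.0))
    star_ratio_log_sd: float = 1.0
    iso_read_prob: float = 0.10  # iso-reads per mature read
    background_24nt_fraction: float = 0.40  # of all simulated reads
    background_mappable_fraction: float = 0.85
    n_libraries: int = 3
    adaptor: str = DEFAULT_ADAPTOR
    read_length: int = 50
    duplicated_pair_fraction: float = 0.5
    retention_prob: float = 0.45
    # miR15/49-style mode: plant this many tandem near-copies of one
    # hairpin (0 disables)
    ir_cluster_copies: int = 0
    ir_cluster_max_mutations: int = 2
    arm_pad: int = 8  # stem positions flanking the mature on its arm
    loop_length: int = 8
    stem_mutations_max: int = 3

    def __post_init__(self) -> None:
        probs = list(self.mature_len_probs.values()) + [
            self.mature_5prime_U_prob,
            self.iso_read_prob,
            self.background_24nt_fraction,
            self.background_mappable_fraction,
            self.duplicated_pair_fraction,
            self.retention_prob,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.mature_len_probs.values()) - 1.0) > 1e-9:
            raise ValueError("mature_len_probs must sum to 1")
        if min(self.n_chromosomes, self.chrom_length, self.n_libraries,
               self.read_length) <= 0:
            raise ValueError("sizes must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """One named random stream per generator stage so stages can be
        regenerated independently."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        return np.random.default_rng([self.seed, _STAGES.index(stage)])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["mature_len_probs"] = {
            int(k): float(v) for k, v in raw["mature_len_probs"].items()
        }
        return cls(**raw)


@dataclass
class PlantedHairpin:
    hairpin_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mature: str
    mature_start: int  # genomic
    star: str
    star_start: int
    family_id: str
    expressed: bool = True
    is_partner_copy: bool = False
    mature_counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)
    n_iso_reads: int = 0
    n_planted_reads: int = 0  # all reads planted on this hairpin

    @property
    def mature_total(self) -> int:
        return sum(self.mature_counts.values())

    @property
    def star_total(self) -> int:
        return sum(self.star_counts.values())


@dataclass
class PlantedSegmentPair:
    pair_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    hairpin_id_a: str
    hairpin_id_b: Optional[str]
    retained: bool


@dataclass
class SyntheticTruth:
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    segment_pairs: list[PlantedSegmentPair] = field(default_factory=list)
    read_provenance: list[tuple[str, str, Optional[str]]] = field(
        default_factory=list
    )  # (read_id, origin in {mature, star, iso, background}, hairpin_id)

    def expressed_hairpins(self, min_mature_reads: int = 1) -> list[PlantedHairpin]:
        return [
            h
            for h in self.hairpins
            if h.expressed and h.mature_total >= min_mature_reads
        ]


# ---------------------------------------------------------------------------
# Genome generation


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def _sample_mature(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    lengths = sorted(cfg.mature_len_probs)
    probs = [cfg.mature_len_probs[l] for l in lengths]
    length = int(rng.choice(lengths, p=probs))
    seq = _random_seq(rng, length)
    if rng.random() < cfg.mature_5prime_U_prob:
        seq = "T" + seq[1:]
    elif seq[0] == "T":
        seq = rng.choice(list("ACG")) + seq[1:]
    return seq


def _build_hairpin(
    rng: np.random.Generator, cfg: SyntheticConfig, mature: str
) -> tuple[str, int, str, int]:
    """Construct one fold-back sequence around ``mature``.

    Returns (hairpin sequence, mature offset, star sequence, star offset).
    The 3' arm is the reverse complement of the 5' arm with 0-3 point
    mutations placed outside the star's terminal dinucleotides, so the
    duplex keeps its 2-nt 3' overhangs but exercises the mismatch filters.
    """
    pad = cfg.arm_pad
    arm5 = _random_seq(rng, pad) + mature + _random_seq(rng, pad)
    loop = _random_seq(rng, cfg.loop_length, alphabet="AC")  # weakly pairing
    arm3 = list(revcomp(arm5))
    n = len(arm5) * 2 + cfg.loop_length

    L = len(mature)
    a = pad  # mature offset in hairpin
    star_start = n - a - L + 2
    star_end = n - a + 2
    n_mut = int(rng.integers(0, cfg.stem_mutations_max + 1))
    arm3_off = len(arm5) + cfg.loop_length
    mutable = [
        i
        for i in range(len(arm3))
        # keep the duplex ends intact so overhangs stay canonical
        if not (star_start - arm3_off <= i < star_start - arm3_off + 3)
        and not (star_end - arm3_off - 3 <= i < star_end - arm3_off)
    ]
    for i in rng.choice(mutable, size=min(n_mut, len(mutable)), replace=False):
        current = arm3[i]
        arm3[i] = rng.choice([b for b in "ACGT" if b != current])
    hairpin = arm5 + loop + "".join(arm3)
    star = hairpin[star_start:star_end]
    return hairpin, a, star, star_start


def _verify_foldable(hairpin: str, energy_max: float = -25.0) -> bool:
    import RNA

    _struct, mfe = RNA.fold(hairpin.replace("T", "U"))
    return mfe <= energy_max


def generate_genome(cfg: SyntheticConfig) -> tuple[Genome, SyntheticTruth]:
    """Random background chromosomes with planted hairpins and duplicated
    segment pairs.

    Hairpins are spaced >= 600 bp apart. Segment pairs copy a window
    around a hairpin to a fresh location; with probability
    ``retention_prob`` the copy keeps a (1-2 nt mutated) hairpin,
    otherwise the hairpin region is replaced with random sequence.
    """
    rng_h = cfg.rng("hairpins")
    rng_g = cfg.rng("genome")
    rng_s = cfg.rng("segments")

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chroms = {name: list(_random_seq(rng_g, cfg.chrom_length)) for name in chrom_names}
    truth = SyntheticTruth()

    # hairpin construction (redraw until comfortably below the energy gate)
    built = []
    n_primary = cfg.n_hairpins if cfg.ir_cluster_copies == 0 else max(
        cfg.n_hairpins, 1
    )
    for idx in range(n_primary):
        for _attempt in range(20):
            mature = _sample_mature(rng_h, cfg)
            hairpin, m_off, star, s_off = _build_hairpin(rng_h, cfg, mature)
            if _verify_foldable(hairpin):
                break
        built.append((hairpin, m_off, star, s_off, mature))

    # IR-cluster mode: tandem near-copies of hairpin 0 (soy-miR15/49-style)
    if cfg.ir_cluster_copies > 0:
        # build the cluster base with a clean stem so per-copy mutations on
        # both arms stay within the 5-mismatch duplex budget
        from dataclasses import replace as _replace

        clean = _replace(cfg, stem_mutations_max=0)
        for _attempt in range(20):
            mature0 = _sample_mature(rng_h, cfg)
            hairpin0, m_off, star0, s_off, mature0 = (
                *_build_hairpin(rng_h, clean, mature0),
                mature0,
            )
            if _verify_foldable(hairpin0):
                break
        built = [(hairpin0, m_off, star0, s_off, mature0)]
        for _copy in range(cfg.ir_cluster_copies - 1):
            hp = list(hairpin0)
            # mutate the mature interior (spreading the family) and the
            # star interior (so star reads map copy-specifically), sparing
            # the 5' U and the duplex ends
            for region_lo, region_hi in (
                (m_off + 1, m_off + len(mature0) - 3),
                (s_off + 3, s_off + len(star0) - 3),
            ):
                n_mut = int(rng_h.integers(1, cfg.ir_cluster_max_mutations + 1))
                positions = rng_h.choice(
                    np.arange(region_lo, region_hi), size=n_mut, replace=False
                )
                for pos in positions:
                    hp[pos] = rng_h.choice([b for b in "ACGT" if b != hp[pos]])
            hp = "".join(hp)
            mature = hp[m_off : m_off + len(mature0)]
            star = hp[s_off : s_off + len(mature0)]
            built.append((hp, m_off, star, s_off, mature))

    # placement, spaced out and away from chromosome edges
    slots_per_chrom = -(-len(built) // cfg.n_chromosomes)
    placements = []
    for idx in range(len(built)):
        chrom = chrom_names[idx // slots_per_chrom]
        within = idx % slots_per_chrom
        usable = cfg.chrom_length - 2 * 1000
        slot_width = usable // slots_per_chrom
        if slot_width < 800:
            raise ValueError("hairpins do not fit in chromosome; increase chrom_length")
        jitter = int(rng_h.integers(0, max(1, slot_width - 700)))
        pos = 1000 + within * slot_width + jitter
        placements.append((chrom, pos))

    for idx, ((hairpin, m_off, star, s_off, mature), (chrom, pos)) in enumerate(
        zip(built, placements)
    ):
        chroms[chrom][pos : pos + len(hairpin)] = list(hairpin)
        truth.hairpins.append(
            PlantedHairpin(
                hairpin_id=f"hp{idx + 1:03d}",
                chrom=chrom,
                start=pos,
                end=pos + len(hairpin),
                strand="+",
                mature=mature,
                mature_start=pos + m_off,
                star=star,
                star_start=pos + s_off,
                family_id=(
                    "fam_ir_cluster" if cfg.ir_cluster_copies > 0 else f"fam_hp{idx + 1:03d}"
                ),
            )
        )

    # duplicated segment pairs: copy a window around selected hairpins to a
    # reserved region at the end of the last chromosome
    primaries = list(truth.hairpins)
    n_pairs = int(round(cfg.duplicated_pair_fraction * len(primaries)))
    seg_flank = 300
    if n_pairs > 0:
        seg_len = None
        copies_needed = n_pairs
        last_chrom = chrom_names[-1]
        # extend the last chromosome to hold the copies
        for pair_idx in range(copies_needed):
            hp = primaries[pair_idx]
            start_a = max(0, hp.start - seg_flank)
            end_a = min(cfg.chrom_length, hp.end + seg_flank)
            segment = chroms[hp.chrom][start_a:end_a]
            retained = bool(rng_s.random() < cfg.retention_prob)
            start_b = len(chroms[last_chrom]) + 400
            partner_id = None
            copy = list(segment)
            hp_lo = hp.start - start_a
            hp_hi = hp.end - start_a
            if retained:
                # mutate the mature (and star) copies by 1-2 nt: within the
                # retention homology threshold but mapping distinctly, so
                # reads from the original never multi-map to the partner
                for region_lo, region_len in (
                    (hp.mature_start - start_a, len(hp.mature)),
                    (hp.star_start - start_a, len(hp.star)),
                ):
                    n_mut = int(rng_s.integers(1, 3))
                    for pos in rng_s.choice(
                        np.arange(region_lo + 1, region_lo + region_len - 1),
                        size=n_mut,
                        replace=False,
                    ):
                        copy[pos] = rng_s.choice([b for b in "ACGT" if b != copy[pos]])
                partner_id = f"{hp.hairpin_id}_copy"
                truth.hairpins.append(
                    PlantedHairpin(
                        hairpin_id=partner_id,
                        chrom=last_chrom,
                        start=start_b + hp_lo,
                        end=start_b + hp_hi,
                        strand="+",
                        mature="".join(
                            copy[hp.mature_start - start_a : hp.mature_start - start_a + len(hp.mature)]
                        ),
                        mature_start=start_b + (hp.mature_start - start_a),
                        star="".join(
                            copy[hp.star_start - start_a : hp.star_start - start_a + len(hp.star)]
                        ),
                        star_start=start_b + (hp.star_start - start_a),
                        family_id=hp.family_id,
                        expressed=False,
                        is_partner_copy=True,
                    )
                )
            else:
                # partner lost the locus: random sequence in its place
                copy[hp_lo:hp_hi] = list(_random_seq(rng_s, hp_hi - hp_lo))
            chroms[last_chrom].extend(_random_seq(rng_s, 400))
            chroms[last_chrom].extend(copy)
            truth.segment_pairs.append(
                PlantedSegmentPair(
                    pair_id=f"pair{pair_idx + 1:03d}",
                    chrom_a=hp.chrom,
                    start_a=start_a,
                    end_a=end_a,
                    chrom_b=last_chrom,
                    start_b=start_b,
                    end_b=start_b + len(copy),
                    hairpin_id_a=hp.hairpin_id,
                    hairpin_id_b=partner_id,
                    retained=retained,
                )
            )

    genome = Genome(chromosomes={name: "".join(seq) for name, seq in chroms.items()})
    return genome, truth


# ---------------------------------------------------------------------------
# Read simulation


def _to_raw(
    insert: str, cfg: SyntheticConfig, library: str
) -> RawRead:
    read = (insert + cfg.adaptor)[: cfg.read_length]
    return RawRead(sequence=read, library_id=library, quality="I" * len(read))


def simulate_dicer_reads(
    genome: Genome, truth: SyntheticTruth, cfg: SyntheticConfig
) -> list[RawRead]:
    """Simulate adaptor-ligated raw reads from the planted hairpins plus
    background, recording provenance in the truth ledger.

    Per expressed hairpin: mature reads ~ Poisson(reads_per_mature) split
    uniformly over libraries; star reads at a log-normal miRNA/miRNA*
    ratio, iso-reads (1-2 nt offsets of the mature) at ``iso_read_prob``
    per mature read; then genome-wide background 24-mers making up
    ``background_24nt_fraction`` of all reads, 85% drawn from the genome
    (mappable) and the rest random.
    """
    rng = cfg.rng("reads")
    rng_bg = cfg.rng("background")
    libraries = [f"lib{i + 1}" for i in range(cfg.n_libraries)]
    reads: list[RawRead] = []
    truth.read_provenance = []

    def emit(insert: str, origin: str, hairpin_id: Optional[str]) -> str:
        library = libraries[int(rng.integers(0, cfg.n_libraries))]
        read = _to_raw(insert, cfg, library)
        read_id = f"r{len(reads) + 1:07d}"
        reads.append(read)
        truth.read_provenance.append((read_id, origin, hairpin_id))
        return library

    n_planted = 0
    for hp in truth.hairpins:
        if not hp.expressed:
            continue
        n_mature = int(rng.poisson(cfg.reads_per_mature))
        ratio = float(rng.lognormal(cfg.star_ratio_log_mean, cfg.star_ratio_log_sd))
        n_star = int(rng.poisson(n_mature / ratio)) if n_mature else 0
        n_iso = int(rng.poisson(n_mature * cfg.iso_read_prob))
        hp.mature_counts = {lib: 0 for lib in libraries}
        hp.star_counts = {lib: 0 for lib in libraries}
        for _ in range(n_mature):
            lib = emit(hp.mature, "mature", hp.hairpin_id)
            hp.mature_counts[lib] += 1
        for _ in range(n_star):
            lib = emit(hp.star, "star", hp.hairpin_id)
            hp.star_counts[lib] += 1
        chrom_seq = genome.chromosomes[hp.chrom]
        for _ in range(n_iso):
            shift = int(rng.choice([-2, -1, 1, 2]))
            start = hp.mature_start + shift
            insert = chrom_seq[start : start + len(hp.mature)]
            emit(insert, "iso", hp.hairpin_id)
        hp.n_iso_reads = n_iso
        hp.n_planted_reads = n_mature + n_star + n_iso
        n_planted += hp.n_planted_reads

    f = cfg.background_24nt_fraction
    n_background = int(round(n_planted * f / (1.0 - f))) if f < 1.0 else 0
    chrom_names = list(genome.chromosomes)
    for _ in range(n_background):
        if rng_bg.random() < cfg.background_mappable_fraction:
            chrom = chrom_names[int(rng_bg.integers(0, len(chrom_names)))]
            seq = genome.chromosomes[chrom]
            start = int(rng_bg.integers(0, len(seq) - 24))
            insert = seq[start : start + 24]
            if rng_bg.random() < 0.5:
                insert = revcomp(insert)
        else:
            insert = _random_seq(rng_bg, 24)
        library = libraries[int(rng_bg.integers(0, cfg.n_libraries))]
        read = _to_raw(insert, cfg, library)
        reads.append(read)
        truth.read_provenance.append((f"r{len(reads):07d}", "background", None))
    return reads


# ---------------------------------------------------------------------------
# Truth-ledger evaluation


def evaluate_against_truth(
    accepted_annotations, truth: SyntheticTruth, min_mature_reads: int = 10
) -> dict:
    """Compare discovery output with the planted ledger.

    A planted expressed hairpin (with at least ``min_mature_reads`` planted
    mature reads) counts as recovered when an accepted annotation overlaps
    its genomic span on either strand (perfect inverted repeats make the
    minus-strand description of the same physical hairpin equally valid) or
    calls its exact mature sequence. An accepted annotation overlapping no
    planted hairpin at all is a false discovery.
    """
    targets = truth.expressed_hairpins(min_mature_reads)
    all_spans = [(h.chrom, h.start, h.end) for h in truth.hairpins]

    def overlaps(annotation, chrom: str, start: int, end: int) -> bool:
        a_start, a_end = annotation.span
        return annotation.chrom == chrom and a_start < end and start < a_end

    recovered = []
    for hp in targets:
        hit = any(
            overlaps(a, hp.chrom, hp.start, hp.end)
            or a.mature.sequence == hp.mature
            for a in accepted_annotations
        )
        recovered.append(hit)
    false_discoveries = [
        a
        for a in accepted_annotations
        if not any(overlaps(a, c, s, e) for c, s, e in all_spans)
    ]
    return {
        "n_planted": len(targets),
        "n_recovered": sum(recovered),
        "recall": sum(recovered) / len(targets) if targets else float("nan"),
        "n_false_discoveries": len(false_discoveries),
        "false_discoveries": false_discoveries,
    }


# ---------------------------------------------------------------------------
# Fixture bundle


def write_fixture_bundle(
    outdir,
    cfg: SyntheticConfig,
    genome: Optional[Genome] = None,
    truth: Optional[SyntheticTruth] = None,
    reads: Optional[list[RawRead]] = None,
) -> dict[str, Path]:
    """Write genome FASTA, per-library FASTQ, truth ledger TSV, annotation
    GFF3, segment-pair TSV and the config YAML. Re-running from the config
    reproduces the bundle byte for byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genome is None or truth is None:
        genome, truth = generate_genome(cfg)
        reads = None
    if reads is None:
        reads = simulate_dicer_reads(genome, truth, cfg)

    paths = {"config": outdir / "config.yaml", "genome": outdir / "genome.fa"}
    cfg.to_yaml(paths["config"])
    genome.write_fasta(paths["genome"])

    by_lib: dict[str, list[tuple[int, RawRead]]] = {}
    for i, read in enumerate(reads):
        by_lib.setdefault(read.library_id, []).append((i, read))
    for lib in sorted(by_lib):
        path = outdir / f"{lib}.fastq"
        paths[lib] = path
        with open(path, "w") as fh:
            for i, read in by_lib[lib]:
                fh.write(f"@r{i + 1:07d}\n{read.sequence}\n+\n{read.quality}\n")

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write(
            "hairpin_id\tchrom\tstart\tend\tstrand\tmature\tmature_start\tstar\t"
            "star_start\tfamily_id\texpressed\tis_partner_copy\tmature_total\t"
            "star_total\tn_iso\tn_planted\n"
        )
        for hp in truth.hairpins:
            fh.write(
                f"{hp.hairpin_id}\t{hp.chrom}\t{hp.start}\t{hp.end}\t{hp.strand}\t"
                f"{hp.mature}\t{hp.mature_start}\t{hp.star}\t{hp.star_start}\t"
                f"{hp.family_id}\t{int(hp.expressed)}\t{int(hp.is_partner_copy)}\t"
                f"{hp.mature_total}\t{hp.star_total}\t{hp.n_iso_reads}\t"
                f"{hp.n_planted_reads}\n"
            )

    paths["segment_pairs"] = outdir / "segment_pairs.tsv"
    with open(paths["segment_pairs"], "w") as fh:
        fh.write(
            "pair_id\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\tretained\n"
        )
        for sp in truth.segment_pairs:
            fh.write(
                f"{sp.pair_id}\t{sp.chrom_a}\t{sp.start_a}\t{sp.end_a}\t"
                f"{sp.chrom_b}\t{sp.start_b}\t{sp.end_b}\t{int(sp.retained)}\n"
            )

    feats = [
        GffFeature(
            chrom=hp.chrom,
            type="miRNA_primary_transcript",
            start=hp.start,
            end=hp.end,
            strand=hp.strand,
            attributes={"ID": hp.hairpin_id, "family": hp.family_id},
        )
        for hp in truth.hairpins
    ]
    paths["annotations"] = outdir / "annotations.gff3"
    write_gff3(feats, paths["annotations"], chrom_lengths=genome.lengths)

    paths["provenance"] = outdir / "read_provenance.tsv"
    with open(paths["provenance"], "w") as fh:
        fh.write("read_id\torigin\thairpin_id\n")
        for read_id, origin, hp_id in truth.read_provenance:
            fh.write(f"{read_id}\t{origin}\t{hp_id or '.'}\n")
    return paths
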