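"""Evolutionary analyses: homoeolog retention after whole-genome
duplication, Kimura 2-parameter distances, neighbor-joining trees,
divergence-time dating and conservation-age classification.

The retention analysis asks, for each miRNA locus lying on a duplicated
genome segment, whether the partner segment carries a homologous locus
(mature sequences within a small edit distance). K2P separates transition
(P) and transversion (Q) proportions: K = -1/2 ln((1-2P-Q) sqrt(1-2Q)),
and divergence time follows T = K / (2R) for a per-site per-year
substitution rate R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

DEFAULT_RETENTION_EDIT = 2
DEFAULT_RATE = 6.1e-9  # substitutions per site per year

PURINES = frozenset("AG")
GAPS = frozenset("-.~")

AGE_CLASSES = (
    "land_plant",
    "seed_plant",
    "angiosperm",
    "core_eudicot",
    "rosid",
    "fabales",
    "soybean_specific",
)

# default age class per plant order, deepest-diverging first
DEFAULT_ORDER_AGES: dict[str, str] = {
    "funariales": "land_plant",
    "selaginellales": "land_plant",
    "coniferales": "seed_plant",
    "pinales": "seed_plant",
    "poales": "angiosperm",
    "zingiberales": "angiosperm",
    "solanales": "core_eudicot",
    "caryophyllales": "core_eudicot",
    "vitales": "core_eudicot",
    "brassicales": "rosid",
    "sapindales": "rosid",
    "malpighiales": "rosid",
    "rosales": "rosid",
    "cucurbitales": "rosid",
    "fabales": "fabales",
}


# ---------------------------------------------------------------------------
# Homoeolog retention


@dataclass
class MirnaLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    mature_sequence: str
    conserved: Optional[bool] = None
    cotyledon: Optional[bool] = None
    known: Optional[bool] = None


@dataclass
class SegmentPair:
    pair_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int


@dataclass
class HomoeologPairRecord:
    pair_id: str
    loci_a: list[MirnaLocus] = field(default_factory=list)
    loci_b: list[MirnaLocus] = field(default_factory=list)
    retained: dict[str, bool] = field(default_factory=dict)  # locus_id -> bool


def _within(locus: MirnaLocus, chrom: str, start: int, end: int) -> bool:
    return locus.chrom == chrom and locus.start >= start and locus.end <= end


def homoeolog_retention(
    loci: Sequence[MirnaLocus],
    pairs: Sequence[SegmentPair],
    max_edit: int = DEFAULT_RETENTION_EDIT,
) -> tuple[list[HomoeologPairRecord], pd.DataFrame]:
    """Classify each on-segment miRNA locus as retained or not.

    A locus is retained iff the partner segment of its pair contains a
    locus whose mature sequence is within edit distance ``max_edit``.
    Returns the per-pair records and a summary table with retained counts
    and integer percentages, overall and per category (conserved,
    cotyledon, known — where annotated).
    """
    records = []
    assigned: set[str] = set()
    for pair in pairs:
        rec = HomoeologPairRecord(pair_id=pair.pair_id)
        for locus in loci:
            if _within(locus, pair.chrom_a, pair.start_a, pair.end_a):
                rec.loci_a.append(locus)
                assigned.add(locus.locus_id)
            elif _within(locus, pair.chrom_b, pair.start_b, pair.end_b):
                rec.loci_b.append(locus)
                assigned.add(locus.locus_id)
        for own, partner in ((rec.loci_a, rec.loci_b), (rec.loci_b, rec.loci_a)):
            for locus in own:
                rec.retained[locus.locus_id] = any(
                    edlib.align(
                        locus.mature_sequence, other.mature_sequence, task="distance"
                    )["editDistance"]
                    <= max_edit
                    for other in partner
                )
        records.append(rec)

    verdicts: dict[str, bool] = {}
    for rec in records:
        verdicts.update(rec.retained)
    by_id = {l.locus_id: l for l in loci}

    def summarize(label: str, ids: Iterable[str]) -> dict:
        ids = list(ids)
        retained = sum(1 for i in ids if verdicts[i])
        total = len(ids)
        return {
            "category": label,
            "retained": retained,
            "not_retained": total - retained,
            "total": total,
            "percent_retained": int(round(100 * retained / total)) if total else 0,
        }

    rows = [summarize("all", verdicts)]
    for attr, true_label, false_label in (
        ("conserved", "conserved", "non_conserved"),
        ("cotyledon", "cotyledon", "non_cotyledon"),
        ("known", "known", "novel"),
    ):
        values = [getattr(by_id[i], attr) for i in verdicts]
        if all(v is None for v in values):
            continue
        rows.append(
            summarize(true_label, (i for i in verdicts if getattr(by_id[i], attr)))
        )
        rows.append(
            summarize(
                false_label, (i for i in verdicts if getattr(by_id[i], attr) is False)
            )
        )
    return records, pd.DataFrame(rows)


def read_segment_pairs_tsv(path) -> list[SegmentPair]:
    """8-column TSV: pair_id, chrom_a, start_a, end_a, chrom_b, start_b, end_b
    (+ optional trailing columns, ignored). Coordinates are 0-based."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("pair_id"):
                continue
            cols = line.split("\t")
            pairs.append(
                SegmentPair(
                    pair_id=cols[0],
                    chrom_a=cols[1],
                    start_a=int(cols[2]),
                    end_a=int(cols[3]),
                    chrom_b=cols[4],
                    start_b=int(cols[5]),
                    end_b=int(cols[6]),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# K2P distance and divergence time


@dataclass
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # substitutions per site
    n_sites: int
    T: Optional[float] = None  # years, set by divergence_time


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura 2-parameter distance between two aligned sequences.

    Gap columns (and columns with non-ACGT symbols) are excluded pairwise.
    Raises on saturation (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    sites = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites after gap removal")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance undefined: sequences saturated")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P=P, Q=Q, K=K, n_sites=sites)


def divergence_time(K: float, rate: float = DEFAULT_RATE) -> float:
    """Divergence time in years: T = K / (2R)."""
    if K < 0:
        raise ValueError("K must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return K / (2.0 * rate)


def k2p_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """Pairwise K2P distance matrix for a set of aligned sequences."""
    labels = list(sequences)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            k = k2p_distance(sequences[labels[i]], sequences[labels[j]]).K
            mat[i, j] = mat[j, i] = k
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class _Node:
    label: Optional[str] = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"

    def total_length(self) -> float:
        return sum(bl + c.total_length() for c, bl in self.children)


def nj_tree(
    distances, labels: Optional[Sequence[str]] = None
) -> tuple[str, float]:
    """Neighbor-joining tree from a symmetric distance matrix.

    Returns (newick, total branch length). The final join is a
    trifurcation, so the newick describes an unrooted tree. Ties in the
    Q-matrix minimisation are broken by the smallest (i, j) taxon-index
    pair for determinism.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        dm = distances.to_numpy(dtype=float)
    else:
        dm = np.asarray(distances, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(dm.shape[0])]
    n = dm.shape[0]
    if dm.shape != (n, n) or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if (dm < 0).any():
        raise ValueError("distances must be non-negative")

    nodes: list[_Node] = [_Node(label=l) for l in labels]
    d = dm.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _q, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # grow the arrays with the new cluster's distances
        newdist = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newdist[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(newdist) - 1] = newdist[:-1]
        d[: len(newdist) - 1, -1] = newdist[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = _Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return root.newick() + ";", root.total_length()


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    dm.to_csv(path, sep="\t", float_format="%.8f")


# ---------------------------------------------------------------------------
# Conservation age


@dataclass
class ConservationCall:
    family_id: str
    presence: dict[str, bool]
    age_class: str


def conservation_age(
    family_id: str,
    presence: dict[str, bool],
    order_ages: Optional[dict[str, str]] = None,
) -> ConservationCall:
    """Age class of a miRNA family: the class of the deepest-diverging
    plant order where it is present; absent everywhere outside fabales
    (and in fabales) -> soybean_specific."""
    ages = order_ages if order_ages is not None else DEFAULT_ORDER_AGES
    rank = {cls: i for i, cls in enumerate(AGE_CLASSES)}
    best: Optional[str] = None
    for order, present in presence.items():
        if order not in ages:
            raise ValueError(f"unknown plant order {order!r}")
        if not present:
            continue
        cls = ages[order]
        if best is None or rank[cls] < rank[best]:
            best = cls
    return ConservationCall(
        family_id=family_id,
        presence=dict(presence),
        age_class=best if best is not None else "soybean_specific",
    )


def read_presence_matrix(path) -> pd.DataFrame:
    """family x order 0/1 TSV."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)
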