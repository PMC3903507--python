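"""Functional-bin enrichment of miRNA-targeted genes.

Genes sit in hierarchical dotted bins (e.g. ``RNA.regulation_of_
transcription.TCP_transcription_factor_family``); membership in a child
bin propagates to every ancestor. Per bin, a 2x2 table of target vs
non-target genes in vs outside the bin is tested with Fisher's exact test
(two-sided by default, matching reporting of both over- and
under-representation) and the sample odds ratio (a*d)/(b*c).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from scipy import stats


@dataclass
class BinTable:
    """gene -> set of hierarchical bin labels."""

    memberships: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, bins in self.memberships.items():
            if any(not b for b in bins):
                raise ValueError(f"empty bin label for gene {gene}")

    @property
    def genes(self) -> set[str]:
        return set(self.memberships)

    def with_parents(self) -> "BinTable":
        """Prefix-closure: membership in ``a.b.c`` implies ``a.b`` and ``a``."""
        closed = {}
        for gene, bins in self.memberships.items():
            full = set()
            for label in bins:
                parts = label.split(".")
                for i in range(1, len(parts) + 1):
                    full.add(".".join(parts[:i]))
            closed[gene] = full
        return BinTable(memberships=closed)

    def all_bins(self) -> list[str]:
        bins = set()
        for members in self.memberships.values():
            bins |= members
        return sorted(bins)

    @classmethod
    def from_tsv(cls, path) -> "BinTable":
        """TSV: gene_id <tab> bin_path (one row per membership)."""
        memberships: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("gene_id"):
                    continue
                gene, _, bin_path = line.partition("\t")
                memberships.setdefault(gene, set()).add(bin_path.strip())
        return cls(memberships=memberships)


@dataclass
class EnrichmentResult:
    bin: str
    a: int  # targets in bin
    b: int  # targets not in bin
    c: int  # non-targets in bin
    d: int  # non-targets not in bin
    odds_ratio: float
    p_value: float
    direction: str  # over | under | null


def fisher_bin_enrichment(
    targets: Iterable[str],
    bin_table: BinTable,
    universe: Optional[Iterable[str]] = None,
    alternative: str = "two-sided",
    propagate_parents: bool = True,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Fisher's exact over/under-representation of target genes per bin.

    The universe defaults to all genes in the bin table. Raw p-values are
    reported; ``fdr=True`` additionally attaches Benjamini-Hochberg
    adjusted p-values without replacing the raw ones.
    """
    if not bin_table.memberships:
        raise ValueError("empty bin table")
    table = bin_table.with_parents() if propagate_parents else bin_table
    universe_set = set(universe) if universe is not None else table.genes
    if not universe_set:
        raise ValueError("empty universe")
    target_set = set(targets) & universe_set

    results = []
    for bin_label in table.all_bins():
        in_bin = {
            g for g, bins in table.memberships.items() if bin_label in bins
        } & universe_set
        a = len(target_set & in_bin)
        b = len(target_set - in_bin)
        c = len(in_bin - target_set)
        d = len(universe_set) - a - b - c
        odds = (a * d) / (b * c) if b * c > 0 else (0.0 if a == 0 else float("inf"))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        if odds > 1.0:
            direction = "over"
        elif odds < 1.0:
            direction = "under"
        else:
            direction = "null"
        results.append(
            EnrichmentResult(
                bin=bin_label, a=a, b=b, c=c, d=d,
                odds_ratio=odds, p_value=float(p), direction=direction,
            )
        )
    if fdr:
        _benjamini_hochberg(results)
    return results


def _benjamini_hochberg(results: list[EnrichmentResult]) -> None:
    """Attach BH-adjusted p-values as ``p_adjusted`` attributes."""
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p_value)
    adj = [0.0] * m
    prev = 1.0
    for rank_from_last, idx in enumerate(reversed(order)):
        rank = m - rank_from_last
        val = min(prev, results[idx].p_value * m / rank)
        adj[idx] = val
        prev = val
    for res, p_adj in zip(results, adj):
        res.p_adjusted = p_adj  # type: ignore[attr-defined]


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "bin": r.bin,
            "a": r.a,
            "b": r.b,
            "c": r.c,
            "d": r.d,
            "odds_ratio": r.odds_ratio,
            "p_value": r.p_value,
            "direction": r.direction,
            **({"p_adjusted": r.p_adjusted} if hasattr(r, "p_adjusted") else {}),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# miRNA family -> pathway edges


def read_interaction_table(path) -> pd.DataFrame:
    """TSV: family_id, gene_id, alignment_score, site_region."""
    return pd.read_csv(
        path,
        sep="\t",
        names=["family_id", "gene_id", "alignment_score", "site_region"],
        comment="#",
        header=0,
    )


def build_mirna_pathway_edges(
    interactions: pd.DataFrame,
    bin_table: BinTable,
    p_cutoff: float = 0.05,
    universe: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Edges (family, bin) where a family's targets are significantly
    over-represented at ``p_cutoff``. Edge count is monotone non-decreasing
    as the cutoff is relaxed."""
    edges = []
    for family, group in interactions.groupby("family_id"):
        family_targets = set(group["gene_id"])
        for res in fisher_bin_enrichment(family_targets, bin_table, universe=universe):
            if res.direction == "over" and res.p_value <= p_cutoff:
                edges.append(
                    {
                        "family_id": family,
                        "bin": res.bin,
                        "odds_ratio": res.odds_ratio,
                        "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(edges, columns=["family_id", "bin", "odds_ratio", "p_value"])
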