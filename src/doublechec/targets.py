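"""Target-gene assignment and catalog overlap enrichment.

A gene is a target when a high-confidence site falls in its strand-aware
upstream window (default 700 bp before the start codon).  Overlap with
curated per-TF target sets is scored with a one-sided (enrichment) Fisher
exact test, Bonferroni-corrected across the TFs tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .doublets import HighConfidenceSite
from .io_formats import GeneRecord, TargetSetCatalog

__all__ = [
    "TargetAssignment",
    "OverlapEnrichment",
    "assign_targets",
    "fisher_overlap",
]


@dataclass
class TargetAssignment:
    """gene id -> supporting site midpoints; target set = keys."""

    supporting: dict[str, list[int]] = field(default_factory=dict)
    upstream: int = 700

    @property
    def target_genes(self) -> frozenset[str]:
        return frozenset(self.supporting)

    def __len__(self) -> int:
        return len(self.supporting)


@dataclass
class OverlapEnrichment:
    tf_name: str
    overlap: int                # k
    query_size: int             # a
    target_set_size: int        # b
    universe_size: int          # N
    p_value: float
    adjusted_p: float


def _upstream_window(gene: GeneRecord, upstream: int) -> tuple[int, int]:
    """Half-open upstream window, clipped at 0 on the left."""
    if gene.strand == "+":
        return max(0, gene.position - upstream), gene.position
    return gene.position + 1, gene.position + 1 + upstream


def assign_targets(
    sites: Sequence[HighConfidenceSite],
    genes: Sequence[GeneRecord],
    upstream: int = 700,
    mode: str = "midpoint",
) -> TargetAssignment:
    """Genes with >= 1 site in their upstream window.

    ``mode='midpoint'`` (default) requires the site midpoint inside the
    window; ``mode='interval'`` accepts any overlap of the merged site
    interval with the window.
    """
    if mode not in ("midpoint", "interval"):
        raise ValueError("mode must be 'midpoint' or 'interval'")
    by_contig: dict[str, list[HighConfidenceSite]] = {}
    for site in sites:
        by_contig.setdefault(site.contig, []).append(site)
    assignment = TargetAssignment(upstream=upstream)
    for gene in genes:
        win_start, win_end = _upstream_window(gene, upstream)
        for site in by_contig.get(gene.contig, ()):
            if mode == "midpoint":
                hit = win_start <= site.midpoint < win_end
            else:
                hit = site.start < win_end and win_start < site.end
            if hit:
                assignment.supporting.setdefault(gene.gene_id, []).append(site.midpoint)
    return assignment


def fisher_overlap(
    query: frozenset[str] | set[str],
    catalog: TargetSetCatalog,
    universe: frozenset[str] | set[str],
) -> list[OverlapEnrichment]:
    """One-sided Fisher exact enrichment of ``query`` against each catalog set.

    Catalog sets are intersected with ``universe`` first; ``query`` must be
    a subset of ``universe``.  The Bonferroni multiplier is the number of
    TFs actually tested.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    if not query <= universe:
        raise ValueError("query genes not all in universe")
    n = len(universe)
    a = len(query)
    rows: list[OverlapEnrichment] = []
    n_tests = len(catalog)
    for tf, genes in catalog.items():
        target = frozenset(genes) & universe
        b = len(target)
        k = len(query & target)
        # P(X >= k) for X ~ Hypergeom(N, b, a)
        p = float(stats.hypergeom.sf(k - 1, n, b, a)) if b > 0 else 1.0
        p = min(p, 1.0)
        rows.append(
            OverlapEnrichment(
                tf_name=tf,
                overlap=k,
                query_size=a,
                target_set_size=b,
                universe_size=n,
                p_value=p,
                adjusted_p=min(1.0, p * n_tests),
            )
        )
    rows.sort(key=lambda r: r.p_value)
    return rows
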