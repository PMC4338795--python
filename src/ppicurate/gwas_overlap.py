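"""Overlap of the interactome with GWAS risk loci.

A trait-associated SNP tags a genomic locus, not a specific gene; genes
whose interval intersects a +/- 200 kb window around the SNP position
are considered locus members (closed intervals, base-pair window).  The
SNP-to-gene distance is zero when the SNP falls inside the gene
interval, otherwise the distance to the nearer boundary, in kb.

The comparison uses the *complete* interactome (filtered set plus the
singleton interactors), matching accessions to gene symbols through a
user-supplied map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .evidence import InteractorSummary
from .io_formats import GeneInterval, SnpLocus

logger = logging.getLogger(__name__)

WINDOW_BP = 200_000


@dataclass
class OverlapHit:
    """One (interactor, SNP) locus overlap."""

    interactor: str
    gene_symbol: str
    snp: SnpLocus
    distance_kbp: float
    candidate: bool = False
    htp: bool = False

    def __post_init__(self) -> None:
        if self.distance_kbp < 0:
            raise ValueError("distance must be non-negative")


def _chromosome_trees(genes: Iterable[GeneInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # interval tree is half-open; +1 makes the gene span closed
        trees.setdefault(gene.chromosome, IntervalTree()).addi(
            gene.start, gene.end + 1, gene
        )
    return trees


def genes_near_snp(
    snp: SnpLocus,
    genes: Sequence[GeneInterval],
    window_bp: int = WINDOW_BP,
) -> list[GeneInterval]:
    """Genes on the SNP's chromosome intersecting the +/- window (closed)."""
    tree = _chromosome_trees(g for g in genes if g.chromosome == snp.chromosome).get(
        snp.chromosome, IntervalTree()
    )
    lo = max(1, snp.position - window_bp)
    hi = snp.position + window_bp
    hits = [iv.data for iv in tree.overlap(lo, hi + 1)]
    return sorted(hits, key=lambda g: (g.start, g.end, g.gene_symbol))


def snp_gene_distance(snp: SnpLocus, gene: GeneInterval) -> float:
    """Distance in kb from the SNP to the gene interval (0 if inside)."""
    if snp.chromosome != gene.chromosome:
        raise ValueError(
            f"{snp.rsid} on chromosome {snp.chromosome} vs {gene.gene_symbol} "
            f"on {gene.chromosome}"
        )
    if gene.start <= snp.position <= gene.end:
        return 0.0
    return min(abs(snp.position - gene.start), abs(snp.position - gene.end)) / 1000.0


def match_interactome(
    complete_interactome: Iterable[str],
    snps: Sequence[SnpLocus],
    genes: Sequence[GeneInterval],
    symbol_map: Mapping[str, str],
    candidate_list: Iterable[str] = (),
    summaries: Mapping[str, InteractorSummary] | None = None,
    window_bp: int = WINDOW_BP,
) -> list[OverlapHit]:
    """One hit per (interactor, SNP) pair whose gene lies in the SNP window.

    Interactors without a symbol mapping or without a gene interval are
    skipped with a logged count.  ``candidate_list`` holds the gene
    symbols the original GWAS named as candidates; the HTP flag is
    copied from the interactor summaries when given.  Hits are sorted
    by (trait, distance, SNP, symbol).
    """
    candidates = set(candidate_list)
    by_symbol: dict[str, list[GeneInterval]] = {}
    for gene in genes:
        by_symbol.setdefault(gene.gene_symbol, []).append(gene)

    interactome_genes: list[tuple[str, GeneInterval]] = []
    skipped = 0
    for acc in sorted(set(complete_interactome)):
        symbol = symbol_map.get(acc)
        if symbol is None or symbol not in by_symbol:
            skipped += 1
            logger.warning("interactor %s has no mapped gene interval; skipped", acc)
            continue
        for gene in by_symbol[symbol]:
            interactome_genes.append((acc, gene))
    if skipped:
        logger.warning("%d interactors skipped for missing symbol/interval mapping", skipped)

    trees = _chromosome_trees(g for _, g in interactome_genes)
    gene_to_accs: dict[GeneInterval, list[str]] = {}
    for acc, gene in interactome_genes:
        gene_to_accs.setdefault(gene, []).append(acc)

    hits: list[OverlapHit] = []
    for snp in snps:
        tree = trees.get(snp.chromosome)
        if tree is None:
            continue
        lo = max(1, snp.position - window_bp)
        hi = snp.position + window_bp
        for iv in tree.overlap(lo, hi + 1):
            gene = iv.data
            distance = snp_gene_distance(snp, gene)
            for acc in gene_to_accs[gene]:
                summary = summaries.get(acc) if summaries else None
                hits.append(
                    OverlapHit(
                        interactor=acc,
                        gene_symbol=gene.gene_symbol,
                        snp=snp,
                        distance_kbp=distance,
                        candidate=gene.gene_symbol in candidates,
                        htp=summary.htp if summary else False,
                    )
                )
    hits.sort(key=lambda h: (h.snp.trait, h.distance_kbp, h.snp.rsid, h.gene_symbol))
    return hits


__all__ = [
    "WINDOW_BP",
    "OverlapHit",
    "genes_near_snp",
    "snp_gene_distance",
    "match_interactome",
]
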