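"""GO over-representation analysis with two selection modes.

The statistic is the hypergeometric upper tail: drawing the study set
of size ``n`` from a reference universe of ``N`` genes of which ``K``
are annotated to a term, the raw p-value is ``P(X >= k)`` for the ``k``
study genes annotated.  Multiple testing is handled with Bonferroni
(``p_adj = min(1, m * p_raw)``, ``m`` = number of tested terms).  The
tail is computed with exact big-integer arithmetic, so it is accurate
to the last floating-point digit at any size used here.

Two result-selection modes mirror the two classic ORA portals:

* ``top10`` — the ten smallest adjusted p-values (ties broken
  deterministically by raw p then term id);
* ``threshold`` — every term with ``p_adj`` below a cut-off
  (default 1e-7).

Annotations are propagated up the ontology first (the true-path rule:
a gene annotated to a term is annotated to all its ancestors).

Downstream summaries: per-group contributor sets, the asymmetric
group-by-group intersection-percentage matrix, and the composition of
each significance level (per level ``N``, the share of terms each
functional group contributes: ``100 * g / n``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AnnotationTable, OntologyDag

logger = logging.getLogger(__name__)

GENERAL_TERMS_LABEL = "general terms"


@dataclass
class EnrichmentResult:
    """Per-term outcome of the over-representation test."""

    term_id: str
    term_name: str
    ref_count: int
    study_count: int
    p_raw: float
    p_adj: float
    contributors: frozenset[str]

    def __post_init__(self) -> None:
        if self.study_count > self.ref_count:
            raise ValueError(f"{self.term_id}: study_count exceeds ref_count")
        if self.study_count != len(self.contributors):
            raise ValueError(f"{self.term_id}: contributor set inconsistent with study_count")
        if not (0 < self.p_raw <= 1) or not (self.p_raw <= self.p_adj <= 1):
            raise ValueError(f"{self.term_id}: invalid p-values {self.p_raw}, {self.p_adj}")


@dataclass
class TermGrouping:
    """User-supplied assignment of enriched terms to functional groups."""

    mapping: Mapping[str, str]
    general_label: str = GENERAL_TERMS_LABEL

    def __getitem__(self, term_id: str) -> str:
        try:
            return self.mapping[term_id]
        except KeyError:
            raise KeyError(f"enriched term {term_id} missing from grouping") from None

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.mapping.values():
            seen.setdefault(label, None)
        return list(seen)


@dataclass
class IntersectionMatrix:
    """Asymmetric contributor-overlap matrix between functional groups.

    ``matrix.loc[row, col]`` is the percentage of the row group's
    contributors also contributing to the column group; rows with an
    empty contributor set are reported as missing (NaN), not zero.  The
    extra ``last_row`` uses the full study size as denominator.
    """

    groups: list[str]
    contributor_sets: dict[str, frozenset[str]]
    matrix: pd.DataFrame
    last_row: pd.Series


@dataclass
class SignificanceComposition:
    """Per-significance-level breakdown of enriched terms by group.

    Level ``N`` holds the terms with ``ceil(-log10(p_adj)) == N``
    (clamped into ``level_range``); within a level, group ``G`` with
    ``g`` of the level's ``n`` terms contributes ``100 * g / n``
    percent.
    """

    level_range: tuple[int, int]
    counts: dict[int, dict[str, int]] = field(default_factory=dict)

    def total(self, level: int) -> int:
        return sum(self.counts.get(level, {}).values())

    def percentages(self, level: int) -> dict[str, float]:
        n = self.total(level)
        if n == 0:
            return {}
        return {g: 100.0 * c / n for g, c in self.counts[level].items()}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability ``P(X >= k)``.

    ``N`` reference size, ``K`` annotated in the reference, ``n`` study
    size, ``k`` annotated in the study.  Computed as a big-integer sum
    of ``C(K, j) * C(N - K, n - j)`` over ``j >= k`` divided by
    ``C(N, n)``; the single float division at the end is correctly
    rounded.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    if k > min(K, n) or k < 0:
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    lo = max(k, n - (N - K))  # smallest j with a non-zero pmf term
    numerator = sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(lo, min(K, n) + 1)
    )
    return numerator / math.comb(N, n)


# ---------------------------------------------------------------------------
# propagation and the test proper
# ---------------------------------------------------------------------------


def propagate_annotations(dag: OntologyDag, table: AnnotationTable) -> AnnotationTable:
    """Apply the true-path rule: close every gene's term set over ancestors."""
    closure_cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in closure_cache:
            closure_cache[term] = {term} | dag.ancestors(term)
        return closure_cache[term]

    propagated = {
        gene: set().union(*(closure(t) for t in terms)) if terms else set()
        for gene, terms in table.annotations.items()
    }
    return AnnotationTable(annotations=propagated, reference_genes=set(table.reference_genes))


def enrich(
    study: Iterable[str],
    table: AnnotationTable,
    dag: OntologyDag | None = None,
    mode: str = "top10",
    min_genes: int = 2,
    top_n: int = 10,
    p_threshold: float = 1e-7,
    propagate: bool = True,
) -> list[EnrichmentResult]:
    """Over-representation test of ``study`` against the annotation table.

    Study genes outside the reference universe are dropped with a
    logged warning.  Terms with fewer than ``min_genes`` study genes
    are not tested and do not count toward the Bonferroni family size.
    Results are sorted ascending by ``(p_adj, p_raw, term_id)``.
    """
    study_set = set(study)
    if not study_set:
        raise ValueError("empty study set")
    if mode not in {"top10", "threshold"}:
        raise ValueError(f"unknown mode {mode!r}")
    dropped = study_set - table.reference_genes
    if dropped:
        logger.warning(
            "%d study genes outside the reference universe dropped: %s",
            len(dropped), sorted(dropped)[:5],
        )
        study_set -= dropped
    if not study_set:
        raise ValueError("no study genes remain inside the reference universe")
    if propagate and dag is not None:
        table = propagate_annotations(dag, table)

    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in table.annotations.items():
        for term in terms:
            term_to_genes.setdefault(term, set()).add(gene)

    N = len(table.reference_genes)
    n = len(study_set)
    tested: list[tuple[str, set[str], frozenset[str]]] = []
    for term in sorted(term_to_genes):
        annotated = term_to_genes[term]
        contributors = frozenset(annotated & study_set)
        if len(contributors) >= min_genes:
            tested.append((term, annotated, contributors))
    m = len(tested)

    results: list[EnrichmentResult] = []
    for term, annotated, contributors in tested:
        p_raw = hypergeom_upper_tail(N, len(annotated), n, len(contributors))
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=dag.name(term) if dag is not None else term,
                ref_count=len(annotated),
                study_count=len(contributors),
                p_raw=p_raw,
                p_adj=min(1.0, m * p_raw),
                contributors=contributors,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    if mode == "top10":
        return results[:top_n]
    return [r for r in results if r.p_adj < p_threshold]


# ---------------------------------------------------------------------------
# grouping summaries
# ---------------------------------------------------------------------------


def contributor_sets(
    results: Sequence[EnrichmentResult], grouping: TermGrouping
) -> dict[str, frozenset[str]]:
    """Per-group union of contributor genes over the group's enriched terms.

    Groups declared in the grouping but without enriched terms map to
    the empty set.  An enriched term absent from the grouping is an
    error.
    """
    sets: dict[str, set[str]] = {g: set() for g in grouping.groups}
    for result in results:
        sets[grouping[result.term_id]] |= result.contributors
    return {g: frozenset(s) for g, s in sets.items()}


def intersection_matrix(
    P: Mapping[str, frozenset[str]], study_size: int
) -> IntersectionMatrix:
    """Pairwise contributor-overlap percentages between groups.

    Entry (row, col) = ``100 * |P_row & P_col| / |P_row|``; undefined
    (NaN) when ``P_row`` is empty.  The extra last row is
    ``100 * |P_g| / study_size``.
    """
    groups = list(P)
    if not any(P[g] for g in groups):
        raise ValueError("all contributor sets are empty")
    if study_size <= 0:
        raise ValueError("study_size must be positive")
    matrix = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for row in groups:
        for col in groups:
            if not P[row]:
                matrix.loc[row, col] = float("nan")
            else:
                matrix.loc[row, col] = 100.0 * len(P[row] & P[col]) / len(P[row])
    last_row = pd.Series(
        {g: 100.0 * len(P[g]) / study_size for g in groups}, name="of study set"
    )
    return IntersectionMatrix(
        groups=groups,
        contributor_sets={g: frozenset(P[g]) for g in groups},
        matrix=matrix,
        last_row=last_row,
    )


def significance_composition(
    results: Sequence[EnrichmentResult],
    grouping: TermGrouping,
    level_range: tuple[int, int] = (7, 16),
) -> SignificanceComposition:
    """Bin threshold-mode results into significance levels by group.

    Terms of the distinguished general-terms group are excluded.  A
    term's level is ``ceil(-log10(p_adj))`` clamped into
    ``level_range``; ``p_adj == 0`` is assigned the top level (logged).
    """
    low, high = level_range
    if low > high:
        raise ValueError("level_range must be (low, high) with low <= high")
    composition = SignificanceComposition(level_range=(low, high))
    for result in results:
        group = grouping[result.term_id]
        if group == grouping.general_label:
            continue
        if result.p_adj == 0.0:
            logger.warning("%s: p_adj == 0, assigned top significance level", result.term_id)
            level = high
        else:
            level = math.ceil(-math.log10(result.p_adj))
            level = min(max(level, low), high)
        composition.counts.setdefault(level, {})
        composition.counts[level][group] = composition.counts[level].get(group, 0) + 1
    return composition


__all__ = [
    "GENERAL_TERMS_LABEL",
    "EnrichmentResult",
    "TermGrouping",
    "IntersectionMatrix",
    "SignificanceComposition",
    "hypergeom_upper_tail",
    "propagate_annotations",
    "enrich",
    "contributor_sets",
    "intersection_matrix",
    "significance_composition",
]
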