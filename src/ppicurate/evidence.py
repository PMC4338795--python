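"""Per-interactor evidence summaries and the four-tier occurrence ranking.

Each partner of the query protein is scored by how often, and how
independently, its interaction was observed:

* ``low`` — a single annotation overall;
* ``medium_low`` — one publication, but replicated (>= 2 annotations;
  normally >= 2 methods);
* ``medium_high`` — >= 2 publications, all with the same method;
* ``high`` — >= 2 publications and >= 2 methods.

Method counting uses the harmonized categories, not the raw source
vocabulary.  The *filtered interactome* is the set of partners with at
least two annotations (i.e. everything above ``low``); the *complete
interactome* additionally includes the singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .curation import MethodHarmonizationMap
from .io_formats import InteractionRecord

logger = logging.getLogger(__name__)

TIERS = ("low", "medium_low", "medium_high", "high")


@dataclass
class InteractorSummary:
    """Evidence counts for one partner of the query protein."""

    protein: str
    n_annotations: int
    n_publications: int
    n_methods: int
    publications: tuple[str, ...] = ()
    methods: tuple[str, ...] = ()
    tier: str = ""
    htp: bool = False
    #: one publication, >= 2 annotations yet only one method (e.g. hosts
    #: differ) — replication exists but the ranking never named this case
    flagged_uncovered: bool = False

    def __post_init__(self) -> None:
        if self.n_annotations < self.n_publications or self.n_annotations < self.n_methods:
            raise ValueError(
                f"{self.protein}: annotation count below publication or method count"
            )


@dataclass
class FamilyGroup:
    """Interactors sharing a protein family, with authorship independence."""

    family_name: str
    members: tuple[str, ...]
    n_publications: int
    independent: bool


def classify_occurrence(n_annotations: int, n_publications: int, n_methods: int) -> str:
    """Assign the occurrence tier from the three evidence counts.

    The uncovered corner case (one publication, >= 2 annotations, one
    method) is ranked ``medium_low``: replication within a publication.
    """
    if n_annotations <= 0 or n_publications <= 0 or n_methods <= 0:
        raise ValueError("occurrence counts must be positive")
    if n_annotations < max(n_publications, n_methods):
        raise ValueError("annotation count below publication or method count")
    if n_annotations == 1:
        return "low"
    if n_publications >= 2 and n_methods >= 2:
        return "high"
    if n_publications >= 2:
        return "medium_high"
    return "medium_low"


def summarize_interactors(
    hetero_records: Sequence[InteractionRecord],
    harmonization: MethodHarmonizationMap | None = None,
    query: str | None = None,
) -> list[InteractorSummary]:
    """One summary per distinct partner in the merged heterologous set.

    Records must carry harmonized methods already, or a harmonization
    map must be given.  ``query`` defaults to the accession present in
    every record.
    """
    records = list(hetero_records)
    if harmonization is not None and any(not r.harmonized_method for r in records):
        records = harmonization.apply(records)
    if any(not r.harmonized_method for r in records):
        raise ValueError("records lack harmonized methods and no map was given")
    if query is None:
        query = _infer_query(records)

    by_partner: dict[str, list[InteractionRecord]] = {}
    for rec in records:
        by_partner.setdefault(rec.partner_of(query), []).append(rec)

    summaries: list[InteractorSummary] = []
    for partner in sorted(by_partner):
        recs = by_partner[partner]
        pubs = tuple(sorted({r.publication_id for r in recs}))
        methods = tuple(sorted({r.harmonized_method for r in recs}))
        tier = classify_occurrence(len(recs), len(pubs), len(methods))
        flagged = len(recs) >= 2 and len(pubs) == 1 and len(methods) == 1
        if flagged:
            logger.warning(
                "%s: %d annotations in one publication with one method; ranked medium_low",
                partner, len(recs),
            )
        summaries.append(
            InteractorSummary(
                protein=partner,
                n_annotations=len(recs),
                n_publications=len(pubs),
                n_methods=len(methods),
                publications=pubs,
                methods=methods,
                tier=tier,
                htp=any(r.throughput == "high" for r in recs),
                flagged_uncovered=flagged,
            )
        )
    return summaries


def _infer_query(records: Sequence[InteractionRecord]) -> str:
    if not records:
        raise ValueError("cannot infer query protein from an empty record list")
    candidates = {records[0].interactor_a, records[0].interactor_b}
    for rec in records[1:]:
        candidates &= {rec.interactor_a, rec.interactor_b}
        if not candidates:
            raise ValueError("no common interactor across records; pass query explicitly")
    return min(candidates)


def tier_histogram(summaries: Iterable[InteractorSummary]) -> dict[str, int]:
    hist = {tier: 0 for tier in TIERS}
    for s in summaries:
        hist[s.tier] += 1
    return hist


def filtered_interactome(summaries: Iterable[InteractorSummary]) -> set[str]:
    """Partners supported by >= 2 annotations (complement of tier ``low``)."""
    return {s.protein for s in summaries if s.n_annotations >= 2}


def complete_interactome(summaries: Iterable[InteractorSummary]) -> set[str]:
    """All distinct partners, singletons included."""
    return {s.protein for s in summaries}


def group_families(
    filtered_summaries: Sequence[InteractorSummary],
    family_map: Mapping[str, str],
    pub_to_group_map: Mapping[str, str],
) -> tuple[list[FamilyGroup], list[str]]:
    """Group the filtered interactome into protein families.

    A family is *independent* when the publications supporting its
    members come from at least two distinct research groups.  Returns
    the family groups and the interactors with no family assignment.
    """
    by_family: dict[str, list[InteractorSummary]] = {}
    unassigned: list[str] = []
    for summary in filtered_summaries:
        family = family_map.get(summary.protein)
        if family is None:
            unassigned.append(summary.protein)
            continue
        by_family.setdefault(family, []).append(summary)
    if unassigned:
        logger.info("%d interactors without family assignment: %s", len(unassigned), unassigned)

    groups: list[FamilyGroup] = []
    for family in sorted(by_family):
        members = by_family[family]
        pubs = sorted({p for m in members for p in m.publications})
        missing = [p for p in pubs if p not in pub_to_group_map]
        if missing:
            raise KeyError(f"publications missing from research-group map: {missing}")
        research_groups = {pub_to_group_map[p] for p in pubs}
        groups.append(
            FamilyGroup(
                family_name=family,
                members=tuple(sorted(m.protein for m in members)),
                n_publications=len(pubs),
                independent=len(research_groups) >= 2,
            )
        )
    return groups, sorted(unassigned)


__all__ = [
    "TIERS",
    "InteractorSummary",
    "FamilyGroup",
    "classify_occurrence",
    "summarize_interactors",
    "tier_histogram",
    "filtered_interactome",
    "complete_interactome",
    "group_families",
]
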