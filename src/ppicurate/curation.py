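"""Curation filters and the cross-database merge for a query protein.

The pipeline applies, in order:

* filter #0 — drop spoke-expanded co-complex rows (pairs derived by
  expanding an n-member complex around the query; possibly not direct
  contacts);
* filter #1 — keep only records where both interactors carry the
  allowed taxon (human, 9606, by default); chemical interactors are
  removed here too;
* filter #2 — within one publication, collapse records that describe
  the same experiment twice (bait/prey swaps, tag variants): two
  records are duplicates iff they share publication, unordered
  canonical pair, detection method and host organism.

Two curated single-source datasets are then merged per publication:
a publication present in only one source is copied verbatim; when both
sources annotated it, the source with more annotations wins wholesale;
on a tie the union is taken and re-deduplicated with the *harmonized*
method vocabulary (sources name the same assay differently), dropping
host from the key because one source never reports it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import InteractionRecord

logger = logging.getLogger(__name__)

#: Order of the provenance stages; counts are non-increasing along it.
STAGES = ("raw", "post_spoke", "post_filter1", "post_filter2")

HUMAN_TAXID = 9606


class HarmonizationError(KeyError):
    """A detection method present in the data has no harmonized category."""


#: Default harmonization of source-specific detection-method vocabularies
#: into shared categories.  Keys are matched case-insensitively.
DEFAULT_HARMONIZATION: dict[str, str] = {
    # affinity capture family
    "anti bait coimmunoprecipitation": "Affinity Capture",
    "anti tag coimmunoprecipitation": "Affinity Capture",
    "coimmunoprecipitation": "Affinity Capture",
    "pull down": "Affinity Capture",
    "affinity chromatography technology": "Affinity Capture",
    "affinity capture-western": "Affinity Capture",
    "affinity capture-ms": "Affinity Capture",
    "affinity capture": "Affinity Capture",
    # enzymatic assays
    "protein kinase assay": "Biochemical Activity",
    "biochemical activity": "Biochemical Activity",
    # imaging
    "confocal microscopy": "Co-localization",
    "fluorescence microscopy": "Co-localization",
    "co-localization": "Co-localization",
    # in vitro reconstitution
    "fluorescence polarization spectroscopy": "Reconstituted Complex",
    "surface plasmon resonance": "Reconstituted Complex",
    "reconstituted complex": "Reconstituted Complex",
    # passthrough categories common to both sources
    "two hybrid": "Two Hybrid",
    "protein array": "Protein Array",
    "proximity label-ms": "Proximity Label",
}


@dataclass
class MethodHarmonizationMap:
    """Total map from source method vocabulary to harmonized categories."""

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_HARMONIZATION))

    def __post_init__(self) -> None:
        self._lower = {k.lower(): v for k, v in self.mapping.items()}

    def __getitem__(self, method: str) -> str:
        try:
            return self._lower[method.lower()]
        except KeyError:
            raise HarmonizationError(
                f"no harmonized category for detection method {method!r}"
            ) from None

    def apply(self, records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
        """Return copies with ``harmonized_method`` filled in.

        Raises :class:`HarmonizationError` listing every unmapped method
        if the map is not total on the input.
        """
        records = list(records)
        unmapped = sorted(
            {r.detection_method for r in records if r.detection_method.lower() not in self._lower}
        )
        if unmapped:
            raise HarmonizationError(f"unmapped detection methods: {unmapped}")
        return [replace(r, harmonized_method=self[r.detection_method]) for r in records]


@dataclass
class CuratedDataset:
    """Filtered records for one query protein plus per-stage provenance."""

    records: list[InteractionRecord]
    provenance: dict
    query_protein: str
    source: str = ""

    def __post_init__(self) -> None:
        counts = [self.provenance[s] for s in STAGES if s in self.provenance]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"provenance counts increase along stages: {counts}")
        for rec in self.records:
            rec.partner_of(self.query_protein)  # raises if query absent

    @property
    def publications(self) -> set[str]:
        return {r.publication_id for r in self.records}


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def remove_spoke_expanded(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Filter #0: drop rows flagged as spoke-expanded co-complex pairs."""
    return [r for r in records if not r.expansion]


def filter_taxid(
    records: Sequence[InteractionRecord], allowed_taxid: int = HUMAN_TAXID
) -> list[InteractionRecord]:
    """Filter #1: keep records where both taxids equal ``allowed_taxid``.

    Chemical interactors carry a non-integer taxon sentinel and are
    therefore removed here as well.
    """
    return [r for r in records if r.taxid_a == allowed_taxid and r.taxid_b == allowed_taxid]


def _dedup_key(rec: InteractionRecord, harmonized: bool = False) -> tuple:
    method = rec.harmonized_method if harmonized else rec.detection_method
    if harmonized and not rec.harmonized_method:
        raise ValueError("harmonized dedup requested but harmonized_method empty")
    key = (rec.publication_id, rec.unordered_pair(), method)
    if not harmonized:
        key += (rec.host_organism,)
    return key


def dedup_within_publication(
    records: Sequence[InteractionRecord], harmonized: bool = False
) -> list[InteractionRecord]:
    """Filter #2: one representative per duplicate class.

    Duplicates share publication, unordered canonical pair, detection
    method and host organism; the first record in input order survives.
    With ``harmonized=True`` the harmonized method replaces the raw one
    and host is dropped from the key (cross-source merge mode).
    """
    seen: set[tuple] = set()
    kept: list[InteractionRecord] = []
    for rec in records:
        key = _dedup_key(rec, harmonized=harmonized)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return kept


def curate(
    records: Sequence[InteractionRecord],
    query: str,
    allowed_taxid: int = HUMAN_TAXID,
    source: str = "",
) -> CuratedDataset:
    """Run filters #0 -> #1 -> #2 and record per-stage counts."""
    provenance = {"raw": len(records)}
    stage = remove_spoke_expanded(records)
    provenance["post_spoke"] = len(stage)
    stage = filter_taxid(stage, allowed_taxid)
    provenance["post_filter1"] = len(stage)
    stage = dedup_within_publication(stage)
    provenance["post_filter2"] = len(stage)
    return CuratedDataset(
        records=stage, provenance=provenance, query_protein=query, source=source
    )


def split_homo_hetero(
    records: Sequence[InteractionRecord], query: str
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Partition into (heterologous, homologous) annotations.

    Homologous means the query interacting with itself (dimerization);
    every record must involve the query.
    """
    hetero: list[InteractionRecord] = []
    homo: list[InteractionRecord] = []
    for rec in records:
        rec.partner_of(query)  # contract check: raises if query absent
        if rec.interactor_a == query and rec.interactor_b == query:
            homo.append(rec)
        else:
            hetero.append(rec)
    return hetero, homo


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------


def merge_datasets(
    ds_a: CuratedDataset,
    ds_b: CuratedDataset,
    harmonization: MethodHarmonizationMap | None = None,
) -> CuratedDataset:
    """Merge two fully filtered single-source datasets per publication.

    Publication in one source only -> copied verbatim.  Publication in
    both -> the source with more annotations is selected wholesale; on a
    tie the union is re-deduplicated with harmonized methods (host
    excluded from the key, since one source never reports it).
    Provenance records the per-publication source choice.
    """
    if ds_a.query_protein != ds_b.query_protein:
        raise ValueError(
            f"cannot merge datasets for different query proteins "
            f"({ds_a.query_protein} vs {ds_b.query_protein})"
        )
    harmonization = harmonization or MethodHarmonizationMap()
    recs_a = harmonization.apply(ds_a.records)
    recs_b = harmonization.apply(ds_b.records)
    by_pub_a: dict[str, list[InteractionRecord]] = {}
    by_pub_b: dict[str, list[InteractionRecord]] = {}
    for rec in recs_a:
        by_pub_a.setdefault(rec.publication_id, []).append(rec)
    for rec in recs_b:
        by_pub_b.setdefault(rec.publication_id, []).append(rec)

    label_a = ds_a.source or "a"
    label_b = ds_b.source or "b"
    merged: list[InteractionRecord] = []
    pub_source: dict[str, str] = {}
    for pub in sorted(set(by_pub_a) | set(by_pub_b)):
        in_a, in_b = by_pub_a.get(pub, []), by_pub_b.get(pub, [])
        if not in_b:
            merged.extend(in_a)
            pub_source[pub] = label_a
        elif not in_a:
            merged.extend(in_b)
            pub_source[pub] = label_b
        elif len(in_a) > len(in_b):
            merged.extend(in_a)
            pub_source[pub] = label_a
        elif len(in_b) > len(in_a):
            merged.extend(in_b)
            pub_source[pub] = label_b
        else:
            union = dedup_within_publication(in_a + in_b, harmonized=True)
            merged.extend(union)
            pub_source[pub] = "union"
            logger.info(
                "publication %s: tie (%d vs %d annotations), harmonized union kept %d",
                pub, len(in_a), len(in_b), len(union),
            )
    provenance = {
        "merged": len(merged),
        "n_" + label_a: len(recs_a),
        "n_" + label_b: len(recs_b),
        "publication_source": pub_source,
    }
    return CuratedDataset(
        records=merged,
        provenance=provenance,
        query_protein=ds_a.query_protein,
        source="merged",
    )


__all__ = [
    "STAGES",
    "HUMAN_TAXID",
    "DEFAULT_HARMONIZATION",
    "HarmonizationError",
    "MethodHarmonizationMap",
    "CuratedDataset",
    "remove_spoke_expanded",
    "filter_taxid",
    "dedup_within_publication",
    "curate",
    "split_homo_hetero",
    "merge_datasets",
]
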