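"""File-format readers and writers for interactome curation.

Covers every external format the pipeline touches: PSI-MI TAB 2.7 and
BioGRID TAB 2.0 interaction tables, OBO ontologies, GAF gene-to-term
annotation tables, BED gene intervals, delimited SNP tables and a SIF
edge-list export.

Identifier canonicalization is applied at parse time: isoform suffixes
("-2") and processed-chain suffixes ("-PRO_0000018605") are stripped so
that protein fragments and isoforms collapse onto the parent accession,
the convention curated PPI databases themselves follow when assigning
UniProtKB identifiers.  The raw accession as printed in the file is
retained alongside the canonical form.

Internal coordinates are 1-based inclusive everywhere (protein residues
and base pairs); converters live at the file boundary (BED's half-open
0-based intervals are converted on read and restored on write).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from Bio.UniProt import GOA as _goa

logger = logging.getLogger(__name__)

#: Taxon sentinel assigned to small-molecule interactors (detected by
#: identifier namespace, e.g. ChEBI), removed by the taxid filter.
CHEMICAL = "chemical"

#: Host-organism sentinel for formats without a host column (BioGRID TAB 2.0).
UNSPECIFIED_HOST = "unspecified"

SPOKE_EXPANSION = "spoke expansion"

_CHEMICAL_NAMESPACES = {"chebi", "chembl", "chembl target", "pubchem"}

_ISOFORM_OR_CHAIN = re.compile(r"-(?:PRO_\d+|\d+)$")


class ParseError(ValueError):
    """Raised for malformed rows; message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class InteractionRecord:
    """One curated interaction annotation.

    An *annotation* is a single experimental record: a specific
    interactor pair, detection method, host organism and publication.
    """

    interactor_a: str
    interactor_b: str
    raw_id_a: str
    raw_id_b: str
    taxid_a: int | str
    taxid_b: int | str
    detection_method: str
    publication_id: str
    first_author: str
    source_db: str
    host_organism: str = UNSPECIFIED_HOST
    harmonized_method: str = ""
    expansion: str = ""
    regions: list[tuple[int, int]] = field(default_factory=list)
    throughput: str = "unknown"

    def __post_init__(self) -> None:
        if not self.interactor_a or not self.interactor_b:
            raise ValueError("interactor accessions must be non-empty")
        if not self.publication_id:
            raise ValueError("publication_id must be non-empty")
        if self.source_db not in {"intact", "biogrid"}:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        if self.throughput not in {"high", "low", "unknown"}:
            raise ValueError(f"invalid throughput {self.throughput!r}")
        for start, end in self.regions:
            if not (1 <= start <= end):
                raise ValueError(f"invalid region ({start}, {end})")

    def unordered_pair(self) -> tuple[str, str]:
        """Canonical pair irrespective of bait/prey orientation."""
        a, b = self.interactor_a, self.interactor_b
        return (a, b) if a <= b else (b, a)

    def partner_of(self, query: str) -> str:
        """The non-query interactor (the query itself for self-interactions)."""
        if self.interactor_a == query:
            return self.interactor_b
        if self.interactor_b == query:
            return self.interactor_a
        raise ValueError(
            f"record {self.raw_id_a}/{self.raw_id_b} does not involve query {query}"
        )


@dataclass
class OntologyDag:
    """Term hierarchy: nodes are term IDs, edges point child -> parent."""

    graph: nx.MultiDiGraph
    relations: frozenset[str] = frozenset({"is_a", "part_of"})

    def __post_init__(self) -> None:
        self._parents = nx.DiGraph()
        self._parents.add_nodes_from(self.graph.nodes)
        for child, parent, key in self.graph.edges(keys=True):
            if key in self.relations:
                self._parents.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._parents):
            raise ValueError("ontology contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via the configured relations."""
        return nx.descendants(self._parents, term)

    def n_edges(self) -> int:
        return self._parents.number_of_edges()


@dataclass
class AnnotationTable:
    """Gene -> set-of-term assignments over a reference gene universe."""

    annotations: dict[str, set[str]]
    reference_genes: set[str]

    def __post_init__(self) -> None:
        missing = set(self.annotations) - self.reference_genes
        if missing:
            raise ValueError(f"annotated genes outside reference: {sorted(missing)[:5]}")

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, terms in self.annotations.items() if term in terms}


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic span, 1-based inclusive coordinates."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 < self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")


@dataclass(frozen=True)
class SnpLocus:
    """A trait-associated SNP marking a GWAS risk locus."""

    rsid: str
    chromosome: str
    position: int
    trait: str = "other"

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError("SNP position must be positive")


# ---------------------------------------------------------------------------
# accession handling
# ---------------------------------------------------------------------------


def canonicalize_accession(raw: str) -> str:
    """Strip isoform ("-2") and chain ("-PRO_...") suffixes from an accession.

    Applied to a fixed point, so the function is idempotent even on
    pathological multi-suffix inputs.  Strings without such suffixes are
    returned unchanged.
    """
    if not raw or not raw.strip():
        raise ValueError("empty accession")
    acc = raw.strip()
    while True:
        stripped = _ISOFORM_OR_CHAIN.sub("", acc)
        if stripped == acc or not stripped:
            return acc
        acc = stripped


def _is_chemical_id(namespace: str) -> bool:
    return namespace.lower() in _CHEMICAL_NAMESPACES


def _split_xref(fieldval: str) -> tuple[str, str]:
    """First ``db:value`` cross-reference in a MI-TAB field."""
    first = fieldval.split("|")[0].strip()
    if ":" in first:
        db, _, value = first.partition(":")
        return db.strip().lower(), value.strip().strip('"')
    return "", first


_PAREN = re.compile(r"\(([^()]*)\)\s*$")
_TAXID = re.compile(r"taxid:(-?\d+)")
_REGION = re.compile(r"(\d+)-(\d+)")


def _controlled_term(fieldval: str) -> str:
    """Human-readable label of a ``psi-mi:"MI:0006"(label)`` style field."""
    m = _PAREN.search(fieldval.strip())
    return m.group(1) if m else fieldval.strip()


def _parse_taxid(fieldval: str, raw_id_namespace: str) -> int | str:
    if _is_chemical_id(raw_id_namespace):
        return CHEMICAL
    m = _TAXID.search(fieldval)
    if m:
        return int(m.group(1))
    raise ParseError(f"cannot parse taxid from {fieldval!r}")


def _parse_regions(fieldval: str) -> list[tuple[int, int]]:
    regions: list[tuple[int, int]] = []
    if not fieldval or fieldval.strip() == "-":
        return regions
    for token in fieldval.split("|"):
        m = _REGION.search(token)
        if m:
            start, end = int(m.group(1)), int(m.group(2))
            regions.append((start, end))
    return regions


# ---------------------------------------------------------------------------
# MI-TAB 2.7
# ---------------------------------------------------------------------------

#: Default MI-TAB 2.7 column layout (36 tab-separated columns).  Other
#: dialects are handled by passing a different map.
MITAB_COLUMNS: dict[str, int] = {
    "id_a": 0,
    "id_b": 1,
    "detection_method": 6,
    "first_author": 7,
    "publication": 8,
    "taxid_a": 9,
    "taxid_b": 10,
    "source_db": 12,
    "expansion": 15,
    "host": 28,
    "features_a": 32,
    "features_b": 33,
    "n_columns": 36,
}

_MITAB_HEADER_NAMES = [
    "#ID(s) interactor A", "ID(s) interactor B", "Alt. ID(s) interactor A",
    "Alt. ID(s) interactor B", "Alias(es) interactor A", "Alias(es) interactor B",
    "Interaction detection method(s)", "Publication 1st author(s)",
    "Publication Identifier(s)", "Taxid interactor A", "Taxid interactor B",
    "Interaction type(s)", "Source database(s)", "Interaction identifier(s)",
    "Confidence value(s)", "Expansion method(s)", "Biological role(s) interactor A",
    "Biological role(s) interactor B", "Experimental role(s) interactor A",
    "Experimental role(s) interactor B", "Type(s) interactor A",
    "Type(s) interactor B", "Xref(s) interactor A", "Xref(s) interactor B",
    "Interaction Xref(s)", "Annotation(s) interactor A",
    "Annotation(s) interactor B", "Interaction annotation(s)",
    "Host organism(s)", "Interaction parameter(s)", "Creation date",
    "Update date", "Feature(s) interactor A", "Feature(s) interactor B",
    "Stoichiometry(s) interactor A", "Stoichiometry(s) interactor B",
]


def read_mitab(
    path: str | Path,
    column_map: Mapping[str, int] | None = None,
    throughput_map: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Parse a PSI-MI TAB 2.7 file into :class:`InteractionRecord` rows.

    ``throughput_map`` optionally maps detection-method labels to
    ``high``/``low``; MI-TAB itself carries no throughput column, so
    records default to ``unknown``.
    """
    cmap = dict(column_map or MITAB_COLUMNS)
    n_columns = cmap["n_columns"]
    records: list[InteractionRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_columns} columns, got {len(fields)}"
                )
            ns_a, raw_a = _split_xref(fields[cmap["id_a"]])
            ns_b, raw_b = _split_xref(fields[cmap["id_b"]])
            method = _controlled_term(fields[cmap["detection_method"]])
            expansion_field = fields[cmap["expansion"]]
            expansion = SPOKE_EXPANSION if SPOKE_EXPANSION in expansion_field else ""
            host_field = fields[cmap["host"]].strip()
            host = UNSPECIFIED_HOST if host_field in {"", "-"} else host_field
            _, pub = _split_xref(fields[cmap["publication"]])
            regions = _parse_regions(fields[cmap["features_a"]])
            for reg in _parse_regions(fields[cmap["features_b"]]):
                if reg not in regions:
                    regions.append(reg)
            throughput = "unknown"
            if throughput_map:
                throughput = throughput_map.get(method, "unknown")
            try:
                records.append(
                    InteractionRecord(
                        interactor_a=canonicalize_accession(raw_a),
                        interactor_b=canonicalize_accession(raw_b),
                        raw_id_a=raw_a,
                        raw_id_b=raw_b,
                        taxid_a=_parse_taxid(fields[cmap["taxid_a"]], ns_a),
                        taxid_b=_parse_taxid(fields[cmap["taxid_b"]], ns_b),
                        detection_method=method,
                        publication_id=pub,
                        first_author=fields[cmap["first_author"]].strip(),
                        source_db="intact",
                        host_organism=host,
                        expansion=expansion,
                        regions=regions,
                        throughput=throughput,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_mitab(
    records: Iterable[InteractionRecord],
    path: str | Path,
    column_map: Mapping[str, int] | None = None,
) -> None:
    """Serialize records back to the 36-column MI-TAB layout."""
    cmap = dict(column_map or MITAB_COLUMNS)
    n_columns = cmap["n_columns"]
    with open(path, "w") as handle:
        handle.write("\t".join(_MITAB_HEADER_NAMES[:n_columns]) + "\n")
        for rec in records:
            fields = ["-"] * n_columns
            ns_a = "chebi" if rec.taxid_a == CHEMICAL else "uniprotkb"
            ns_b = "chebi" if rec.taxid_b == CHEMICAL else "uniprotkb"
            fields[cmap["id_a"]] = f"{ns_a}:{rec.raw_id_a}"
            fields[cmap["id_b"]] = f"{ns_b}:{rec.raw_id_b}"
            fields[cmap["detection_method"]] = f'psi-mi:"MI:0000"({rec.detection_method})'
            fields[cmap["first_author"]] = rec.first_author or "-"
            fields[cmap["publication"]] = f"pubmed:{rec.publication_id}"
            for key, taxid in (("taxid_a", rec.taxid_a), ("taxid_b", rec.taxid_b)):
                fields[cmap[key]] = "-" if taxid == CHEMICAL else f"taxid:{taxid}"
            fields[cmap["source_db"]] = 'psi-mi:"MI:0469"(IntAct)'
            if rec.expansion:
                fields[cmap["expansion"]] = f'psi-mi:"MI:1060"({rec.expansion})'
            if rec.host_organism != UNSPECIFIED_HOST:
                fields[cmap["host"]] = rec.host_organism
            if rec.regions:
                fields[cmap["features_a"]] = "|".join(
                    f"binding region:{s}-{e}" for s, e in rec.regions
                )
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BioGRID TAB 2.0
# ---------------------------------------------------------------------------

#: Default BioGRID TAB 2.0 column layout (24 tab-separated columns).
BIOGRID_COLUMNS: dict[str, int] = {
    "id_a": 7,
    "id_b": 8,
    "detection_method": 11,
    "first_author": 13,
    "publication": 14,
    "taxid_a": 15,
    "taxid_b": 16,
    "throughput": 17,
    "n_columns": 24,
}

_BIOGRID_HEADER_NAMES = [
    "#BioGRID Interaction ID", "Entrez Gene Interactor A", "Entrez Gene Interactor B",
    "BioGRID ID Interactor A", "BioGRID ID Interactor B",
    "Systematic Name Interactor A", "Systematic Name Interactor B",
    "Official Symbol Interactor A", "Official Symbol Interactor B",
    "Synonyms Interactor A", "Synonyms Interactor B", "Experimental System",
    "Experimental System Type", "Author", "Pubmed ID",
    "Organism Interactor A", "Organism Interactor B", "Throughput", "Score",
    "Modification", "Phenotypes", "Qualifications", "Tags", "Source Database",
]


def _parse_throughput(fieldval: str) -> str:
    if "High Throughput" in fieldval:
        return "high"
    if "Low Throughput" in fieldval:
        return "low"
    return "unknown"


def read_biogrid_tab2(
    path: str | Path, column_map: Mapping[str, int] | None = None
) -> list[InteractionRecord]:
    """Parse a BioGRID TAB 2.0 file.

    Detection method comes from the ``Experimental System`` column.  The
    format has no host-organism column, so every record carries the
    ``unspecified`` host sentinel (the within-publication dedup key then
    degenerates to publication + pair + method for this source).
    """
    cmap = dict(column_map or BIOGRID_COLUMNS)
    n_columns = cmap["n_columns"]
    records: list[InteractionRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_columns} columns, got {len(fields)}"
                )
            raw_a = fields[cmap["id_a"]].strip()
            raw_b = fields[cmap["id_b"]].strip()

            def taxid_of(raw_id: str, fieldval: str) -> int | str:
                ns = raw_id.partition(":")[0] if ":" in raw_id else ""
                if _is_chemical_id(ns):
                    return CHEMICAL
                try:
                    return int(fieldval)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: bad organism field {fieldval!r}"
                    ) from exc

            try:
                records.append(
                    InteractionRecord(
                        interactor_a=canonicalize_accession(raw_a),
                        interactor_b=canonicalize_accession(raw_b),
                        raw_id_a=raw_a,
                        raw_id_b=raw_b,
                        taxid_a=taxid_of(raw_a, fields[cmap["taxid_a"]]),
                        taxid_b=taxid_of(raw_b, fields[cmap["taxid_b"]]),
                        detection_method=fields[cmap["detection_method"]].strip(),
                        publication_id=fields[cmap["publication"]].strip(),
                        first_author=fields[cmap["first_author"]].strip(),
                        source_db="biogrid",
                        host_organism=UNSPECIFIED_HOST,
                        throughput=_parse_throughput(fields[cmap["throughput"]]),
                    )
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_biogrid_tab2(
    records: Iterable[InteractionRecord],
    path: str | Path,
    column_map: Mapping[str, int] | None = None,
) -> None:
    cmap = dict(column_map or BIOGRID_COLUMNS)
    n_columns = cmap["n_columns"]
    throughput_labels = {"high": "High Throughput", "low": "Low Throughput", "unknown": "-"}
    with open(path, "w") as handle:
        handle.write("\t".join(_BIOGRID_HEADER_NAMES[:n_columns]) + "\n")
        for i, rec in enumerate(records, start=1):
            fields = ["-"] * n_columns
            fields[0] = str(i)
            fields[cmap["id_a"]] = rec.raw_id_a
            fields[cmap["id_b"]] = rec.raw_id_b
            fields[cmap["detection_method"]] = rec.detection_method
            fields[cmap["first_author"]] = rec.first_author or "-"
            fields[cmap["publication"]] = rec.publication_id
            fields[cmap["taxid_a"]] = "-" if rec.taxid_a == CHEMICAL else str(rec.taxid_a)
            fields[cmap["taxid_b"]] = "-" if rec.taxid_b == CHEMICAL else str(rec.taxid_b)
            fields[cmap["throughput"]] = throughput_labels[rec.throughput]
            fields[n_columns - 1] = "BIOGRID"
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# ontology, annotations, intervals, SNPs
# ---------------------------------------------------------------------------


def read_obo(path: str | Path, relations: Iterable[str] = ("is_a", "part_of")) -> OntologyDag:
    """Read an OBO 1.2 ontology into an :class:`OntologyDag`.

    Raises ``ValueError`` if the relation-restricted graph is cyclic.
    """
    graph = obonet.read_obo(str(path))
    return OntologyDag(graph=graph, relations=frozenset(relations))


def read_gaf(path: str | Path, dag: OntologyDag | None = None) -> AnnotationTable:
    """Read a GAF 2.x annotation file.

    Genes are keyed by object symbol.  If ``dag`` is given, annotations
    to terms absent from the ontology are skipped with a logged warning.
    The reference universe is the set of all genes seen in the file.
    """
    annotations: dict[str, set[str]] = {}
    skipped = 0
    with open(path) as handle:
        for entry in _goa.gafiterator(handle):
            gene = entry["DB_Object_Symbol"]
            term = entry["GO_ID"]
            if dag is not None and term not in dag.terms:
                skipped += 1
                logger.warning("annotation of %s to unknown term %s skipped", gene, term)
                continue
            annotations.setdefault(gene, set()).add(term)
    if skipped:
        logger.warning("skipped %d annotations to unknown terms", skipped)
    return AnnotationTable(annotations=annotations, reference_genes=set(annotations))


def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read a BED file of gene intervals (half-open 0-based on disk,
    converted to inclusive 1-based internally)."""
    intervals: list[GeneInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: BED needs >= 4 columns")
            chrom, start0, end, name = fields[:4]
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "unknown"
            intervals.append(
                GeneInterval(
                    gene_symbol=name,
                    chromosome=chrom,
                    start=int(start0) + 1,
                    end=int(end),
                    strand=strand,
                )
            )
    return intervals


def write_gene_bed(intervals: Iterable[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            strand = iv.strand if iv.strand in {"+", "-"} else "."
            handle.write(
                f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{iv.gene_symbol}\t0\t{strand}\n"
            )


def read_snp_table(path: str | Path) -> list[SnpLocus]:
    """Read a TSV SNP table with columns rsid, chromosome, position, trait."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"rsid", "chromosome", "position", "trait"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: SNP table needs columns {sorted(required)}")
    return [
        SnpLocus(
            rsid=row.rsid,
            chromosome=str(row.chromosome),
            position=int(row.position),
            trait=str(row.trait),
        )
        for row in df.itertuples()
    ]


def write_snp_table(snps: Iterable[SnpLocus], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("rsid\tchromosome\tposition\ttrait\n")
        for snp in snps:
            handle.write(f"{snp.rsid}\t{snp.chromosome}\t{snp.position}\t{snp.trait}\n")


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Generic key<TAB>value map reader (family, research-group, symbol maps)."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("\t")
            mapping[key] = value
    return mapping


def write_edge_list(
    records: Sequence[InteractionRecord], query: str, path: str | Path
) -> None:
    """SIF-style export: one ``query <method> partner`` line per annotation,
    deterministically ordered."""
    lines = sorted(
        f"{query}\t{rec.harmonized_method or rec.detection_method}\t{rec.partner_of(query)}"
        for rec in records
    )
    with open(path, "w") as handle:
        for line in lines:
            handle.write(line + "\n")


__all__ = [
    "CHEMICAL",
    "UNSPECIFIED_HOST",
    "SPOKE_EXPANSION",
    "ParseError",
    "InteractionRecord",
    "OntologyDag",
    "AnnotationTable",
    "GeneInterval",
    "SnpLocus",
    "canonicalize_accession",
    "read_mitab",
    "write_mitab",
    "read_biogrid_tab2",
    "write_biogrid_tab2",
    "read_obo",
    "read_gaf",
    "read_gene_bed",
    "write_gene_bed",
    "read_snp_table",
    "write_snp_table",
    "read_two_column_map",
    "write_edge_list",
    "MITAB_COLUMNS",
    "BIOGRID_COLUMNS",
]
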