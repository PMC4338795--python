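"""End-to-end orchestration: curate -> merge -> tier -> enrich -> profile -> overlap.

Mirrors the full interactome-curation workflow: both source snapshots
are filtered independently (spoke removal, taxon filter, within-
publication dedup), split into heterologous and homologous annotations,
merged per publication, tiered by occurrence, and the filtered
interactome is carried into GO over-representation while the *complete*
interactome (singletons included) is compared with GWAS risk loci.  The
self-interaction records build the residue profile.

All analysis stages are deterministic; a rerun on the same inputs
produces byte-identical reports.  Every stage's output is written as
TSV under the configured output directory, and a provenance table
records the per-stage annotation counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import curation, enrichment, evidence, gwas_overlap, self_interaction
from .io_formats import (
    read_biogrid_tab2,
    read_gaf,
    read_gene_bed,
    read_mitab,
    read_obo,
    read_snp_table,
    read_two_column_map,
    write_edge_list,
    write_mitab,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Run configuration, typically loaded from YAML."""

    query: str
    intact_path: Path
    biogrid_path: Path
    out_dir: Path
    allowed_taxid: int = 9606
    harmonization_path: Path | None = None
    throughput_map_path: Path | None = None
    # enrichment
    obo_path: Path | None = None
    gaf_path: Path | None = None
    grouping_path: Path | None = None
    mode: str = "top10"
    min_genes: int = 2
    top_n: int = 10
    p_threshold: float = 1e-7
    propagate: bool = True
    level_range: tuple[int, int] = (7, 16)
    # self-interaction
    protein_length: int = 2527
    # GWAS
    bed_path: Path | None = None
    snp_path: Path | None = None
    symbol_map_path: Path | None = None
    candidate_path: Path | None = None
    window_bp: int = 200_000
    # families
    family_map_path: Path | None = None
    pub_group_path: Path | None = None

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle)
        base = path.parent

        def resolve(key: str) -> None:
            if raw.get(key) is not None:
                raw[key] = (base / raw[key]).resolve()

        for key in (
            "intact_path", "biogrid_path", "out_dir", "harmonization_path",
            "throughput_map_path", "obo_path", "gaf_path", "grouping_path",
            "bed_path", "snp_path", "symbol_map_path", "candidate_path",
            "family_map_path", "pub_group_path",
        ):
            resolve(key)
        if "level_range" in raw:
            raw["level_range"] = tuple(raw["level_range"])
        return cls(**raw)


@dataclass
class RunResult:
    """Everything the pipeline computed, stage by stage."""

    curated: dict[str, curation.CuratedDataset]
    hetero: dict[str, curation.CuratedDataset]
    homo: dict[str, curation.CuratedDataset]
    merged_hetero: curation.CuratedDataset
    merged_homo: curation.CuratedDataset
    summaries: list[evidence.InteractorSummary]
    tier_histogram: dict[str, int]
    filtered: set[str]
    complete: set[str]
    enrichment_results: list[enrichment.EnrichmentResult] | None = None
    contributor_sets: dict[str, frozenset[str]] | None = None
    matrix: enrichment.IntersectionMatrix | None = None
    composition: enrichment.SignificanceComposition | None = None
    families: list[evidence.FamilyGroup] | None = None
    family_unassigned: list[str] | None = None
    profile: self_interaction.ResidueProfile | None = None
    hits: list[gwas_overlap.OverlapHit] | None = None
    skipped: list[str] = field(default_factory=list)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_all(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and write the TSV report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    query = config.query

    harmonization = curation.MethodHarmonizationMap(
        read_two_column_map(config.harmonization_path)
        if config.harmonization_path
        else curation.DEFAULT_HARMONIZATION
    )
    throughput_map = (
        read_two_column_map(config.throughput_map_path)
        if config.throughput_map_path
        else None
    )

    # --- curate each source ------------------------------------------------
    raw_records = {
        "intact": _stage("read intact")(read_mitab, config.intact_path, None, throughput_map),
        "biogrid": _stage("read biogrid")(read_biogrid_tab2, config.biogrid_path),
    }
    curated: dict[str, curation.CuratedDataset] = {}
    hetero: dict[str, curation.CuratedDataset] = {}
    homo: dict[str, curation.CuratedDataset] = {}
    for src, records in raw_records.items():
        ds = _stage(f"curate {src}")(
            curation.curate, records, query, config.allowed_taxid, src
        )
        curated[src] = ds
        het, hom = _stage(f"split {src}")(curation.split_homo_hetero, ds.records, query)
        if len(het) + len(hom) != ds.provenance["post_filter2"]:
            raise PipelineError(f"stage 'split {src}': hetero+homo != post_filter2")
        hetero[src] = curation.CuratedDataset(het, {"post_filter2": len(het)}, query, src)
        homo[src] = curation.CuratedDataset(hom, {"post_filter2": len(hom)}, query, src)

    merged_hetero = _stage("merge hetero")(
        curation.merge_datasets, hetero["intact"], hetero["biogrid"], harmonization
    )
    merged_homo = _stage("merge homo")(
        curation.merge_datasets, homo["intact"], homo["biogrid"], harmonization
    )

    # --- evidence tiers ----------------------------------------------------
    summaries = _stage("summarize")(
        evidence.summarize_interactors, merged_hetero.records, harmonization, query
    )
    hist = evidence.tier_histogram(summaries)
    filtered = evidence.filtered_interactome(summaries)
    complete = evidence.complete_interactome(summaries)
    if len(filtered) + hist["low"] != len(complete):
        raise PipelineError("stage 'summarize': filtered + singletons != complete")

    result = RunResult(
        curated=curated,
        hetero=hetero,
        homo=homo,
        merged_hetero=merged_hetero,
        merged_homo=merged_homo,
        summaries=summaries,
        tier_histogram=hist,
        filtered=filtered,
        complete=complete,
    )

    # --- families (optional maps) -----------------------------------------
    if config.family_map_path and config.pub_group_path:
        family_map = read_two_column_map(config.family_map_path)
        pub_groups = read_two_column_map(config.pub_group_path)
        filtered_summaries = [s for s in summaries if s.protein in filtered]
        result.families, result.family_unassigned = _stage("families")(
            evidence.group_families, filtered_summaries, family_map, pub_groups
        )

    # --- enrichment (filtered interactome) ---------------------------------
    if config.obo_path and config.gaf_path:
        if not filtered:
            result.skipped.append("enrichment: empty filtered interactome")
            logger.warning("enrichment skipped: empty filtered interactome")
        else:
            dag = _stage("read ontology")(read_obo, config.obo_path)
            table = _stage("read annotations")(read_gaf, config.gaf_path, dag)
            result.enrichment_results = _stage("enrichment")(
                enrichment.enrich,
                filtered,
                table,
                dag,
                config.mode,
                config.min_genes,
                config.top_n,
                config.p_threshold,
                config.propagate,
            )
            if config.grouping_path and result.enrichment_results:
                grouping = enrichment.TermGrouping(
                    read_two_column_map(config.grouping_path)
                )
                result.contributor_sets = _stage("contributors")(
                    enrichment.contributor_sets, result.enrichment_results, grouping
                )
                if any(result.contributor_sets.values()):
                    result.matrix = enrichment.intersection_matrix(
                        result.contributor_sets, len(filtered)
                    )
                result.composition = _stage("composition")(
                    enrichment.significance_composition,
                    result.enrichment_results,
                    grouping,
                    config.level_range,
                )
    else:
        result.skipped.append("enrichment: no ontology/annotation inputs")

    # --- self-interaction profile ------------------------------------------
    result.profile = _stage("profile")(
        self_interaction.build_profile, merged_homo.records, config.protein_length
    )

    # --- GWAS overlap (complete interactome) -------------------------------
    if config.bed_path and config.snp_path and config.symbol_map_path:
        genes = _stage("read genes")(read_gene_bed, config.bed_path)
        snps = _stage("read snps")(read_snp_table, config.snp_path)
        symbol_map = read_two_column_map(config.symbol_map_path)
        candidates = (
            set(read_two_column_map(config.candidate_path))
            if config.candidate_path
            else set()
        )
        result.hits = _stage("gwas overlap")(
            gwas_overlap.match_interactome,
            complete,  # deliberately the complete interactome, not the filtered set
            snps,
            genes,
            symbol_map,
            candidates,
            {s.protein: s for s in summaries},
            config.window_bp,
        )
    else:
        result.skipped.append("gwas overlap: no locus inputs")

    _write_reports(config, result, out)
    return result


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def _write_reports(config: RunConfig, result: RunResult, out: Path) -> None:
    with open(out / "provenance.tsv", "w") as handle:
        handle.write("source\tstage\tcount\n")
        for src in ("intact", "biogrid"):
            for stage in curation.STAGES:
                handle.write(f"{src}\t{stage}\t{result.curated[src].provenance[stage]}\n")
            handle.write(f"{src}\thetero\t{len(result.hetero[src].records)}\n")
            handle.write(f"{src}\thomo\t{len(result.homo[src].records)}\n")
        handle.write(f"merged\thetero\t{len(result.merged_hetero.records)}\n")
        handle.write(f"merged\thetero_publications\t{len(result.merged_hetero.publications)}\n")
        handle.write(f"merged\thomo\t{len(result.merged_homo.records)}\n")
        handle.write(f"merged\tcomplete_interactome\t{len(result.complete)}\n")
        handle.write(f"merged\tfiltered_interactome\t{len(result.filtered)}\n")

    write_mitab(result.merged_hetero.records, out / "merged_hetero.mitab.tsv")
    write_edge_list(result.merged_hetero.records, config.query, out / "interactome.sif")

    with open(out / "interactors.tsv", "w") as handle:
        handle.write("protein\tA\tP\tmethods\ttier\tHTP\tflagged\n")
        for s in result.summaries:
            handle.write(
                f"{s.protein}\t{s.n_annotations}\t{s.n_publications}\t"
                f"{','.join(s.methods)}\t{s.tier}\t{'+' if s.htp else '-'}\t"
                f"{'*' if s.flagged_uncovered else ''}\n"
            )

    if result.families is not None:
        with open(out / "families.tsv", "w") as handle:
            handle.write("family\tmembers\tP\tindependent\n")
            for fam in result.families:
                handle.write(
                    f"{fam.family_name}\t{','.join(fam.members)}\t"
                    f"{fam.n_publications}\t{fam.independent}\n"
                )

    if result.enrichment_results is not None:
        with open(out / "enrichment.tsv", "w") as handle:
            handle.write("term_id\tname\tref_count\tstudy_count\tp_raw\tp_adj\tcontributors\n")
            for r in result.enrichment_results:
                handle.write(
                    f"{r.term_id}\t{r.term_name}\t{r.ref_count}\t{r.study_count}\t"
                    f"{r.p_raw:.6g}\t{r.p_adj:.6g}\t{','.join(sorted(r.contributors))}\n"
                )
    if result.matrix is not None:
        result.matrix.matrix.round(6).to_csv(out / "intersection_matrix.tsv", sep="\t")
        result.matrix.last_row.round(6).to_csv(out / "group_share.tsv", sep="\t", header=["percent"])
    if result.composition is not None:
        with open(out / "significance_composition.tsv", "w") as handle:
            handle.write("level\tgroup\tcount\tpercent\n")
            for level in sorted(result.composition.counts, reverse=True):
                pct = result.composition.percentages(level)
                for group in sorted(pct):
                    handle.write(
                        f"{level}\t{group}\t{result.composition.counts[level][group]}\t"
                        f"{pct[group]:.6g}\n"
                    )

    if result.profile is not None:
        with open(out / "self_profile.tsv", "w") as handle:
            handle.write("residue\tcoverage\n")
            for i, value in enumerate(result.profile.coverage, start=1):
                handle.write(f"{i}\t{int(value)}\n")
        with open(out / "self_points.tsv", "w") as handle:
            handle.write("residue\tpublications\n")
            for residue in sorted(result.profile.point_residues):
                handle.write(f"{residue}\t{result.profile.point_residues[residue]}\n")

    if result.hits is not None:
        with open(out / "gwas_hits.tsv", "w") as handle:
            handle.write("protein\tgene\ttrait\tsnp\tdistance_kbp\tcandidate\tHTP\n")
            for hit in result.hits:
                handle.write(
                    f"{hit.interactor}\t{hit.gene_symbol}\t{hit.snp.trait}\t"
                    f"{hit.snp.rsid}\t{hit.distance_kbp:g}\t"
                    f"{'Yes' if hit.candidate else 'No'}\t{'+' if hit.htp else '-'}\n"
                )


def config_from_bundle(
    bundle: dict[str, Path],
    out_dir: str | Path,
    query: str = "Q5S007",
    mode: str = "threshold",
    protein_length: int = 2527,
    **overrides: Any,
) -> RunConfig:
    """Build a :class:`RunConfig` for a synthetic input bundle."""
    kwargs: dict[str, Any] = dict(
        query=query,
        intact_path=bundle["intact"],
        biogrid_path=bundle["biogrid"],
        out_dir=Path(out_dir),
        obo_path=bundle.get("obo"),
        gaf_path=bundle.get("gaf"),
        grouping_path=bundle.get("grouping"),
        bed_path=bundle.get("genes_bed"),
        snp_path=bundle.get("snps"),
        symbol_map_path=bundle.get("symbol_map"),
        candidate_path=bundle.get("candidates"),
        family_map_path=bundle.get("family_map"),
        pub_group_path=bundle.get("pub_groups"),
        mode=mode,
        protein_length=protein_length,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


__all__ = ["PipelineError", "RunConfig", "RunResult", "run_all", "config_from_bundle"]
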