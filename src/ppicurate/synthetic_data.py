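"""Seeded generators for every pipeline input, with planted ground truth.

The generator emulates the real study conditions at desk scale: two
partially overlapping curated interaction snapshots for one query
protein (with within-publication duplicates, spoke-expanded rows,
non-human and chemical interactors, and region-annotated
self-interaction records), an ontology plus gene annotations with a
few strongly enriched terms planted into the study set, and a genome
of gene intervals with SNPs placed at known distances from chosen
interactors.

Every quantity the pipeline later computes — per-stage filter counts,
the heterologous/homologous split, the occurrence-tier histogram, the
filtered-set membership, the threshold-mode enriched terms, the
locus-overlap hits and the self-interaction profile at probe residues
— is known by construction and serialized as a machine-readable
:class:`PlantedTruth` sidecar.

The same seed yields a byte-identical file bundle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    CHEMICAL,
    SPOKE_EXPANSION,
    UNSPECIFIED_HOST,
    GeneInterval,
    InteractionRecord,
    SnpLocus,
    write_biogrid_tab2,
    write_gene_bed,
    write_mitab,
    write_snp_table,
)

_HARMONIZED_METHODS = [
    "Affinity Capture",
    "Biochemical Activity",
    "Co-localization",
    "Reconstituted Complex",
    "Two Hybrid",
    "Protein Array",
]

#: source vocabularies realizing each harmonized category
_INTACT_VOCAB = {
    "Affinity Capture": ["pull down", "anti tag coimmunoprecipitation", "coimmunoprecipitation"],
    "Biochemical Activity": ["protein kinase assay"],
    "Co-localization": ["confocal microscopy", "fluorescence microscopy"],
    "Reconstituted Complex": ["surface plasmon resonance"],
    "Two Hybrid": ["two hybrid"],
    "Protein Array": ["protein array"],
}
_BIOGRID_VOCAB = {
    "Affinity Capture": ["Affinity Capture-Western", "Affinity Capture-MS"],
    "Biochemical Activity": ["Biochemical Activity"],
    "Co-localization": ["Co-localization"],
    "Reconstituted Complex": ["Reconstituted Complex"],
    "Two Hybrid": ["Two Hybrid"],
    "Protein Array": ["Protein Array"],
}

_HOSTS = [
    "taxid:9606(human-293t)",
    "taxid:9606(human-sh-sy5y)",
    "taxid:10090(mouse embryo)",
    "taxid:-1(in vitro)",
]


class UnachievableSpecError(ValueError):
    """The requested fixture cannot be constructed consistently."""


@dataclass
class FixtureSpec:
    """Generator configuration; defaults mirror the study conditions at
    roughly one-tenth scale (publication overlap ~50% of the smaller
    source, ~77% of interactors as singletons, ~23% filtered)."""

    seed: int = 0
    query: str = "Q5S007"
    n_publications_intact: int = 11
    n_publications_biogrid: int = 10
    shared_publication_fraction: float = 0.5
    tier_composition: dict[str, int] = field(
        default_factory=lambda: {"low": 26, "medium_low": 3, "medium_high": 2, "high": 3}
    )
    n_spoke: dict[str, int] = field(default_factory=lambda: {"intact": 6, "biogrid": 0})
    n_nonhuman: dict[str, int] = field(default_factory=lambda: {"intact": 4, "biogrid": 2})
    n_chemical: dict[str, int] = field(default_factory=lambda: {"intact": 2, "biogrid": 0})
    n_duplicates: dict[str, int] = field(default_factory=lambda: {"intact": 6, "biogrid": 2})
    n_self_publications: dict[str, int] = field(
        default_factory=lambda: {"intact": 4, "biogrid": 3}
    )
    n_point_residues: int = 2
    protein_length: int = 2527
    # enrichment inputs
    n_background_terms: int = 30
    n_planted_terms: int = 3
    background_rate: float = 0.05
    planted_study_fraction: float = 0.8
    n_reference_genes: int = 1000
    min_genes: int = 2
    p_threshold: float = 1e-7
    # GWAS inputs
    n_snps: int = 8
    planted_distances_kbp: list[float] = field(
        default_factory=lambda: [0.0, 20.0, 50.0, 150.0]
    )
    n_decoy_genes: int = 20
    window_bp: int = 200_000
    probe_residues: list[int] | None = None


@dataclass
class PlantedTruth:
    """Every pipeline output the fixture determines by construction."""

    counts: dict[str, dict[str, int]]
    merged_hetero_annotations: int
    merged_publications: int
    merged_homo_annotations: int
    tier_map: dict[str, str]
    tier_histogram: dict[str, int]
    filtered_interactome: list[str]
    complete_interactome: list[str]
    enriched_terms: list[str]
    overlap_hits: list[dict]
    profile_probe_coverage: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


def _exact_tail(N: int, K: int, n: int, k: int) -> float:
    # achievability bound for the planted terms; plain tail sum
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return num / math.comb(N, n)


def _validate(spec: FixtureSpec, n_study: int) -> None:
    for name in ("n_spoke", "n_nonhuman", "n_chemical", "n_duplicates", "n_self_publications"):
        values = getattr(spec, name)
        if any(v < 0 for v in values.values()):
            raise UnachievableSpecError(f"{name} must be non-negative")
    if any(v < 0 for v in spec.tier_composition.values()):
        raise UnachievableSpecError("tier counts must be non-negative")
    if spec.n_spoke.get("biogrid", 0):
        raise UnachievableSpecError("TAB 2.0 has no expansion column; spoke rows must be intact")
    n_shared = round(
        spec.shared_publication_fraction
        * min(spec.n_publications_intact, spec.n_publications_biogrid)
    )
    if n_shared > min(spec.n_publications_intact, spec.n_publications_biogrid):
        raise UnachievableSpecError("shared publications exceed a source's publication count")
    n_hetero_pubs = spec.n_publications_intact + spec.n_publications_biogrid - n_shared
    needs_two_pubs = spec.tier_composition.get("medium_high", 0) + spec.tier_composition.get(
        "high", 0
    )
    if needs_two_pubs and n_hetero_pubs < 2:
        raise UnachievableSpecError("tiers needing two publications but fewer than 2 exist")
    if sum(spec.tier_composition.values()) == 0:
        raise UnachievableSpecError("empty tier composition")
    if sum(spec.tier_composition.values()) + 50 > spec.n_reference_genes:
        raise UnachievableSpecError("reference universe too small for the interactome")
    if spec.n_planted_terms:
        if n_study < max(3, spec.min_genes + 1):
            raise UnachievableSpecError(
                "planted enrichment requires a filtered interactome of >= 3 proteins"
            )
        k = max(spec.min_genes, round(spec.planted_study_fraction * n_study))
        K = k + max(1, round(0.2 * spec.background_rate * spec.n_reference_genes))
        p = _exact_tail(spec.n_reference_genes, K, n_study, k)
        if (spec.n_planted_terms + 1) * p >= spec.p_threshold / 10:
            raise UnachievableSpecError(
                f"planted effect too weak: bound {(spec.n_planted_terms + 1) * p:.3g} "
                f"not safely below threshold {spec.p_threshold:g}"
            )
    if len(spec.planted_distances_kbp) > spec.n_snps:
        raise UnachievableSpecError("more planted hits than SNPs")
    if any(d * 1000 > spec.window_bp for d in spec.planted_distances_kbp):
        raise UnachievableSpecError("planted distance outside the overlap window")
    if len(spec.planted_distances_kbp) > sum(spec.tier_composition.values()):
        raise UnachievableSpecError("more planted hits than interactors")


def generate(spec: FixtureSpec, out_dir: str | Path) -> tuple[dict[str, Path], PlantedTruth]:
    """Write the full input bundle under ``out_dir``; return paths and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    tiers = {t: spec.tier_composition.get(t, 0) for t in ("low", "medium_low", "medium_high", "high")}
    partners = [f"P{i:05d}" for i in range(1, sum(tiers.values()) + 1)]
    tier_map: dict[str, str] = {}
    idx = 0
    for tier, count in tiers.items():
        for _ in range(count):
            tier_map[partners[idx]] = tier
            idx += 1
    study = sorted(p for p, t in tier_map.items() if t != "low")
    _validate(spec, len(study))

    # ----- publications ---------------------------------------------------
    n_shared = round(
        spec.shared_publication_fraction
        * min(spec.n_publications_intact, spec.n_publications_biogrid)
    )
    next_pub = 1_000_001

    def take_pubs(n: int) -> list[str]:
        nonlocal next_pub
        pubs = [str(next_pub + i) for i in range(n)]
        next_pub += n
        return pubs

    shared_pubs = take_pubs(n_shared)
    intact_only = take_pubs(spec.n_publications_intact - n_shared)
    biogrid_only = take_pubs(spec.n_publications_biogrid - n_shared)
    hetero_pubs = shared_pubs + intact_only + biogrid_only
    pub_origin = {p: "shared" for p in shared_pubs}
    pub_origin.update({p: "intact" for p in intact_only})
    pub_origin.update({p: "biogrid" for p in biogrid_only})

    # ----- heterologous design (the intended merged dataset) -------------
    design: dict[str, list[tuple[str, str]]] = {p: [] for p in hetero_pubs}

    def pick_pubs(n: int) -> list[str]:
        return [hetero_pubs[i] for i in sorted(rng.choice(len(hetero_pubs), n, replace=False))]

    def pick_methods(n: int) -> list[str]:
        return [
            _HARMONIZED_METHODS[i]
            for i in rng.choice(len(_HARMONIZED_METHODS), n, replace=False)
        ]

    for partner in partners:
        tier = tier_map[partner]
        if tier == "low":
            design[pick_pubs(1)[0]].append((partner, pick_methods(1)[0]))
        elif tier == "medium_low":
            pub = pick_pubs(1)[0]
            for method in pick_methods(2):
                design[pub].append((partner, method))
        elif tier == "medium_high":
            method = pick_methods(1)[0]
            for pub in pick_pubs(2):
                design[pub].append((partner, method))
        else:  # high
            pubs2, methods2 = pick_pubs(2), pick_methods(2)
            design[pubs2[0]].append((partner, methods2[0]))
            design[pubs2[1]].append((partner, methods2[1]))

    merged_hetero = sum(len(v) for v in design.values())
    merged_pubs = sum(1 for v in design.values() if v)

    # ----- self-interaction design ----------------------------------------
    self_design: dict[str, dict] = {}
    for src in ("intact", "biogrid"):
        for pub in take_pubs(spec.n_self_publications[src]):
            n_ann = int(rng.integers(1, 3))
            regions = []
            if src == "intact":
                for _ in range(n_ann):
                    length = int(rng.integers(100, 601))
                    start = int(rng.integers(1, spec.protein_length - length))
                    regions.append((start, start + length))
            self_design[pub] = {"source": src, "n_annotations": n_ann, "regions": regions}
    # single-residue annotations ride on the first intact self publication
    point_pubs = [p for p, d in self_design.items() if d["source"] == "intact"]
    point_residues: list[tuple[str, int]] = []
    if spec.n_point_residues and point_pubs:
        for _ in range(spec.n_point_residues):
            pub = point_pubs[int(rng.integers(0, len(point_pubs)))]
            residue = int(rng.integers(1, spec.protein_length + 1))
            point_residues.append((pub, residue))
            self_design[pub]["n_annotations"] += 1

    merged_homo = sum(d["n_annotations"] for d in self_design.values())

    # ----- emit per-source rows -------------------------------------------
    def intact_row(partner, pub, harm, regions=(), expansion="", taxid_b=9606, raw_b=None):
        vocab = _INTACT_VOCAB[harm]
        return InteractionRecord(
            interactor_a=spec.query,
            interactor_b=partner,
            raw_id_a=spec.query,
            raw_id_b=raw_b or partner,
            taxid_a=9606,
            taxid_b=taxid_b,
            detection_method=vocab[int(rng.integers(0, len(vocab)))],
            publication_id=pub,
            first_author=f"author-{pub}",
            source_db="intact",
            host_organism=_HOSTS[int(rng.integers(0, len(_HOSTS)))],
            expansion=expansion,
            regions=list(regions),
        )

    def biogrid_row(partner, pub, harm, taxid_b=9606, htp=False):
        vocab = _BIOGRID_VOCAB[harm]
        return InteractionRecord(
            interactor_a=spec.query,
            interactor_b=partner,
            raw_id_a=spec.query,
            raw_id_b=partner,
            taxid_a=9606,
            taxid_b=taxid_b,
            detection_method=vocab[int(rng.integers(0, len(vocab)))],
            publication_id=pub,
            first_author=f"author-{pub}",
            source_db="biogrid",
            host_organism=UNSPECIFIED_HOST,
            throughput="high" if htp else "low",
        )

    rows: dict[str, list[InteractionRecord]] = {"intact": [], "biogrid": []}
    clean_counts = {"intact": {"hetero": 0, "homo": 0}, "biogrid": {"hetero": 0, "homo": 0}}
    htp_pubs = {p for p in hetero_pubs if rng.random() < 0.3}

    for pub in hetero_pubs:
        anns = design[pub]
        if not anns:
            continue
        origin = pub_origin[pub]
        if origin in {"shared", "intact"}:
            for partner, harm in anns:
                rows["intact"].append(intact_row(partner, pub, harm))
            clean_counts["intact"]["hetero"] += len(anns)
        if origin in {"shared", "biogrid"}:
            emit = anns
            if origin == "shared" and len(anns) >= 2 and rng.random() < 0.5:
                emit = anns[:-1]  # source with fewer annotations loses wholesale
            for partner, harm in emit:
                rows["biogrid"].append(biogrid_row(partner, pub, harm, htp=pub in htp_pubs))
            clean_counts["biogrid"]["hetero"] += len(emit)

    for pub in sorted(self_design):
        info = self_design[pub]
        harm_pool = ["Affinity Capture", "Biochemical Activity"]
        pub_points = [r for p, r in point_residues if p == pub]
        if info["source"] == "intact":
            region_sets = [[r] for r in info["regions"]] + [[(r, r)] for r in pub_points]
            for regs in region_sets:
                rows["intact"].append(
                    intact_row(spec.query, pub, harm_pool[int(rng.integers(0, 2))], regions=regs)
                )
            clean_counts["intact"]["homo"] += len(region_sets)
        else:
            for _ in range(info["n_annotations"]):
                rows["biogrid"].append(
                    biogrid_row(spec.query, pub, harm_pool[int(rng.integers(0, 2))])
                )
            clean_counts["biogrid"]["homo"] += info["n_annotations"]

    # within-publication duplicate classes in a self publication would collapse
    # annotations the design counts separately; give each self annotation in one
    # publication a distinct method/host combination
    # (handled by construction above: intact self rows draw random hosts, and a
    # collision would break planted counts -> deduplicate proactively)
    def _fix_self_collisions() -> None:
        for src in ("intact", "biogrid"):
            seen: set[tuple] = set()
            for rec in rows[src]:
                key = (
                    rec.publication_id,
                    rec.unordered_pair(),
                    rec.detection_method,
                    rec.host_organism,
                )
                while key in seen:
                    if src == "intact":
                        rec.host_organism = _HOSTS[int(rng.integers(0, len(_HOSTS)))]
                        vocab = [m for c in _INTACT_VOCAB.values() for m in c]
                        rec.detection_method = vocab[int(rng.integers(0, len(vocab)))]
                    else:
                        vocab = [m for c in _BIOGRID_VOCAB.values() for m in c]
                        rec.detection_method = vocab[int(rng.integers(0, len(vocab)))]
                    key = (
                        rec.publication_id,
                        rec.unordered_pair(),
                        rec.detection_method,
                        rec.host_organism,
                    )
                seen.add(key)

    _fix_self_collisions()

    truth_counts: dict[str, dict[str, int]] = {}
    for src in ("intact", "biogrid"):
        clean = list(rows[src])
        n_clean = len(clean)
        if spec.n_duplicates[src] and not clean:
            raise UnachievableSpecError(f"{src}: duplicates requested but no clean rows")
        fodder: list[InteractionRecord] = []
        for i in range(spec.n_spoke[src]):
            fodder.append(
                intact_row(f"PS{i:04d}", hetero_pubs[int(rng.integers(0, len(hetero_pubs)))],
                           "Affinity Capture", expansion=SPOKE_EXPANSION)
            )
        for i in range(spec.n_nonhuman[src]):
            pub = hetero_pubs[int(rng.integers(0, len(hetero_pubs)))]
            if src == "intact":
                fodder.append(intact_row(f"PN{i:04d}", pub, "Affinity Capture", taxid_b=10090))
            else:
                fodder.append(biogrid_row(f"PN{i:04d}", pub, "Affinity Capture", taxid_b=10090))
        for i in range(spec.n_chemical[src]):
            pub = hetero_pubs[int(rng.integers(0, len(hetero_pubs)))]
            if src == "intact":
                fodder.append(
                    intact_row(f"CHEBI:{15000 + i}", pub, "Biochemical Activity",
                               taxid_b=CHEMICAL, raw_b=f"CHEBI:{15000 + i}")
                )
            else:
                fodder.append(
                    biogrid_row(f"CHEBI:{15000 + i}", pub, "Biochemical Activity",
                                taxid_b=CHEMICAL)
                )
        for _ in range(spec.n_duplicates[src]):
            base = clean[int(rng.integers(0, n_clean))]
            dup = dataclasses.replace(
                base,
                interactor_a=base.interactor_b,
                interactor_b=base.interactor_a,
                raw_id_a=base.raw_id_b,
                raw_id_b=base.raw_id_a,
                taxid_a=base.taxid_b,
                taxid_b=base.taxid_a,
                regions=list(base.regions),
            )
            fodder.append(dup)
        all_rows = clean + fodder
        order = rng.permutation(len(all_rows))
        rows[src] = [all_rows[i] for i in order]
        raw = len(all_rows)
        truth_counts[src] = {
            "raw": raw,
            "post_spoke": raw - spec.n_spoke[src],
            "post_filter1": raw - spec.n_spoke[src] - spec.n_nonhuman[src] - spec.n_chemical[src],
            "post_filter2": n_clean,
            "hetero": clean_counts[src]["hetero"],
            "homo": clean_counts[src]["homo"],
        }

    # ----- ontology + annotations -----------------------------------------
    root = "GO:0000001"
    chain_mid, chain_leaf = "GO:0000002", "GO:0000003"
    background_terms = [f"GO:{100000 + i:07d}" for i in range(1, spec.n_background_terms + 1)]
    planted_terms = [f"GO:{200000 + i:07d}" for i in range(1, spec.n_planted_terms + 1)]

    fillers = [f"G{i:05d}" for i in range(1, spec.n_reference_genes - len(partners) + 1)]
    reference = sorted(partners) + fillers
    non_study = sorted(set(reference) - set(study))

    gaf_rows: list[tuple[str, str]] = [(g, root) for g in reference]
    k_background = max(1, round(spec.background_rate * spec.n_reference_genes))
    for term in background_terms:
        chosen = rng.choice(len(non_study), k_background, replace=False)
        gaf_rows.extend((non_study[i], term) for i in sorted(chosen))
    k_study = max(spec.min_genes, round(spec.planted_study_fraction * len(study))) if study else 0
    k_extra = max(1, round(0.2 * spec.background_rate * spec.n_reference_genes))
    for term in planted_terms:
        chosen_s = rng.choice(len(study), k_study, replace=False)
        chosen_b = rng.choice(len(non_study), k_extra, replace=False)
        gaf_rows.extend((study[i], term) for i in sorted(chosen_s))
        gaf_rows.extend((non_study[i], term) for i in sorted(chosen_b))
    # a short is_a/part_of chain exercised by propagation, kept under min_genes
    chain_genes = ([study[0]] if study else []) + fillers[:5]
    gaf_rows.extend((g, chain_leaf) for g in chain_genes)

    obo_path = out / "ontology.obo"
    _write_obo(obo_path, root, chain_mid, chain_leaf, background_terms + planted_terms)
    gaf_path = out / "annotations.gaf"
    _write_gaf(gaf_path, gaf_rows)

    # ----- GWAS layout ------------------------------------------------------
    symbol_map = {p: f"GN{p}" for p in partners}
    candidate_hits = spec.planted_distances_kbp[: max(1, len(spec.planted_distances_kbp) // 2)]
    hit_partner_idx = rng.choice(len(partners), len(spec.planted_distances_kbp), replace=False)
    hit_partners = [sorted(partners)[i] for i in sorted(hit_partner_idx)]

    genes: list[GeneInterval] = []
    snps: list[SnpLocus] = []
    overlap_truth: list[dict] = []
    candidates: list[str] = []
    for b in range(spec.n_snps):
        chrom = str((b % 5) + 1)
        base = 10_000_000 + (b // 5) * 5_000_000
        pos = base + 1_000_000
        trait = "PD" if b % 2 == 0 else "IBD"
        rsid = f"rs{770000 + b}"
        snps.append(SnpLocus(rsid=rsid, chromosome=chrom, position=pos, trait=trait))
        if b < len(hit_partners):
            partner = hit_partners[b]
            d_bp = int(spec.planted_distances_kbp[b] * 1000)
            length = int(rng.integers(20_000, 80_000))
            if d_bp == 0:
                start = pos - length // 2
            else:
                start = pos + d_bp
            genes.append(
                GeneInterval(symbol_map[partner], chrom, start, start + length, "+")
            )
            is_candidate = len(overlap_truth) < len(candidate_hits)
            if is_candidate:
                candidates.append(symbol_map[partner])
            overlap_truth.append(
                {
                    "interactor": partner,
                    "gene_symbol": symbol_map[partner],
                    "rsid": rsid,
                    "trait": trait,
                    "distance_kbp": float(spec.planted_distances_kbp[b]),
                    "candidate": is_candidate,
                }
            )
        # decoy genes near the SNP, never in the interactome
        n_local_decoys = spec.n_decoy_genes // spec.n_snps
        for j in range(n_local_decoys):
            off = int(rng.integers(10_000, 150_000))
            length = int(rng.integers(5_000, 30_000))
            genes.append(GeneInterval(f"DEC{b:02d}{j:02d}", chrom, pos + off, pos + off + length, "-"))
    # interactome members without planted hits live far from every SNP
    far_partners = [p for p in sorted(partners) if p not in set(hit_partners)]
    for i, partner in enumerate(far_partners):
        chrom = str(6 + (i % 3))
        start = 200_000_000 + i * 1_000_000
        genes.append(GeneInterval(symbol_map[partner], chrom, start, start + 30_000, "+"))
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_symbol))

    # ----- maps --------------------------------------------------------------
    research_groups = [f"RG{i}" for i in range(1, 7)]
    all_pubs = hetero_pubs + sorted(self_design)
    pub_to_group = {
        pub: research_groups[int(rng.integers(0, len(research_groups)))] for pub in all_pubs
    }
    family_map: dict[str, str] = {}
    for i in range(len(study) // 3):
        for member in study[3 * i : 3 * i + 2]:
            family_map[member] = f"FAM{i + 1}"

    # ----- profile truth ------------------------------------------------------
    length = spec.protein_length
    probes = spec.probe_residues or [1, length // 4, length // 2, 3 * length // 4, length]
    probe_coverage: dict[str, int] = {}
    for residue in probes:
        support = 0
        for pub, info in self_design.items():
            if any(s <= residue <= e for s, e in info["regions"]):
                support += 1
        probe_coverage[str(residue)] = support

    # ----- write everything ---------------------------------------------------
    paths = {
        "intact": out / "intact.mitab27.tsv",
        "biogrid": out / "biogrid.tab2.tsv",
        "obo": obo_path,
        "gaf": gaf_path,
        "genes_bed": out / "genes.bed",
        "snps": out / "snps.tsv",
        "symbol_map": out / "symbol_map.tsv",
        "candidates": out / "gwas_candidates.tsv",
        "family_map": out / "family_map.tsv",
        "pub_groups": out / "publication_groups.tsv",
        "grouping": out / "term_groups.tsv",
        "truth": out / "truth.json",
    }
    write_mitab(rows["intact"], paths["intact"])
    write_biogrid_tab2(rows["biogrid"], paths["biogrid"])
    write_gene_bed(genes, paths["genes_bed"])
    write_snp_table(snps, paths["snps"])
    _write_map(paths["symbol_map"], symbol_map)
    _write_map(paths["candidates"], {c: "candidate" for c in sorted(candidates)})
    _write_map(paths["family_map"], family_map)
    _write_map(paths["pub_groups"], pub_to_group)
    grouping = {term: "planted signal" for term in planted_terms}
    grouping.update({term: "background" for term in background_terms})
    grouping.update({root: "general terms", chain_mid: "general terms", chain_leaf: "background"})
    _write_map(paths["grouping"], grouping)

    histogram = {t: sum(1 for v in tier_map.values() if v == t) for t in tiers}
    truth = PlantedTruth(
        counts=truth_counts,
        merged_hetero_annotations=merged_hetero,
        merged_publications=merged_pubs,
        merged_homo_annotations=merged_homo,
        tier_map=dict(sorted(tier_map.items())),
        tier_histogram=histogram,
        filtered_interactome=study,
        complete_interactome=sorted(partners),
        enriched_terms=sorted(planted_terms),
        overlap_hits=sorted(
            overlap_truth, key=lambda h: (h["trait"], h["distance_kbp"], h["rsid"])
        ),
        profile_probe_coverage=probe_coverage,
    )
    truth.to_json(paths["truth"])
    return paths, truth


def _write_obo(path: Path, root: str, chain_mid: str, chain_leaf: str, flat_terms: list[str]) -> None:
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\nontology: synthetic\n")

        def term(term_id: str, name: str, is_a: str | None = None, part_of: str | None = None):
            handle.write(f"\n[Term]\nid: {term_id}\nname: {name}\nnamespace: biological_process\n")
            if is_a:
                handle.write(f"is_a: {is_a} ! parent\n")
            if part_of:
                handle.write(f"relationship: part_of {part_of} ! parent\n")

        term(root, "root process")
        term(chain_mid, "mid-level process", is_a=root)
        term(chain_leaf, "leaf process", part_of=chain_mid)
        for t in flat_terms:
            term(t, f"synthetic process {t[-4:]}", is_a=root)


def _write_gaf(path: Path, gaf_rows: list[tuple[str, str]]) -> None:
    with open(path, "w") as handle:
        handle.write("!gaf-version: 2.1\n")
        for gene, term in gaf_rows:
            fields = [
                "SYNT", gene, gene, "", term, "SYNT:0000001", "IEA", "", "P",
                "", "", "protein", "taxon:9606", "20140801", "SYNT", "", "",
            ]
            handle.write("\t".join(fields) + "\n")


def _write_map(path: Path, mapping: dict[str, str]) -> None:
    with open(path, "w") as handle:
        for key in sorted(mapping):
            handle.write(f"{key}\t{mapping[key]}\n")


__all__ = ["FixtureSpec", "PlantedTruth", "UnachievableSpecError", "generate"]
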