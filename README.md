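# ppicurate

Curation and analysis of a single protein's interactome from curated
protein–protein interaction (PPI) database snapshots.

Public PPI repositories annotate the same literature differently: they
expand co-complexes into binary pairs, record bait/prey swaps and tag
variants as separate rows, mix species and small-molecule partners, and
overlap only partially in the publications they cover. `ppicurate`
turns two such snapshots for one query protein — a PSI-MI TAB 2.7 file
and a BioGRID TAB 2.0 file — into a single audited interactome, ranks
each interactor by the independence of its supporting evidence, runs GO
over-representation on the well-supported core, profiles the residues
involved in self-interaction (dimerization), and intersects the full
interactome with GWAS risk loci. The motivating use case is a disease
hub protein such as LRRK2, whose literature is too large to appraise by
hand.

## What it computes

**Curation.** Per source: spoke-expanded co-complex rows are removed;
only records with both interactors of the allowed taxon (human, 9606)
are kept; within one publication, records with the same unordered
canonical pair, detection method and host organism are collapsed to one
(bait/prey swaps, tag variants). Isoform (`-2`) and fragment
(`-PRO_…`) suffixes are stripped from accessions at parse time. The two
curated sets are merged per publication: exclusive publications are
copied, a shared publication is taken from the source with more
annotations, and ties are resolved by a union re-deduplicated in a
*harmonized* method vocabulary (sources name the same assay
differently).

**Evidence tiers.** Each interactor is ranked by annotation count *A*,
distinct publications *P* and distinct harmonized methods *M*:

| tier | rule |
|---|---|
| low | A = 1 |
| medium-low | P = 1, A ≥ 2 |
| medium-high | P ≥ 2, M = 1 |
| high | P ≥ 2, M ≥ 2 |

Interactors with A ≥ 2 form the *filtered* interactome (used for
enrichment); everything forms the *complete* interactome (used for the
GWAS comparison).

**Enrichment.** Over-representation of a term with `K` of `N` reference
genes annotated, and `k` of the `n` study genes, uses the exact
hypergeometric upper tail

&nbsp;&nbsp;&nbsp;&nbsp;p = Σ<sub>j≥k</sub> C(K, j) · C(N−K, n−j) / C(N, n)

with Bonferroni adjustment `p_adj = min(1, m·p)` over the `m` tested
terms, annotations propagated up the ontology (true-path rule). Two
selection modes: the ten smallest adjusted p-values, or every term with
`p_adj < 1e-7`. Grouped summaries report per-group contributor sets,
the asymmetric group-intersection percentage matrix, and the per-
significance-level composition `100·g/n` (group contributes `g` of a
level's `n` terms).

**Self-interaction profile.** Per residue, the number of distinct
publications annotating a region that covers it (per-publication union
of fragments); single-residue annotations form a separate point
channel.

**GWAS overlap.** Genes whose interval intersects ±200 kb around a
trait-associated SNP are locus members; the SNP–gene distance is 0
inside the gene, else the distance to the nearer boundary in kb.

A seeded synthetic-data module generates every input format with
planted ground truth (filter counts, tier histogram, enriched terms,
overlap hits, profile coverage), so the whole pipeline is testable
offline.

## Worked example

Generate a synthetic bundle and run the full pipeline:

```sh
ppicurate simulate --seed 1 --out demo/bundle
ppicurate run-all --config demo/run.yaml     # YAML pointing at the bundle
```

which prints

```
complete interactome: 34 proteins
filtered interactome: 8 proteins
merged heterologous annotations: 42
reports written to demo/reports
```

and writes the stage ledger `provenance.tsv`:

```
source   stage          count
intact   raw            57
intact   post_spoke     51
intact   post_filter1   45
intact   post_filter2   39
intact   hetero         30
intact   homo           9
biogrid  raw            34
...
merged   hetero         42
```

57 raw annotations drop to 39 after the three filters (6 spoke-expanded,
6 non-human/chemical, 6 within-publication duplicates); 39 split into 30
partner annotations and 9 self-interactions; merging with the BioGRID
side yields 42 heterologous annotations for 34 distinct interactors, 8
of which are supported by two or more annotations. `gwas_hits.tsv`
lists the planted locus overlaps with their distances:

```
protein  gene      trait  snp       distance_kbp  candidate  HTP
P00020   GNP00020  IBD    rs770001  20            Yes        -
P00030   GNP00030  IBD    rs770003  150           No         -
P00002   GNP00002  PD     rs770000  0             Yes        +
P00025   GNP00025  PD     rs770002  50            No         -
```

Other reports: `interactors.tsv` (per-interactor A/P/methods/tier/HTP),
`enrichment.tsv`, `intersection_matrix.tsv`,
`significance_composition.tsv`, `self_profile.tsv`, `interactome.sif`.

The same analyses are available as library calls
(`ppicurate.curation`, `.evidence`, `.enrichment`, `.self_interaction`,
`.gwas_overlap`) and as the subcommands `curate`, `tiers`, `enrich`,
`profile`, `overlap`, `simulate`.

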