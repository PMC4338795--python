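# Methods

This note documents the models and procedures implemented in
`ppicurate`, the conventions chosen where the problem was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Curation model

An *annotation* is one experimental record: an unordered interactor
pair, a detection method, a host organism and a publication. The
pipeline treats the two database snapshots as noisy, partially
redundant views of the same literature and reduces them in a fixed
order so that stage counts are well defined:

1. **Spoke removal.** Rows flagged with a spoke-expansion method are
   dropped: they are derived from n-member co-complexes and may not
   reflect direct contact with the query.
2. **Taxon filter.** Both interactors must carry the allowed NCBI
   taxon (default 9606). Small-molecule partners are detected by
   identifier namespace (ChEBI/ChEMBL/PubChem) rather than by a
   missing taxid, because curated exports frequently print a host
   taxid even for chemicals; they are removed here.
3. **Within-publication dedup.** Two records are duplicates iff they
   share publication, unordered *canonical* pair, detection method and
   host organism. Canonical accessions have isoform (`-2`) and
   processed-chain (`-PRO_…`) suffixes stripped, so a fragment-vs-
   parent pair collapses. The first record in file order is kept —
   the choice of representative is arbitrary in principle, so a
   deterministic rule is required.

The three filters are idempotent, and spoke/taxon commute; this is
property-tested. BioGRID TAB 2.0 has no host-organism column, so all
its records carry one `unspecified` sentinel and the dedup key for that
source degenerates to (publication, pair, method).

### Merge

Heterologous (query–partner) and homologous (query–query) annotations
are merged separately, per publication. A publication annotated by one
source is copied verbatim. When both sources annotated it, the source
with more annotations is selected wholesale — the larger record is
assumed to be the more complete curation of the same experiments. On a
tie, the union of both records is re-deduplicated with the harmonized
method vocabulary substituted for the raw one, which collapses
same-assay pairs such as *Protein Kinase Assay* vs *Biochemical
Activity*. The host organism is excluded from this cross-source key:
one source never reports it, so a host-inclusive key could not collapse
anything across sources and the tie rule would be vacuous. The
harmonization map ships with defaults covering the common
immunoprecipitation / kinase-assay / microscopy / reconstitution
vocabularies and must be total on the input (an unmapped method is an
error, not a silent passthrough).

## Occurrence tiers

Evidence for an interactor is summarized as annotation count *A*,
distinct publications *P* and distinct harmonized methods *M*
(harmonized, because raw vocabularies would count the same assay twice
across sources). The ranking is: `low` iff A = 1; `high` iff P ≥ 2 and
M ≥ 2; `medium_high` iff P ≥ 2 and M = 1; `medium_low` iff P = 1 and
A ≥ 2. The corner case P = 1, M = 1, A ≥ 2 (possible when only hosts
differ) is not covered by the four published rules; it is ranked
`medium_low` — replication within one publication — and flagged in the
per-interactor report. The ranking is total on valid count triples and
monotone: new evidence from a new publication with a new method never
lowers a tier.

Family grouping is driven entirely by user maps (protein → family,
publication → research group); a family is *independent* when its
members' publications span at least two research groups. No automated
authorship clustering is attempted — operational definitions of
"research group" (e.g., shared last author) belong to the caller.

## Over-representation

The test statistic is the hypergeometric upper tail
P(X ≥ k | N, K, n), computed with exact big-integer combinatorics and
a single correctly-rounded float division; an acceptance test checks
the full N ≤ 60 grid against an independent rational-arithmetic oracle
at 1e-12 relative error. Bonferroni uses m = the number of terms with
at least `min_genes` (default 2) study genes — terms that could not
have been reported are not counted as tests. The reference universe
defaults to all genes in the annotation table; annotations are
propagated over `is_a` and `part_of` (configurable) before testing.
Whether the historical web portals propagated or used a slim is not
reconstructable; propagation is on by default and switchable.

Mode `top10` returns the `top_n` smallest adjusted p-values with
deterministic tie-breaking by (p_adj, p_raw, term id); mode
`threshold` returns all terms with p_adj < 1e-7.

Significance levels bin terms by N = ⌈−log₁₀ p_adj⌉, clamped to the
configured range (default 7–16); p_adj = 0 goes to the top level with a
logged warning. The ceiling convention places a term with
p = 5×10⁻⁸ in level 8; the boundary case p = 10⁻⁷ lands in level 7.
Terms of the distinguished "general terms" group are excluded from the
composition. The intersection matrix is deliberately asymmetric —
entry (row, col) is |P_row ∩ P_col| / |P_row| in percent — and an empty
row group yields missing entries, not zeros.

## Self-interaction profile

Coverage at residue i is the number of distinct publications with at
least one annotated interval covering i; fragments from the same
publication are unioned first, so repeated within-paper mapping does
not inflate the profile. Single-residue annotations (start = end) are
kept in a separate point channel weighted by publication count rather
than folded into interval coverage — they typically represent directed
mutagenesis rather than fragment mapping. A per-annotation counting
mode is available behind a flag for comparison. Only records carrying
region data contribute (in practice one source database reports
regions); a region outside [1, protein length] is an error naming the
offending record. Default protein length is 2527 residues (LRRK2).

## GWAS-locus overlap

Windows are ±200,000 bp around the SNP position, intersected with gene
intervals as closed intervals; distances are reported to the nearer
boundary of the supplied interval (callers deciding between full gene
spans and CDS intervals simply supply the corresponding BED). The
comparison uses the complete interactome, singletons included — locus
evidence is independent of annotation depth, so weakly annotated
interactors are deliberately not excluded. Multiple SNPs near one gene
yield one hit each. BED input is converted from half-open 0-based to
the 1-based inclusive coordinates used internally everywhere.

## Synthetic data

The generator emulates the real inputs at roughly one-tenth scale, and
its defaults are fixed study conditions, not tuning knobs: 11 + 10
publications with half the smaller source shared (the real snapshots
shared ~52% of the smaller source's publications), a tier composition
of 26/3/2/3 (≈77% singletons, ≈23% filtered — matching the published
proportions), per-source planted counts of spoke-expanded, non-human,
chemical and duplicate rows, 4 + 3 self-interaction publications with
regions only on the MI-TAB side, a 1,000-gene reference with ≤5
planted terms annotated to 80% of the study set against a 5%
background rate, and SNPs placed at exact planted distances
(0/20/50/150 kb) in well-separated 5-Mb blocks.

Planted truth is exact by construction: shared publications emit
either equal-count S1-style vocabulary conflicts (exercising the
harmonized-union path) or a strict subset on one side (exercising the
winner-wholesale path), and both resolve to the designed annotation
set. Background ontology terms are annotated only outside the study
set, so with `min_genes` = 2 the threshold mode can return exactly the
planted terms; the generator verifies with an exact tail bound that the
planted effect clears the cut-off and raises `UnachievableSpecError`
otherwise (e.g., too small a study set), before writing any file. The
same seed produces a byte-identical bundle.

What the synthetic tests show: the pipeline's bookkeeping — filters,
merge arithmetic, tier assignment, set memberships, distances,
coverage — is exact. What they do not show: robustness to real-world
curation noise (inconsistent identifiers across sources, partial taxid
fields, method vocabularies outside the harmonization map — the last is
a hard error by design), to annotation-release drift in GO, or to
genome-build differences in locus coordinates.

## Numerical and degenerate-input conventions

- All analysis stages are deterministic; randomness exists only in the
  generator. Reports are byte-identical across reruns.
- Iteration orders are fixed by sorting; no result depends on hash
  order.
- Empty inputs degrade explicitly: an empty filtered interactome skips
  enrichment with a logged reason; an empty study set or an all-empty
  contributor family is an error.
- The acceptance script and the test battery run the full pipeline on
  bundles of ~60–90 interaction rows, 35 ontology terms and a
  1,000-gene reference; the whole suite completes in well under a
  minute on one CPU.

## Known limitations

- No MI-score/confidence filtering; no multi-query network curation.
- The 36-column MI-TAB layout is the default; other dialects (including
  42-column exports) are handled by passing a custom column map, not
  auto-detected.
- Throughput for MI-TAB records is `unknown` unless a method →
  throughput map is supplied; the HTP flag is only as good as that map.
- Enrichment is Bonferroni-only by design; no FDR or permutation
  alternatives.
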