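"""Hypergeometric ORA, propagation, grouping summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from ppicurate.enrichment import (
    TermGrouping,
    contributor_sets,
    enrich,
    hypergeom_upper_tail,
    intersection_matrix,
    propagate_annotations,
    significance_composition,
)
from ppicurate.io_formats import AnnotationTable, OntologyDag

import networkx as nx


def make_dag(edges, terms=None):
    g = nx.MultiDiGraph()
    nodes = terms or sorted({t for e in edges for t in e})
    g.add_nodes_from(nodes)
    for child, parent in edges:
        g.add_edge(child, parent, key="is_a")
    return OntologyDag(graph=g)


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------


def test_hypergeom_worked_examples():
    assert hypergeom_upper_tail(5, 5, 2, 2) == 1.0  # every draw annotated
    assert hypergeom_upper_tail(10, 4, 5, 0) == 1.0  # certain event
    # exact rational tail: sum_{j>=3} C(4,j) C(6,5-j) / C(10,5) = 66/252
    assert hypergeom_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252, rel=1e-14)


def test_hypergeom_invalid_inputs():
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 4, 5, 5)  # k > K
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 4, 3, 4)  # k > n
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 11, 5, 2)  # K > N


def test_hypergeom_against_scipy_cross_check():
    rng = np.random.default_rng(0)
    for _ in range(200):
        N = int(rng.integers(1, 200))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        ours = hypergeom_upper_tail(N, K, n, k)
        scipy_val = stats.hypergeom.sf(k - 1, N, K, n)
        assert ours == pytest.approx(scipy_val, rel=1e-9, abs=1e-12)


def test_hypergeom_monotone_in_k():
    for N, K, n in [(20, 8, 10), (60, 30, 15), (7, 7, 3)]:
        values = [hypergeom_upper_tail(N, K, n, k) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def test_propagation_true_path_rule():
    dag = make_dag([("T", "P"), ("P", "R")])
    table = AnnotationTable({"g1": {"T"}, "g2": {"P"}}, {"g1", "g2", "g3"})
    propagated = propagate_annotations(dag, table)
    assert propagated.annotations["g1"] == {"T", "P", "R"}
    # root's annotation set contains every other term's
    for term in ("T", "P"):
        assert propagated.genes_for_term(term) <= propagated.genes_for_term("R")
    # idempotent
    again = propagate_annotations(dag, propagated)
    assert again.annotations == propagated.annotations


# ---------------------------------------------------------------------------
# the test proper
# ---------------------------------------------------------------------------


def _planted_table(rng, n_ref=600, n_study=60, planted="T0", background_rate=0.10):
    """40 of 60 study genes annotated to the planted term; background terms
    annotated at ~10% of the reference."""
    study = [f"s{i}" for i in range(n_study)]
    fillers = [f"g{i}" for i in range(n_ref - n_study)]
    reference = set(study) | set(fillers)
    annotations = {g: {"ROOT"} for g in reference}
    for gene in study[:40]:
        annotations[gene].add(planted)
    for i in rng.choice(len(fillers), 20, replace=False):
        annotations[fillers[i]].add(planted)
    for t in range(8):
        term = f"B{t}"
        for i in rng.choice(n_ref, int(background_rate * n_ref), replace=False):
            annotations[sorted(reference)[i]].add(term)
    return study, AnnotationTable(annotations, reference)


def test_enrich_planted_term_is_top_hit():
    rng = np.random.default_rng(3)
    study, table = _planted_table(rng)
    results = enrich(study, table, dag=None, mode="top10", propagate=False)
    assert results[0].term_id == "T0"
    # oracle comparison: the planted term has the smallest tail p across terms
    term_genes = {}
    for gene, terms in table.annotations.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N, n = len(table.reference_genes), len(study)
    oracle_p = {
        t: stats.hypergeom.sf(len(genes & set(study)) - 1, N, len(genes), n)
        for t, genes in term_genes.items()
    }
    assert min(oracle_p, key=oracle_p.get) == "T0"
    assert results[0].p_raw == pytest.approx(oracle_p["T0"], rel=1e-9)


def test_enrich_study_equals_reference_gives_p_one():
    table = AnnotationTable(
        {f"g{i}": {"A" if i < 4 else "B", "ROOT"} for i in range(8)},
        {f"g{i}" for i in range(8)},
    )
    results = enrich(table.reference_genes, table, propagate=False, mode="top10")
    assert results and all(r.p_raw == 1.0 for r in results)


def test_enrich_single_tested_term_has_m_one():
    table = AnnotationTable(
        {"a": {"T"}, "b": {"T"}, "c": set(), "d": set()}, {"a", "b", "c", "d"}
    )
    (result,) = enrich(["a", "b"], table, propagate=False, mode="top10")
    assert result.p_adj == result.p_raw


def test_enrich_contracts_and_determinism():
    rng = np.random.default_rng(11)
    study, table = _planted_table(rng)
    results = enrich(study, table, propagate=False, mode="top10")
    for r in results:
        assert r.p_raw <= r.p_adj <= 1.0
    # order invariant under study permutation
    shuffled = list(study)
    rng.shuffle(shuffled)
    assert [r.term_id for r in enrich(shuffled, table, propagate=False, mode="top10")] == [
        r.term_id for r in results
    ]


def test_enrich_drops_out_of_reference_and_rejects_empty():
    table = AnnotationTable({"a": {"T"}, "b": {"T"}}, {"a", "b"})
    results = enrich(["a", "b", "zz"], table, propagate=False, mode="top10")
    assert results[0].study_count == 2
    with pytest.raises(ValueError):
        enrich([], table)


def test_parent_study_count_dominates_child_after_propagation():
    dag = make_dag([("T", "P"), ("P", "R")])
    table = AnnotationTable(
        {"a": {"T"}, "b": {"T"}, "c": {"P"}, "d": {"R"}},
        {"a", "b", "c", "d", "e"},
    )
    results = enrich(["a", "b", "c"], table, dag=dag, mode="top10", min_genes=1)
    counts = {r.term_id: r.study_count for r in results}
    assert counts["P"] >= counts["T"]
    assert counts["R"] >= counts["P"]


# ---------------------------------------------------------------------------
# grouping summaries
# ---------------------------------------------------------------------------


def _result(term, contributors, p_adj, p_raw=None):
    from ppicurate.enrichment import EnrichmentResult

    return EnrichmentResult(
        term_id=term,
        term_name=term,
        ref_count=max(10, len(contributors)),
        study_count=len(contributors),
        p_raw=p_raw if p_raw is not None else p_adj / 2,
        p_adj=p_adj,
        contributors=frozenset(contributors),
    )


def test_contributor_sets_union_and_errors():
    grouping = TermGrouping({"t1": "vesicles", "t2": "vesicles", "t3": "transport"})
    results = [_result("t1", {"a", "b"}, 1e-9), _result("t2", {"b", "c"}, 1e-8)]
    sets = contributor_sets(results, grouping)
    assert sets["vesicles"] == {"a", "b", "c"}
    assert sets["transport"] == frozenset()  # declared group, no enriched terms
    with pytest.raises(KeyError, match="unmapped"):
        contributor_sets([_result("unmapped", {"a", "b"}, 1e-9)], grouping)


def test_intersection_matrix_worked_example():
    m = intersection_matrix({"A": frozenset({"p1", "p2"}), "B": frozenset({"p2"})}, 62)
    assert m.matrix.loc["A", "B"] == 50.0
    assert m.matrix.loc["B", "A"] == 100.0
    assert m.matrix.loc["A", "A"] == 100.0 and m.matrix.loc["B", "B"] == 100.0
    # empty group row is missing, not zero
    m2 = intersection_matrix({"A": frozenset({"p1"}), "E": frozenset()}, 4)
    assert math.isnan(m2.matrix.loc["E", "A"])
    # last row against the full study set: 31 of 62 -> 50%
    m3 = intersection_matrix({"G": frozenset(f"p{i}" for i in range(31))}, 62)
    assert m3.last_row["G"] == 50.0


def test_significance_composition_function():
    grouping = TermGrouping(
        {"t1": "G1", "t2": "G2", "t3": "G2", "t4": "G2", "t5": "general terms"}
    )
    results = [
        _result("t1", {"a", "b"}, 4e-10),  # level 10
        _result("t2", {"a", "b"}, 2e-10),
        _result("t3", {"a", "b"}, 9e-10),
        _result("t4", {"a", "b"}, 1e-10),  # exactly 1e-10 -> level 10
        _result("t5", {"a", "b"}, 1e-10),  # general terms -> excluded
    ]
    comp = significance_composition(results, grouping, level_range=(7, 16))
    assert comp.total(10) == 4
    assert comp.percentages(10) == {"G1": 25.0, "G2": 75.0}
    # a level with one group only -> 100%
    comp2 = significance_composition([_result("t2", {"a"}, 5e-8, p_raw=2e-8)], grouping)
    assert comp2.percentages(8) == {"G2": 100.0}


def test_significance_composition_percentages_sum_to_100():
    rng = np.random.default_rng(5)
    grouping = TermGrouping({f"t{i}": f"G{i % 4}" for i in range(40)})
    results = [
        _result(f"t{i}", {"a"}, float(10.0 ** -rng.uniform(7, 16))) for i in range(40)
    ]
    comp = significance_composition(results, grouping)
    for level in comp.counts:
        assert sum(comp.percentages(level).values()) == pytest.approx(100.0, abs=1e-9)
        # direct re-count oracle
        assert comp.total(level) == sum(comp.counts[level].values())
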