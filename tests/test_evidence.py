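"""Occurrence tiers, interactor summaries and family grouping."""

import pytest

from ppicurate.curation import MethodHarmonizationMap
from ppicurate.evidence import (
    classify_occurrence,
    complete_interactome,
    filtered_interactome,
    group_families,
    summarize_interactors,
    tier_histogram,
)

from .conftest import QUERY, make_record


def occurrence_oracle(n_annotations, n_publications, n_methods):
    """Literal translation of the four ranking rules, independent of the
    implementation's branch structure."""
    if n_annotations == 1:
        return "low"
    if n_publications == 1 and n_methods >= 2:
        return "medium_low"
    if n_publications >= 2 and n_methods == 1:
        return "medium_high"
    if n_publications >= 2 and n_methods >= 2:
        return "high"
    # one publication, one method, several annotations: replication within
    # a publication -> ranked with the other single-publication tier
    return "medium_low"


def test_classify_examples():
    assert classify_occurrence(1, 1, 1) == "low"
    assert classify_occurrence(2, 1, 2) == "medium_low"
    assert classify_occurrence(3, 3, 1) == "medium_high"
    assert classify_occurrence(2, 2, 2) == "high"


def test_classify_matches_oracle_on_grid():
    for pubs in range(1, 4):
        for methods in range(1, 4):
            for ann in range(max(pubs, methods), 7):
                assert classify_occurrence(ann, pubs, methods) == occurrence_oracle(
                    ann, pubs, methods
                )


def test_classify_rejects_invalid_counts():
    with pytest.raises(ValueError):
        classify_occurrence(0, 1, 1)
    with pytest.raises(ValueError):
        classify_occurrence(1, 2, 1)  # more publications than annotations


def test_tier_monotone_under_new_independent_evidence():
    """Adding an annotation from a new publication with a new method never
    lowers a tier (no transition into low; high stays high)."""
    rank = {"low": 0, "medium_low": 1, "medium_high": 1, "high": 2}
    for pubs in range(1, 4):
        for methods in range(1, 4):
            for ann in range(max(pubs, methods), 6):
                before = classify_occurrence(ann, pubs, methods)
                after = classify_occurrence(ann + 1, pubs + 1, methods + 1)
                assert rank[after] >= rank[before]
                assert after != "low"
                if before == "high":
                    assert after == "high"


def test_summarize_interactors_counts():
    records = [
        make_record(b="P1", pub="100", method="pull down"),
        make_record(b="P1", pub="100", method="protein kinase assay"),
        # SNCA-like partner: 6 annotations across 2 publications
        *[make_record(b="P2", pub="200", method=m)
          for m in ("pull down", "confocal microscopy", "protein kinase assay", "two hybrid")],
        make_record(b="P2", pub="201", method="pull down"),
        make_record(b="P2", pub="201", method="two hybrid"),
    ]
    summaries = summarize_interactors(records, MethodHarmonizationMap(), QUERY)
    by_protein = {s.protein: s for s in summaries}
    assert (by_protein["P1"].n_annotations, by_protein["P1"].n_publications,
            by_protein["P1"].n_methods) == (2, 1, 2)
    assert (by_protein["P2"].n_annotations, by_protein["P2"].n_publications) == (6, 2)
    # conservation: annotations distribute over partners
    assert sum(s.n_annotations for s in summaries) == len(records)


def test_summarize_flags_uncovered_case_and_htp():
    records = [
        make_record(b="P1", pub="100", method="pull down", host="taxid:9606(hela)"),
        make_record(b="P1", pub="100", method="pull down", host="taxid:-1(in vitro)",
                    throughput="high"),
    ]
    (summary,) = summarize_interactors(records, MethodHarmonizationMap(), QUERY)
    assert summary.tier == "medium_low"
    assert summary.flagged_uncovered
    assert summary.htp


def test_filtered_interactome_partition():
    records = (
        [make_record(b=f"L{i}", pub=str(100 + i)) for i in range(3)]  # singletons
        + [make_record(b="H1", pub="200", method="pull down"),
           make_record(b="H1", pub="201", method="two hybrid"),
           make_record(b="H2", pub="202", method="pull down"),
           make_record(b="H2", pub="203", method="two hybrid")]
    )
    summaries = summarize_interactors(records, MethodHarmonizationMap(), QUERY)
    filtered = filtered_interactome(summaries)
    hist = tier_histogram(summaries)
    assert filtered == {"H1", "H2"}
    assert len(filtered) + hist["low"] == len(complete_interactome(summaries))
    assert filtered_interactome([]) == set()


def test_group_families_independence():
    records = [
        make_record(b="F1", pub="100", method="pull down"),
        make_record(b="F1", pub="101", method="two hybrid"),
        make_record(b="F2", pub="102", method="pull down"),
        make_record(b="F2", pub="103", method="two hybrid"),
        make_record(b="U1", pub="104", method="pull down"),
        make_record(b="U1", pub="104", method="two hybrid"),
    ]
    summaries = summarize_interactors(records, MethodHarmonizationMap(), QUERY)
    family_map = {"F1": "tubulin", "F2": "tubulin"}
    # two distinct research groups -> independent
    groups, unassigned = group_families(
        summaries, family_map,
        {"100": "G1", "101": "G1", "102": "G2", "103": "G2", "104": "G1"},
    )
    assert groups[0].independent and groups[0].members == ("F1", "F2")
    assert unassigned == ["U1"]
    # all publications from one research group -> non-independent
    groups, _ = group_families(
        summaries, family_map, {p: "G1" for p in ("100", "101", "102", "103", "104")}
    )
    assert not groups[0].independent
    # missing publication in the research-group map is an error
    with pytest.raises(KeyError, match="101"):
        group_families(summaries, family_map, {"100": "G1"})
    # empty family map: no groups, everything unassigned
    groups, unassigned = group_families(summaries, {}, {})
    assert groups == [] and len(unassigned) == 3
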