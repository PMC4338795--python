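"""Filters, within-publication dedup and the cross-database merge."""

import numpy as np
import pytest

from ppicurate.curation import (
    CuratedDataset,
    MethodHarmonizationMap,
    HarmonizationError,
    curate,
    dedup_within_publication,
    filter_taxid,
    merge_datasets,
    remove_spoke_expanded,
    split_homo_hetero,
)
from ppicurate.io_formats import CHEMICAL

from .conftest import QUERY, make_record, random_records


def dedup_oracle_classes(records):
    """O(n^2) pairwise equivalence-class construction (independent oracle)."""

    def duplicated(r1, r2):
        return (
            r1.publication_id == r2.publication_id
            and r1.unordered_pair() == r2.unordered_pair()
            and r1.detection_method == r2.detection_method
            and r1.host_organism == r2.host_organism
        )

    classes = []
    for rec in records:
        for cls in classes:
            if duplicated(rec, cls[0]):
                cls.append(rec)
                break
        else:
            classes.append([rec])
    return classes


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def test_remove_spoke_expanded():
    records = [make_record(b=f"P{i}") for i in range(7)]
    expanded = [make_record(b=f"S{i}", expansion="spoke expansion") for i in range(3)]
    assert len(remove_spoke_expanded(records + expanded)) == 7
    assert remove_spoke_expanded(records) == records
    assert remove_spoke_expanded(expanded) == []


def test_filter_taxid():
    human = make_record(b="P1")
    mouse = make_record(b="P2", taxid_b=10090)
    chemical = make_record(b="CHEBI:1", raw_id_b="CHEBI:1", taxid_b=CHEMICAL)
    assert filter_taxid([human, mouse, chemical]) == [human]


def test_dedup_bait_prey_swap_collapses():
    first = make_record(b="P1", pub="100", method="pull down")
    swapped = make_record(a="P1", b=QUERY, raw_id_a="P1", raw_id_b=QUERY,
                          pub="100", method="pull down")
    assert dedup_within_publication([first, swapped]) == [first]


def test_dedup_different_host_kept():
    r1 = make_record(pub="100", host="taxid:9606(hela)")
    r2 = make_record(pub="100", host="taxid:-1(in vitro)")
    assert dedup_within_publication([r1, r2]) == [r1, r2]


def test_dedup_planted_fixture_seven_to_five():
    # 7 records with 2 planted duplicate pairs; expected size computed by
    # the pairwise-comparison oracle
    records = [
        make_record(b="P1", pub="100", method="pull down"),
        make_record(a="P1", b=QUERY, raw_id_a="P1", raw_id_b=QUERY,
                    pub="100", method="pull down"),  # dup of 0
        make_record(b="P2", pub="100", method="pull down"),
        make_record(b="P2", pub="101", method="pull down"),
        make_record(b="P2", pub="101", method="pull down"),  # dup of 3
        make_record(b="P3", pub="101", method="two hybrid"),
        make_record(b="P1", pub="101", method="pull down"),
    ]
    expected = len(dedup_oracle_classes(records))
    assert expected == 5
    assert len(dedup_within_publication(records)) == expected


def test_dedup_isoform_collapses_onto_parent():
    # canonical accessions drive pair identity, so isoform vs parent is a dup
    parent = make_record(b="O14641", pub="100")
    isoform = make_record(b="O14641", raw_id_b="O14641-2", pub="100")
    assert dedup_within_publication([parent, isoform]) == [parent]


def test_filters_idempotent_and_order_immaterial():
    rng = np.random.default_rng(42)
    for _ in range(20):
        records = random_records(rng, 40)
        for fn in (remove_spoke_expanded, filter_taxid, dedup_within_publication):
            once = fn(records)
            assert fn(once) == once
        a = filter_taxid(remove_spoke_expanded(records))
        b = remove_spoke_expanded(filter_taxid(records))
        assert a == b


def test_split_homo_hetero():
    homo = make_record(b=QUERY, raw_id_b=QUERY)
    hetero = make_record(b="P46821")
    het, hom = split_homo_hetero([homo, hetero], QUERY)
    assert (het, hom) == ([hetero], [homo])
    assert len(het) + len(hom) == 2
    with pytest.raises(ValueError):
        split_homo_hetero([make_record(a="P1", b="P2", raw_id_a="P1", raw_id_b="P2")], QUERY)


def test_curate_provenance_counts():
    records = (
        [make_record(b=f"P{i}") for i in range(5)]
        + [make_record(b="S1", expansion="spoke expansion")]
        + [make_record(b="M1", taxid_b=10090)]
        + [make_record(b="P0")]  # duplicate of the first record
    )
    ds = curate(records, QUERY, source="intact")
    assert ds.provenance == {"raw": 8, "post_spoke": 7, "post_filter1": 6, "post_filter2": 5}


# ---------------------------------------------------------------------------
# harmonization and merge
# ---------------------------------------------------------------------------


def test_harmonization_total_or_error():
    records = [make_record(method="some exotic assay")]
    with pytest.raises(HarmonizationError, match="exotic"):
        MethodHarmonizationMap().apply(records)
    out = MethodHarmonizationMap().apply([make_record(method="Pull Down")])
    assert out[0].harmonized_method == "Affinity Capture"


def _dataset(records, source):
    return CuratedDataset(records, {"post_filter2": len(records)}, QUERY, source)


def test_merge_exclusive_publication_copied_verbatim():
    intact = _dataset([make_record(b=f"P{i}", pub="100") for i in range(4)], "intact")
    biogrid = _dataset([], "biogrid")
    merged = merge_datasets(intact, biogrid)
    assert len(merged.records) == 4
    assert merged.provenance["publication_source"]["100"] == "intact"


def test_merge_larger_source_wins_wholesale():
    intact = _dataset(
        [make_record(b=f"P{i}", pub="100", method="pull down") for i in range(5)], "intact"
    )
    biogrid = _dataset(
        [make_record(b=f"P{i}", pub="100", method="Affinity Capture-MS", source="biogrid")
         for i in range(3)],
        "biogrid",
    )
    merged = merge_datasets(intact, biogrid)
    assert len(merged.records) == 5
    assert all(r.source_db == "intact" for r in merged.records)


def test_merge_tie_harmonized_dedup():
    # equal counts; vocabularies differ but harmonize to the same category
    intact = _dataset([make_record(b="P1", pub="100", method="Protein Kinase Assay")], "intact")
    biogrid = _dataset(
        [make_record(b="P1", pub="100", method="Biochemical Activity", source="biogrid")],
        "biogrid",
    )
    merged = merge_datasets(intact, biogrid)
    assert len(merged.records) == 1
    assert merged.provenance["publication_source"]["100"] == "union"


def test_merge_publication_union_and_query_check():
    intact = _dataset([make_record(b="P1", pub="100")], "intact")
    biogrid = _dataset([make_record(b="P2", pub="200", source="biogrid")], "biogrid")
    merged = merge_datasets(intact, biogrid)
    assert merged.publications == {"100", "200"}
    other = CuratedDataset(
        [make_record(a="X1", b="P1", raw_id_a="X1")], {"post_filter2": 1}, "X1", "biogrid"
    )
    with pytest.raises(ValueError, match="different query"):
        merge_datasets(intact, other)


def test_merge_symmetric_when_counts_differ():
    intact = _dataset(
        [make_record(b=f"P{i}", pub="100", method="pull down") for i in range(3)], "intact"
    )
    biogrid = _dataset(
        [make_record(b="P9", pub="100", method="Two Hybrid", source="biogrid")], "biogrid"
    )
    ab = merge_datasets(intact, biogrid)
    ba = merge_datasets(biogrid, intact)
    key = lambda r: (r.publication_id, r.unordered_pair(), r.harmonized_method)
    assert sorted(map(key, ab.records)) == sorted(map(key, ba.records))


def test_dedup_matches_oracle_on_random_fixtures():
    rng = np.random.default_rng(7)
    for _ in range(30):
        records = random_records(rng, int(rng.integers(1, 60)))
        assert len(dedup_within_publication(records)) == len(dedup_oracle_classes(records))
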