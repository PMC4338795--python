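"""Shared fixtures: record factories, random-record generators and the
default synthetic bundle."""

from __future__ import annotations

import numpy as np
import pytest

from ppicurate.io_formats import InteractionRecord
from ppicurate.pipeline import config_from_bundle, run_all
from ppicurate.synthetic_data import FixtureSpec, generate

QUERY = "Q5S007"


def make_record(
    b: str = "P00001",
    pub: str = "100",
    method: str = "pull down",
    host: str = "taxid:9606(hela)",
    a: str = QUERY,
    source: str = "intact",
    **kwargs,
) -> InteractionRecord:
    defaults = dict(
        interactor_a=a,
        interactor_b=b,
        raw_id_a=a,
        raw_id_b=b,
        taxid_a=9606,
        taxid_b=9606,
        detection_method=method,
        publication_id=pub,
        first_author="author",
        source_db=source,
        host_organism=host,
    )
    defaults.update(kwargs)
    return InteractionRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record


def random_records(rng: np.random.Generator, n: int) -> list[InteractionRecord]:
    """Random records over small label pools, so duplicate classes and
    filter fodder arise by chance."""
    partners = [f"P{i}" for i in range(6)] + [QUERY]
    pubs = [str(100 + i) for i in range(4)]
    methods = ["pull down", "two hybrid", "protein kinase assay"]
    hosts = ["taxid:9606(hela)", "taxid:-1(in vitro)"]
    records = []
    for _ in range(n):
        a, b = QUERY, partners[rng.integers(0, len(partners))]
        if rng.random() < 0.3:
            a, b = b, a
        records.append(
            make_record(
                a=a,
                b=b,
                pub=pubs[rng.integers(0, len(pubs))],
                method=methods[rng.integers(0, len(methods))],
                host=hosts[rng.integers(0, len(hosts))],
                taxid_a=9606 if rng.random() < 0.9 else 10090,
                expansion="spoke expansion" if rng.random() < 0.15 else "",
            )
        )
    return records


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default-spec synthetic bundle plus its planted truth."""
    out = tmp_path_factory.mktemp("bundle")
    paths, truth = generate(FixtureSpec(seed=20140726), out)
    return paths, truth


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """Full pipeline run over the default bundle."""
    paths, truth = default_bundle
    out = tmp_path_factory.mktemp("run")
    result = run_all(config_from_bundle(paths, out))
    return result, truth, out
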