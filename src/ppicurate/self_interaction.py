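"""Residue-level profile of self-interaction evidence.

Curated self-interaction annotations sometimes carry the regions of the
query protein involved (typically only one source database reports
them).  The profile counts, per residue, how many distinct publications
annotated at least one interval covering that residue; overlapping
fragments from the same publication count once (per-publication union).

Single-residue annotations (start == end) are kept in a separate point
channel — the "dots" of a profile figure — with the publication count
as the dot weight, rather than folded into the interval coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import InteractionRecord


@dataclass
class ResidueProfile:
    """Per-residue publication support for self-interaction."""

    protein_length: int
    coverage: np.ndarray  # coverage[i - 1] = support for residue i
    point_residues: dict[int, int]

    def __post_init__(self) -> None:
        if len(self.coverage) != self.protein_length:
            raise ValueError("coverage length must equal protein_length")

    def at(self, residue: int) -> int:
        if not (1 <= residue <= self.protein_length):
            raise ValueError(f"residue {residue} outside [1, {self.protein_length}]")
        return int(self.coverage[residue - 1])


def build_profile(
    homo_records: Sequence[InteractionRecord],
    protein_length: int,
    count: str = "publications",
) -> ResidueProfile:
    """Build the residue profile from region-annotated self-interaction records.

    ``count="publications"`` (default) counts distinct publications per
    residue; ``count="annotations"`` counts raw region annotations
    instead, for comparison.  Records without regions are ignored here
    (they still contribute to annotation tallies elsewhere).  A region
    outside ``[1, protein_length]`` is an error naming the record.
    """
    if count not in {"publications", "annotations"}:
        raise ValueError(f"unknown count mode {count!r}")
    coverage = np.zeros(protein_length, dtype=int)
    points: dict[int, set[str] | int] = {}

    by_pub: dict[str, list[tuple[int, int]]] = {}
    for rec in homo_records:
        for start, end in rec.regions:
            if not (1 <= start <= end <= protein_length):
                raise ValueError(
                    f"record {rec.publication_id} ({rec.raw_id_a}/{rec.raw_id_b}): "
                    f"region ({start}, {end}) outside [1, {protein_length}]"
                )
            if start == end:
                if count == "publications":
                    points.setdefault(start, set()).add(rec.publication_id)  # type: ignore[union-attr]
                else:
                    points[start] = points.get(start, 0) + 1  # type: ignore[operator]
            else:
                by_pub.setdefault(rec.publication_id, []).append((start, end))

    if count == "publications":
        for intervals in by_pub.values():
            mask = np.zeros(protein_length, dtype=bool)
            for start, end in intervals:
                mask[start - 1 : end] = True
            coverage += mask
        point_residues = {r: len(pubs) for r, pubs in points.items()}  # type: ignore[arg-type]
    else:
        for intervals in by_pub.values():
            for start, end in intervals:
                coverage[start - 1 : end] += 1
        point_residues = dict(points)  # type: ignore[arg-type]

    return ResidueProfile(
        protein_length=protein_length,
        coverage=coverage,
        point_residues=point_residues,
    )


__all__ = ["ResidueProfile", "build_profile"]
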