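"""Horizontal coverage of CDSs from best-hit read alignments.

Horizontal coverage is the fraction of a CDS's length covered by the union
of best-hit alignment footprints — a presence signal, not a depth measure.
A degeneracy rule guards against single-locus artifacts: a CDS with only
one read mapping, or with several reads all sharing the same start and end
coordinates, is assigned horizontal coverage 0.  Footprint identity is
judged on strand-normalized subject coordinates, so two reads hitting
opposite strands of the same locus count as the same footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from covloss.alignment import TabularHit

Span = tuple[int, int]


@dataclass(frozen=True)
class CoverageRecord:
    """Per-CDS horizontal coverage and its provenance."""

    species_id: str
    gene_id: str
    cds_len: int
    covered_bases: int
    horizontal_coverage: float
    n_reads: int
    n_distinct_footprints: int


def merge_intervals(spans: Iterable[Span]) -> tuple[tuple[Span, ...], int]:
    """Union of 0-based half-open intervals.

    Returns the merged, disjoint, sorted spans and the total covered length.
    Touching intervals ([0,50), [50,60)) merge.  An inverted or empty span
    raises ``ValueError``.
    """
    spans = sorted(spans)
    for s in spans:
        if s[0] >= s[1]:
            raise ValueError(f"inverted or empty span {s}")
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    out = tuple((a, b) for a, b in merged)
    return out, sum(b - a for a, b in out)


def horizontal_coverage(footprints: Sequence[Span], cds_len: int) -> float:
    """Fraction of the CDS covered by the union of footprints.

    Returns 0.0 when at most one read maps, or when every footprint shares
    the same (start, end) — both degenerate single-locus situations.
    """
    for s in footprints:
        if s[0] < 0 or s[1] > cds_len:
            raise ValueError(f"footprint {s} exceeds CDS bounds [0, {cds_len})")
    if len(footprints) <= 1:
        return 0.0
    if len(set(footprints)) == 1:
        return 0.0
    _, covered = merge_intervals(footprints)
    return covered / cds_len


def build_coverage_table(
    best_hits: Iterable[TabularHit], cds_db: dict[str, str], species_id: str = ""
) -> list[CoverageRecord]:
    """One CoverageRecord per CDS of one species database.

    ``best_hits`` must already be best-hit-filtered (one hit per read).
    CDSs without any hit are reported with coverage 0 and n_reads 0 rather
    than omitted, so downstream averages never silently drop members.
    """
    per_cds: dict[str, list[Span]] = {g: [] for g in cds_db}
    for h in best_hits:
        if h.subject_id not in per_cds:
            raise KeyError(f"hit references unknown CDS {h.subject_id!r}")
        per_cds[h.subject_id].append(h.footprint().span)

    records: list[CoverageRecord] = []
    for gene, spans in per_cds.items():
        cds_len = len(cds_db[gene])
        hcov = horizontal_coverage(spans, cds_len)
        covered = 0
        if spans:
            _, covered = merge_intervals(spans)
        records.append(
            CoverageRecord(
                species_id=species_id,
                gene_id=gene,
                cds_len=cds_len,
                covered_bases=covered,
                horizontal_coverage=hcov,
                n_reads=len(spans),
                n_distinct_footprints=len(set(spans)),
            )
        )
    return records


def coverage_table_to_tsv(records: Iterable[CoverageRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def read_coverage_table(path) -> list[CoverageRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "gene_id": str})
    return [CoverageRecord(**row) for row in df.to_dict(orient="records")]
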