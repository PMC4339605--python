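"""Lost/conserved classification of ortholog clusters and presence panels.

A cluster anchored on a pivot gene is evaluated by averaging the horizontal
coverage of the pivot CDS and of every member CDS from the evaluation
species (by default the pivot plus the monocot comparators).  The average
is compared against two cut-offs with strict inequalities: mean < 2% calls
the gene lost in the query lineage, mean > 50% calls it conserved, anything
between is undetermined.  Only OGCsM clusters (>= 1 monocot member) are
evaluable.  Presence panels for named gene lists use the inclusive >= 2%
rule for presence, mirroring how absence (<2%, strict) and presence (>=2%)
are worded asymmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from covloss.coverage import CoverageRecord
from covloss.orthology import OrthoCluster

LOST = "lost"
CONSERVED = "conserved"
UNDETERMINED = "undetermined"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class GeneCall:
    """Classification of one cluster by mean member coverage."""

    pivot_gene_id: str
    mean_coverage: float
    status: str
    n_members_evaluated: int
    reason: str = ""


def _coverage_lookup(
    coverage: Iterable[CoverageRecord] | Mapping[tuple[str, str], float]
) -> Mapping[tuple[str, str], float]:
    if isinstance(coverage, Mapping):
        return coverage
    return {(r.species_id, r.gene_id): r.horizontal_coverage for r in coverage}


def classify_cluster(
    cluster: OrthoCluster,
    coverage: Iterable[CoverageRecord] | Mapping[tuple[str, str], float],
    pivot_species: str,
    eval_species: set[str] | frozenset[str],
    lost_cutoff: float = 0.02,
    conserved_cutoff: float = 0.50,
) -> GeneCall:
    """Classify one cluster as lost / conserved / undetermined.

    ``coverage`` maps (species_id, gene_id) to horizontal coverage (or is an
    iterable of CoverageRecord).  The mean is taken over the pivot gene plus
    members whose species is in ``eval_species``; members with no reads must
    still carry a (zero) coverage record — a missing record makes the
    cluster not_evaluable rather than silently shrinking the mean.
    """
    cov = _coverage_lookup(coverage)
    if not cluster.has_monocot:
        return GeneCall(cluster.pivot_gene_id, float("nan"), NOT_EVALUABLE, 0,
                        reason="cluster has no monocot member (not in OGCsM)")

    genes = [(pivot_species, cluster.pivot_gene_id)]
    genes += [(sp, g) for sp, g in cluster.member_genes() if sp in eval_species]
    values = []
    for sp, g in genes:
        if (sp, g) not in cov:
            return GeneCall(cluster.pivot_gene_id, float("nan"), NOT_EVALUABLE, 0,
                            reason=f"missing coverage record for {sp}:{g}")
        values.append(cov[(sp, g)])
    mean = sum(values) / len(values)
    if mean < lost_cutoff:
        status = LOST
    elif mean > conserved_cutoff:
        status = CONSERVED
    else:
        status = UNDETERMINED
    return GeneCall(cluster.pivot_gene_id, mean, status, len(values))


def classify_clusters(
    clusters: Iterable[OrthoCluster],
    coverage: Iterable[CoverageRecord] | Mapping[tuple[str, str], float],
    pivot_species: str,
    eval_species: set[str] | frozenset[str],
    lost_cutoff: float = 0.02,
    conserved_cutoff: float = 0.50,
) -> list[GeneCall]:
    cov = _coverage_lookup(coverage)
    return [
        classify_cluster(cl, cov, pivot_species, eval_species, lost_cutoff, conserved_cutoff)
        for cl in clusters
    ]


def calls_to_tsv(calls: Iterable[GeneCall], path) -> None:
    pd.DataFrame(calls).to_csv(path, sep="\t", index=False)


def presence_panel(
    gene_ids: Sequence[str],
    known_genes: set[str],
    cluster_mean_coverage: Mapping[str, Mapping[str, float]],
    est_rbb_sets: Mapping[str, set[str]] | None = None,
    present_cutoff: float = 0.02,
) -> pd.DataFrame:
    """Presence/absence panel for named pivot genes.

    ``cluster_mean_coverage`` maps each query genome label to
    {pivot gene -> mean cluster coverage} over the genes that have an OGCsM
    cluster; ``est_rbb_sets`` maps each transcriptome label to the set of
    pivot genes with an EST RBB partner.  Cells are '+' (mean coverage >=
    ``present_cutoff``, or an RBB partner exists), '-' otherwise, and 'N/A'
    in genome columns for genes without an OGCsM cluster.  Unknown gene ids
    raise ``KeyError`` listing them.
    """
    unknown = [g for g in gene_ids if g not in known_genes]
    if unknown:
        raise KeyError(f"unknown gene ids: {unknown}")
    est_rbb_sets = est_rbb_sets or {}

    in_ogcm = set()
    for per_gene in cluster_mean_coverage.values():
        in_ogcm.update(per_gene)

    rows = {}
    for g in gene_ids:
        row: dict[str, str] = {"OGCsM": "+" if g in in_ogcm else "-"}
        for genome, per_gene in cluster_mean_coverage.items():
            if g not in per_gene:
                row[genome] = "N/A"
            else:
                row[genome] = "+" if per_gene[g] >= present_cutoff else "-"
        for tx, rbb in est_rbb_sets.items():
            row[tx] = "+" if g in rbb else "-"
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index")
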