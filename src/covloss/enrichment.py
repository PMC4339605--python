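"""GO over-representation of gene sets: OBO ingestion, true-path
annotation propagation with evidence-code filtering, and Fisher exact
testing (classic and elim).

The study set (e.g. genes called lost) is tested against a background (all
OGCsM pivot genes) term by term with the one-sided hypergeometric tail.
``elim`` processes terms most-specific-first and removes the genes of
significantly enriched terms from their ancestors before those are tested,
decorrelating the DAG; with ``elim_alpha=0`` it reduces to ``classic``.
Raw p-values are reported (an optional Benjamini-Hochberg column can be
added); only ``is_a`` edges are traversed by default.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet
from scipy.stats import hypergeom


@dataclass(frozen=True)
class TermInfo:
    name: str
    namespace: str
    parents: tuple[str, ...]


@dataclass(frozen=True)
class OntologyDag:
    """Minimal is_a ontology: term id -> (name, namespace, parents)."""

    terms: Mapping[str, TermInfo]
    dangling: frozenset[str] = frozenset()

    def ancestors(self, term_id: str) -> set[str]:
        """All is_a ancestors of a term (the term itself excluded)."""
        out: set[str] = set()
        stack = list(self.terms[term_id].parents)
        while stack:
            t = stack.pop()
            if t in out or t not in self.terms:
                continue
            out.add(t)
            stack.extend(self.terms[t].parents)
        return out

    def depth_order(self) -> list[str]:
        """Terms ordered children-before-parents (most specific first)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t, info in self.terms.items():
            for p in info.parents:
                if p in self.terms:
                    g.add_edge(t, p)   # child -> parent
        return list(nx.topological_sort(g))


def parse_obo_minimal(
    source: str | os.PathLike | TextIO, include_part_of: bool = False
) -> OntologyDag:
    """Parse an OBO 1.2 file into an is_a DAG.

    Obsolete terms are skipped.  Parents referenced but not defined are
    flagged as dangling rather than invented.  A cyclic is_a graph raises
    ``ValueError``.  ``include_part_of`` additionally treats part_of
    relationships as parent edges.
    """
    graph = obonet.read_obo(source, ignore_obsolete=True)
    wanted = {"is_a"} | ({"part_of"} if include_part_of else set())
    terms: dict[str, TermInfo] = {}
    dangling: set[str] = set()
    check = nx.DiGraph()
    check.add_nodes_from(graph.nodes)
    for node, data in graph.nodes(data=True):
        parents: list[str] = []
        for _, parent, key in graph.out_edges(node, keys=True):
            if key in wanted:
                parents.append(parent)
                check.add_edge(node, parent)
        terms[node] = TermInfo(
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            parents=tuple(sorted(parents)),
        )
    for info in terms.values():
        dangling.update(p for p in info.parents if p not in terms)
    if not nx.is_directed_acyclic_graph(check):
        raise ValueError("cyclic is_a graph; not a valid ontology")
    return OntologyDag(terms=terms, dangling=frozenset(dangling))


def propagate_annotations(
    gene2go: Iterable[tuple[str, str, str]],
    dag: OntologyDag,
    excluded_codes: frozenset[str] | set[str] = frozenset({"NR", "ND"}),
) -> dict[str, frozenset[str]]:
    """Gene -> ancestor-closed term set (true-path rule).

    ``gene2go`` rows are (gene_id, term_id, evidence_code); rows with an
    excluded evidence code are dropped, rows pointing at unknown terms are
    dropped with a warning, duplicates collapse by set semantics.
    """
    out: dict[str, set[str]] = {}
    for gene, term, evidence in gene2go:
        if evidence in excluded_codes:
            continue
        if term not in dag.terms:
            warnings.warn(f"annotation of {gene} to unknown term {term} dropped")
            continue
        s = out.setdefault(gene, set())
        s.add(term)
        s.update(dag.ancestors(term))
    return {g: frozenset(ts) for g, ts in out.items()}


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    n_background_annotated: int
    n_study_annotated: int
    p_value: float


def _hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided over-representation p: P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    study: set[str],
    background: set[str],
    annotations: Mapping[str, frozenset[str]],
    dag: OntologyDag | None = None,
    method: str = "classic",
    elim_alpha: float = 0.01,
    add_bh: bool = False,
) -> list[EnrichmentRow]:
    """Per-term one-sided Fisher exact test of the study set vs background.

    ``annotations`` must already be propagated (true-path closed).  With
    ``method='elim'`` (requires ``dag``), terms are processed most-specific
    first and the genes of terms with p < ``elim_alpha`` are removed from
    their ancestors' gene sets before those are tested.  Rows are sorted by
    p-value, then term id.
    """
    if not study or not background:
        raise ValueError("study and background sets must be non-empty")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    if method not in {"classic", "elim"}:
        raise ValueError(f"unknown method {method!r}")

    term_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    N = len(background)
    n = len(study)
    rows: list[EnrichmentRow] = []

    if method == "classic":
        order = sorted(term_genes)
        for term in order:
            genes = term_genes[term]
            k = len(genes & study)
            rows.append(_make_row(term, dag, len(genes), k, _hypergeom_tail(k, N, len(genes), n)))
    else:
        if dag is None:
            raise ValueError("method='elim' requires the ontology dag")
        removed: dict[str, set[str]] = {}
        order = [t for t in dag.depth_order() if t in term_genes]
        # terms annotated but absent from the dag are tested classically last
        order += sorted(set(term_genes) - set(order))
        for term in order:
            genes = term_genes[term] - removed.get(term, set())
            k = len(genes & study)
            p = _hypergeom_tail(k, N, len(genes), n)
            rows.append(_make_row(term, dag, len(genes), k, p))
            if p < elim_alpha and term in dag.terms:
                for anc in dag.ancestors(term):
                    removed.setdefault(anc, set()).update(genes)

    rows.sort(key=lambda r: (r.p_value, r.term_id))
    if add_bh:
        rows = _with_bh(rows)
    return rows


def _make_row(term: str, dag: OntologyDag | None, n_bg: int, n_study: int, p: float) -> EnrichmentRow:
    name = dag.terms[term].name if dag is not None and term in dag.terms else ""
    return EnrichmentRow(term, name, n_bg, n_study, p)


@dataclass(frozen=True)
class AdjustedRow(EnrichmentRow):
    p_bh: float = 1.0


def _with_bh(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
    from scipy.stats import false_discovery_control

    adj = false_discovery_control([r.p_value for r in rows], method="bh")
    return [
        AdjustedRow(r.term_id, r.name, r.n_background_annotated, r.n_study_annotated, r.p_value, float(q))
        for r, q in zip(rows, adj)
    ]


def enrichment_to_tsv(rows: Iterable[EnrichmentRow], path) -> None:
    import pandas as pd

    pd.DataFrame(rows).rename(
        columns={"term_id": "GO ID", "name": "Term", "p_value": "P-value"}
    ).to_csv(path, sep="\t", index=False)
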