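"""OBO ingestion, true-path propagation, and Fisher exact testing against
an exact-summation oracle."""

import io

import numpy as np
import pytest

from covloss.enrichment import (
    fisher_enrichment,
    parse_obo_minimal,
    propagate_annotations,
)
from oracles import OBO, annotation_world as _world, hypergeom_tail_oracle

@pytest.fixture(scope="module")
def dag():
    return parse_obo_minimal(io.StringIO(OBO))


class TestOboParsing:
    def test_is_a_edges_recorded(self, dag):
        assert dag.terms["GO:0009693"].parents == ("GO:0009058",)
        assert dag.ancestors("GO:0009693") == {"GO:0009058", "GO:0008150"}

    def test_obsolete_terms_skipped(self, dag):
        assert "GO:0999999" not in dag.terms

    def test_empty_file_gives_empty_dag(self):
        assert parse_obo_minimal(io.StringIO("format-version: 1.2\n")).terms == {}

    def test_cyclic_graph_rejected(self):
        cyclic = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:1\n"
        )
        with pytest.raises(ValueError, match="cyclic"):
            parse_obo_minimal(io.StringIO(cyclic))


class TestPropagation:
    def test_true_path_rule(self, dag):
        ann = propagate_annotations([("g1", "GO:0009693", "IDA")], dag)
        assert ann["g1"] == {"GO:0009693", "GO:0009058", "GO:0008150"}

    @pytest.mark.parametrize("code", ["NR", "ND"])
    def test_excluded_evidence_dropped(self, dag, code):
        assert propagate_annotations([("g1", "GO:0009693", code)], dag) == {}

    def test_unknown_term_warned_and_dropped(self, dag):
        with pytest.warns(UserWarning, match="unknown term"):
            ann = propagate_annotations([("g1", "GO:7777777", "IDA")], dag)
        assert ann == {}

    def test_duplicates_collapse(self, dag):
        ann = propagate_annotations(
            [("g1", "GO:0009693", "IDA"), ("g1", "GO:0009693", "IEA")], dag
        )
        assert len(ann["g1"]) == 3

    def test_ancestor_counts_dominate_descendants(self, dag):
        genes = [f"g{i}" for i in range(20)]
        assoc = [(g, "GO:0009693", "IDA") for g in genes[:7]]
        assoc += [(g, "GO:0009058", "IDA") for g in genes[7:12]]
        ann = propagate_annotations(assoc, dag)
        count = lambda t: sum(t in ts for ts in ann.values())
        assert count("GO:0008150") >= count("GO:0009058") >= count("GO:0009693")


def _world(N, K, n, k, dag):
    """Gene sets realizing one 2x2 table on the leaf term."""
    background = {f"g{i}" for i in range(N)}
    annotated = {f"g{i}" for i in range(K)}
    study = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
    annotations = {g: frozenset({"GO:0009693", "GO:0009058", "GO:0008150"}) for g in annotated}
    return study, background, annotations


class TestFisherClassic:
    def test_matches_exact_summation_oracle_on_random_tables(self, dag):
        rng = np.random.default_rng(23)
        for _ in range(300):
            N = int(rng.integers(2, 501))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            if n - k > N - K:
                continue
            study, background, ann = _world(N, K, n, k, dag)
            rows = {r.term_id: r for r in fisher_enrichment(study, background, ann, dag=dag)}
            row = rows["GO:0009693"]
            assert row.n_background_annotated == K and row.n_study_annotated == k
            assert row.p_value == pytest.approx(hypergeom_tail_oracle(k, N, K, n), abs=1e-10)

    def test_ethylene_table_p_value(self, dag):
        # 78 annotated of 16 007 background; 23 in a 2 147-gene study set
        study, background, ann = _world(16_007, 78, 2_147, 23, dag)
        rows = {r.term_id: r for r in fisher_enrichment(study, background, ann, dag=dag)}
        assert rows["GO:0009693"].p_value == pytest.approx(
            hypergeom_tail_oracle(23, 16_007, 78, 2_147), rel=1e-9
        )

    def test_term_without_study_genes_has_p_one(self, dag):
        study, background, ann = _world(50, 10, 5, 0, dag)
        rows = fisher_enrichment(study, background, ann, dag=dag)
        assert all(r.p_value == pytest.approx(1.0) for r in rows)

    def test_study_equal_background_degenerate(self, dag):
        _, background, ann = _world(30, 12, 0, 0, dag)
        rows = fisher_enrichment(set(background), background, ann, dag=dag)
        assert all(r.p_value == pytest.approx(1.0) for r in rows)

    def test_input_validation(self, dag):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"g"}, {}, dag=dag)
        with pytest.raises(ValueError):
            fisher_enrichment({"x"}, {"g"}, {}, dag=dag)


class TestElim:
    def test_alpha_zero_equals_classic(self, dag):
        study, background, ann = _world(100, 30, 20, 15, dag)
        classic = fisher_enrichment(study, background, ann, dag=dag, method="classic")
        elim = fisher_enrichment(study, background, ann, dag=dag, method="elim", elim_alpha=0.0)
        assert classic == elim

    def test_significant_child_genes_removed_from_ancestors(self, dag):
        # leaf and parent share the same annotated genes; the leaf is tested
        # first and is significant, so the parent's set is emptied
        study, background, ann = _world(200, 20, 20, 20, dag)
        rows = {r.term_id: r for r in fisher_enrichment(
            study, background, ann, dag=dag, method="elim", elim_alpha=0.01
        )}
        assert rows["GO:0009693"].p_value < 1e-10
        assert rows["GO:0009058"].n_background_annotated == 0
        assert rows["GO:0009058"].p_value == pytest.approx(1.0)
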