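"""RBB tie-window semantics, cluster assembly, EST dedup, and ORF finding."""

import numpy as np
import pytest

from covloss.alignment import TabularHit, align_cds_sets
from covloss.orthology import (
    build_clusters,
    dedup_sequences,
    longest_orf,
    rbb_pairs,
)
from covloss.seqio import revcomp


def _hit(q, s, evalue=1e-30, bit=200.0):
    return TabularHit(q, s, 99.0, 100, 1, 0, 1, 100, 1, 100, evalue, bit)


class TestRbbPairs:
    def test_bit_score_window_inclusive(self):
        # tied e-values, bits {200, 195, 189}: 195 is within 10, 189 is not
        ab = [_hit("a1", "b1", bit=200.0), _hit("a1", "b2", bit=195.0), _hit("a1", "b3", bit=189.0)]
        ba = [_hit("b1", "a1"), _hit("b2", "a1"), _hit("b3", "a1")]
        assert rbb_pairs(ab, ba) == {"a1": ["b1", "b2"]}

    def test_exact_boundary_admitted(self):
        ab = [_hit("a1", "b1", bit=200.0), _hit("a1", "b2", bit=190.0)]
        ba = [_hit("b1", "a1"), _hit("b2", "a1")]
        assert rbb_pairs(ab, ba) == {"a1": ["b1", "b2"]}

    def test_window_only_among_evalue_tied_top(self):
        # b2 has a worse e-value; its bit score being close is irrelevant
        ab = [_hit("a1", "b1", evalue=1e-40, bit=200.0), _hit("a1", "b2", evalue=1e-20, bit=199.0)]
        ba = [_hit("b1", "a1"), _hit("b2", "a1")]
        assert rbb_pairs(ab, ba) == {"a1": ["b1"]}

    def test_reciprocity_required(self):
        ab = [_hit("a1", "b1")]
        ba = [_hit("b1", "a2")]
        assert rbb_pairs(ab, ba) == {}

    def test_symmetry_of_admission(self):
        ab = [_hit("a1", "b1", bit=200.0), _hit("a2", "b1", bit=150.0)]
        ba = [_hit("b1", "a1", bit=200.0), _hit("b1", "a2", bit=195.0)]
        fwd = rbb_pairs(ab, ba)
        rev = rbb_pairs(ba, ab)
        pairs_fwd = {(a, b) for a, bs in fwd.items() for b in bs}
        pairs_rev = {(a, b) for b, as_ in rev.items() for a in as_}
        assert pairs_fwd == pairs_rev

    def test_zero_divergence_recovers_truth_pairing(self, zero_div_data):
        cds, truth = zero_div_data["cds_sets"], zero_div_data["truth"]
        ab = align_cds_sets(cds["ath"], cds["osa"])
        ba = align_cds_sets(cds["osa"], cds["ath"])
        expected = {truth.genes[f]["ath"]: [truth.genes[f]["osa"]] for f in truth.status}
        assert rbb_pairs(ab, ba) == expected

    def test_diverged_truth_recovery_above_95pct(self, diverged_small):
        cds, truth = diverged_small["cds_sets"], diverged_small["truth"]
        ab = align_cds_sets(cds["ath"], cds["osa"])
        ba = align_cds_sets(cds["osa"], cds["ath"])
        pairs = rbb_pairs(ab, ba)
        ok = sum(
            truth.genes[f]["osa"] in pairs.get(truth.genes[f]["ath"], [])
            for f in truth.status
        )
        assert ok / len(truth.status) >= 0.95


class TestBuildClusters:
    def test_monocot_flag_and_ogcm_membership(self):
        rbb = {"tomato": {"a1": ["t1"]}, "rice": {"a2": ["r1"]}}
        clusters = {c.pivot_gene_id: c for c in build_clusters("ath", rbb, {"rice"})}
        assert not clusters["a1"].has_monocot
        assert clusters["a2"].has_monocot

    def test_gene_without_partner_forms_no_cluster(self):
        clusters = build_clusters("ath", {"rice": {"a1": [], "a2": ["r1"]}}, {"rice"})
        assert [c.pivot_gene_id for c in clusters] == ["a2"]

    def test_pivot_label_collision_rejected(self):
        with pytest.raises(ValueError, match="collision"):
            build_clusters("ath", {"ath": {}}, set())

    def test_zero_divergence_cluster_count_equals_families(self, zero_div_data):
        cds, truth = zero_div_data["cds_sets"], zero_div_data["truth"]
        rbb = {}
        for sp in ("osa", "spo"):
            rbb[sp] = rbb_pairs(
                align_cds_sets(cds["ath"], cds[sp]), align_cds_sets(cds[sp], cds["ath"])
            )
        clusters = build_clusters("ath", rbb, {"osa", "spo"})
        assert len(clusters) == len(truth.status)
        assert all(c.has_monocot for c in clusters)


class TestDedup:
    def _mutated(self, seq, n, seed=0):
        rng = np.random.default_rng(seed)
        out = list(seq)
        for i in rng.choice(len(seq), size=n, replace=False):
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        return "".join(out)

    def test_identical_sequences_collapse(self):
        seq = "ACGT" * 100
        centroids, amap = dedup_sequences({"a": seq, "b": seq})
        assert len(centroids) == 1
        assert len(set(amap.values())) == 1

    def test_sequences_below_threshold_stay_apart(self):
        seq = "ACGT" * 100
        other = self._mutated(seq, 8)  # 2% different
        centroids, _ = dedup_sequences({"a": seq, "b": other}, identity_threshold=0.99)
        assert len(centroids) == 2

    def test_sequences_above_threshold_merge(self):
        seq = "ACGT" * 100
        near = self._mutated(seq, 2)  # 0.5% different
        centroids, amap = dedup_sequences({"a": seq, "b": near}, identity_threshold=0.99)
        assert len(centroids) == 1

    def test_idempotent_on_centroids(self):
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=200)) for i in range(10)}
        centroids, _ = dedup_sequences(seqs)
        again, _ = dedup_sequences(centroids)
        assert again == centroids
        assert len(centroids) <= len(seqs)


class TestLongestOrf:
    def test_simple_translation(self):
        assert longest_orf("ATGAAATAG") == "MK"

    def test_reverse_frame_wins_when_longer(self):
        fwd_orf = "ATGAAATAG"                       # MK on +1
        rev_orf = revcomp("ATGAAACCCGGGAAATAG")     # MKPGK on reverse strand
        assert longest_orf(fwd_orf + rev_orf) == "MKPGK"

    def test_no_start_codon_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert longest_orf("CCCCCCCCC") == ""

    def test_start_without_stop_is_not_an_orf(self):
        with pytest.warns(UserWarning):
            assert longest_orf("ATGAAAAAA") == ""

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            longest_orf("AC")
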