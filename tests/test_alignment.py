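"""Mapper and tabular-hit contracts: parsing, statistics, exact-match
limits, best-hit filtering, and agreement with a Smith-Waterman oracle."""

import io
import math

import numpy as np
import pytest

from covloss.alignment import (
    ScoringScheme,
    TabularHit,
    align_cds_sets,
    best_hit_filter,
    map_reads_to_cds,
    parse_tabular_hits,
    write_tabular_hits,
)
from covloss.seqio import revcomp

PLUS_LINE = "r1\tg1\t100.0\t100\t0\t0\t1\t100\t51\t150\t1e-50\t185.0"


def _hit(**kw):
    base = dict(
        query_id="q", subject_id="s", pct_identity=100.0, aln_len=50, mismatches=0,
        gap_opens=0, q_start=1, q_end=50, s_start=1, s_end=50, evalue=1e-20, bit_score=90.0,
    )
    base.update(kw)
    return TabularHit(**base)


class TestTabularIO:
    def test_parse_plus_strand_fields(self):
        (h,) = parse_tabular_hits([PLUS_LINE])
        assert (h.subject_id, h.s_start, h.s_end, h.is_minus) == ("g1", 51, 150, False)
        assert h.footprint().span == (50, 150)

    def test_minus_strand_normalized_footprint(self):
        line = PLUS_LINE.replace("\t51\t150\t", "\t150\t51\t")
        (h,) = parse_tabular_hits([line])
        assert h.is_minus
        assert h.footprint().span == (50, 150)

    def test_wrong_column_count_names_line(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_tabular_hits([PLUS_LINE, "\t".join(PLUS_LINE.split("\t")[:11])])

    def test_bad_numeric_field_names_line(self):
        with pytest.raises(ValueError, match="line 1"):
            parse_tabular_hits([PLUS_LINE.replace("100\t0", "xx\t0")])

    def test_comments_and_blanks_skipped(self):
        hits = parse_tabular_hits(["# comment", "", PLUS_LINE])
        assert len(hits) == 1

    def test_write_parse_roundtrip_is_identity(self):
        hits = [_hit(), _hit(query_id="q2", evalue=3.7e-13, bit_score=41.2, s_start=90, s_end=41, q_end=50)]
        buf = io.StringIO()
        write_tabular_hits(hits, buf)
        assert parse_tabular_hits(io.StringIO(buf.getvalue())) == hits


class TestStatistics:
    def test_lambda_solves_karlin_altschul_identity(self):
        s = ScoringScheme()
        lam = s.lam
        assert lam > 0
        assert 0.25 * math.exp(lam * s.reward) + 0.75 * math.exp(lam * s.penalty) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(reward=-1, penalty=-3)


class TestMapper:
    def test_exact_substring_read_yields_single_full_length_hit(self):
        rng = np.random.default_rng(0)
        cds = {"g1": "".join(rng.choice(list("ACGT"), size=500)),
               "g2": "".join(rng.choice(list("ACGT"), size=500))}
        read = cds["g1"][100:200]
        hits = map_reads_to_cds([("r", read)], cds)
        assert {h.subject_id for h in hits} == {"g1"}
        best = hits[0]
        assert (best.pct_identity, best.aln_len) == (100.0, 100)
        assert (best.s_start, best.s_end) == (101, 200)

    def test_minus_strand_read_recovered(self):
        rng = np.random.default_rng(1)
        cds = {"g1": "".join(rng.choice(list("ACGT"), size=500))}
        hits = map_reads_to_cds([("r", revcomp(cds["g1"][100:200]))], cds)
        assert hits and all(h.is_minus for h in hits)
        assert hits[0].footprint().span == (100, 200)

    def test_read_without_homolog_has_no_hit(self):
        rng = np.random.default_rng(2)
        cds = {"g1": "".join(rng.choice(list("ACGT"), size=500))}
        foreign = "".join(rng.choice(list("ACGT"), size=100))
        assert map_reads_to_cds([("r", foreign)], cds) == []

    def test_evalue_threshold_respected(self, diverged_small):
        cds = diverged_small["cds_sets"]
        hits = align_cds_sets(cds["osa"], cds["ath"], evalue_max=1e-5)
        assert hits and all(h.evalue <= 1e-5 for h in hits)

    def test_non_acgtn_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            map_reads_to_cds([("r", "ACGU" * 25)], {"g": "ACGT" * 50})

    def test_short_seed_rejected(self):
        with pytest.raises(ValueError, match="seed_len"):
            map_reads_to_cds([("r", "ACGT" * 25)], {"g": "ACGT" * 50}, seed_len=5)

    def test_self_alignment_best_hit_is_self(self, diverged_small):
        cds = diverged_small["cds_sets"]["ath"]
        best = best_hit_filter(align_cds_sets(cds, cds))
        assert all(h.query_id == h.subject_id for h in best)
        assert len(best) == len(cds)

    def test_best_subject_agrees_with_smith_waterman_oracle(self, diverged_small):
        """Exhaustive local alignment over all read x CDS pairs as oracle."""
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="local", match_score=2, mismatch_score=-3,
            open_gap_score=-5, extend_gap_score=-2,
        )
        cds = diverged_small["cds_sets"]["ath"]
        rng = np.random.default_rng(9)
        # oversample: reads from intergenic spacers have no hit at all
        sampled = [diverged_small["reads"][i] for i in rng.choice(len(diverged_small["reads"]), 120, replace=False)]
        best = {h.query_id: h.subject_id for h in best_hit_filter(map_reads_to_cds(sampled, cds))}
        reads = [r for r in sampled if r[0] in best][:50]
        agree = total = 0
        for name, seq in reads:
            scores = {
                g: max(aligner.score(seq, s), aligner.score(revcomp(seq), s))
                for g, s in cds.items()
            }
            oracle = max(scores, key=lambda g: (scores[g], g))
            if name in best:
                total += 1
                agree += best[name] == oracle
        assert total >= 40
        assert agree / total >= 0.95


class TestBestHitFilter:
    def test_lowest_evalue_wins(self):
        kept = best_hit_filter([_hit(subject_id="a", evalue=1e-5), _hit(subject_id="b", evalue=1e-20)])
        assert [h.subject_id for h in kept] == ["b"]

    def test_bit_score_breaks_evalue_tie(self):
        kept = best_hit_filter([_hit(subject_id="a", bit_score=150.0), _hit(subject_id="b", bit_score=180.0)])
        assert [h.subject_id for h in kept] == ["b"]

    def test_subject_id_breaks_full_tie(self):
        kept = best_hit_filter([_hit(subject_id="b"), _hit(subject_id="a")])
        assert [h.subject_id for h in kept] == ["a"]

    def test_empty_input(self):
        assert best_hit_filter([]) == []
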