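"""BLAST tabular filtering, best-hit reduction and gene-level aggregation."""

import pytest

from annoverlap.blast import (
    BlastHit,
    best_hit_per_query,
    filter_hits,
    hits_to_gene_pairs,
    load_tx2gene,
    parse_blast_tab,
    reciprocal_filter,
)


def hit(q="q1", s="s1", bit=500.0, pident=95.0, qcov=90.0):
    return BlastHit(query_id=q, subject_id=s, percent_identity=pident,
                    alignment_length=500, bit_score=bit, e_value=1e-50,
                    query_coverage=qcov)


class TestParse:
    def test_fixture_parses_fully(self, blast_fixture):
        hits, rejected = parse_blast_tab(blast_fixture["paths"]["hits"])
        assert rejected == 0
        assert len(hits) > 0

    def test_malformed_rows_rejected_and_counted(self, tmp_path):
        p = tmp_path / "h.tsv"
        good = "q1\ts1\t95.0\t500\t5\t1\t1\t500\t1\t500\t1e-50\t400.0\t90\n"
        p.write_text(good + "q2\ts2\tbadscore\t500\t5\t1\t1\t500\t1\t500\t1e-50\tNaNope\t90\n"
                     + "q3\tonly\tthree\n")
        hits, rejected = parse_blast_tab(str(p))
        assert len(hits) == 1 and rejected == 2

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert parse_blast_tab(str(p)) == ([], 0)


class TestFilter:
    @pytest.mark.parametrize(
        "bit,qcov,kept",
        [(500, 95, True), (40, 95, False), (500, 60, False), (50, 70, True)],
    )
    def test_thresholds_inclusive(self, bit, qcov, kept):
        out = filter_hits([hit(bit=bit, qcov=qcov)], min_bitscore=50, min_qcov=70)
        assert bool(out) is kept

    def test_zero_thresholds_vacuous(self):
        hits = [hit(bit=1, qcov=1), hit(bit=0, qcov=0)]
        assert filter_hits(hits, 0, 0) == hits

    def test_raising_thresholds_monotone(self, blast_fixture):
        hits, _ = parse_blast_tab(blast_fixture["paths"]["hits"])
        prev = None
        for min_bit in (0, 50, 200, 500):
            kept = {(h.query_id, h.subject_id) for h in filter_hits(hits, min_bit, 0)}
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestBestHit:
    def test_argmax_on_bitscore(self):
        best = best_hit_per_query([hit(s="s1", bit=500), hit(s="s2", bit=480)])
        assert [(h.query_id, h.subject_id) for h in best] == [("q1", "s1")]

    def test_single_hits_unchanged(self):
        hits = [hit(q="q1"), hit(q="q2", s="s2")]
        assert sorted(h.query_id for h in best_hit_per_query(hits)) == ["q1", "q2"]

    def test_bitscore_tie_broken_by_identity(self):
        best = best_hit_per_query([hit(s="s1", bit=500, pident=98),
                                   hit(s="s2", bit=500, pident=99)])
        assert best[0].subject_id == "s2"

    def test_full_tie_broken_by_smaller_subject_id(self):
        best = best_hit_per_query([hit(s="s2"), hit(s="s1")])
        assert best[0].subject_id == "s1"

    def test_unique_queries_and_count(self, blast_fixture):
        hits, _ = parse_blast_tab(blast_fixture["paths"]["hits"])
        kept = filter_hits(hits)
        best = best_hit_per_query(kept)
        queries = [h.query_id for h in best]
        assert len(queries) == len(set(queries)) == len({h.query_id for h in kept})

    def test_tie_winner_matches_truth(self, blast_fixture):
        hits, _ = parse_blast_tab(blast_fixture["paths"]["hits"])
        best = {h.query_id: h.subject_id for h in best_hit_per_query(filter_hits(hits))}
        for q, s in blast_fixture["tie_winners"].items():
            assert best[q] == s


class TestGenePairs:
    def test_fixture_pairs_and_support(self, blast_fixture):
        hits, _ = parse_blast_tab(blast_fixture["paths"]["hits"])
        best = best_hit_per_query(filter_hits(hits))
        tx_q = load_tx2gene(blast_fixture["paths"]["tx2gene_query"])
        tx_s = load_tx2gene(blast_fixture["paths"]["tx2gene_subject"])
        pairs = hits_to_gene_pairs(best, tx_q, tx_s)
        got = {(p.gene_query, p.gene_subject): p.support_count for p in pairs}
        assert got == blast_fixture["expected_pairs"]

    def test_two_transcripts_one_pair_support_two(self):
        best = [hit(q="t1", s="u1"), hit(q="t2", s="u2")]
        pairs = hits_to_gene_pairs(best, {"t1": "GA", "t2": "GA"}, {"u1": "GB", "u2": "GB"})
        assert len(pairs) == 1
        assert pairs[0].support_count == 2 and not pairs[0].one_to_many

    def test_split_subjects_flagged_one_to_many(self):
        best = [hit(q="t1", s="u1"), hit(q="t2", s="u2")]
        pairs = hits_to_gene_pairs(best, {"t1": "GA", "t2": "GA"}, {"u1": "GB", "u2": "GC"})
        assert len(pairs) == 2 and all(p.one_to_many for p in pairs)

    def test_unknown_transcript_raises(self):
        with pytest.raises(KeyError, match="t1"):
            hits_to_gene_pairs([hit(q="t1")], {}, {"s1": "GB"})

    def test_empty_input(self):
        assert hits_to_gene_pairs([], {}, {}) == []

    def test_input_permutation_invariance(self, blast_fixture):
        hits, _ = parse_blast_tab(blast_fixture["paths"]["hits"])
        tx_q = load_tx2gene(blast_fixture["paths"]["tx2gene_query"])
        tx_s = load_tx2gene(blast_fixture["paths"]["tx2gene_subject"])
        a = hits_to_gene_pairs(best_hit_per_query(filter_hits(hits)), tx_q, tx_s)
        b = hits_to_gene_pairs(best_hit_per_query(filter_hits(hits[::-1])), tx_q, tx_s)
        assert a == b


def test_reciprocal_filter_keeps_mutual_pairs():
    fwd = hits_to_gene_pairs([hit(q="t1", s="u1"), hit(q="t2", s="u2")],
                             {"t1": "GA", "t2": "GX"}, {"u1": "GB", "u2": "GY"})
    rev = hits_to_gene_pairs([hit(q="u1", s="t1")], {"u1": "GB"}, {"t1": "GA"})
    kept = reciprocal_filter(fwd, rev)
    assert [(p.gene_query, p.gene_subject) for p in kept] == [("GA", "GB")]
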