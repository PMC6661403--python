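"""The position-based pairing algorithm: interval arithmetic, the three
filtering steps, the duplicate filter and the composed pipeline."""

import random
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annoverlap.model import ENSEMBL, NCBI
from annoverlap.overlap import (
    CONTAINED,
    DIRECT_POSITIVE,
    DISMISSED_PREFILTER,
    DROPPED_DUPLICATE,
    IDENTICAL,
    PROTRUDING,
    REJECTED,
    RESCUED_POSITIVE,
    UNDECIDED,
    AorParams,
    OverlapCandidate,
    classify_direct,
    deduplicate,
    find_gene_overlaps,
    inner_outer_widths,
    interval_overlap_width,
    mean_feature_overlap,
    prefilter_protruding,
    rescue_by_features,
    run_overlap_pipeline,
)

from .conftest import ensembl_set, gene, iv, ncbi_set


# --- interval primitives -----------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((100, 200), (150, 250), 51),
        ((100, 200), (300, 400), 0),
        ((100, 200), (100, 200), 101),
        ((1, 1), (1, 1), 1),
    ],
)
def test_overlap_width_examples(a, b, expected):
    assert interval_overlap_width(iv("1", *a), iv("1", *b)) == expected


def test_overlap_width_zero_across_chromosomes_and_strands():
    assert interval_overlap_width(iv("1", 100, 200), iv("2", 100, 200)) == 0
    a, b = iv("1", 100, 200, "+"), iv("1", 100, 200, "-")
    assert interval_overlap_width(a, b, strand_mode="require_same") == 0
    assert interval_overlap_width(a, b) == 101


def _bases(lo, hi):
    return set(range(lo, hi + 1))


interval_st = st.tuples(st.integers(1, 500), st.integers(0, 120)).map(
    lambda t: (t[0], t[0] + t[1])
)


@settings(max_examples=300, derandomize=True)
@given(interval_st, interval_st)
def test_overlap_width_matches_base_enumeration(a, b):
    """Interval arithmetic equals brute-force enumeration of covered bases."""
    ia, ib = iv("1", *a), iv("1", *b)
    sa, sb = _bases(*a), _bases(*b)
    assert interval_overlap_width(ia, ib) == len(sa & sb)
    inner, outer = inner_outer_widths(ia, ib)
    assert inner == len(sa & sb)
    assert outer == max(sa | sb) - min(sa | sb) + 1


@settings(max_examples=300, derandomize=True)
@given(interval_st, interval_st)
def test_inner_outer_ratio_bounded_by_smaller_fraction(a, b):
    """Per-element inner/outer never exceeds intersection over smaller width."""
    ia, ib = iv("1", *a), iv("1", *b)
    inner, outer = inner_outer_widths(ia, ib)
    if inner:
        assert inner / outer <= inner / min(ia.width, ib.width)


# --- candidate search --------------------------------------------------------


class TestFindGeneOverlaps:
    def test_protruding_fraction_of_smaller_gene(self):
        n = ncbi_set(gene("N1", NCBI, "1", 100, 200))
        e = ensembl_set(gene("E1", ENSEMBL, "1", 150, 250))
        (c,) = find_gene_overlaps(n, e, AorParams())
        assert c.gene_overlap_frac == 51 / 101
        assert c.topology == PROTRUDING

    def test_contained_gene_scores_one(self):
        n = ncbi_set(gene("N1", NCBI, "1", 100, 200))
        e = ensembl_set(gene("E1", ENSEMBL, "1", 120, 180))
        (c,) = find_gene_overlaps(n, e, AorParams())
        assert c.gene_overlap_frac == 1.0
        assert c.topology == CONTAINED

    def test_identical_spans(self):
        n = ncbi_set(gene("N1", NCBI, "1", 100, 200))
        e = ensembl_set(gene("E1", ENSEMBL, "1", 100, 200))
        (c,) = find_gene_overlaps(n, e, AorParams())
        assert c.topology == IDENTICAL

    def test_different_chromosomes_yield_no_candidate(self):
        n = ncbi_set(gene("N1", NCBI, "1", 100, 200))
        e = ensembl_set(gene("E1", ENSEMBL, "2", 100, 200))
        assert find_gene_overlaps(n, e, AorParams()) == []


# --- filtering steps ---------------------------------------------------------


def _cand(frac, topology=PROTRUDING, decision=UNDECIDED, exon=None, cds=None,
          ncbi_id="N1", ensembl_id="E1"):
    return OverlapCandidate(
        ncbi_id=ncbi_id,
        ensembl_id=ensembl_id,
        gene_overlap_frac=frac,
        overlap_width=1,
        topology=topology,
        exon_mean_overlap=exon,
        cds_mean_overlap=cds,
        decision=decision,
    )


class TestPrefilter:
    def test_low_protruding_dismissed(self):
        (c,) = prefilter_protruding([_cand(11 / 101)], AorParams())
        assert c.decision == DISMISSED_PREFILTER

    def test_exactly_at_cutoff_retained(self):
        (c,) = prefilter_protruding([_cand(0.25)], AorParams())
        assert c.decision == UNDECIDED

    def test_contained_never_dismissed(self):
        (c,) = prefilter_protruding([_cand(1.0, topology=CONTAINED)], AorParams())
        assert c.decision == UNDECIDED


class TestDirectAcceptance:
    @pytest.mark.parametrize(
        "frac,expected",
        [(51 / 101, DIRECT_POSITIVE), (0.50, UNDECIDED), (1.0, DIRECT_POSITIVE)],
    )
    def test_strictly_above_half(self, frac, expected):
        (c,) = classify_direct([_cand(frac)], AorParams())
        assert c.decision == expected


class TestMeanFeatureOverlap:
    def test_single_pair_inner_over_outer(self):
        a = gene("N1", NCBI, "1", 1, 1000, exons=[(100, 150)])
        b = gene("E1", ENSEMBL, "1", 1, 1000, exons=[(120, 170)])
        assert mean_feature_overlap(a, b, "exon") == pytest.approx(31 / 71)

    def test_identical_exon_sets_mean_one(self):
        a = gene("N1", NCBI, "1", 1, 1000, exons=[(100, 150), (300, 400)])
        b = gene("E1", ENSEMBL, "1", 1, 1000, exons=[(100, 150), (300, 400)])
        assert mean_feature_overlap(a, b, "exon") == pytest.approx(1.0)

    def test_absent_when_one_side_has_no_features(self):
        a = gene("N1", NCBI, "1", 1, 1000, exons=[(100, 150)])
        b = gene("E1", ENSEMBL, "1", 1, 1000)
        assert mean_feature_overlap(a, b, "exon") is None

    def test_absent_when_no_element_pair_overlaps(self):
        a = gene("N1", NCBI, "1", 1, 1000, exons=[(100, 150)])
        b = gene("E1", ENSEMBL, "1", 1, 1000, exons=[(500, 600)])
        assert mean_feature_overlap(a, b, "exon") is None


class TestRescue:
    def test_exon_evidence_alone_rescues(self):
        (c,) = rescue_by_features([_cand(0.4, exon=0.80, cds=None)], AorParams())
        assert c.decision == RESCUED_POSITIVE

    def test_both_means_below_cutoff_rejected(self):
        (c,) = rescue_by_features([_cand(0.4, exon=31 / 71, cds=0.30)], AorParams())
        assert c.decision == REJECTED

    def test_exactly_half_rejected(self):
        (c,) = rescue_by_features([_cand(0.4, exon=0.50)], AorParams())
        assert c.decision == REJECTED

    def test_absent_means_never_rescue(self):
        (c,) = rescue_by_features([_cand(0.4)], AorParams())
        assert c.decision == REJECTED


class TestDeduplicate:
    def test_keeps_best_partner(self):
        cands = [
            _cand(0.9, decision=DIRECT_POSITIVE, ncbi_id="N1", ensembl_id="ENSX"),
            _cand(0.6, decision=DIRECT_POSITIVE, ncbi_id="N2", ensembl_id="ENSX"),
        ]
        pairs, dropped = deduplicate(cands)
        assert [(p.ncbi_id, p.ensembl_id) for p in pairs] == [("N1", "ENSX")]
        assert [d.decision for d in dropped] == [DROPPED_DUPLICATE]

    def test_no_duplicates_unchanged(self):
        cands = [
            _cand(0.9, decision=DIRECT_POSITIVE, ncbi_id="N1", ensembl_id="E1"),
            _cand(0.6, decision=DIRECT_POSITIVE, ncbi_id="N2", ensembl_id="E2"),
        ]
        pairs, dropped = deduplicate(cands)
        assert len(pairs) == 2 and not dropped

    def test_full_tie_breaks_lexicographically(self):
        cands = [
            _cand(0.8, decision=DIRECT_POSITIVE, ncbi_id="N1", ensembl_id="ENSB"),
            _cand(0.8, decision=DIRECT_POSITIVE, ncbi_id="N1", ensembl_id="ENSA"),
        ]
        pairs, _ = deduplicate(cands)
        assert [(p.ncbi_id, p.ensembl_id) for p in pairs] == [("N1", "ENSA")]

    def test_rejects_non_positive_input(self):
        with pytest.raises(ValueError):
            deduplicate([_cand(0.4, decision=REJECTED)])


# --- composed pipeline -------------------------------------------------------


class TestPipeline:
    def test_planted_scenario_recovered_exactly(self, scenario, aor_result):
        truth = scenario["truth"]
        pairs, ledger, stats = aor_result
        expected = set(
            truth[truth.expected_pair == 1][["ncbi_id", "ensembl_id"]]
            .itertuples(index=False, name=None)
        )
        got = {(p.ncbi_id, p.ensembl_id) for p in pairs}
        assert got == expected
        assert stats.n_validated >= stats.n_pairs == len(pairs)

    def test_candidate_decisions_match_truth(self, scenario, aor_result):
        truth = scenario["truth"]
        _, ledger, _ = aor_result
        decisions = {(c.ncbi_id, c.ensembl_id): c.decision for c in ledger}
        for row in truth.itertuples():
            if row.expected_decision == "none":
                assert (row.ncbi_id, row.ensembl_id) not in decisions
            else:
                assert decisions[(row.ncbi_id, row.ensembl_id)] == row.expected_decision

    def test_lookup_table_is_one_to_one(self, aor_result):
        pairs, _, _ = aor_result
        ncbi_ids = [p.ncbi_id for p in pairs]
        ens_ids = [p.ensembl_id for p in pairs]
        assert len(set(ncbi_ids)) == len(ncbi_ids)
        assert len(set(ens_ids)) == len(ens_ids)

    def test_gene_order_invariance(self, scenario_sets):
        ncbi, ens = scenario_sets
        pairs_a, _, _ = run_overlap_pipeline(ncbi, ens)
        rng = random.Random(3)
        ncbi_shuffled = ncbi_set(*sorted(ncbi.genes, key=lambda g: rng.random()),
                                 assembly=ncbi.assembly)
        ens_shuffled = ensembl_set(*sorted(ens.genes, key=lambda g: rng.random()),
                                   assembly=ens.assembly)
        pairs_b, _, _ = run_overlap_pipeline(ncbi_shuffled, ens_shuffled)
        assert pairs_a == pairs_b

    def test_empty_ensembl_set_warns_and_returns_nothing(self):
        n = ncbi_set(gene("N1", NCBI, "1", 100, 200))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            pairs, _, stats = run_overlap_pipeline(n, ensembl_set())
        assert pairs == []
        assert stats.pct_ensembl_assigned == 0.0
        assert any("empty" in str(w.message) for w in caught)

    def test_raising_thresholds_never_adds_validated_pairs(self, scenario_sets):
        ncbi, ens = scenario_sets
        grid = [0.2, 0.35, 0.5]
        counts = {}
        for mp in grid:
            for da in grid:
                for fa in grid:
                    _, _, stats = run_overlap_pipeline(
                        ncbi, ens,
                        AorParams(min_protruding_frac=mp, direct_accept_frac=da,
                                  feature_accept_frac=fa),
                    )
                    counts[(mp, da, fa)] = stats.n_validated
        for axis in range(3):
            for key, n in counts.items():
                for higher in grid:
                    if higher > key[axis]:
                        key2 = list(key)
                        key2[axis] = higher
                        assert counts[tuple(key2)] <= n
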