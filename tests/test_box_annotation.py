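import pytest
from hypothesis import given, settings, strategies as st

from snokturn.box_annotation import (
    annotate_record,
    find_box_c,
    find_box_cprime,
    find_box_d,
    mismatches_to_box_c,
    score_stem2,
    window_offset,
)
from snokturn.sequence_io import SnoRNARecord


def _rec(seq):
    return SnoRNARecord(id="t", seq=seq)


class TestFindBoxC:
    def test_consensus_at_5prime_end(self):
        box = find_box_c(_rec("GUGAUGA" + "C" * 20))
        assert box.start == 0 and box.mismatches_to_consensus == 0

    def test_within_five_nt_allowance(self):
        box = find_box_c(_rec("CCAUGAUGA" + "C" * 20))
        assert box.start == 2 and box.window_seq == "AUGAUGA"

    def test_match_beyond_allowance_is_rejected(self):
        assert find_box_c(_rec("CCCCCCCAUGAUGA" + "C" * 10)) is None

    def test_one_mismatch_accepted_two_rejected(self):
        assert find_box_c(_rec("AUGAUCA" + "C" * 20)).mismatches_to_consensus == 1
        assert find_box_c(_rec("AUGAUCC" + "C" * 20)) is None

    def test_fewest_mismatches_wins_over_smaller_start(self):
        # offset 0 has 1 mismatch, offset 1 a perfect match
        box = find_box_c(_rec("CAUGAUGA" + "C" * 20))
        assert box.start == 1 and box.mismatches_to_consensus == 0


class TestFindBoxD:
    def test_terminal_box_d_near_3prime_end(self):
        seq = "G" * 30 + "CUGAUC"
        hits = find_box_d(_rec(seq), kind="D")
        assert len(hits) == 1 and hits[0].start == 30

    def test_3prime_most_ranked_first(self):
        seq = "G" * 25 + "CUGA" + "AA" + "CUGA" + "A"
        hits = find_box_d(_rec(seq), kind="D")
        assert [h.start for h in hits] == [31, 25]

    def test_known_guide_position_filters_to_plus_five(self):
        # CUGA at 10 and at 20; guide position 15 (0-based) keeps only 20
        seq = "A" * 10 + "CUGA" + "A" * 6 + "CUGA" + "A" * 10
        hits = find_box_d(_rec(seq), kind="Dprime", search_region=(0, len(seq)),
                          known_target_guide_pos=15)
        assert [h.start for h in hits] == [20]

    def test_region_without_motif_is_empty(self):
        assert find_box_d(_rec("A" * 40), kind="Dprime", search_region=(0, 40)) == []

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty search region"):
            find_box_d(_rec("A" * 20), kind="Dprime", search_region=(10, 10))


def _stem2_oracle(cw, dw):
    """Independent enumeration: pair (b_i, n_i) identities, antiparallel."""
    pairs = [(cw[2], dw[3]), (cw[3], dw[2]), (cw[4], dw[1]), (cw[5], dw[0])]
    canonical = [("G", "A"), ("A", "G"), ("U", "U"), ("G", "C")]
    return sum(p == c for p, c in zip(pairs, canonical))


class TestScoreStem2:
    @pytest.mark.parametrize(
        "cw,dw,expected",
        [
            ("AUGAUGA", "CUGA", 4),  # consensus vs consensus
            ("UACAUGU", "CUGA", 3),  # (C,A)x (A,G)ok (U,U)ok (G,C)ok
            ("AUGUGCA", "CUGA", 1),  # (G,A)ok (U,G)x (G,U)x (C,C)x
        ],
    )
    def test_printed_candidate_windows(self, cw, dw, expected):
        assert score_stem2(cw, dw) == expected
        assert _stem2_oracle(cw, dw) == expected

    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGUN", min_size=7, max_size=7),
           st.text(alphabet="ACGUN", min_size=4, max_size=4))
    def test_matches_enumeration_oracle(self, cw, dw):
        assert score_stem2(cw, dw) == _stem2_oracle(cw, dw)

    def test_wrong_window_length_errors(self):
        with pytest.raises(ValueError):
            score_stem2("AUGAUG", "CUGA")
        with pytest.raises(ValueError):
            score_stem2("AUGAUGA", "CUG")


def _cprime_test_record(interior):
    """Box C + guide + D' + interior + guide + box D, annotation-ready."""
    seq = "AUGAUGA" + "G" * 12 + "CUGA" + interior + "G" * 12 + "CUGA"
    return SnoRNARecord(id="t", seq=seq)


class TestFindBoxCprime:
    def test_snr41_situation_picks_higher_scoring_shifted_window(self):
        # the two printed candidates tile the region UACAUGUGCA; scores 3 vs 1
        rec = _cprime_test_record("CCCCCC" + "UACAUGUGCA" + "CC")
        dprime = find_box_d(rec, "Dprime", search_region=(7, len(rec.seq) - 16))[0]
        boxd = find_box_d(rec, "D")[0]
        cp = find_box_cprime(rec, dprime, boxd)
        assert cp.window_seq == "UACAUGU"
        assert cp.score == 3

    def test_selected_window_is_argmax_over_interval(self):
        rec = _cprime_test_record("CCCCCC" + "AUGAUGA" + "CC")
        dprime = find_box_d(rec, "Dprime", search_region=(7, len(rec.seq) - 16))[0]
        boxd = find_box_d(rec, "D")[0]
        cp = find_box_cprime(rec, dprime, boxd)
        best = max(
            score_stem2(rec.seq[s : s + 7], dprime.window_seq)
            for s in range(dprime.end + 3, boxd.start - 6 - 7 + 1)
        )
        assert cp.score == best == 4

    def test_interval_too_short_returns_none(self):
        rec = _cprime_test_record("CCC")
        dprime = find_box_d(rec, "Dprime", search_region=(7, len(rec.seq) - 16))[0]
        boxd = find_box_d(rec, "D")[0]
        assert find_box_cprime(rec, dprime, boxd) is None

    def test_no_credible_window_returns_none(self):
        # all-C interior and guide: no window can score >= 1 against CUGA
        seq = "AUGAUGA" + "G" * 12 + "CUGA" + "C" * 14 + "C" * 12 + "CUGA"
        rec = SnoRNARecord(id="t", seq=seq)
        dprime = find_box_d(rec, "Dprime", search_region=(7, 25))[0]
        boxd = find_box_d(rec, "D")[0]
        assert find_box_cprime(rec, dprime, boxd) is None


class TestWindowOffset:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("UUGAUGA", "AUGACUA", 3),  # crystal re-annotation shift
            ("UACAUGU", "AUGUGCA", 3),  # snR41 candidate windows
            ("AUGAUGA", "AUGAUGA", 0),
        ],
    )
    def test_printed_pairs(self, a, b, expected):
        assert window_offset(a, b) == expected

    def test_no_tiling_returns_none(self):
        assert window_offset("AAAAAAA", "CCCCCCC") is None

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            window_offset("AUGA", "AUGAU")

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=4, max_size=8))
    def test_self_offset_is_zero(self, w):
        assert window_offset(w, w) == 0

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="AC", min_size=5, max_size=7),
           st.text(alphabet="AC", min_size=5, max_size=7))
    def test_symmetry_under_region_reversal(self, a, b):
        """Reversing the tiled region (both windows, swapped) preserves the
        shift: a 3' shift of b relative to a becomes a 3' shift of
        reversed(a) relative to reversed(b)."""
        if len(a) != len(b):
            return
        assert window_offset(a, b) == window_offset(b[::-1], a[::-1])


class TestAnnotationInvariants:
    def test_boxes_ordered_and_non_overlapping(self, small_benchmark):
        for lr in small_benchmark:
            ann = annotate_record(lr.record)
            boxes = ann.boxes
            for earlier, later in zip(boxes, boxes[1:]):
                assert earlier.end <= later.start
            kinds = [b.box_kind for b in boxes]
            assert kinds == [k for k in ("C", "Dprime", "Cprime", "D") if k in kinds]

    def test_consensus_cprime_implies_both_sheared_pairs(self, small_benchmark):
        """FeatureSet invariant on pipeline output (box D' is exact CUGA)."""
        for lr in small_benchmark:
            ann = annotate_record(lr.record)
            f = ann.internal_features
            if f is not None and f.cprime_consensus and f.dprime_consensus:
                assert f.has_sheared_1 and f.has_sheared_2
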