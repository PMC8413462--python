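import numpy as np
import pytest

from snokturn.box_annotation import BoxAnnotation
from snokturn.kturn_model import PairType, classify_pair
from snokturn.methylation_targeting import (
    find_guide_duplex,
    predict_methylation_site,
    validate_prediction,
)
from snokturn.sequence_io import SnoRNARecord


def _box_d(start):
    return BoxAnnotation("D", start, start + 4, "CUGA")


# toy duplex: guide ACGUACGUACGU at 1-based 10-21, box D CUGA at 22-25,
# substrate GG + reverse complement + GG -> duplex with substrate 3-14
TOY_REC = SnoRNARecord(id="toy", seq="AAAAAAAAA" + "ACGUACGUACGU" + "CUGA" + "AAA")
TOY_BOX = _box_d(21)  # 0-based start of CUGA (1-based 22)
TOY_SUB = "GG" + "ACGUACGUACGU" + "GG"


class TestFindGuideDuplex:
    def test_toy_exact_reverse_complement(self):
        dup = find_guide_duplex(TOY_REC, TOY_BOX, "sub", TOY_SUB)
        assert dup.length == 12
        assert dup.guide_range == (9, 21)  # 1-based 10..21
        assert dup.substrate_range == (2, 14)  # 1-based 3..14

    def test_no_complementarity_returns_none(self):
        assert find_guide_duplex(TOY_REC, TOY_BOX, "sub", "A" * 16) is None

    def test_below_min_len_returns_none(self):
        # only the last 6 guide nt pair
        sub = "GG" + "ACGUAC" + "CCCCCCCC"
        assert find_guide_duplex(TOY_REC, TOY_BOX, "sub", sub) is None

    def test_all_wc_placement_beats_wobble_on_tie(self):
        rec = SnoRNARecord(id="t", seq="AAAA" + "GGGGGGGG" + "CUGA")
        box = _box_d(12)
        # two length-8 placements: CCCCCCCC (all WC) and UUUUUUUU (all wobble)
        sub = "CCCCCCCC" + "AA" + "UUUUUUUU"
        dup = find_guide_duplex(rec, box, "sub", sub)
        assert dup.substrate_range == (0, 8)

    def test_wobble_disallowed_shortens_duplex(self):
        rec = SnoRNARecord(id="t", seq="AAAA" + "GGGGGGGG" + "CUGA")
        dup = find_guide_duplex(rec, _box_d(12), "sub", "UUUUUUUUCCCC",
                                allow_wobble=False, min_len=4)
        assert dup.length == 4  # only the C-run pairs without wobble

    def test_pair_map_is_antiparallel_monotonic(self):
        dup = find_guide_duplex(TOY_REC, TOY_BOX, "sub", TOY_SUB)
        guides = [g for g, _ in dup.pair_map]
        subs = [s for _, s in dup.pair_map]
        assert guides == sorted(guides)
        assert subs == sorted(subs, reverse=True)
        assert dup.length == len(dup.pair_map)


def _oracle_duplex(guide_region, substrate, min_len=8, allow_wobble=True):
    """Brute force: enumerate every (anchor, length) contiguous pairing."""
    ok = {PairType.WC} | ({PairType.WOBBLE} if allow_wobble else set())
    g0 = len(guide_region) - 1
    best = None  # (-length, n_wobble, t)
    for t in range(len(substrate)):
        for length in range(1, min(g0 + 1, len(substrate) - t) + 1):
            pairs = [(guide_region[g0 - k], substrate[t + k]) for k in range(length)]
            if not all(classify_pair(a, b) in ok for a, b in pairs):
                continue
            wob = sum(classify_pair(a, b) is PairType.WOBBLE for a, b in pairs)
            key = (-length, wob, t)
            if best is None or key < best:
                best = key
    if best is None or -best[0] < min_len:
        return None
    return (-best[0], best[2])


@pytest.mark.parametrize("allow_wobble", [True, False])
def test_duplex_search_equals_brute_force_oracle(allow_wobble):
    rng = np.random.default_rng(2024)
    nt = np.array(list("ACGU"))
    for _ in range(300):
        guide_region = "".join(rng.choice(nt, size=rng.integers(8, 16)))
        substrate = "".join(rng.choice(nt, size=rng.integers(10, 30)))
        rec = SnoRNARecord(id="r", seq=guide_region + "CUGA")
        box = _box_d(len(guide_region))
        got = find_guide_duplex(rec, box, "s", substrate, min_len=3,
                                allow_wobble=allow_wobble)
        want = _oracle_duplex(guide_region, substrate, min_len=3,
                              allow_wobble=allow_wobble)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert (got.length, got.substrate_range[0]) == want


class TestPredictSite:
    def test_toy_fifth_nucleotide_rule(self):
        dup = find_guide_duplex(TOY_REC, TOY_BOX, "sub", TOY_SUB)
        # box D starts at 1-based 22; guide position 17 pairs substrate 7
        site = predict_methylation_site(dup, TOY_BOX, rec=TOY_REC, substrate_seq=TOY_SUB)
        assert site == 7

    def test_unpaired_target_position_errors(self):
        # duplex covers only the last 3 guide nt; position box.start-5 unpaired
        sub = "GGACG" + "C" * 11
        dup = find_guide_duplex(TOY_REC, TOY_BOX, "sub", sub, min_len=3)
        assert dup.length == 3
        with pytest.raises(ValueError, match="target outside duplex"):
            predict_methylation_site(dup, TOY_BOX)

    def test_wobble_at_target_position_rejected_by_default(self):
        # replace the substrate partner of the target with a wobble pair:
        # guide position 17 (1-based) is U; partner becomes G (U•G wobble)
        sub = TOY_SUB[:6] + "G" + TOY_SUB[7:]
        dup = find_guide_duplex(TOY_REC, TOY_BOX, "sub", sub, min_len=8)
        with pytest.raises(ValueError, match="wobble"):
            predict_methylation_site(dup, TOY_BOX, rec=TOY_REC, substrate_seq=sub)
        assert predict_methylation_site(dup, TOY_BOX, rec=TOY_REC, substrate_seq=sub,
                                        allow_wobble_at_target=True) == 7

    def test_validation_flag(self):
        assert validate_prediction(7, 7) == "consistent"
        assert validate_prediction(7, 8) == "inconsistent"


def test_round_trip_on_generated_records(small_benchmark):
    """Predicted site equals the planted target for every generated record."""
    from snokturn.box_annotation import annotate_record

    checked = 0
    for lr in small_benchmark:
        ann = annotate_record(lr.record)
        for st_truth in lr.substrates.values():
            box = ann.box_d if st_truth.box_kind == "D" else ann.box_dprime
            assert box is not None
            dup = find_guide_duplex(lr.record, box, st_truth.substrate_id, st_truth.seq)
            assert dup is not None
            assert dup.length >= sum(
                1 for g, s in dup.pair_map
            ) == dup.length  # length == count of paired positions
            site = predict_methylation_site(dup, box, rec=lr.record,
                                            substrate_seq=st_truth.seq)
            assert site == st_truth.target_pos
            checked += 1
    assert checked > 0
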