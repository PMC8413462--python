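"""Labelled synthetic snoRNA benchmark generator.

Emulates the methylation-guide snoRNA architecture

    5'-[tail]-boxC-[guide1]-boxD'-[stem I / loop]-boxC'-[guide2]-boxD-[tail]-3'

with controllable internal-motif categories (consensus, functional
non-canonical, tandem sheared pairs without stem I, missing a sheared pair,
or no motif at all) and matched substrate RNAs whose planted methylation
target sits at the fifth guide nucleotide upstream of the box.

Every record is rejection-sampled until its planted motifs are unambiguous:
no spurious CUGA occurs anywhere, no competing box C' window ties or beats
the planted stem-II score in the annotation interval, the planted box C is
the best 5'-proximal RUGAUGA match, and each guide–substrate duplex has a
unique best anchor.  This makes "100% recovery on unambiguous records" a
well-defined property of the annotation pipeline, not of luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .box_annotation import mismatches_to_box_c, score_stem2
from .functional_classification import Category
from .kturn_model import FeatureSet, KTurnFrame, build_frame, evaluate_features
from .sequence_io import KnownTarget, SnoRNARecord, write_rna_records

NT = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

CATEGORY_ORDER = (
    Category.CANONICAL,
    Category.FUNCTIONAL_NONCANONICAL,
    Category.TANDEM_NO_STEM1,
    Category.MISSING_SHEARED,
    Category.NO_MOTIF,
)

#: default category proportions: the yeast box C/D methylation-guide census
#: (2 canonical, 6 functional non-canonical, 18 without stem I, 17 missing a
#: sheared pair, out of 43)
DEFAULT_CATEGORY_MIX = {
    Category.CANONICAL: 2 / 43,
    Category.FUNCTIONAL_NONCANONICAL: 6 / 43,
    Category.TANDEM_NO_STEM1: 18 / 43,
    Category.MISSING_SHEARED: 17 / 43,
    Category.NO_MOTIF: 0.0,
}

#: non-consensus (L2, L3) choices for the box C' window that keep the b-side
#: GAUGA intact; (C, U) is excluded because it would spell a spurious CUGA
_NONCONSENSUS_L2L3 = (
    ("U", "U"),
    ("A", "A"), ("A", "C"), ("A", "G"),
    ("G", "A"), ("G", "C"), ("G", "G"),
)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class GenerationSpec:
    """Stated world of the generator; defaults follow the yeast census."""

    seed: int
    n: int
    category_mix: Optional[dict[Category, float]] = None
    guide_len_D: int = 12
    guide_len_Dprime: int = 12
    stem1_len: int = 2  # extra stem-I pairs beyond the -1/-2 core
    loop_len: int = 4  # terminal loop closing the internal stem I
    kloop_fraction: float = 0.5  # of TANDEM_NO_STEM1 records, fraction with both -1/-2 broken
    tail_max: int = 3  # max random tail length at either end

    def __post_init__(self) -> None:
        if self.category_mix is None:
            self.category_mix = dict(DEFAULT_CATEGORY_MIX)
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1, got {total}")
        if self.guide_len_D < 8 or self.guide_len_Dprime < 8:
            raise ValueError("guide lengths must be >= 8 nt")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.stem1_len < 0 or self.loop_len < 3:
            raise ValueError("stem1_len must be >= 0 and loop_len >= 3")
        if not 0.0 <= self.kloop_fraction <= 1.0:
            raise ValueError("kloop_fraction must be within [0, 1]")


@dataclass
class SubstrateTruth:
    """A substrate RNA with its planted methylation target."""

    substrate_id: str
    seq: str
    target_pos: int  # 1-based on the substrate
    guide_range: tuple[int, int]  # 0-based half-open on the snoRNA
    box_kind: str  # "D" or "Dprime"


@dataclass
class LabeledRecord:
    """A generated snoRNA with full ground truth."""

    record: SnoRNARecord
    category: Category
    boxes: dict[str, tuple[int, int]]  # kind -> 0-based half-open
    internal_frame: Optional[KTurnFrame]
    features: Optional[FeatureSet]
    substrates: dict[str, SubstrateTruth] = field(default_factory=dict)
    edits: list[tuple[int, str, str]] = field(default_factory=list)


def apportion(mix: dict[Category, float], n: int) -> dict[Category, int]:
    """Largest-remainder apportionment of n records over the categories."""
    quotas = [(cat, n * mix.get(cat, 0.0)) for cat in CATEGORY_ORDER]
    counts = {cat: int(np.floor(q)) for cat, q in quotas}
    remainder = n - sum(counts.values())
    by_frac = sorted(
        quotas, key=lambda cq: (-(cq[1] - np.floor(cq[1])), CATEGORY_ORDER.index(cq[0]))
    )
    for cat, _ in by_frac[:remainder]:
        counts[cat] += 1
    return counts


def _rand_nt(rng: np.random.Generator, k: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=k))


def _cuga_positions(seq: str) -> set[int]:
    return {i for i in range(len(seq) - 3) if seq[i : i + 4] == "CUGA"}


def _stem1_block(rng: np.random.Generator, s: int, loop_len: int,
                 minus1_intact: bool, minus2_intact: bool) -> tuple[str, str, str]:
    """n-side, loop, and b-side segments of the internal stem I.

    Returns (n_segment, loop, b_segment) where n_segment = minus1_n,
    minus2_n, extra…, and b_segment is laid out 5'→3' ending with minus2_b,
    minus1_b (the b strand runs antiparallel to the n strand).  A broken
    pair puts the same nucleotide on both sides (never WC nor wobble).
    """
    m1n, m2n = _rand_nt(rng, 1), _rand_nt(rng, 1)
    m1b = _COMPLEMENT[m1n] if minus1_intact else m1n
    m2b = _COMPLEMENT[m2n] if minus2_intact else m2n
    extra_n = _rand_nt(rng, s)
    extra_b = revcomp(extra_n)
    loop = _rand_nt(rng, loop_len)
    n_segment = m1n + m2n + extra_n
    b_segment = extra_b + m2b + m1b
    return n_segment, loop, b_segment


def _cprime_window(rng: np.random.Generator, category: Category) -> str:
    """Plant the 7-mer box C'-like window realising the requested category."""
    if category == Category.CANONICAL:
        return rng.choice(["A", "G"]) + "UGAUGA"
    if category in (Category.FUNCTIONAL_NONCANONICAL, Category.TANDEM_NO_STEM1):
        l2, l3 = _NONCONSENSUS_L2L3[rng.integers(0, len(_NONCONSENSUS_L2L3))]
        return l2 + l3 + "GAUGA"
    if category == Category.MISSING_SHEARED:
        l2 = rng.choice(["A", "G"])
        if rng.random() < 0.5:  # break the 1b•1n G•A pair
            b1 = rng.choice(["A", "C", "U"])
            return l2 + "U" + b1 + "AUGA"
        b2 = rng.choice(["G", "U"])  # break the 2b•2n A•G pair ("C" would spell CUGA)
        return l2 + "UG" + b2 + "UGA"
    raise ValueError(f"no box C' window for category {category}")


def _intended_features(category: Category, window: str,
                       minus1: bool, minus2: bool) -> Optional[FeatureSet]:
    if category == Category.NO_MOTIF:
        return None
    s1 = window[2] == "G"
    s2 = window[3] == "A"
    return FeatureSet(
        has_sheared_1=s1,
        has_sheared_2=s2,
        stem1_minus1=minus1,
        stem1_minus2=minus2,
        is_kloop=not minus1 and not minus2,
        cprime_consensus=window[0] in "AG" and window[1:] == "UGAUGA",
        dprime_consensus=True,
        stem2_score=score_stem2(window, "CUGA"),
    )


def _duplex_runs(guide_region: str, substrate: str) -> list[int]:
    """Run length of contiguous WC/wobble pairing at each substrate anchor.

    The 3'-most guide nucleotide anchors substrate position t and the run
    extends guide-5'-wards / substrate-3'-wards (antiparallel duplex).
    Deliberately written as direct arithmetic, independent of the
    methylation-targeting module it guards.
    """
    ok_pairs = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
    runs = []
    g0 = len(guide_region) - 1
    for t in range(len(substrate)):
        k = 0
        while g0 - k >= 0 and t + k < len(substrate) and \
                (guide_region[g0 - k], substrate[t + k]) in ok_pairs:
            k += 1
        runs.append(k)
    return runs


def _build_substrate(rng: np.random.Generator, snorna_seq: str, box_start: int,
                     guide_len: int, box_kind: str, substrate_id: str) -> Optional[SubstrateTruth]:
    """Substrate = 2-nt flank + reverse complement of the guide + 2-nt flank.

    The methylation target is the substrate nucleotide paired with guide
    position box_start − 5 (1-based), i.e. substrate position 7 under the
    2-nt 5' flank.  Returns None when the flanks make the duplex anchor
    ambiguous (caller regenerates).
    """
    guide = snorna_seq[box_start - guide_len : box_start]
    core = revcomp(guide)
    substrate = _rand_nt(rng, 2) + core + _rand_nt(rng, 2)
    runs = _duplex_runs(snorna_seq[:box_start], substrate)
    planted_run = runs[2]
    if planted_run < guide_len:  # cannot happen by construction, but be safe
        return None
    if any(r >= planted_run for t, r in enumerate(runs) if t != 2):
        return None
    return SubstrateTruth(
        substrate_id=substrate_id,
        seq=substrate,
        target_pos=7,  # 2-nt flank + fifth nucleotide of the reversed guide
        guide_range=(box_start - guide_len, box_start),
        box_kind=box_kind,
    )


def _attempt_record(rng: np.random.Generator, idx: int, category: Category,
                    spec: GenerationSpec) -> Optional[LabeledRecord]:
    s, l = spec.stem1_len, spec.loop_len
    g1, g2 = spec.guide_len_Dprime, spec.guide_len_D
    t5 = int(rng.integers(0, spec.tail_max + 1))
    t3 = int(rng.integers(0, spec.tail_max + 1))
    tail5, tail3 = _rand_nt(rng, t5), _rand_nt(rng, t3)
    box_c = str(rng.choice(["A", "G"])) + "UGAUGA"

    if category == Category.NO_MOTIF:
        filler_len = g1 + 4 + (2 + s) + l + (s + 2) + 1 + 7
        internal = _rand_nt(rng, filler_len)
        minus1 = minus2 = False
        window = None
    else:
        if category == Category.TANDEM_NO_STEM1:
            minus1 = False
            minus2 = not (rng.random() < spec.kloop_fraction)
        else:
            minus1 = minus2 = True
        guide1 = _rand_nt(rng, g1)
        n_seg, loop, b_seg = _stem1_block(rng, s, l, minus1, minus2)
        L1 = _rand_nt(rng, 1)
        window = _cprime_window(rng, category)
        internal = guide1 + "CUGA" + n_seg + loop + b_seg + L1 + window

    guide2 = _rand_nt(rng, g2)
    seq = tail5 + box_c + internal + guide2 + "CUGA" + tail3
    box_d_start = len(tail5) + 7 + len(internal) + g2

    boxes: dict[str, tuple[int, int]] = {
        "C": (t5, t5 + 7),
        "D": (box_d_start, box_d_start + 4),
    }
    expected_cuga = {box_d_start}
    c_start = d_start = None
    if category != Category.NO_MOTIF:
        d_start = t5 + 7 + g1
        c_start = d_start + 4 + (2 + s) + l + (s + 2) + 1
        boxes["Dprime"] = (d_start, d_start + 4)
        boxes["Cprime"] = (c_start, c_start + 7)
        expected_cuga.add(d_start)

    # --- ambiguity guard -------------------------------------------------
    if _cuga_positions(seq) != expected_cuga:
        return None
    for off in range(t5):  # earlier windows must not tie the planted box C
        if mismatches_to_box_c(seq[off : off + 7]) == 0:
            return None
    frame = features = None
    if category != Category.NO_MOTIF:
        planted_score = score_stem2(seq[c_start : c_start + 7], "CUGA")
        first = d_start + 4 + 3
        last = box_d_start - 6 - 7
        for w in range(first, last + 1):
            if w == c_start:
                continue
            if score_stem2(seq[w : w + 7], "CUGA") >= planted_score:
                return None
        frame = build_frame(seq, c_start, d_start, "internal")
        features = evaluate_features(frame, seq)
        intended = _intended_features(category, window, minus1, minus2)
        if features != intended:  # generator self-consistency; never expected
            raise AssertionError(
                f"planted features disagree with re-derived features for {category}"
            )

    rec_id = f"synth{idx:04d}"
    substrates: dict[str, SubstrateTruth] = {}
    sub_d = _build_substrate(rng, seq, box_d_start, g2, "D", f"{rec_id}_subD")
    if sub_d is None:
        return None
    substrates["D"] = sub_d
    if category != Category.NO_MOTIF:
        sub_dp = _build_substrate(rng, seq, d_start, g1, "Dprime", f"{rec_id}_subDp")
        if sub_dp is None:
            return None
        substrates["Dprime"] = sub_dp

    record = SnoRNARecord(
        id=rec_id,
        seq=seq,
        known_targets=[
            KnownTarget(st.substrate_id, st.target_pos, st.box_kind)
            for st in substrates.values()
        ],
        source=f"synthetic category={category.value}",
    )
    return LabeledRecord(
        record=record,
        category=category,
        boxes=boxes,
        internal_frame=frame,
        features=features,
        substrates=substrates,
    )


def generate_snorna(spec: GenerationSpec) -> list[LabeledRecord]:
    """Generate n labelled records; deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    counts = apportion(spec.category_mix, spec.n)
    out: list[LabeledRecord] = []
    idx = 0
    for cat in CATEGORY_ORDER:
        for _ in range(counts[cat]):
            for _attempt in range(500):
                lr = _attempt_record(rng, idx, cat, spec)
                if lr is not None:
                    break
            else:
                raise RuntimeError(f"could not generate an unambiguous {cat} record")
            out.append(lr)
            idx += 1
    return out


# --- construct-style edits (kl-panel analogues) ---------------------------

EDITS = (
    "introduce_sheared2",
    "remove_minus1",
    "stem1_to_loop",
    "introduce_sheared2_drop_minus1",
)


def _break_pair(seq: list[str], b_idx: int, n_idx: int) -> None:
    """Break a stem-I pair by copying the n-side nucleotide onto the b side."""
    seq[b_idx] = seq[n_idx]


def apply_construct_edit(rec: LabeledRecord, edit: str) -> LabeledRecord:
    """Minimal nucleotide substitutions realising a construct-style edit.

    * ``introduce_sheared2`` — create the 2b•2n A•G pair (kl2 analogue);
    * ``remove_minus1`` — break the −1 stem-I pair (kl4 analogue combined
      with the previous edit);
    * ``stem1_to_loop`` — break both −1 and −2 pairs (kl3 analogue);
    * ``introduce_sheared2_drop_minus1`` — both at once (kl4 analogue).

    Inapplicable edits (the feature is already present/absent) raise.  Truth
    labels are recomputed from the edited sequence.
    """
    if edit not in EDITS:
        raise ValueError(f"unknown edit {edit!r}")
    if rec.internal_frame is None or rec.features is None:
        raise ValueError("record has no internal motif to edit")
    frame, feats = rec.internal_frame, rec.features
    seq = list(rec.record.seq)
    before = rec.record.seq
    if edit in ("introduce_sheared2", "introduce_sheared2_drop_minus1"):
        if feats.has_sheared_2:
            raise ValueError("2b•2n A•G pair already present")
        seq[frame.b2] = "A"
        seq[frame.n2] = "G"
    if edit == "remove_minus1":
        if not feats.stem1_minus1:
            raise ValueError("-1 stem-I pair already broken or absent")
        _break_pair(seq, frame.minus1_b, frame.minus1_n)
    if edit == "introduce_sheared2_drop_minus1":
        if not feats.stem1_minus1:
            raise ValueError("-1 stem-I pair already broken or absent")
        _break_pair(seq, frame.minus1_b, frame.minus1_n)
    if edit == "stem1_to_loop":
        if feats.is_kloop:
            raise ValueError("stem I is already a loop")
        if feats.stem1_minus1:
            _break_pair(seq, frame.minus1_b, frame.minus1_n)
        if feats.stem1_minus2:
            _break_pair(seq, frame.minus2_b, frame.minus2_n)
    new_seq = "".join(seq)
    subs = [(i, before[i], new_seq[i]) for i in range(len(seq)) if before[i] != new_seq[i]]
    new_record = replace(rec.record, seq=new_seq)
    new_features = evaluate_features(frame, new_seq)
    from .functional_classification import classify_motif  # local to avoid cycle

    new_category = classify_motif(new_features).category
    return LabeledRecord(
        record=new_record,
        category=new_category,
        boxes=dict(rec.boxes),
        internal_frame=frame,
        features=new_features,
        substrates=dict(rec.substrates),
        edits=rec.edits + subs,
    )


def revert_last_edit(rec: LabeledRecord, n_subs: int) -> LabeledRecord:
    """Undo the last ``n_subs`` recorded substitutions (involution check)."""
    if len(rec.edits) < n_subs:
        raise ValueError("fewer recorded substitutions than requested")
    seq = list(rec.record.seq)
    for pos, old, _new in reversed(rec.edits[-n_subs:]):
        seq[pos] = old
    new_seq = "".join(seq)
    new_record = replace(rec.record, seq=new_seq)
    frame = rec.internal_frame
    feats = evaluate_features(frame, new_seq) if frame else None
    from .functional_classification import classify_motif

    cat = classify_motif(feats).category if feats else rec.category
    return LabeledRecord(
        record=new_record,
        category=cat,
        boxes=dict(rec.boxes),
        internal_frame=frame,
        features=feats,
        substrates=dict(rec.substrates),
        edits=rec.edits[:-n_subs],
    )


# --- serialisation --------------------------------------------------------

def write_benchmark(records: list[LabeledRecord], outdir: str | Path) -> dict[str, Path]:
    """Write snoRNA FASTA, substrate FASTA and a 1-based truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sno_path = outdir / "snornas.fasta"
    sub_path = outdir / "substrates.fasta"
    truth_path = outdir / "truth.tsv"
    targets_path = outdir / "targets.tsv"
    write_rna_records([lr.record for lr in records], sno_path)
    subs = [
        SnoRNARecord(id=st.substrate_id, seq=st.seq, source="synthetic substrate")
        for lr in records
        for st in lr.substrates.values()
    ]
    write_rna_records(subs, sub_path)
    with open(truth_path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("snoRNA_id\tcategory\t" + "\t".join(
            f"box_{k}_start\tbox_{k}_end" for k in ("C", "Dprime", "Cprime", "D")
        ) + "\n")
        for lr in records:
            cells = [lr.record.id, lr.category.value]
            for k in ("C", "Dprime", "Cprime", "D"):
                if k in lr.boxes:
                    s, e = lr.boxes[k]
                    cells += [str(s + 1), str(e)]
                else:
                    cells += ["NA", "NA"]
            fh.write("\t".join(cells) + "\n")
    with open(targets_path, "w") as fh:
        fh.write("snoRNA_id\tsubstrate_id\tposition\tbox_kind\n")
        for lr in records:
            for st in lr.substrates.values():
                fh.write(f"{lr.record.id}\t{st.substrate_id}\t{st.target_pos}\t{st.box_kind}\n")
    return {"snornas": sno_path, "substrates": sub_path, "truth": truth_path,
            "targets": targets_path}
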