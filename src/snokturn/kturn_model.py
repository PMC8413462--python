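"""K-turn coordinate frame, base-pair types, and structural features.

A box C/D (or box C'/D') k-turn is built from a 7-mer box C-like window and
a 4-mer box D-like window on the same strand.  Nucleotides are named after
their structural role:

* stem II pairs ``1b•1n`` … ``4b•4n`` count outward from the kink; the
  kink-proximal ``1b•1n`` (G•A) and ``2b•2n`` (A•G) are the tandem sheared
  pairs characteristic of k-turns;
* stem I pairs are numbered ``−1``, ``−2`` outward from the loop;
* ``L1–L3`` are the bulged loop nucleotides on the box C-like strand.

On the consensus windows 5'-RUGAUGA (box C/C') and 5'-CUGA (box D/D') the
roles map as: box C window = (L2, L3, 1b, 2b, 3b, 4b, 5b) and box D window =
(4n, 3n, 2n, 1n).  The two strands are antiparallel: ascending b-positions
pair descending n-positions.  In a k-loop, stem I is replaced by a loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

BOX_C_CONSENSUS = "RUGAUGA"  # R = A or G
BOX_D_CONSENSUS = "CUGA"

#: canonical stem-II pair identities (b-side, n-side), kink-proximal first
CANONICAL_STEM2_PAIRS = {
    1: ("G", "A"),  # sheared G•A
    2: ("A", "G"),  # sheared A•G
    3: ("U", "U"),
    4: ("G", "C"),
}


class PairType(Enum):
    WC = "WC"
    WOBBLE = "WOBBLE"
    SHEARED_GA = "SHEARED_GA"
    SHEARED_AG = "SHEARED_AG"
    OTHER = "OTHER"
    ABSENT = "ABSENT"


_WC = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
_WOBBLE = {("G", "U"), ("U", "G")}


def classify_pair(b_nt: Optional[str], n_nt: Optional[str]) -> PairType:
    """Classify an ordered (b-side, n-side) nucleotide pair.

    Total function: any pair containing N or an absent (None) position is
    ABSENT; sheared pairs are the strict identity checks (G,A) and (A,G).
    """
    if b_nt is None or n_nt is None or b_nt == "N" or n_nt == "N":
        return PairType.ABSENT
    pair = (b_nt, n_nt)
    if pair in _WC:
        return PairType.WC
    if pair in _WOBBLE:
        return PairType.WOBBLE
    if pair == ("G", "A"):
        return PairType.SHEARED_GA
    if pair == ("A", "G"):
        return PairType.SHEARED_AG
    return PairType.OTHER


@dataclass(frozen=True)
class KTurnFrame:
    """Index map from k-turn positions onto 0-based sequence coordinates.

    ``c_start`` is the start of the 7-mer box C-like window, ``d_start`` the
    start of the 4-mer box D-like window.  Slots that fall outside the
    sequence are ``None`` (absent); the core slots b1–b5 and n1–n4 are always
    inside the sequence (construction fails otherwise).
    """

    c_start: int
    d_start: int
    seq_len: int
    motif_kind: str  # "terminal" or "internal"

    def _clip(self, i: int) -> Optional[int]:
        return i if 0 <= i < self.seq_len else None

    # --- box C-like strand -------------------------------------------------
    @property
    def L2(self) -> int:
        return self.c_start

    @property
    def L3(self) -> int:
        return self.c_start + 1

    @property
    def b1(self) -> int:
        return self.c_start + 2

    @property
    def b2(self) -> int:
        return self.c_start + 3

    @property
    def b3(self) -> int:
        return self.c_start + 4

    @property
    def b4(self) -> int:
        return self.c_start + 5

    @property
    def b5(self) -> int:
        return self.c_start + 6

    @property
    def L1(self) -> Optional[int]:
        return self._clip(self.c_start - 1)

    @property
    def minus1_b(self) -> Optional[int]:
        return self._clip(self.c_start - 2)

    @property
    def minus2_b(self) -> Optional[int]:
        return self._clip(self.c_start - 3)

    # --- box D-like strand -------------------------------------------------
    @property
    def n4(self) -> int:
        return self.d_start

    @property
    def n3(self) -> int:
        return self.d_start + 1

    @property
    def n2(self) -> int:
        return self.d_start + 2

    @property
    def n1(self) -> int:
        return self.d_start + 3

    @property
    def n5(self) -> Optional[int]:
        return self._clip(self.d_start - 1)

    @property
    def minus1_n(self) -> Optional[int]:
        return self._clip(self.d_start + 4)

    @property
    def minus2_n(self) -> Optional[int]:
        return self._clip(self.d_start + 5)

    def stem2_pair_indices(self, i: int) -> tuple[int, int]:
        """Sequence indices of stem-II pair i (1..4), b-side first."""
        b = {1: self.b1, 2: self.b2, 3: self.b3, 4: self.b4}[i]
        n = {1: self.n1, 2: self.n2, 3: self.n3, 4: self.n4}[i]
        return b, n


def build_frame(seq: str, c_start: int, d_start: int, motif_kind: str) -> KTurnFrame:
    """Place a k-turn frame on ``seq`` and validate window geometry.

    For an ``internal`` motif the box D'-like window lies 5' of the box
    C'-like window and its stem-I slots (d+4, d+5) must not overlap the 7-mer
    window; for the ``terminal`` box C/D motif the box C window lies 5' of
    the box D window.
    """
    if motif_kind not in ("terminal", "internal"):
        raise ValueError(f"motif_kind must be 'terminal' or 'internal', got {motif_kind!r}")
    n = len(seq)
    if not (0 <= c_start and c_start + 7 <= n):
        raise ValueError(f"box C-like window [{c_start}, {c_start + 7}) outside sequence of length {n}")
    if not (0 <= d_start and d_start + 4 <= n):
        raise ValueError(f"box D-like window [{d_start}, {d_start + 4}) outside sequence of length {n}")
    if motif_kind == "internal":
        # d window and its minus1_n/minus2_n slots (d+4, d+5) must precede c
        if d_start + 5 >= c_start:
            raise ValueError(
                f"internal motif requires the box D'-like window plus 2 nt "
                f"(stem-I slots) entirely 5' of the box C'-like window "
                f"(d_start={d_start}, c_start={c_start})"
            )
    else:
        if c_start + 7 > d_start:
            raise ValueError(
                f"terminal motif requires the box C window entirely 5' of the "
                f"box D window (c_start={c_start}, d_start={d_start})"
            )
    return KTurnFrame(c_start=c_start, d_start=d_start, seq_len=n, motif_kind=motif_kind)


@dataclass(frozen=True)
class FeatureSet:
    """Boolean/enumerated evaluation of the features used by all rules."""

    has_sheared_1: bool  # 1b=G with 1n=A
    has_sheared_2: bool  # 2b=A with 2n=G
    stem1_minus1: bool  # −1 pair WC or wobble
    stem1_minus2: bool  # −2 pair WC or wobble
    is_kloop: bool  # stem I absent/broken at both −1 and −2
    cprime_consensus: bool  # 7-mer matches RUGAUGA
    dprime_consensus: bool  # 4-mer equals CUGA
    stem2_score: int  # 0..4 canonical stem-II pair identities


def _matches_box_c_consensus(window: str) -> bool:
    if len(window) != 7:
        return False
    return window[0] in "AG" and window[1:] == "UGAUGA"


def _stem1_pair_ok(seq: str, b_idx: Optional[int], n_idx: Optional[int]) -> bool:
    if b_idx is None or n_idx is None or b_idx == n_idx:
        return False
    return classify_pair(seq[b_idx], seq[n_idx]) in (PairType.WC, PairType.WOBBLE)


def evaluate_features(frame: KTurnFrame, seq: str) -> FeatureSet:
    """Evaluate sheared pairs, stem I, k-loop status and consensus flags.

    The sheared-pair flags are strict nucleotide-identity checks (exactly
    G•A / A•G); an "intact" stem-I pair admits Watson–Crick and G•U wobble
    geometries, because genuine k-turn stems can open with a wobble pair.
    k-loop is declared only when both the −1 and the −2 pair fail or are
    absent; a failed −1 with intact −2 is a broken stem I, not a k-loop.
    """
    if frame.seq_len != len(seq):
        raise ValueError("frame was built for a sequence of different length")
    s1 = (seq[frame.b1], seq[frame.n1]) == ("G", "A")
    s2 = (seq[frame.b2], seq[frame.n2]) == ("A", "G")
    m1 = _stem1_pair_ok(seq, frame.minus1_b, frame.minus1_n)
    m2 = _stem1_pair_ok(seq, frame.minus2_b, frame.minus2_n)
    c_window = seq[frame.c_start : frame.c_start + 7]
    d_window = seq[frame.d_start : frame.d_start + 4]
    return FeatureSet(
        has_sheared_1=s1,
        has_sheared_2=s2,
        stem1_minus1=m1,
        stem1_minus2=m2,
        is_kloop=not m1 and not m2,
        cprime_consensus=_matches_box_c_consensus(c_window),
        dprime_consensus=d_window == BOX_D_CONSENSUS,
        stem2_score=_stem2_score_on_frame(frame, seq),
    )


def _stem2_score_on_frame(frame: KTurnFrame, seq: str) -> int:
    score = 0
    for i, (b_c, n_c) in CANONICAL_STEM2_PAIRS.items():
        b, n = frame.stem2_pair_indices(i)
        if (seq[b], seq[n]) == (b_c, n_c):
            score += 1
    return score
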