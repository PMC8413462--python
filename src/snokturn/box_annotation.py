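"""Locate boxes C, D, D' and C' on snoRNA sequences.

Rules implemented:

* box C matches 5'-RUGAUGA (≤ 1 mismatch by default) and must start within
  5 nt of the 5' end;
* box D and box D' are exact 5'-CUGA matches; when the guide position paired
  with a known methylation target is given, the box must start exactly five
  nucleotides downstream of it;
* box C' is the 7-mer window between box D' and the guide upstream of box D
  that maximises the number of stem-II base pairs matching a canonical box
  C'/D' motif (tandem sheared G•A / A•G, then U•U and G•C).

Coordinates are 0-based half-open internally; writers emit 1-based inclusive
coordinates and say so in their headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .kturn_model import (
    BOX_D_CONSENSUS,
    FeatureSet,
    KTurnFrame,
    build_frame,
    evaluate_features,
)
from .sequence_io import SnoRNARecord

logger = logging.getLogger(__name__)


@dataclass
class BoxAnnotation:
    """One located box motif (0-based half-open coordinates)."""

    box_kind: str  # "C", "D", "Dprime", "Cprime"
    start: int
    end: int
    window_seq: str
    mismatches_to_consensus: int = 0
    score: Optional[int] = None  # stem2 score, box C' only
    selection_rank: int = 1


def mismatches_to_box_c(window: str) -> int:
    """Mismatch count of a 7-mer against RUGAUGA (R matches A or G)."""
    if len(window) != 7:
        raise ValueError(f"box C window must be 7 nt, got {len(window)}")
    mm = 0 if window[0] in "AG" else 1
    mm += sum(1 for a, b in zip(window[1:], "UGAUGA") if a != b)
    return mm


def find_box_c(
    rec: SnoRNARecord, max_start: int = 5, max_mismatch: int = 1
) -> Optional[BoxAnnotation]:
    """Scan offsets 0..max_start for the best RUGAUGA match.

    Returns the window with the fewest mismatches ≤ ``max_mismatch``; ties
    are broken by the smaller start.  None when no window qualifies.
    """
    seq = rec.seq
    if len(seq) < 7:
        return None
    best: Optional[tuple[int, int]] = None  # (mismatches, start)
    for s in range(0, min(max_start, len(seq) - 7) + 1):
        mm = mismatches_to_box_c(seq[s : s + 7])
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, s)
    if best is None:
        return None
    mm, s = best
    return BoxAnnotation("C", s, s + 7, seq[s : s + 7], mismatches_to_consensus=mm)


def find_box_d(
    rec: SnoRNARecord,
    kind: str = "D",
    search_region: Optional[tuple[int, int]] = None,
    known_target_guide_pos: Optional[int] = None,
) -> list[BoxAnnotation]:
    """Find exact CUGA occurrences of box D or box D'.

    ``known_target_guide_pos`` is the 0-based guide position that pairs the
    methylation target; the box must then start exactly five nucleotides
    downstream of it (start == guide_pos + 5).  For box D with no target
    information the default region is the final 15 nt and candidates are
    ranked 3'-most first.
    """
    if kind not in ("D", "Dprime"):
        raise ValueError(f"kind must be 'D' or 'Dprime', got {kind!r}")
    seq = rec.seq
    if search_region is None:
        if kind == "D":
            search_region = (max(0, len(seq) - 15), len(seq))
        else:
            search_region = (0, len(seq))
    lo, hi = search_region
    lo, hi = max(0, lo), min(len(seq), hi)
    if lo >= hi:
        raise ValueError(f"empty search region ({lo}, {hi}) for record {rec.id!r}")
    hits = []
    for s in range(lo, hi - 3):
        if seq[s : s + 4] == BOX_D_CONSENSUS:
            hits.append(s)
    if known_target_guide_pos is not None:
        hits = [s for s in hits if s == known_target_guide_pos + 5]
    if kind == "D" and known_target_guide_pos is None:
        hits.sort(reverse=True)  # 3'-most first
    return [
        BoxAnnotation(kind, s, s + 4, seq[s : s + 4], selection_rank=i + 1)
        for i, s in enumerate(hits)
    ]


def score_stem2(cprime_window: str, dprime_window: str) -> int:
    """Number of stem-II pairs matching a canonical box C'/D' motif (0–4).

    The four scored pairs, kink-proximal first, are (1b,1n)=(G,A),
    (2b,2n)=(A,G), (3b,3n)=(U,U) and (4b,4n)=(G,C), where the b side is
    window positions 3–6 of the 7-mer and the n side is the 4-mer read
    3'→5' (antiparallel strands).
    """
    if len(cprime_window) != 7:
        raise ValueError(f"box C'-like window must be 7 nt, got {len(cprime_window)}")
    if len(dprime_window) != 4:
        raise ValueError(f"box D'-like window must be 4 nt, got {len(dprime_window)}")
    bad = (set(cprime_window) | set(dprime_window)) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in window")
    b = {1: cprime_window[2], 2: cprime_window[3], 3: cprime_window[4], 4: cprime_window[5]}
    n = {1: dprime_window[3], 2: dprime_window[2], 3: dprime_window[1], 4: dprime_window[0]}
    canonical = {1: ("G", "A"), 2: ("A", "G"), 3: ("U", "U"), 4: ("G", "C")}
    return sum(1 for i in range(1, 5) if (b[i], n[i]) == canonical[i])


def find_box_cprime(
    rec: SnoRNARecord,
    dprime: BoxAnnotation,
    boxd: BoxAnnotation,
    min_gap_to_d: int = 6,
    min_score: int = 1,
) -> Optional[BoxAnnotation]:
    """Select the box C' window between box D' and the box D guide region.

    Enumerates 7-mer windows with start ≥ dprime.end + 3 (leaving the stem-I
    slots 3' of box D' free) and end ≤ boxd.start − min_gap_to_d (reserving a
    minimal guide upstream of box D); each window is scored by
    :func:`score_stem2` against the box D' window, the argmax wins, ties are
    broken by fewer mismatches to RUGAUGA and then by smaller start.  When no
    window reaches ``min_score`` the snoRNA has no credible box C'/D' and
    None is returned.
    """
    if dprime.end >= boxd.start:
        raise ValueError("box D' must lie 5' of box D")
    seq = rec.seq
    first = dprime.end + 3
    last = boxd.start - min_gap_to_d - 7  # last admissible start
    if last < first:
        logger.warning("record %s: no room for a box C' window", rec.id)
        return None
    best: Optional[tuple[int, int, int]] = None  # (-score, mismatches, start)
    for s in range(first, last + 1):
        w = seq[s : s + 7]
        key = (-score_stem2(w, dprime.window_seq), mismatches_to_box_c(w), s)
        if best is None or key < best:
            best = key
    assert best is not None
    score = -best[0]
    if score < min_score:
        logger.warning("record %s: best box C' candidate scores %d (< %d); "
                       "no credible box C'/D'", rec.id, score, min_score)
        return None
    s = best[2]
    return BoxAnnotation(
        "Cprime", s, s + 7, seq[s : s + 7],
        mismatches_to_consensus=best[1], score=score,
    )


def window_offset(window_a: str, window_b: str) -> Optional[int]:
    """Shift (in nt) between two equal-length windows tiling one region.

    Returns the smallest positive s with ``window_a[s:] == window_b[:len-s]``
    (window_b starts s nucleotides 3' of window_a), 0 for identical windows,
    None when no shift ≤ len−1 works.
    """
    if len(window_a) != len(window_b):
        raise ValueError("windows must have equal length")
    if window_a == window_b:
        return 0
    n = len(window_a)
    for s in range(1, n):
        if window_a[s:] == window_b[: n - s]:
            return s
    return None


@dataclass
class SnoRNAAnnotation:
    """Full box annotation of one snoRNA, plus evaluated k-turn features."""

    record: SnoRNARecord
    box_c: Optional[BoxAnnotation] = None
    box_d: Optional[BoxAnnotation] = None
    box_dprime: Optional[BoxAnnotation] = None
    box_cprime: Optional[BoxAnnotation] = None
    terminal_frame: Optional[KTurnFrame] = None
    terminal_features: Optional[FeatureSet] = None
    internal_frame: Optional[KTurnFrame] = None
    internal_features: Optional[FeatureSet] = None
    notes: list[str] = field(default_factory=list)

    @property
    def boxes(self) -> list[BoxAnnotation]:
        return [b for b in (self.box_c, self.box_dprime, self.box_cprime, self.box_d) if b]


def annotate_record(
    rec: SnoRNARecord,
    max_start: int = 5,
    max_mismatch: int = 1,
    min_gap_to_d: int = 6,
) -> SnoRNAAnnotation:
    """Annotate boxes C, D, D', C' and evaluate both k-turn frames.

    Box D' placement without target information keeps every CUGA occurrence
    between box C and box D as a candidate and selects the (D', C') pair that
    jointly maximises the stem-II score; ties go to the 5'-most box D'.
    """
    ann = SnoRNAAnnotation(record=rec)
    seq = rec.seq
    ann.box_c = find_box_c(rec, max_start=max_start, max_mismatch=max_mismatch)
    if ann.box_c is None:
        ann.notes.append("no box C within 5 nt of the 5' end")
    if len(seq) >= 15:
        d_candidates = find_box_d(rec, kind="D")
    else:
        d_candidates = []
    if not d_candidates:
        ann.notes.append("no box D (CUGA) in the final 15 nt")
        return ann
    ann.box_d = d_candidates[0]  # 3'-most
    if ann.box_c is not None and ann.box_c.end + 7 <= ann.box_d.start:
        ann.terminal_frame = build_frame(seq, ann.box_c.start, ann.box_d.start, "terminal")
        ann.terminal_features = evaluate_features(ann.terminal_frame, seq)

    # internal box D'/C' joint selection
    region_start = ann.box_c.end if ann.box_c is not None else 0
    dp_candidates = [
        b for b in find_box_d(rec, kind="Dprime", search_region=(region_start, ann.box_d.start))
        if b.end < ann.box_d.start
    ]
    best: Optional[tuple[BoxAnnotation, BoxAnnotation]] = None
    best_key: Optional[tuple] = None
    for dp in dp_candidates:
        cp = find_box_cprime(rec, dp, ann.box_d, min_gap_to_d=min_gap_to_d)
        if cp is None:
            continue
        key = (-cp.score, dp.start)  # max score; ties -> 5'-most D'
        if best_key is None or key < best_key:
            best_key, best = key, (dp, cp)
    if best is None:
        ann.notes.append("no credible box C'/D' motif")
        return ann
    ann.box_dprime, ann.box_cprime = best
    ann.internal_frame = build_frame(seq, ann.box_cprime.start, ann.box_dprime.start, "internal")
    ann.internal_features = evaluate_features(ann.internal_frame, seq)
    return ann


def boxes_to_bed(ann: SnoRNAAnnotation) -> list[str]:
    """BED6-like lines (0-based half-open) for the annotated boxes."""
    lines = []
    for b in ann.boxes:
        score = b.score if b.score is not None else 0
        lines.append(f"{ann.record.id}\t{b.start}\t{b.end}\t{b.box_kind}\t{score}\t+")
    return lines
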