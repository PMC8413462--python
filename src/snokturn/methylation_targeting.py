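"""Guide–substrate duplex search and 2'-O-methylation site prediction.

The guide region immediately 5' of box D (or box D') base-pairs an
antiparallel substrate window; the methyl group is deposited on the
substrate nucleotide paired with the fifth guide nucleotide upstream of the
box (the classic D+5 rule: guide position box_start − 5 in 1-based
coordinates, counting the C of CUGA as box_start).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .box_annotation import BoxAnnotation
from .kturn_model import PairType, classify_pair
from .sequence_io import SnoRNARecord


@dataclass
class GuideDuplex:
    """A contiguous antiparallel guide–substrate duplex ending at the box."""

    snorna_id: str
    box_kind: str
    guide_range: tuple[int, int]  # 0-based half-open on the snoRNA
    substrate_id: str
    substrate_range: tuple[int, int]  # 0-based half-open on the substrate
    length: int
    pair_map: list[tuple[int, int]]  # ascending guide index ↔ descending substrate index

    def substrate_partner(self, guide_index: int) -> Optional[int]:
        for g, s in self.pair_map:
            if g == guide_index:
                return s
        return None


def _pairs(guide_nt: str, substrate_nt: str, allow_wobble: bool) -> bool:
    pt = classify_pair(guide_nt, substrate_nt)
    return pt is PairType.WC or (allow_wobble and pt is PairType.WOBBLE)


def _is_wobble(a: str, b: str) -> bool:
    return classify_pair(a, b) is PairType.WOBBLE


def find_guide_duplex(
    rec: SnoRNARecord,
    box: BoxAnnotation,
    substrate_id: str,
    substrate_seq: str,
    min_len: int = 8,
    allow_wobble: bool = True,
) -> Optional[GuideDuplex]:
    """Longest contiguous duplex whose guide side ends at box.start − 1.

    The guide is read 5'→3' and pairs the substrate window 3'→5'
    (antiparallel), so the 3'-most guide nucleotide pairs the 5'-most
    nucleotide of the substrate window.  Ties are broken by more
    Watson–Crick (fewer wobble) pairs, then by the 5'-most substrate
    window.  None when the best duplex is shorter than ``min_len``.
    """
    if box.box_kind not in ("D", "Dprime"):
        raise ValueError("guide duplexes are anchored to box D or box D'")
    if not substrate_seq:
        raise ValueError("substrate sequence is empty")
    g0 = box.start - 1  # 3'-most guide nucleotide
    if g0 < 0:
        return None
    best: Optional[tuple[int, int, int]] = None  # (-length, n_wobble, t)
    for t in range(len(substrate_seq)):
        k = 0
        wob = 0
        while (
            g0 - k >= 0
            and t + k < len(substrate_seq)
            and _pairs(rec.seq[g0 - k], substrate_seq[t + k], allow_wobble)
        ):
            if _is_wobble(rec.seq[g0 - k], substrate_seq[t + k]):
                wob += 1
            k += 1
        if k == 0:
            continue
        key = (-k, wob, t)
        if best is None or key < best:
            best = key
    if best is None or -best[0] < min_len:
        return None
    length, t = -best[0], best[2]
    pair_map = [(g0 - k, t + k) for k in range(length)]
    pair_map.sort()  # ascending guide index, descending substrate index
    return GuideDuplex(
        snorna_id=rec.id,
        box_kind=box.box_kind,
        guide_range=(g0 - length + 1, g0 + 1),
        substrate_id=substrate_id,
        substrate_range=(t, t + length),
        length=length,
        pair_map=pair_map,
    )


def predict_methylation_site(
    duplex: GuideDuplex,
    box: BoxAnnotation,
    rec: Optional[SnoRNARecord] = None,
    substrate_seq: Optional[str] = None,
    allow_wobble_at_target: bool = False,
) -> int:
    """Predicted 2'-O-methylation site (1-based substrate position).

    Returns the substrate nucleotide paired with the fifth guide nucleotide
    upstream of the box (guide position box.start − 5, 1-based).  Raises
    when that guide position lies outside the duplex, or when the target
    pair is a wobble and ``allow_wobble_at_target`` is False (a wobble at
    the methylated position is not accepted by default).
    """
    guide_idx = box.start - 5  # 0-based: five positions before the C of CUGA
    partner = duplex.substrate_partner(guide_idx)
    if partner is None:
        raise ValueError(
            f"{duplex.snorna_id}: target outside duplex — guide position "
            f"{guide_idx + 1} (1-based) is unpaired"
        )
    if not allow_wobble_at_target and rec is not None and substrate_seq is not None:
        if _is_wobble(rec.seq[guide_idx], substrate_seq[partner]):
            raise ValueError(
                f"{duplex.snorna_id}: wobble pair at the target position "
                f"(substrate {partner + 1}, 1-based) is not allowed"
            )
    return partner + 1


def validate_prediction(predicted_site: int, known_site: int) -> str:
    """Compare a predicted site with known-target metadata ("consistent"/"inconsistent")."""
    return "consistent" if predicted_site == known_site else "inconsistent"
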