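"""Feature-level reconstruction of the box C'/D' EMSA construct panel.

The kl constructs isolate the internal box C'/D' motif of yeast snoRNAs
snR51, snR41 and snR54 (plus the archaeal sR26 k-loop control and a fully
canonical k-turn control) and were titrated against L7Ae and Snu13 in gel
shift assays.  The construct sequences themselves are not published as
text, so the entries below are SYNTHETIC stand-ins: feature sets
reconstructed from the described base-pairing of each construct, paired
with the experimentally observed qualitative binding outcome.

``snu13`` / ``l7ae`` record the observed call; ``None`` means the outcome
is not asserted against the predicates (snR41-kl2 carries all three
required features yet showed no Snu13 binding — the feature criteria are
necessary, not sufficient, so the predicate over-calls this construct;
see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .functional_classification import BindingCall
from .kturn_model import FeatureSet


@dataclass(frozen=True)
class PanelEntry:
    name: str
    features: FeatureSet
    l7ae: Optional[BindingCall]
    snu13: Optional[BindingCall]
    note: str = ""


def _fs(s1, s2, m1, m2, kloop, ccons, dcons, stem2) -> FeatureSet:
    return FeatureSet(
        has_sheared_1=s1, has_sheared_2=s2, stem1_minus1=m1, stem1_minus2=m2,
        is_kloop=kloop, cprime_consensus=ccons, dprime_consensus=dcons,
        stem2_score=stem2,
    )


KL_PANEL: tuple[PanelEntry, ...] = (
    PanelEntry(
        "sR26-kl",
        _fs(True, True, False, False, True, True, True, 4),
        l7ae=BindingCall.BINDER, snu13=BindingCall.NONBINDER,
        note="archaeal consensus box C'/D' k-loop; Snu13 cannot bind k-loops",
    ),
    PanelEntry(
        "snR51-kl1",
        _fs(True, False, True, True, False, False, False, 3),
        l7ae=BindingCall.BINDER, snu13=BindingCall.NONBINDER,
        note="1b•1n G•A plus intact -1/-2 stem-I pairs; 2b•2n pair absent",
    ),
    PanelEntry(
        "snR51-kl2",
        _fs(True, True, True, True, False, False, True, 3),
        l7ae=BindingCall.BINDER, snu13=BindingCall.WEAK,
        note="kl1 plus the 2b•2n A•G pair; weak smeared Snu13 band",
    ),
    PanelEntry(
        "snR51-kl3",
        _fs(True, False, False, False, True, False, False, 3),
        l7ae=BindingCall.WEAK, snu13=BindingCall.NONBINDER,
        note="kl1 with stem I replaced by a loop; fast-dissociating L7Ae complex",
    ),
    PanelEntry(
        "snR51-kl4",
        _fs(True, True, False, True, False, False, True, 3),
        l7ae=BindingCall.BINDER, snu13=BindingCall.NONBINDER,
        note="2b•2n A•G pair present but -1 stem-I pair broken",
    ),
    PanelEntry(
        "snR41-kl1",
        _fs(False, True, True, True, False, False, True, 3),
        l7ae=BindingCall.NONBINDER, snu13=BindingCall.NONBINDER,
        note="lacks the 1b•1n G•A pair (window UACAUGU vs CUGA)",
    ),
    PanelEntry(
        "snR41-kl2",
        _fs(True, True, True, True, False, False, True, 4),
        l7ae=BindingCall.BINDER, snu13=None,
        note="1b restored; bound L7Ae (weaker than snR51-kl1); Snu13 outcome "
             "not reproduced by the feature criteria (necessary, not sufficient)",
    ),
    PanelEntry(
        "snR54-kl1",
        _fs(True, False, False, True, False, False, True, 3),
        l7ae=BindingCall.NONBINDER, snu13=BindingCall.NONBINDER,
        note="lacks both the -1 stem-I pair and the 2b•2n A•G pair",
    ),
    PanelEntry(
        "canonical-control",
        _fs(True, True, True, True, False, True, True, 4),
        l7ae=BindingCall.BINDER, snu13=BindingCall.BINDER,
        note="full consensus k-turn; Snu13 saturates at a 1:1 ratio",
    ),
)
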