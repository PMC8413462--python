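"""Functional classification of box C/D and box C'/D' motifs.

A motif is *functional* when its sequence can form the k-turn recognised by
Snu13: this requires the tandem sheared pairs 1b•1n (G•A) and 2b•2n (A•G)
of stem II and an intact −1 base pair in stem I.  The archaeal orthologue
L7Ae is more permissive: a conserved 1b•1n G•A pair together with either an
intact −1 pair or the second sheared pair suffices, and it tolerates
k-loops (stem I replaced by a loop) with reduced complex lifetime.

The census summarises a snoRNA set into the five categories and the
fraction of motifs predicted non-functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .kturn_model import FeatureSet


class Category(str, Enum):
    CANONICAL = "CANONICAL"
    FUNCTIONAL_NONCANONICAL = "FUNCTIONAL_NONCANONICAL"
    TANDEM_NO_STEM1 = "TANDEM_NO_STEM1"
    MISSING_SHEARED = "MISSING_SHEARED"
    NO_MOTIF = "NO_MOTIF"


FUNCTIONAL_CATEGORIES = (Category.CANONICAL, Category.FUNCTIONAL_NONCANONICAL)


class BindingCall(str, Enum):
    BINDER = "BINDER"
    WEAK = "WEAK"
    NONBINDER = "NONBINDER"


@dataclass
class MotifClassification:
    """Category label plus feature provenance for one motif site."""

    snorna_id: str
    site: str  # "terminal" or "internal"
    category: Category
    functional: bool
    features: Optional[FeatureSet] = None
    evidence: list[str] = field(default_factory=list)


def classify_motif(
    features: Optional[FeatureSet],
    snorna_id: str = "",
    site: str = "internal",
) -> MotifClassification:
    """Classify one motif site from its evaluated features.

    ``features=None`` means annotation failed (no credible motif) and yields
    NO_MOTIF.  The five categories partition all inputs:

    * CANONICAL — both windows match the consensus (RUGAUGA / CUGA);
    * FUNCTIONAL_NONCANONICAL — both sheared pairs and an intact −1 stem-I
      pair, without full consensus;
    * TANDEM_NO_STEM1 — tandem sheared pairs but the −1 pair is broken;
    * MISSING_SHEARED — at least one sheared pair absent.
    """
    evidence: list[str] = []
    if features is None:
        return MotifClassification(snorna_id, site, Category.NO_MOTIF, False,
                                   evidence=["no credible motif annotated"])
    if features.cprime_consensus and features.dprime_consensus:
        cat = Category.CANONICAL
        evidence.append("both windows match consensus")
    elif features.has_sheared_1 and features.has_sheared_2 and features.stem1_minus1:
        cat = Category.FUNCTIONAL_NONCANONICAL
        evidence.append("tandem sheared pairs + intact -1 stem-I pair")
    elif features.has_sheared_1 and features.has_sheared_2:
        cat = Category.TANDEM_NO_STEM1
        evidence.append("tandem sheared pairs, -1 stem-I pair broken or absent")
    else:
        cat = Category.MISSING_SHEARED
        missing = []
        if not features.has_sheared_1:
            missing.append("1b•1n G•A")
        if not features.has_sheared_2:
            missing.append("2b•2n A•G")
        evidence.append("missing sheared pair(s): " + ", ".join(missing))
    return MotifClassification(
        snorna_id, site, cat, cat in FUNCTIONAL_CATEGORIES, features, evidence
    )


def predict_snu13_binding(features: Optional[FeatureSet]) -> BindingCall:
    """Snu13 recognisability from sequence features.

    Requires all three features (both sheared pairs and the −1 stem-I pair).
    When they hold but the stem-II score is below the canonical maximum of 4,
    only weak binding (band smearing) is predicted — the three features are
    necessary, not sufficient, for a strong complex.
    """
    if features is None:
        return BindingCall.NONBINDER
    if features.has_sheared_1 and features.has_sheared_2 and features.stem1_minus1:
        return BindingCall.BINDER if features.stem2_score >= 4 else BindingCall.WEAK
    return BindingCall.NONBINDER


def predict_l7ae_binding(features: Optional[FeatureSet]) -> BindingCall:
    """L7Ae recognisability from sequence features.

    L7Ae binds when the 1b•1n G•A pair is present together with either an
    intact −1 stem-I pair or the 2b•2n A•G pair; a k-loop carrying only the
    first sheared pair binds weakly (fast-dissociating, smearing bands).
    """
    if features is None:
        return BindingCall.NONBINDER
    if features.has_sheared_1 and (features.stem1_minus1 or features.has_sheared_2):
        return BindingCall.BINDER
    if features.has_sheared_1 and features.is_kloop and not features.has_sheared_2:
        return BindingCall.WEAK
    return BindingCall.NONBINDER


@dataclass
class CensusReport:
    n_total: int
    n_canonical: int
    n_functional_noncanonical: int
    n_tandem_no_stem1: int
    n_missing_sheared: int
    n_no_motif: int
    fraction_nonfunctional: float  # percentage

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_canonical": self.n_canonical,
            "n_functional_noncanonical": self.n_functional_noncanonical,
            "n_tandem_no_stem1": self.n_tandem_no_stem1,
            "n_missing_sheared": self.n_missing_sheared,
            "n_no_motif": self.n_no_motif,
            "fraction_nonfunctional": self.fraction_nonfunctional,
        }


def census(classifications: Iterable[MotifClassification]) -> CensusReport:
    """Count categories over a snoRNA set; NO_MOTIF counts as non-functional."""
    cls = list(classifications)
    if not cls:
        raise ValueError("census requires a non-empty classification list")
    counts = {cat: 0 for cat in Category}
    for c in cls:
        counts[c.category] += 1
    n = len(cls)
    n_functional = counts[Category.CANONICAL] + counts[Category.FUNCTIONAL_NONCANONICAL]
    return CensusReport(
        n_total=n,
        n_canonical=counts[Category.CANONICAL],
        n_functional_noncanonical=counts[Category.FUNCTIONAL_NONCANONICAL],
        n_tandem_no_stem1=counts[Category.TANDEM_NO_STEM1],
        n_missing_sheared=counts[Category.MISSING_SHEARED],
        n_no_motif=counts[Category.NO_MOTIF],
        fraction_nonfunctional=100.0 * (n - n_functional) / n,
    )


@dataclass
class AffinityBound:
    """Order-of-magnitude K_D bound derived from an EMSA titration."""

    direction: str  # "upper" or "lower"
    value: float  # nM
    basis: str  # "saturating_ratio" or "nonbinding_ratio"
    rna_total: float  # µM

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("affinity bound must be positive")


def kd_upper_bound(rna_total_uM: float) -> AffinityBound:
    """Upper K_D bound when an EMSA saturates at a 1:1 protein:RNA ratio.

    Full displacement at equimolar protein implies the K_D is at least one
    order of magnitude below the total RNA concentration; the bound is
    rna_total/10, reported in nM.
    """
    if rna_total_uM <= 0:
        raise ValueError(f"RNA concentration must be positive, got {rna_total_uM}")
    return AffinityBound(
        direction="upper",
        value=rna_total_uM * 1000.0 / 10.0,
        basis="saturating_ratio",
        rna_total=rna_total_uM,
    )
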