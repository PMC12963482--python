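"""ACMG evidence combining, similarity-calibrated PP4 and case statuses.

Variant-level evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic
side; BA1, BS1-4, BP1-7 on the benign side) are combined into the five-tier
classification B < LB < VUS < LP < P with the Richards-style rules
operationalised in :func:`combine_evidence`.  The package's contribution to
this layer is quantitative PP4: the mean phenotype similarity score is
converted into PP4 evidence — supporting at score >= 0.3, moderate at
score >= 0.4, nothing below — and appended to each allele's evidence before
re-combining, which can upgrade a VUS to LP/P but never downgrades.

Evidence codes other than PP4 are *inputs* here (curated or tool-derived);
this module never derives PM2 from frequencies or PVS1 from consequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .similarity import PhenotypeScore, SimilarityConfig

__all__ = [
    "Strength",
    "Classification",
    "CaseStatus",
    "Evidence",
    "pp4_from_score",
    "combine_evidence",
    "revise_classifications",
    "classify_case_status",
]


class Strength(enum.Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Classification(enum.IntEnum):
    """Five-tier variant classification with the 'VUS or higher' order."""

    B = 0
    LB = 1
    VUS = 2
    LP = 3
    P = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class CaseStatus(enum.Enum):
    LIKELY_DIAGNOSIS = "likely_diagnosis"
    CANDIDATE_FURTHER_INVESTIGATION = "candidate_further_investigation"
    VUS_FINDING = "vus_finding"
    NOT_PRIORITISED = "not_prioritised"


_PATHOGENIC_DEFAULTS: dict[str, Strength] = {"PVS1": Strength.VERY_STRONG}
_PATHOGENIC_DEFAULTS.update({f"PS{i}": Strength.STRONG for i in range(1, 5)})
_PATHOGENIC_DEFAULTS.update({f"PM{i}": Strength.MODERATE for i in range(1, 7)})
_PATHOGENIC_DEFAULTS.update({f"PP{i}": Strength.SUPPORTING for i in range(1, 6)})
_BENIGN_DEFAULTS: dict[str, Strength] = {"BA1": Strength.STAND_ALONE}
_BENIGN_DEFAULTS.update({f"BS{i}": Strength.STRONG for i in range(1, 5)})
_BENIGN_DEFAULTS.update({f"BP{i}": Strength.SUPPORTING for i in range(1, 8)})

KNOWN_CODES = frozenset(_PATHOGENIC_DEFAULTS) | frozenset(_BENIGN_DEFAULTS)


@dataclass(frozen=True)
class Evidence:
    """One applied evidence code, possibly at a modulated strength."""

    code: str
    strength: Strength | None = None

    def __post_init__(self) -> None:
        if self.code not in KNOWN_CODES:
            raise ValueError(f"unknown ACMG code {self.code!r}")
        if self.code == "BA1" and self.strength not in (None, Strength.STAND_ALONE):
            raise ValueError("BA1 is stand-alone only")

    @property
    def direction(self) -> str:
        return "pathogenic" if self.code in _PATHOGENIC_DEFAULTS else "benign"

    @property
    def effective_strength(self) -> Strength:
        if self.strength is not None:
            return self.strength
        if self.direction == "pathogenic":
            return _PATHOGENIC_DEFAULTS[self.code]
        return _BENIGN_DEFAULTS[self.code]


def pp4_from_score(
    score: PhenotypeScore | float,
    policy: SimilarityConfig | None = None,
    has_phenotype: bool = True,
) -> Evidence | None:
    """Similarity-calibrated PP4: moderate at >= 0.4, supporting at >= 0.3.

    Returns ``None`` below the supporting threshold or when the individual
    has no phenotype terms at all (PP4 requires phenotype data).  PP4 is
    capped at moderate strength.
    """
    policy = policy or SimilarityConfig()
    value = score.value if isinstance(score, PhenotypeScore) else float(score)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"similarity score outside [0, 1]: {value}")
    if not has_phenotype:
        return None
    if value >= policy.pp4_moderate_min:
        return Evidence("PP4", Strength.MODERATE)
    if value >= policy.pp4_supporting_min:
        return Evidence("PP4", Strength.SUPPORTING)
    return None


def combine_evidence(evidence: Iterable[Evidence]) -> Classification:
    """Combine evidence codes into a classification.

    Pathogenic: P for 1 very-strong plus (>=1 strong | >=2 moderate |
    1 moderate + 1 supporting | >=2 supporting), >=2 very-strong,
    >=2 strong, or 1 strong plus (>=3 moderate | 2 moderate + 2 supporting |
    1 moderate + >=4 supporting).  LP for 1 very-strong + 1 moderate;
    1 strong + 1-2 moderate; 1 strong + >=2 supporting; >=3 moderate;
    2 moderate + >=2 supporting; 1 moderate + >=4 supporting.
    Benign: B for BA1 or >=2 benign strong; LB for 1 benign strong +
    1 benign supporting, or >=2 benign supporting.  Meeting a classifying
    pattern on both sides is a conflict and yields VUS; so does an empty or
    insufficient evidence list.  Benign evidence at moderate strength (no
    slot in the table) counts as supporting.
    """
    items = list(evidence)
    codes = [e.code for e in items]
    if len(codes) != len(set(codes)):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate evidence code(s): {dup}")

    vs = s = m = p = 0
    ba = bs = bp = 0
    for e in items:
        st = e.effective_strength
        if e.direction == "pathogenic":
            if st is Strength.VERY_STRONG:
                vs += 1
            elif st is Strength.STRONG:
                s += 1
            elif st is Strength.MODERATE:
                m += 1
            elif st is Strength.SUPPORTING:
                p += 1
            else:
                raise ValueError(f"{e.code}: stand_alone is benign-only")
        else:
            if st is Strength.STAND_ALONE:
                ba += 1
            elif st is Strength.STRONG:
                bs += 1
            else:  # moderate folded into supporting, see docstring
                bp += 1

    is_p = (
        vs >= 2
        or (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    is_lp = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    is_b = ba >= 1 or bs >= 2
    is_lb = (bs >= 1 and bp >= 1) or bp >= 2

    if (is_p or is_lp) and (is_b or is_lb):
        return Classification.VUS
    if is_p:
        return Classification.P
    if is_lp:
        return Classification.LP
    if is_b:
        return Classification.B
    if is_lb:
        return Classification.LB
    return Classification.VUS


def revise_classifications(
    initial: Sequence[Classification],
    evidence_lists: Sequence[Sequence[Evidence]],
    pp4: Evidence | None,
) -> list[Classification]:
    """Append PP4 to each allele's evidence and re-combine.

    The revised classification is never lower than the initial one (PP4 is
    pathogenic-direction evidence; a curated initial class also acts as a
    floor when it encodes information beyond the listed codes).  An existing
    PP4 entry is replaced by the computed one rather than duplicated.
    """
    if len(initial) != len(evidence_lists):
        raise ValueError("initial classifications and evidence lists differ in length")
    revised: list[Classification] = []
    for init, ev in zip(initial, evidence_lists):
        items = [e for e in ev if e.code != "PP4"]
        if pp4 is not None:
            items.append(pp4)
        combined = combine_evidence(items)
        revised.append(max(init, combined))
    return revised


def classify_case_status(classifications: Sequence[Classification]) -> CaseStatus:
    """Per-genotype outcome from the (1 or 2) allele classifications.

    Both alleles LP/P -> likely diagnosis; exactly one LP/P with the other
    at least VUS -> candidate for further investigation; all VUS -> VUS
    finding; any allele below VUS -> not prioritised.  A homozygous genotype
    passes a single classification.
    """
    if not 1 <= len(classifications) <= 2:
        raise ValueError("expected one (hom) or two (pair) classifications")
    if any(c < Classification.VUS for c in classifications):
        return CaseStatus.NOT_PRIORITISED
    lp_or_p = [c >= Classification.LP for c in classifications]
    if all(lp_or_p):
        return CaseStatus.LIKELY_DIAGNOSIS
    if any(lp_or_p):
        return CaseStatus.CANDIDATE_FURTHER_INVESTIGATION
    return CaseStatus.VUS_FINDING
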