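"""ACMG/AMP evidence combination: the published combining rules and a
point-based engine mirroring automated classifiers.

Evidence is a set of criterion codes (PVS1; PS1-4; PM1-6; PP1-5; BA1;
BS1-4; BP1-7), each optionally carrying an overridden strength.  Default
strength is encoded in the code prefix (PVS = very strong pathogenic,
PS = strong, PM = moderate, PP = supporting; BA = stand-alone benign,
BS = strong benign, BP = supporting benign).  Overrides are accepted as
input but never inferred — tags come from an external classifier, and the
engine only combines them.

Two engines:

* ``classify_rules`` — the literal combining table from the 2015 ACMG/AMP
  guideline.  Pathogenic/benign conflicts, and tag sets matching no rule,
  yield VUS.
* ``classify_points`` — the additive heuristic used by automated
  classifiers: very strong 8, strong 4, moderate 2, supporting 1 on the
  pathogenic side; supporting −1, strong −4, stand-alone −8 on the benign
  side; totals >= 10 pathogenic, 6–9 likely pathogenic, 0–5 VUS, −6…−1
  likely benign, <= −7 benign.

PP5 and BP6 (reputable-source assertions) are accepted despite their later
deprecation, because external classifier output still carries them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

__all__ = [
    "Strength",
    "Classification",
    "AcmgEvidence",
    "AcmgClassification",
    "classify_rules",
    "classify_points",
    "VALID_TAGS",
]


class Strength(str, Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Classification(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


_PATHOGENIC_TAGS = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
_BENIGN_TAGS = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
VALID_TAGS: frozenset[str] = frozenset(_PATHOGENIC_TAGS + _BENIGN_TAGS)

_DEFAULT_STRENGTH: dict[str, Strength] = {}
for _t in VALID_TAGS:
    if _t.startswith("PVS"):
        _DEFAULT_STRENGTH[_t] = Strength.VERY_STRONG
    elif _t.startswith("PS"):
        _DEFAULT_STRENGTH[_t] = Strength.STRONG
    elif _t.startswith("PM"):
        _DEFAULT_STRENGTH[_t] = Strength.MODERATE
    elif _t.startswith("PP"):
        _DEFAULT_STRENGTH[_t] = Strength.SUPPORTING
    elif _t.startswith("BA"):
        _DEFAULT_STRENGTH[_t] = Strength.STAND_ALONE
    elif _t.startswith("BS"):
        _DEFAULT_STRENGTH[_t] = Strength.STRONG
    else:  # BP*
        _DEFAULT_STRENGTH[_t] = Strength.SUPPORTING

_POINTS = {
    Strength.VERY_STRONG: 8,
    Strength.STRONG: 4,
    Strength.MODERATE: 2,
    Strength.SUPPORTING: 1,
}


@dataclass(frozen=True)
class AcmgEvidence:
    """A set of ACMG criterion codes with optional per-tag strength overrides."""

    tags: frozenset[str]
    overrides: Mapping[str, Strength] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.tags) - VALID_TAGS
        if unknown:
            raise ValueError(f"unknown ACMG tag(s): {sorted(unknown)}")
        stray = set(self.overrides) - set(self.tags)
        if stray:
            raise ValueError(f"override(s) for absent tag(s): {sorted(stray)}")

    @classmethod
    def from_string(cls, text: str, overrides: Optional[Mapping[str, Strength]] = None) -> "AcmgEvidence":
        """Parse a comma-separated tag list like ``"PVS1, PP5"``."""
        tags = frozenset(t.strip() for t in text.split(",") if t.strip())
        return cls(tags=tags, overrides=dict(overrides or {}))

    def strength_of(self, tag: str) -> Strength:
        return self.overrides.get(tag, _DEFAULT_STRENGTH[tag])

    def _count(self, side: str, strength: Strength) -> int:
        wanted_side = (lambda t: t[0] == "P") if side == "pathogenic" else (lambda t: t[0] == "B")
        return sum(1 for t in self.tags if wanted_side(t) and self.strength_of(t) is strength)


@dataclass(frozen=True)
class AcmgClassification:
    classification: Classification
    engine: str  # "rules" | "points"
    points: Optional[int] = None
    rationale: str = ""


def classify_rules(evidence: AcmgEvidence) -> AcmgClassification:
    """Classify by the literal published combining table.

    Tags count in the bucket of their *effective* strength, so an override
    moves a tag between buckets (e.g. a moderate criterion applied at strong
    counts with the PS group).
    """
    pvs = evidence._count("pathogenic", Strength.VERY_STRONG)
    ps = evidence._count("pathogenic", Strength.STRONG)
    pm = evidence._count("pathogenic", Strength.MODERATE)
    pp = evidence._count("pathogenic", Strength.SUPPORTING)
    ba = evidence._count("benign", Strength.STAND_ALONE)
    bs = evidence._count("benign", Strength.STRONG)
    bp = evidence._count("benign", Strength.SUPPORTING)

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2

    path_fires = pathogenic or likely_pathogenic
    benign_fires = benign or likely_benign
    if path_fires and benign_fires:
        return AcmgClassification(Classification.VUS, "rules", rationale="conflicting evidence")
    if pathogenic:
        return AcmgClassification(Classification.PATHOGENIC, "rules", rationale="pathogenic rule")
    if likely_pathogenic:
        return AcmgClassification(Classification.LIKELY_PATHOGENIC, "rules", rationale="likely-pathogenic rule")
    if benign:
        return AcmgClassification(Classification.BENIGN, "rules", rationale="benign rule")
    if likely_benign:
        return AcmgClassification(Classification.LIKELY_BENIGN, "rules", rationale="likely-benign rule")
    return AcmgClassification(Classification.VUS, "rules", rationale="no rule matched")


def classify_points(evidence: AcmgEvidence) -> AcmgClassification:
    """Classify by additive strength points (the automated-classifier heuristic)."""
    total = 0
    for tag in evidence.tags:
        s = evidence.strength_of(tag)
        if tag[0] == "P":
            total += _POINTS[s]
        else:
            total -= 8 if s is Strength.STAND_ALONE else _POINTS[s]
    if total >= 10:
        cls = Classification.PATHOGENIC
    elif total >= 6:
        cls = Classification.LIKELY_PATHOGENIC
    elif total >= 0:
        cls = Classification.VUS
    elif total >= -6:
        cls = Classification.LIKELY_BENIGN
    else:
        cls = Classification.BENIGN
    return AcmgClassification(cls, "points", points=total, rationale=f"{total} points")


def classify(evidence: AcmgEvidence, engine: str = "points") -> AcmgClassification:
    """Dispatch to the configured engine (pipeline default: points)."""
    if engine == "points":
        return classify_points(evidence)
    if engine == "rules":
        return classify_rules(evidence)
    raise ValueError(f"unknown ACMG engine {engine!r}")
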