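"""Rare-variant triage: the candidate-MOV filter cascade.

A variant survives iff all of the following hold:

1. its consequence class is retained (synonymous and "other" are excluded;
   frameshift / stopgain / stoploss count as damaging outright);
2. it is rare: every *present* population frequency (1000 Genomes, ExAC) is
   below the MAF threshold (default 5%); a variant absent from both panels
   counts as rare;
3. no late-onset control carries it;
4. it is deleterious: automatically for the truncating classes, by predictor
   vote for nonsynonymous SNVs — damaging iff, among the tools with an
   available score, at least the vote fraction (default half, inclusive)
   call it damaging;
5. its carrier fraction among the early-onset cases is at least the cohort
   threshold (default 5%);
6. its gene is on the candidate-gene allow-list, when one is given (the
   literature-selection step, mechanized).

The conjunction is order-invariant; the audit trail reports removals in the
documented order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort import AnnotationProfile, CohortDataset, ConsequenceClass, VariantRecord

__all__ = [
    "TriageConfig",
    "TriageAudit",
    "is_damaging_by_vote",
    "passes_rarity",
    "cohort_carrier_fraction",
    "run_triage",
]

AUTO_DAMAGING = frozenset(
    {
        ConsequenceClass.FRAMESHIFT_INSERTION,
        ConsequenceClass.FRAMESHIFT_DELETION,
        ConsequenceClass.STOPGAIN,
        ConsequenceClass.STOPLOSS,
    }
)

#: Filter stages in audit order.
STAGES = (
    "consequence_class",
    "rarity",
    "control_exclusion",
    "deleteriousness",
    "carrier_fraction",
    "gene_allowlist",
)


@dataclass(frozen=True)
class TriageConfig:
    population_maf_threshold: float = 0.05
    cohort_carrier_fraction_threshold: float = 0.05
    vote_fraction: float = 0.5
    auto_damaging_classes: frozenset[ConsequenceClass] = AUTO_DAMAGING
    retained_classes: frozenset[ConsequenceClass] = AUTO_DAMAGING | {
        ConsequenceClass.NONSYNONYMOUS_SNV
    }
    gene_allowlist: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for name in ("population_maf_threshold", "cohort_carrier_fraction_threshold", "vote_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass
class TriageAudit:
    """Per-stage surviving counts and per-variant removal reasons."""

    n_input: int = 0
    surviving_after: dict[str, int] = field(default_factory=dict)
    removed_by: dict[str, str] = field(default_factory=dict)  # variant key -> stage

    def to_rows(self) -> list[dict]:
        rows = [{"stage": "input", "surviving": self.n_input}]
        rows += [{"stage": s, "surviving": self.surviving_after[s]} for s in STAGES]
        return rows


def is_damaging_by_vote(profile: AnnotationProfile, vote_fraction: float = 0.5) -> Optional[bool]:
    """Predictor consensus vote over the tools with an available score.

    Returns True iff ``n_damaging >= vote_fraction * n_available`` ("half or
    more" is inclusive, so a tie at exactly half counts as damaging).
    Returns ``None`` — indeterminate, distinct from False — when every call
    is missing.
    """
    n_avail = profile.n_available
    if n_avail == 0:
        return None
    return profile.n_damaging >= vote_fraction * n_avail


def passes_rarity(profile: AnnotationProfile, threshold: float = 0.05) -> bool:
    """True iff every *present* population frequency is below the threshold.

    A frequency at or above the threshold fails; absence from both panels
    passes (absence from 1000G/ExAC implies rarity).
    """
    for af in (profile.af_1000g, profile.af_exac):
        if af is not None and af >= threshold:
            return False
    return True


def cohort_carrier_fraction(variant: VariantRecord, case_ids: frozenset[str]) -> float:
    """Fraction of the case group carrying the variant."""
    if not case_ids:
        raise ValueError("case set is empty")
    return len(variant.carriers & case_ids) / len(case_ids)


def run_triage(
    cohort: CohortDataset,
    config: TriageConfig = TriageConfig(),
) -> tuple[list[VariantRecord], TriageAudit]:
    """Apply the full filter cascade; return survivors plus an audit trail.

    Survivor order follows the input variant order.  ACMG classification is
    reporting-only and never filters (VUS candidates are retained).
    """
    case_ids = cohort.case_ids
    control_ids = cohort.control_ids
    audit = TriageAudit(n_input=len(cohort.variants))

    def stage_verdicts(v: VariantRecord) -> dict[str, bool]:
        damaging: Optional[bool]
        if v.consequence_class in config.auto_damaging_classes:
            damaging = True
        else:
            damaging = is_damaging_by_vote(v.annotation, config.vote_fraction)
        return {
            "consequence_class": v.consequence_class in config.retained_classes,
            "rarity": passes_rarity(v.annotation, config.population_maf_threshold),
            "control_exclusion": not (v.carriers & control_ids),
            "deleteriousness": damaging is True,
            "carrier_fraction": cohort_carrier_fraction(v, case_ids)
            >= config.cohort_carrier_fraction_threshold,
            "gene_allowlist": config.gene_allowlist is None
            or v.gene in config.gene_allowlist,
        }

    survivors: list[VariantRecord] = []
    alive: list[tuple[VariantRecord, dict[str, bool]]] = [
        (v, stage_verdicts(v)) for v in cohort.variants
    ]
    for stage in STAGES:
        still = []
        for v, verdicts in alive:
            if verdicts[stage]:
                still.append((v, verdicts))
            else:
                audit.removed_by[v.key] = stage
        alive = still
        audit.surviving_after[stage] = len(alive)
    survivors = [v for v, _ in alive]
    return survivors, audit
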