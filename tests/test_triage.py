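"""Filter cascade: vote rule, rarity, carrier fraction, and run_triage."""

import itertools

import pytest

from movscreen.cohort import (
    PREDICTOR_TOOLS,
    AnnotationProfile,
    Call,
    CohortDataset,
    ConsequenceClass,
    SubjectPhenotype,
    VariantRecord,
)
from movscreen.triage import (
    TriageConfig,
    cohort_carrier_fraction,
    is_damaging_by_vote,
    passes_rarity,
    run_triage,
)

D, T, M = Call.DAMAGING, Call.TOLERATED, Call.MISSING


def profile(calls, af_1000g=None, af_exac=None):
    calls = tuple(calls) + tuple([M] * (13 - len(calls)))
    return AnnotationProfile(af_1000g=af_1000g, af_exac=af_exac, predictor_calls=calls)


@pytest.mark.parametrize(
    "n_damaging,n_tolerated,expected",
    [
        (7, 6, True),   # 7 of 13 available: half or more
        (6, 7, False),  # 6 of 13: below half
        (3, 3, True),   # exactly half is inclusive
        (0, 13, False),
        (1, 0, True),   # a single available damaging call carries the vote
    ],
)
def test_vote_rule(n_damaging, n_tolerated, expected):
    p = profile([D] * n_damaging + [T] * n_tolerated)
    assert is_damaging_by_vote(p) is expected


def test_vote_all_missing_is_indeterminate():
    assert is_damaging_by_vote(profile([])) is None


def test_vote_matches_exhaustive_enumeration_on_four_tools():
    """Every 3^4 call vector over a 4-tool reduction agrees with direct counting."""
    for combo in itertools.product([D, T, M], repeat=4):
        p = profile(list(combo))
        avail = [c for c in combo if c is not M]
        expected = None if not avail else (avail.count(D) >= 0.5 * len(avail))
        assert is_damaging_by_vote(p) is expected, combo


@pytest.mark.parametrize(
    "af_1000g,af_exac,expected",
    [
        (0.0129792, None, True),   # rare in 1000G, absent from ExAC
        (0.05, None, False),       # at the threshold is filtered out
        (None, None, True),        # absence from both panels implies rare
        (0.01, 0.09, False),       # either panel at/above threshold fails
    ],
)
def test_rarity(af_1000g, af_exac, expected):
    assert passes_rarity(profile([], af_1000g, af_exac), 0.05) is expected


def _variant(key_pos, carriers, cls=ConsequenceClass.NONSYNONYMOUS_SNV, ann=None, gene="G"):
    return VariantRecord(
        chrom="1", pos=key_pos, ref="A", alt="G", gene=gene, transcript="NM",
        cdna_hgvs=f"c.{key_pos}A>G", protein_hgvs="", consequence_class=cls,
        annotation=ann or profile([D]), carriers=frozenset(carriers),
    )


def _subjects(n_cases, n_controls):
    subs = [
        SubjectPhenotype(subject_id=f"S{i}", group="case", sex="F", age=30, weights={0: 100.0})
        for i in range(n_cases)
    ]
    subs += [
        SubjectPhenotype(subject_id=f"C{i}", group="control", sex="F", age=30, weights={0: 100.0})
        for i in range(n_controls)
    ]
    return subs


def test_carrier_fraction_arithmetic():
    subs = _subjects(62, 0)
    case_ids = frozenset(s.subject_id for s in subs)
    v8 = _variant(1, [f"S{i}" for i in range(8)])
    assert cohort_carrier_fraction(v8, case_ids) == pytest.approx(8 / 62)
    v0 = _variant(2, [])
    assert cohort_carrier_fraction(v0, case_ids) == 0.0
    # smallest k with k/62 >= 0.05 is 4
    assert cohort_carrier_fraction(_variant(3, [f"S{i}" for i in range(4)]), case_ids) >= 0.05
    assert cohort_carrier_fraction(_variant(4, [f"S{i}" for i in range(3)]), case_ids) < 0.05
    with pytest.raises(ValueError):
        cohort_carrier_fraction(v8, frozenset())


def test_run_triage_examples():
    subs = _subjects(10, 2)
    planted = _variant(1, [f"S{i}" for i in range(3)], cls=ConsequenceClass.FRAMESHIFT_INSERTION,
                       ann=profile([]))
    control_hit = _variant(2, ["S0", "C0"], ann=profile([D]))
    synonymous = _variant(3, ["S0", "S1"], cls=ConsequenceClass.SYNONYMOUS_SNV,
                          ann=profile([D] * 13))
    common = _variant(4, ["S0", "S1"], ann=profile([D], af_1000g=0.2))
    cohort = CohortDataset(subjects=subs, variants=[planted, control_hit, synonymous, common])
    survivors, audit = run_triage(cohort)
    assert [v.key for v in survivors] == [planted.key]
    assert audit.removed_by[control_hit.key] == "control_exclusion"
    # class filter precedes the vote: a 13/13-damaging synonymous variant dies at class
    assert audit.removed_by[synonymous.key] == "consequence_class"
    assert audit.removed_by[common.key] == "rarity"


def test_triage_survivors_pass_every_predicate_independently(default_cohort):
    cfg = TriageConfig()
    survivors, _ = run_triage(default_cohort, cfg)
    assert set(v.key for v in survivors) <= set(v.key for v in default_cohort.variants)
    for v in survivors:
        assert v.consequence_class in cfg.retained_classes
        assert passes_rarity(v.annotation, cfg.population_maf_threshold)
        assert not (v.carriers & default_cohort.control_ids)
        assert cohort_carrier_fraction(v, default_cohort.case_ids) >= 0.05
        if v.consequence_class not in cfg.auto_damaging_classes:
            assert is_damaging_by_vote(v.annotation, cfg.vote_fraction) is True


def test_triage_monotone_in_thresholds(default_cohort):
    """Tightening MAF or raising the carrier-fraction bar never adds survivors."""
    base, _ = run_triage(default_cohort, TriageConfig())
    base_keys = {v.key for v in base}
    tighter_maf, _ = run_triage(default_cohort, TriageConfig(population_maf_threshold=0.01))
    assert {v.key for v in tighter_maf} <= base_keys
    higher_cf, _ = run_triage(
        default_cohort, TriageConfig(cohort_carrier_fraction_threshold=0.10)
    )
    assert {v.key for v in higher_cf} <= base_keys


def test_triage_allowlist(default_cohort):
    none_pass, _ = run_triage(
        default_cohort, TriageConfig(gene_allowlist=frozenset({"NOSUCHGENE"}))
    )
    assert none_pass == []
    planted_gene = default_cohort.variants[0].gene
    with_gene, _ = run_triage(
        default_cohort, TriageConfig(gene_allowlist=frozenset({planted_gene}))
    )
    assert [v.gene for v in with_gene] == [planted_gene]


def test_triage_outcome_order_invariant(default_cohort):
    """The surviving set equals the conjunction of predicates regardless of
    the audit's stage order (shuffle input order as a proxy)."""
    import random

    survivors, _ = run_triage(default_cohort)
    shuffled = CohortDataset(
        subjects=default_cohort.subjects,
        variants=random.Random(3).sample(default_cohort.variants, len(default_cohort.variants)),
    )
    survivors2, _ = run_triage(shuffled)
    assert {v.key for v in survivors} == {v.key for v in survivors2}
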