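"""Outcome screen statistics: %TWL, t tests, BH, carrier screen, lipids."""

import math

import numpy as np
import pytest

from movscreen.cohort import (
    AnnotationProfile,
    CohortDataset,
    ConsequenceClass,
    SubjectPhenotype,
    VariantRecord,
)
from movscreen.screen import (
    ScreenConfig,
    bh_adjust,
    carrier_screen,
    independent_t,
    intersection_confounder,
    lipid_analysis,
    percent_weight_loss,
    summarize_cohort,
    summary_t,
)
from movscreen.simulate import SimulationConfig, generate_cohort


def bh_oracle(p):
    """Brute-force BH step-up from its definition, independent of statsmodels."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_percent_weight_loss():
    assert percent_weight_loss(100, 75) == 25
    assert percent_weight_loss(80, 80) == 0
    assert percent_weight_loss(80, 84) == pytest.approx(-5)
    assert percent_weight_loss(100, None) is None
    with pytest.raises(ValueError):
        percent_weight_loss(0, 50)


def test_independent_t_identical_samples():
    t, df, p = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0 and p == 1


def test_independent_t_degenerate_variance():
    t, df, p = independent_t([2.0, 2.0], [2.0, 2.0])
    assert (t, p) == (0.0, 1.0)
    t, df, p = independent_t([3.0, 3.0], [2.0, 2.0])
    assert p == 0.0 and t == math.inf


def test_summary_t_matches_sample_t():
    """summary_t on (mean, sd, n) reproduces independent_t to 1e-12."""
    rng = np.random.default_rng(0)
    for mode in ("pooled", "welch"):
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1.4, 20)
        t1, df1, p1 = independent_t(a, b, mode)
        t2, df2, p2 = summary_t(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), mode
        )
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert df1 == pytest.approx(df2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-12)


def test_pooled_t_agrees_with_permutation_oracle():
    """On a fixed 8-vs-12 draw, the pooled-t p matches a permutation p.

    With the combined sample fixed, the pooled t statistic is monotone in
    the absolute mean difference, so the permutation test uses |mean diff|.
    """
    rng = np.random.default_rng(123)
    a = rng.normal(0.0, 1.0, 8)
    b = rng.normal(1.0, 1.0, 12)
    _, _, p_t = independent_t(a, b, "pooled")
    combined = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n_perm = 100_000
    # random permutations via argsort of uniform noise
    idx = np.argsort(rng.random((n_perm, 20)), axis=1)
    perm = combined[idx]
    diffs = np.abs(perm[:, :8].mean(axis=1) - perm[:, 8:].mean(axis=1))
    p_perm = (1 + np.sum(diffs >= obs)) / (n_perm + 1)
    se = math.sqrt(p_t * (1 - p_t) / n_perm)
    assert abs(p_perm - p_t) < 0.02 + 4 * se


def test_bh_hand_example():
    q = bh_adjust([0.005, 0.1, 0.2, 0.9])
    assert q == pytest.approx([0.02, 0.2, 0.8 / 3, 0.9])


def test_bh_equal_ps_unchanged():
    assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(7)
    for _ in range(200):
        p = rng.random(rng.integers(1, 30))
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# carrier screen on constructed cohorts
# ---------------------------------------------------------------------------

def _cohort_with_twl(twl_by_subject, carriers):
    """Cases only; weights chosen so %TWL at every time point is as given."""
    subjects = []
    for sid, twl in twl_by_subject.items():
        w0 = 100.0
        weights = {0: w0, **{m: w0 * (1 - twl / 100) for m in (1, 3, 6, 12)}}
        subjects.append(
            SubjectPhenotype(subject_id=sid, group="case", sex="F", age=30, weights=weights)
        )
    variant = VariantRecord(
        chrom="1", pos=1, ref="A", alt="G", gene="X", transcript="NM",
        cdna_hgvs="c.1A>G", protein_hgvs="", consequence_class=ConsequenceClass.STOPGAIN,
        annotation=AnnotationProfile(), carriers=frozenset(carriers),
    )
    return CohortDataset(subjects=subjects, variants=[variant]), variant


def test_carrier_screen_large_ps_not_flagged():
    """Overlapping groups with mild separation yield no q < 0.05."""
    rng = np.random.default_rng(1)
    twl = {f"S{i}": float(rng.normal(25, 5)) for i in range(20)}
    cohort, v = _cohort_with_twl(twl, [f"S{i}" for i in range(5)])
    res = carrier_screen(cohort, v)
    assert res.evaluable and not res.flagged
    for tp in res.timepoints:
        assert tp.q >= tp.p  # BH never lowers a p value


def test_carrier_screen_unevaluable_single_carrier():
    twl = {f"S{i}": 25.0 + i for i in range(6)}
    cohort, v = _cohort_with_twl(twl, ["S0"])
    res = carrier_screen(cohort, v)
    assert not res.evaluable and not res.flagged
    assert "fewer than 2" in res.reason


def test_carrier_screen_excludes_controls():
    """Control subjects never enter the comparison even as carriers."""
    cohort = generate_cohort(SimulationConfig(seed=6))
    v = cohort.variants[0]
    res = carrier_screen(cohort, v)
    for tp in res.timepoints:
        assert tp.n_carriers + tp.n_noncarriers <= len(cohort.case_ids)


def test_carrier_screen_group_label_symmetric(default_cohort):
    """Two-sided p values are invariant to which group is 'a'."""
    v = default_cohort.variants[0]
    res = carrier_screen(default_cohort, v)
    case_subjects = [s for s in default_cohort.subjects if s.group == "case"]
    from movscreen.screen import _twl_samples

    carriers = [s for s in case_subjects if s.subject_id in v.carriers]
    noncar = [s for s in case_subjects if s.subject_id not in v.carriers]
    for tp in res.timepoints:
        a = _twl_samples(carriers, tp.month)
        b = _twl_samples(noncar, tp.month)
        t_ab, _, p_ab = independent_t(a, b)
        t_ba, _, p_ba = independent_t(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(tp.p)


def test_intersection_confounder_examples():
    subjects = [
        SubjectPhenotype(subject_id=f"S{i}", group="case", sex="F", age=30, weights={0: 100.0})
        for i in range(10)
    ]

    def var(pos, carriers):
        return VariantRecord(
            chrom="1", pos=pos, ref="A", alt="G", gene=f"G{pos}", transcript="NM",
            cdna_hgvs=f"c.{pos}A>G", protein_hgvs="",
            consequence_class=ConsequenceClass.NONSYNONYMOUS_SNV,
            annotation=AnnotationProfile(), carriers=frozenset(carriers),
        )

    flagged = var(1, ["S0", "S1", "S2"])
    same = var(2, ["S0", "S1", "S2"])          # identical carrier set -> shared
    superset = var(3, ["S0", "S1", "S2", "S3"])  # superset -> shared
    partial = var(4, ["S0", "S1"])             # misses S2 -> not shared
    cohort = CohortDataset(subjects=subjects, variants=[flagged, same, superset, partial])
    assert intersection_confounder(cohort, flagged) == {"G2:c.2A>G", "G3:c.3A>G"}
    # no other variant carried by every carrier -> empty set
    cohort2 = CohortDataset(subjects=subjects, variants=[flagged, partial])
    assert intersection_confounder(cohort2, flagged) == set()


def test_intersection_matches_brute_force_random():
    rng = np.random.default_rng(11)
    ids = [f"S{i}" for i in range(12)]
    subjects = [
        SubjectPhenotype(subject_id=s, group="case", sex="F", age=30, weights={0: 100.0})
        for s in ids
    ]
    for rep in range(30):
        variants = []
        for pos in range(1, 9):
            carriers = [s for s in ids if rng.random() < 0.4]
            variants.append(
                VariantRecord(
                    chrom="1", pos=pos, ref="A", alt="G", gene=f"G{pos}", transcript="NM",
                    cdna_hgvs=f"c.{pos}A>G", protein_hgvs="",
                    consequence_class=ConsequenceClass.NONSYNONYMOUS_SNV,
                    annotation=AnnotationProfile(), carriers=frozenset(carriers),
                )
            )
        cohort = CohortDataset(subjects=subjects, variants=variants)
        flagged = variants[0]
        if not flagged.carriers:
            continue
        brute = {
            v.variant_id
            for v in variants[1:]
            if all(c in v.carriers for c in flagged.carriers)
        }
        assert intersection_confounder(cohort, flagged) == brute


# ---------------------------------------------------------------------------
# lipids and summary
# ---------------------------------------------------------------------------

def test_lipid_missingness_rule(default_cohort):
    """A subject lacking month-12 values contributes to no lipid cell."""
    v = default_cohort.variants[0]
    res = lipid_analysis(default_cohort, v)
    cases = [s for s in default_cohort.subjects if s.group == "case"]
    complete_nc = sum(
        1 for s in cases
        if s.subject_id not in v.carriers and s.lipids[("HDL", 12)] is not None
    )
    hdl_nc = next(
        g for g in res.group_stats if g.lipid == "HDL" and g.group == "noncarriers"
    )
    assert hdl_nc.n == complete_nc
    assert hdl_nc.n < len(cases) - len(v.carriers & default_cohort.case_ids)  # dropout happened


def test_lipid_direction_of_planted_effect(default_cohort):
    v = default_cohort.variants[0]
    res = lipid_analysis(default_cohort, v)
    hdl = next(b for b in res.between_stats if b.lipid == "HDL")
    tg = next(b for b in res.between_stats if b.lipid == "TG")
    assert hdl.mean_pct_change_noncarriers > hdl.mean_pct_change_carriers
    assert tg.mean_pct_change_noncarriers < tg.mean_pct_change_carriers  # deeper TG drop


def test_lipid_log_transform_only_affects_tests(default_cohort):
    """Percentage changes are computed on the raw scale regardless of the
    log-transform set used for the paired tests."""
    v = default_cohort.variants[0]
    raw = lipid_analysis(default_cohort, v, ScreenConfig(log_transform_lipids=frozenset()))
    logged = lipid_analysis(default_cohort, v)
    for a, b in zip(raw.between_stats, logged.between_stats):
        assert a.mean_pct_change_carriers == pytest.approx(b.mean_pct_change_carriers)
    tc_raw = next(g for g in raw.group_stats if g.lipid == "TC" and g.group == "noncarriers")
    tc_log = next(g for g in logged.group_stats if g.lipid == "TC" and g.group == "noncarriers")
    assert tc_raw.paired_p != tc_log.paired_p  # the test itself sees the transform


def test_summarize_cohort_counts_and_p(default_cohort):
    rows = summarize_cohort(default_cohort)
    by_trait = {r["trait"]: r for r in rows}
    assert by_trait["n"]["case"] == 62 and by_trait["n"]["control"] == 9
    m, f = map(int, by_trait["male/female"]["case"].split("/"))
    assert m + f == 62
    assert 0 <= by_trait["bmi"]["p"] <= 1


def test_summarize_identical_groups_all_p_one():
    subjects = []
    for group, prefix in (("case", "S"), ("control", "C")):
        for i in range(5):
            subjects.append(
                SubjectPhenotype(
                    subject_id=f"{prefix}{i}", group=group, sex="F", age=30 + i,
                    bmi=35.0 + i, wc=100.0 + i, whr=1.0, vfl=19.0, pbf=44.0 + i,
                    weights={0: 100.0},
                )
            )
    cohort = CohortDataset(subjects=subjects, variants=[])
    for row in summarize_cohort(cohort):
        if row["trait"] in ("age", "bmi", "wc", "pbf"):
            assert row["p"] == pytest.approx(1.0)
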