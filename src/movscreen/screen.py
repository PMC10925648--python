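"""Postoperative validation screen for candidate variants.

Within the early-onset case group, carriers of one variant are compared to
non-carriers on percent total weight loss (%TWL) at months 1/3/6/12 by
independent t tests, Benjamini-Hochberg adjusted across the four time
points; a candidate is flagged when any adjusted q falls below the
threshold.  Lipid improvement (HDL, LDL, TC, TG; TC/TG log10-transformed
for the tests) is compared baseline vs month 12 by paired t within each
group and by between-group t on per-subject raw-scale percentage changes,
each family BH-adjusted across the four lipids.  A clinical-characteristics group
summary (pooled-t p per continuous trait) and a shared-variant intersection
check round out the screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import LIPIDS, TIME_POINTS, CohortDataset, SubjectPhenotype, VariantRecord

__all__ = [
    "ScreenConfig",
    "TimepointStats",
    "ScreenResult",
    "LipidResult",
    "percent_weight_loss",
    "independent_t",
    "summary_t",
    "bh_adjust",
    "carrier_screen",
    "intersection_confounder",
    "lipid_analysis",
    "summarize_cohort",
]


@dataclass(frozen=True)
class ScreenConfig:
    t_mode: str = "pooled"  # "pooled" | "welch"
    fdr_threshold: float = 0.05
    #: flag when at least this many time points reach q < fdr_threshold
    min_significant_timepoints: int = 1
    log_transform_lipids: frozenset[str] = frozenset({"TC", "TG"})


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def percent_weight_loss(w0: float, wt: Optional[float]) -> Optional[float]:
    """%TWL = 100 x (baseline - current) / baseline; negative = regain.

    Missing follow-up weight yields a missing result (subject excluded at
    that time point).
    """
    if w0 is None or w0 <= 0:
        raise ValueError(f"baseline weight must be > 0, got {w0}")
    if wt is None:
        return None
    if wt <= 0:
        raise ValueError(f"follow-up weight must be > 0, got {wt}")
    return 100.0 * (w0 - wt) / w0


def independent_t(
    sample_a: Sequence[float], sample_b: Sequence[float], mode: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t test; returns (t, df, two-sided p).

    ``pooled`` is the classic Student test, ``welch`` drops the equal
    variance assumption.  Two zero-variance samples with equal means give
    t = 0, p = 1; with unequal means, p = 0 (the test is degenerate and the
    difference is certain at any scale).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, df, 0.0
    if mode == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    elif mode == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError(f"unknown t mode {mode!r}")
    return float(res.statistic), df, float(res.pvalue)


def summary_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    mode: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics; returns (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0.0 and sd2 == 0.0:
        df = float(n1 + n2 - 2)
        if mean1 == mean2:
            return 0.0, df, 1.0
        return math.inf if mean1 > mean2 else -math.inf, df, 0.0
    equal_var = mode == "pooled"
    if mode not in ("pooled", "welch"):
        raise ValueError(f"unknown t mode {mode!r}")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# the carrier screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimepointStats:
    month: int
    n_carriers: int
    n_noncarriers: int
    mean_carriers: float = math.nan
    sd_carriers: float = math.nan
    mean_noncarriers: float = math.nan
    sd_noncarriers: float = math.nan
    t: float = math.nan
    df: float = math.nan
    p: float = math.nan
    q: float = math.nan
    evaluable: bool = False


@dataclass(frozen=True)
class ScreenResult:
    variant_id: str
    timepoints: tuple[TimepointStats, ...]
    flagged: bool
    evaluable: bool
    reason: str = ""

    def to_rows(self) -> list[dict]:
        return [
            {
                "variant": self.variant_id,
                "month": tp.month,
                "n_carriers": tp.n_carriers,
                "n_noncarriers": tp.n_noncarriers,
                "mean_twl_carriers": tp.mean_carriers,
                "sd_twl_carriers": tp.sd_carriers,
                "mean_twl_noncarriers": tp.mean_noncarriers,
                "sd_twl_noncarriers": tp.sd_noncarriers,
                "t": tp.t,
                "df": tp.df,
                "p": tp.p,
                "q": tp.q,
                "flagged": self.flagged,
            }
            for tp in self.timepoints
        ]


def _twl_samples(
    subjects: Sequence[SubjectPhenotype], month: int
) -> np.ndarray:
    vals = [
        percent_weight_loss(s.weights[0], s.weights.get(month)) for s in subjects
    ]
    return np.array([v for v in vals if v is not None], dtype=float)


def carrier_screen(
    cohort: CohortDataset,
    variant: VariantRecord,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Compare %TWL between case carriers and case non-carriers of one variant.

    Controls (late-onset) are excluded.  The BH family is the four time
    points of this variant; families are never pooled across variants.
    Variants with fewer than two carriers or two non-carriers with data at
    every time point yield an unevaluable result, never a silent skip.
    """
    case_ids = cohort.case_ids
    carriers = [s for s in cohort.subjects if s.subject_id in (variant.carriers & case_ids)]
    noncarriers = [
        s for s in cohort.subjects if s.subject_id in case_ids - variant.carriers
    ]

    per_tp: list[TimepointStats] = []
    pvals: list[float] = []
    for month in TIME_POINTS:
        a = _twl_samples(carriers, month)
        b = _twl_samples(noncarriers, month)
        if a.size < 2 or b.size < 2:
            per_tp.append(TimepointStats(month, a.size, b.size, evaluable=False))
            continue
        t, df, p = independent_t(a, b, config.t_mode)
        per_tp.append(
            TimepointStats(
                month=month,
                n_carriers=int(a.size),
                n_noncarriers=int(b.size),
                mean_carriers=float(a.mean()),
                sd_carriers=float(a.std(ddof=1)),
                mean_noncarriers=float(b.mean()),
                sd_noncarriers=float(b.std(ddof=1)),
                t=t,
                df=df,
                p=p,
                evaluable=True,
            )
        )
        pvals.append(p)

    evaluable_idx = [i for i, tp in enumerate(per_tp) if tp.evaluable]
    if not evaluable_idx:
        return ScreenResult(
            variant_id=variant.variant_id,
            timepoints=tuple(per_tp),
            flagged=False,
            evaluable=False,
            reason="fewer than 2 carriers or 2 non-carriers with data at every time point",
        )
    qvals = bh_adjust(pvals)
    filled = list(per_tp)
    for i, q in zip(evaluable_idx, qvals):
        tp = filled[i]
        filled[i] = TimepointStats(
            **{**tp.__dict__, "q": float(q)}
        )
    n_sig = sum(tp.q < config.fdr_threshold for tp in filled if tp.evaluable)
    return ScreenResult(
        variant_id=variant.variant_id,
        timepoints=tuple(filled),
        flagged=n_sig >= config.min_significant_timepoints,
        evaluable=True,
    )


def intersection_confounder(
    cohort: CohortDataset, flagged_variant: VariantRecord
) -> set[str]:
    """Variants (other than the flagged one) carried by *every* carrier of
    the flagged variant.  An empty set rules out a shared confounding
    mutation driving the carrier group's outcome."""
    carriers = flagged_variant.carriers
    if not carriers:
        raise ValueError("flagged variant has no carriers")
    shared: set[str] = set()
    for v in cohort.variants:
        if v.key == flagged_variant.key:
            continue
        if carriers <= v.carriers:
            shared.add(v.variant_id)
    return shared


# ---------------------------------------------------------------------------
# lipid analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidGroupStats:
    lipid: str
    group: str  # carriers | noncarriers
    n: int
    baseline_mean: float = math.nan
    month12_mean: float = math.nan
    paired_t: float = math.nan
    paired_p: float = math.nan
    paired_q: float = math.nan
    mean_pct_change: float = math.nan
    evaluable: bool = False


@dataclass(frozen=True)
class LipidBetweenStats:
    lipid: str
    n_carriers: int
    n_noncarriers: int
    mean_pct_change_carriers: float = math.nan
    mean_pct_change_noncarriers: float = math.nan
    t: float = math.nan
    p: float = math.nan
    q: float = math.nan
    evaluable: bool = False


@dataclass(frozen=True)
class LipidResult:
    variant_id: str
    group_stats: tuple[LipidGroupStats, ...]
    between_stats: tuple[LipidBetweenStats, ...]


def _lipid_pairs(
    subjects: Sequence[SubjectPhenotype], lipid: str
) -> tuple[np.ndarray, np.ndarray]:
    x0, x12 = [], []
    for s in subjects:
        a, b = s.lipids.get((lipid, 0)), s.lipids.get((lipid, 12))
        if a is not None and b is not None:
            x0.append(a)
            x12.append(b)
    return np.array(x0), np.array(x12)


def lipid_analysis(
    cohort: CohortDataset,
    flagged_variant: VariantRecord,
    config: ScreenConfig = ScreenConfig(),
) -> LipidResult:
    """Baseline vs month-12 lipid comparison, carriers vs non-carriers.

    Only subjects with both time points contribute, per lipid.  Paired t
    tests run on log10 values for the configured lipids (TC, TG by
    default); per-subject percentage change is always computed on the raw
    scale.  BH families: the four lipids, separately per paired-test group
    and for the between-group tests.
    """
    case_ids = cohort.case_ids
    groups = {
        "carriers": [
            s for s in cohort.subjects if s.subject_id in (flagged_variant.carriers & case_ids)
        ],
        "noncarriers": [
            s for s in cohort.subjects if s.subject_id in case_ids - flagged_variant.carriers
        ],
    }

    group_stats: list[LipidGroupStats] = []
    for gname, members in groups.items():
        stats_g: list[LipidGroupStats] = []
        pvals, idx = [], []
        for i, lipid in enumerate(LIPIDS):
            x0, x12 = _lipid_pairs(members, lipid)
            if x0.size < 2:
                stats_g.append(LipidGroupStats(lipid, gname, int(x0.size), evaluable=False))
                continue
            if lipid in config.log_transform_lipids:
                t0, t12 = np.log10(x0), np.log10(x12)
            else:
                t0, t12 = x0, x12
            if np.allclose(t0, t12):
                t_stat, p = 0.0, 1.0
            else:
                res = stats.ttest_rel(t12, t0)
                t_stat, p = float(res.statistic), float(res.pvalue)
            pct = 100.0 * (x12 - x0) / x0
            stats_g.append(
                LipidGroupStats(
                    lipid=lipid,
                    group=gname,
                    n=int(x0.size),
                    baseline_mean=float(x0.mean()),
                    month12_mean=float(x12.mean()),
                    paired_t=t_stat,
                    paired_p=p,
                    mean_pct_change=float(pct.mean()),
                    evaluable=True,
                )
            )
            pvals.append(p)
            idx.append(i)
        if pvals:
            for i, q in zip(idx, bh_adjust(pvals)):
                sg = stats_g[i]
                stats_g[i] = LipidGroupStats(**{**sg.__dict__, "paired_q": float(q)})
        group_stats.extend(stats_g)

    between: list[LipidBetweenStats] = []
    pvals, idx = [], []
    for i, lipid in enumerate(LIPIDS):
        pcs = {}
        for gname, members in groups.items():
            x0, x12 = _lipid_pairs(members, lipid)
            pcs[gname] = 100.0 * (x12 - x0) / x0
        a, b = pcs["carriers"], pcs["noncarriers"]
        if a.size < 2 or b.size < 2:
            between.append(
                LipidBetweenStats(lipid, int(a.size), int(b.size), evaluable=False)
            )
            continue
        t, _, p = independent_t(a, b, config.t_mode)
        between.append(
            LipidBetweenStats(
                lipid=lipid,
                n_carriers=int(a.size),
                n_noncarriers=int(b.size),
                mean_pct_change_carriers=float(a.mean()),
                mean_pct_change_noncarriers=float(b.mean()),
                t=t,
                p=p,
                evaluable=True,
            )
        )
        pvals.append(p)
        idx.append(i)
    if pvals:
        for i, q in zip(idx, bh_adjust(pvals)):
            bt = between[i]
            between[i] = LipidBetweenStats(**{**bt.__dict__, "q": float(q)})

    return LipidResult(
        variant_id=flagged_variant.variant_id,
        group_stats=tuple(group_stats),
        between_stats=tuple(between),
    )


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

CONTINUOUS_TRAITS = ("age", "bmi", "wc", "whr", "vfl", "pbf")


def summarize_cohort(cohort: CohortDataset, t_mode: str = "pooled") -> list[dict]:
    """Group summary: counts for sex/comorbidities, mean +/- SD and pooled-t
    p for continuous traits.  All p values are printed; significance at
    0.05 is flagged rather than blanking non-significant cells."""
    groups = {
        "control": [s for s in cohort.subjects if s.group == "control"],
        "case": [s for s in cohort.subjects if s.group == "case"],
    }
    rows: list[dict] = []
    rows.append(
        {
            "trait": "n",
            "control": len(groups["control"]),
            "case": len(groups["case"]),
            "p": math.nan,
            "significant": "",
        }
    )
    for trait, fn in (
        ("male/female", lambda ss: f"{sum(s.sex == 'M' for s in ss)}/{sum(s.sex == 'F' for s in ss)}"),
        ("hypertension", lambda ss: sum(s.hypertension for s in ss)),
        ("diabetes", lambda ss: sum(s.diabetes for s in ss)),
    ):
        rows.append(
            {
                "trait": trait,
                "control": fn(groups["control"]),
                "case": fn(groups["case"]),
                "p": math.nan,
                "significant": "",
            }
        )
    for trait in CONTINUOUS_TRAITS:
        vals = {
            g: np.array([getattr(s, trait) for s in ss if getattr(s, trait) is not None])
            for g, ss in groups.items()
        }
        a, b = vals["control"], vals["case"]
        if a.size >= 2 and b.size >= 2:
            _, _, p = independent_t(a, b, t_mode)
        else:
            p = math.nan
        rows.append(
            {
                "trait": trait,
                "control": f"{a.mean():.2f} +/- {a.std(ddof=1):.2f}" if a.size else ".",
                "case": f"{b.mean():.2f} +/- {b.std(ddof=1):.2f}" if b.size else ".",
                "p": p,
                "significant": "*" if p == p and p < 0.05 else "",
            }
        )
    return rows
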