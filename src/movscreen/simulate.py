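"""Synthetic cohorts with the statistical structure the screen assumes.

The generator emulates a bariatric-surgery exome cohort: 62 early-onset
cases and 9 late-onset controls, a planted rare, truncating candidate
variant carried by 8 cases (and no controls), a background of null variants
with no genotype-outcome association, noisy per-tool deleteriousness calls,
weight trajectories over months 1/3/6/12 and a baseline/month-12 lipid
panel with configured mean improvements (HDL up, TG down, both attenuated
in planted carriers).  Everything is driven by one seed.

Free parameters (trajectory means, noise scales, the planted %TWL deficit)
are documented in the package's methods note; cohort sizes, planted carrier
count, lipid baselines/percent changes and the 12-month dropout rate follow
the study design the screen targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort import (
    LIPIDS,
    PREDICTOR_TOOLS,
    TIME_POINTS,
    AnnotationProfile,
    Call,
    CohortDataset,
    ConsequenceClass,
    SubjectPhenotype,
    VariantRecord,
    write_phenotypes,
    write_variant_files,
)

__all__ = ["SimulationConfig", "generate_cohort", "generate_fixture_files"]

_NULL_CLASSES = (
    ConsequenceClass.NONSYNONYMOUS_SNV,
    ConsequenceClass.SYNONYMOUS_SNV,
    ConsequenceClass.FRAMESHIFT_DELETION,
    ConsequenceClass.STOPGAIN,
    ConsequenceClass.OTHER,
)
_NULL_CLASS_P = (0.55, 0.2, 0.08, 0.07, 0.1)


@dataclass(frozen=True)
class SimulationConfig:
    """All the knobs of the generator; the defaults ARE the study conditions."""

    n_cases: int = 62
    n_controls: int = 9
    time_points: tuple[int, ...] = TIME_POINTS
    n_variants: int = 30  # null background variants, in addition to the planted one

    # planted candidate variant
    planted_gene: str = "CAMKK2"
    planted_carriers: int = 8
    #: %TWL deficit of carriers, percentage points per time point
    planted_deficit_pp: tuple[float, ...] = (3.0, 5.0, 7.0, 8.0)

    # non-carrier weight trajectory: mean %TWL per time point and noise
    twl_mean_pp: tuple[float, ...] = (10.0, 18.0, 25.0, 30.0)
    subject_sd_pp: float = 3.0  # between-subject random effect on %TWL
    timepoint_sd_pp: float = 1.5  # residual per-timepoint noise

    # lipid panel (mmol/L): baseline means/SDs and mean % change to month 12
    lipid_baseline_mean: dict = field(
        default_factory=lambda: {"HDL": 1.15, "LDL": 3.0, "TC": 5.0, "TG": 2.0}
    )
    hdl_baseline_mean_carriers: float = 1.17
    lipid_baseline_sd: dict = field(
        default_factory=lambda: {"HDL": 0.25, "LDL": 0.7, "TC": 0.9, "TG": 0.6}
    )
    lipid_change_noncarrier: dict = field(
        default_factory=lambda: {"HDL": 27.3, "LDL": -15.0, "TC": -3.0, "TG": -29.5}
    )
    #: carrier mean change = non-carrier mean change x attenuation factor
    lipid_attenuation_carrier: dict = field(
        default_factory=lambda: {
            "HDL": 11.5 / 27.3,
            "LDL": 0.5,
            "TC": 1.0,
            "TG": 14.0 / 29.5,
        }
    )
    lipid_change_sd: dict = field(
        default_factory=lambda: {"HDL": 12.0, "LDL": 12.0, "TC": 10.0, "TG": 18.0}
    )

    # anthropometry (location, scale) per group
    bmi_case: tuple[float, float] = (40.13, 5.95)
    bmi_control: tuple[float, float] = (33.52, 3.54)
    wc_case: tuple[float, float] = (121.21, 12.69)
    wc_control: tuple[float, float] = (110.64, 8.20)
    age_case: tuple[float, float] = (28.84, 8.25)
    age_control: tuple[float, float] = (30.00, 5.94)

    # null-variant annotation structure
    rare_fraction: float = 0.5  # fraction of null variants that are population-rare
    predictor_miscall_rate: float = 0.1
    predictor_missing_rate: float = 0.15
    damaging_fraction: float = 0.3  # truly damaging nonsynonymous null variants

    dropout_rate_12m: float = 0.19  # MCAR loss of month-12 weight + lipids

    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_carriers > self.n_cases:
            raise ValueError(
                f"planted_carriers={self.planted_carriers} exceeds n_cases={self.n_cases}"
            )
        for name in ("rare_fraction", "predictor_miscall_rate",
                     "predictor_missing_rate", "damaging_fraction", "dropout_rate_12m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(self.planted_deficit_pp) != len(self.time_points):
            raise ValueError("planted_deficit_pp must match time_points")
        if len(self.twl_mean_pp) != len(self.time_points):
            raise ValueError("twl_mean_pp must match time_points")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from JSON or YAML (keys mirror the dataclass fields)."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        for key in ("time_points", "planted_deficit_pp", "twl_mean_pp",
                    "bmi_case", "bmi_control", "wc_case", "wc_control",
                    "age_case", "age_control"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _truncated_normal(rng: np.random.Generator, mean, sd, size, low=1e-3) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    while np.any(x <= low):
        bad = x <= low
        x[bad] = rng.normal(mean, sd, bad.sum())
    return x


def _predictor_calls(
    rng: np.random.Generator, truly_damaging: bool, miscall: float, missing: float
) -> tuple[Call, ...]:
    calls = []
    for _ in PREDICTOR_TOOLS:
        if rng.random() < missing:
            calls.append(Call.MISSING)
            continue
        call_damaging = truly_damaging != (rng.random() < miscall)
        calls.append(Call.DAMAGING if call_damaging else Call.TOLERATED)
    return tuple(calls)


def generate_cohort(config: SimulationConfig = SimulationConfig()) -> CohortDataset:
    """Generate one cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    case_ids = [f"S{i + 1:03d}" for i in range(n_cases)]
    control_ids = [f"C{i + 1:03d}" for i in range(n_controls)]
    all_ids = case_ids + control_ids

    planted_carrier_ids = frozenset(
        rng.choice(case_ids, size=config.planted_carriers, replace=False)
    )

    subjects = _generate_subjects(
        rng, config, case_ids, control_ids, planted_carrier_ids
    )
    variants = _generate_variants(rng, config, case_ids, control_ids, planted_carrier_ids)
    return CohortDataset(subjects=subjects, variants=variants)


def _generate_subjects(
    rng: np.random.Generator,
    config: SimulationConfig,
    case_ids: list[str],
    control_ids: list[str],
    planted_carrier_ids: frozenset[str],
) -> list[SubjectPhenotype]:
    subjects: list[SubjectPhenotype] = []
    months = config.time_points
    for group, ids in (("case", case_ids), ("control", control_ids)):
        bmi_loc, bmi_sd = config.bmi_case if group == "case" else config.bmi_control
        wc_loc, wc_sd = config.wc_case if group == "case" else config.wc_control
        age_loc, age_sd = config.age_case if group == "case" else config.age_control
        for sid in ids:
            carrier = sid in planted_carrier_ids
            bmi = float(_truncated_normal(rng, bmi_loc, bmi_sd, 1)[0])
            height = float(np.clip(rng.normal(1.66, 0.08), 1.45, 1.95))
            w0 = bmi * height**2

            subj_effect = rng.normal(0.0, config.subject_sd_pp)
            weights: dict[int, Optional[float]] = {0: round(w0, 1)}
            dropout_12m = rng.random() < config.dropout_rate_12m
            for k, m in enumerate(months):
                twl = config.twl_mean_pp[k] + subj_effect + rng.normal(
                    0.0, config.timepoint_sd_pp
                )
                if carrier:
                    twl -= config.planted_deficit_pp[k]
                w = w0 * (1.0 - twl / 100.0)
                weights[m] = None if (m == 12 and dropout_12m) else round(max(w, 30.0), 1)

            lipids: dict[tuple[str, int], Optional[float]] = {}
            for lip in LIPIDS:
                loc = config.lipid_baseline_mean[lip]
                if lip == "HDL" and carrier:
                    loc = config.hdl_baseline_mean_carriers
                base = float(
                    _truncated_normal(rng, loc, config.lipid_baseline_sd[lip], 1, low=0.2)[0]
                )
                change = config.lipid_change_noncarrier[lip]
                if carrier:
                    change *= config.lipid_attenuation_carrier[lip]
                pct = rng.normal(change, config.lipid_change_sd[lip])
                x12 = max(base * (1.0 + pct / 100.0), 0.1)
                lipids[(lip, 0)] = round(base, 3)
                lipids[(lip, 12)] = None if dropout_12m else round(x12, 3)

            subjects.append(
                SubjectPhenotype(
                    subject_id=sid,
                    group=group,
                    sex="M" if rng.random() < 0.47 else "F",
                    age=round(float(_truncated_normal(rng, age_loc, age_sd, 1, low=16.0)[0]), 1),
                    hypertension=bool(rng.random() < 0.16),
                    diabetes=bool(rng.random() < 0.21),
                    bmi=round(bmi, 2),
                    wc=round(float(_truncated_normal(rng, wc_loc, wc_sd, 1)[0]), 1),
                    whr=round(float(rng.normal(1.0, 0.06)), 2),
                    vfl=round(float(_truncated_normal(rng, 19.0, 2.0, 1)[0]), 1),
                    pbf=round(float(_truncated_normal(rng, 44.5, 6.0, 1)[0]), 1),
                    weights=weights,
                    lipids=lipids,
                )
            )
    return subjects


def _generate_variants(
    rng: np.random.Generator,
    config: SimulationConfig,
    case_ids: list[str],
    control_ids: list[str],
    planted_carrier_ids: frozenset[str],
) -> list[VariantRecord]:
    all_ids = case_ids + control_ids
    variants: list[VariantRecord] = [
        VariantRecord(
            chrom="12",
            pos=121_243_614,
            ref="C",
            alt="CA",
            gene=config.planted_gene,
            transcript="NM_001270486.1",
            cdna_hgvs="c.1614dup",
            protein_hgvs="p.Gly539Argfs*3",
            consequence_class=ConsequenceClass.FRAMESHIFT_INSERTION,
            annotation=AnnotationProfile(
                af_1000g=None,
                af_exac=None,
                predictor_calls=tuple([Call.MISSING] * len(PREDICTOR_TOOLS)),
            ),
            carriers=planted_carrier_ids,
            zygosity={s: 1 for s in sorted(planted_carrier_ids)},
            acmg_tags="PM2",
        )
    ]
    for i in range(config.n_variants):
        rare = rng.random() < config.rare_fraction
        if rare:
            af = float(10 ** rng.uniform(-4, np.log10(0.05) - 0.05))
        else:
            af = float(rng.uniform(0.05, 0.4))
        af_exac = None if rng.random() < 0.3 else float(
            np.clip(af * rng.uniform(0.5, 1.5), 0.0, 1.0)
        )
        # carrier status independent of phenotype: null association by design
        p_carry = min(2 * af + 0.01, 0.95)
        carrier_mask = rng.random(len(all_ids)) < p_carry
        carriers = frozenset(np.array(all_ids)[carrier_mask])
        cls = _NULL_CLASSES[rng.choice(len(_NULL_CLASSES), p=_NULL_CLASS_P)]
        damaging = rng.random() < config.damaging_fraction
        variants.append(
            VariantRecord(
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(10_000, 50_000_000)),
                ref="ACGT"[rng.integers(0, 4)],
                alt="ACGT"[rng.integers(0, 4)] * 2 if "frameshift" in cls.value else "ACGT"[rng.integers(0, 4)],
                gene=f"GENE{i + 1:03d}",
                transcript=f"NM_{rng.integers(1000, 999999):06d}.1",
                cdna_hgvs=f"c.{int(rng.integers(1, 3000))}A>G",
                protein_hgvs="",
                consequence_class=cls,
                annotation=AnnotationProfile(
                    af_1000g=af,
                    af_exac=af_exac,
                    predictor_calls=_predictor_calls(
                        rng, damaging, config.predictor_miscall_rate,
                        config.predictor_missing_rate,
                    ),
                ),
                carriers=carriers,
                zygosity={s: 1 for s in sorted(carriers)},
            )
        )
    # REF==ALT collisions would make degenerate keys; regenerate deterministically
    fixed = []
    for v in variants:
        if v.ref == v.alt:
            fixed.append(
                VariantRecord(**{**v.__dict__, "alt": "T" if v.ref != "T" else "G"})
            )
        else:
            fixed.append(v)
    return fixed


def generate_fixture_files(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write the VCF + annotation TSV + phenotype TSV for one cohort.

    Re-reading the files through the cohort readers reproduces the
    in-memory cohort exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    subject_ids = [s.subject_id for s in cohort.subjects]
    write_variant_files(cohort.variants, subject_ids, paths["vcf"], paths["annotations"])
    write_phenotypes(cohort.subjects, paths["phenotypes"])
    return paths
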