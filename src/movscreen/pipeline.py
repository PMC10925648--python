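"""End-to-end orchestration: simulate (or load) -> triage -> classify ->
screen -> report, with one seed and a machine-readable manifest.

Re-running with the same config and seed is byte-identical: no timestamps
are written, all randomness flows from the seed, and output rows are in
deterministic order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .acmg import AcmgEvidence, classify
from .cohort import CohortDataset, read_phenotypes, read_variants
from .screen import (
    ScreenConfig,
    carrier_screen,
    intersection_confounder,
    lipid_analysis,
    summarize_cohort,
)
from .simulate import SimulationConfig, generate_fixture_files
from .triage import TriageConfig, run_triage

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = 3):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    # either a simulation block ...
    simulation: Optional[SimulationConfig] = None
    # ... or paths to existing inputs
    vcf_path: Optional[Path] = None
    annotation_path: Optional[Path] = None
    phenotype_path: Optional[Path] = None
    triage: TriageConfig = field(default_factory=TriageConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    acmg_engine: str = "points"

    def validate(self) -> None:
        have_paths = all(
            p is not None for p in (self.vcf_path, self.annotation_path, self.phenotype_path)
        )
        if self.simulation is None and not have_paths:
            raise PipelineError(
                "config",
                "either a simulation block or all three input paths "
                "(vcf, annotations, phenotypes) must be given",
                exit_code=1,
            )


def _load_cohort(config: PipelineConfig) -> CohortDataset:
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
        paths = generate_fixture_files(sim, Path(config.out_dir) / "simulated")
        variants = read_variants(paths["vcf"], paths["annotations"])
        subjects = read_phenotypes(paths["phenotypes"])
        return CohortDataset(subjects=subjects, variants=variants)
    variants = read_variants(config.vcf_path, config.annotation_path)
    subjects = read_phenotypes(config.phenotype_path)
    return CohortDataset(subjects=subjects, variants=variants)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = _load_cohort(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc), exit_code=2) from exc

    header = f"# movscreen {__version__} seed={config.seed}\n"

    try:
        candidates, audit = run_triage(cohort, config.triage)
        audit_df = pd.DataFrame(audit.to_rows())
        with open(out / "triage_audit.tsv", "w") as fh:
            fh.write(header)
            audit_df.to_csv(fh, sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("triage", str(exc)) from exc

    try:
        cand_rows = []
        for v in candidates:
            row = {
                "gene": v.gene,
                "transcript": v.transcript,
                "cdna_hgvs": v.cdna_hgvs,
                "protein_hgvs": v.protein_hgvs,
                "consequence_class": v.consequence_class.value,
                "af_1000g": v.annotation.af_1000g,
                "af_exac": v.annotation.af_exac,
                "acmg_tags": v.acmg_tags,
                "acmg_class": (
                    classify(AcmgEvidence.from_string(v.acmg_tags), config.acmg_engine).classification.value
                    if v.acmg_tags
                    else ""
                ),
                "carriers": len(v.carriers & cohort.case_ids),
                "total": len(cohort.case_ids),
            }
            cand_rows.append(row)
        with open(out / "candidates.tsv", "w") as fh:
            fh.write(header)
            pd.DataFrame(
                cand_rows,
                columns=["gene", "transcript", "cdna_hgvs", "protein_hgvs",
                         "consequence_class", "af_1000g", "af_exac", "acmg_tags",
                         "acmg_class", "carriers", "total"],
            ).to_csv(fh, sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    try:
        screen_rows, flagged = [], []
        lipid_rows, intersection = [], {}
        for v in candidates:
            res = carrier_screen(cohort, v, config.screen)
            screen_rows.extend(res.to_rows())
            if res.flagged:
                flagged.append(v.variant_id)
                intersection[v.variant_id] = sorted(intersection_confounder(cohort, v))
                lr = lipid_analysis(cohort, v, config.screen)
                for gs in lr.group_stats:
                    lipid_rows.append({"variant": lr.variant_id, **gs.__dict__})
                for bs in lr.between_stats:
                    lipid_rows.append({"variant": lr.variant_id, "group": "between", **bs.__dict__})
        with open(out / "screen.tsv", "w") as fh:
            fh.write(header)
            pd.DataFrame(screen_rows).to_csv(fh, sep="\t", index=False)
        with open(out / "lipids.tsv", "w") as fh:
            fh.write(header)
            pd.DataFrame(lipid_rows).to_csv(fh, sep="\t", index=False)
        with open(out / "cohort_summary.tsv", "w") as fh:
            fh.write(header)
            pd.DataFrame(summarize_cohort(cohort, config.screen.t_mode)).to_csv(
                fh, sep="\t", index=False
            )
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": len(cohort.subjects),
        "n_cases": len(cohort.case_ids),
        "n_controls": len(cohort.control_ids),
        "n_variants_input": len(cohort.variants),
        "stage_counts": audit.surviving_after,
        "n_candidates": len(candidates),
        "flagged_variants": flagged,
        "intersection_check": intersection,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    report_lines = [
        f"movscreen {__version__} (seed {config.seed})",
        f"cohort: {manifest['n_cases']} cases, {manifest['n_controls']} controls, "
        f"{manifest['n_variants_input']} variants",
        f"triage survivors: {manifest['n_candidates']}",
        f"flagged candidate MOVs: {', '.join(flagged) if flagged else 'none'}",
    ]
    for vid, shared in intersection.items():
        outcome = ", ".join(shared) if shared else "no shared variant across all carriers"
        report_lines.append(f"intersection check [{vid}]: {outcome}")
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    return manifest
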