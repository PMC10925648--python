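#!/usr/bin/env python
"""Run the rare-variant filter cascade on the simulated cohort.

Reads results/cohort/ (run 01 first), applies the triage rules — retained
consequence classes, population MAF < 5%, zero control carriers, the
13-predictor damaging vote, case carrier fraction >= 5% — and writes the
surviving candidates plus the per-stage audit to results/triage/.
"""

from pathlib import Path

import pandas as pd

from movscreen.cohort import CohortDataset, read_phenotypes, read_variants
from movscreen.triage import TriageConfig, run_triage

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "triage"


def main() -> None:
    cohort = CohortDataset(
        subjects=read_phenotypes(ROOT / "cohort" / "phenotypes.tsv"),
        variants=read_variants(ROOT / "cohort" / "cohort.vcf", ROOT / "cohort" / "annotations.tsv"),
    )
    survivors, audit = run_triage(cohort, TriageConfig())
    OUT.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "gene": v.gene, "transcript": v.transcript, "cdna_hgvs": v.cdna_hgvs,
            "protein_hgvs": v.protein_hgvs, "consequence_class": v.consequence_class.value,
            "af_1000g": v.annotation.af_1000g, "af_exac": v.annotation.af_exac,
            "acmg_tags": v.acmg_tags,
            "carriers": len(v.carriers & cohort.case_ids), "total": len(cohort.case_ids),
        }
        for v in survivors
    ]
    pd.DataFrame(rows).to_csv(OUT / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(audit.to_rows()).to_csv(OUT / "triage_audit.tsv", sep="\t", index=False)
    print("stage counts:", audit.surviving_after)
    print(f"{len(survivors)} candidate(s):", ", ".join(v.variant_id for v in survivors))


if __name__ == "__main__":
    main()
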