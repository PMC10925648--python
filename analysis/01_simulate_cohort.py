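#!/usr/bin/env python
"""Generate the default synthetic cohort and write its three input files.

The cohort mirrors the study design the screen targets: 62 early-onset
cases, 9 late-onset controls, one planted rare truncating variant carried
by 8 cases, and 30 null background variants.  Outputs land in
results/cohort/ (VCF + annotation TSV + phenotype TSV) and a short summary
is printed.
"""

import sys
from pathlib import Path

from movscreen.cohort import read_phenotypes, read_variants
from movscreen.simulate import SimulationConfig, generate_fixture_files

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    paths = generate_fixture_files(cfg, OUT)
    variants = read_variants(paths["vcf"], paths["annotations"])
    subjects = read_phenotypes(paths["phenotypes"])
    n_cases = sum(s.group == "case" for s in subjects)
    planted = variants[0]
    print(f"wrote {len(paths)} files to {OUT}")
    print(f"cohort: {n_cases} cases, {len(subjects) - n_cases} controls, "
          f"{len(variants)} variants")
    print(f"planted variant {planted.gene} {planted.cdna_hgvs}: "
          f"{len(planted.carriers)}/{n_cases} case carriers")


if __name__ == "__main__":
    main()
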