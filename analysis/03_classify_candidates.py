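#!/usr/bin/env python
"""Classify the bundled candidate-variant table under both ACMG engines.

For each of the six published candidates, combines its external-classifier
evidence tags with (a) the literal combining rules and (b) the additive
points heuristic, and compares both against the class reported with the
table.  The PM4+PM2+BP4 rows are expected to disagree: their reported LP is
unreachable at default strengths (see docs/methods.md).  Writes
results/acmg_classes.tsv.
"""

from pathlib import Path

import pandas as pd

from movscreen.acmg import AcmgEvidence, classify_points, classify_rules
from movscreen.candidates import load_candidate_table

OUT = Path(__file__).resolve().parents[1] / "results"

SHORT = {"pathogenic": "P", "likely_pathogenic": "LP", "VUS": "VUS",
         "likely_benign": "LB", "benign": "B"}


def main() -> None:
    table = load_candidate_table()
    rows = []
    for _, r in table.iterrows():
        ev = AcmgEvidence.from_string(r["acmg_tags"])
        points = classify_points(ev)
        rules = classify_rules(ev)
        rows.append(
            {
                "gene": r["gene"],
                "acmg_tags": r["acmg_tags"],
                "reported": r["acmg_class_reported"],
                "points_engine": SHORT[points.classification.value],
                "points": points.points,
                "rules_engine": SHORT[rules.classification.value],
                "points_matches_reported": SHORT[points.classification.value] == r["acmg_class_reported"],
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "acmg_classes.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    n_match = int(df["points_matches_reported"].sum())
    print(f"\npoints engine reproduces {n_match}/{len(df)} reported classes; "
          "the PM4+PM2+BP4 rows need an explicit strength override to reach LP")


if __name__ == "__main__":
    main()
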