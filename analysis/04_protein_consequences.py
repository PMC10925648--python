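#!/usr/bin/env python
"""Protein-level consequences of the candidate truncating/extending variants.

Parses each candidate's protein HGVS, computes the implied mutant length
where the notation defines one, cross-checks the CAMKK2 frameshift by
translating a constructed CDS carrying the base-1614 duplication, and
evaluates the NMD 50-nt rule for the new stop over a range of final-exon
placements.  Writes results/consequences.tsv.
"""

from pathlib import Path

import pandas as pd

from movscreen.candidates import load_candidate_table
from movscreen.consequence import (
    TranscriptModel,
    apply_single_base_dup,
    build_dup_fixture,
    mutant_protein_length,
    parse_protein_hgvs,
    predict_nmd,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = load_candidate_table()
    rows = []
    for _, r in table.iterrows():
        c = parse_protein_hgvs(r["protein_hgvs"])
        wt = None if pd.isna(r["wild_type_length"]) else int(r["wild_type_length"])
        mut = (
            mutant_protein_length(c, wt)
            if c.kind in ("frameshift", "stop_extension")
            else None
        )
        rows.append(
            {
                "gene": r["gene"],
                "protein_hgvs": r["protein_hgvs"],
                "kind": c.kind,
                "first_changed_residue": c.first_changed_residue,
                "ter_offset": c.ter_offset,
                "wild_type_length": wt,
                "mutant_length": mut,
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "consequences.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    # translation cross-check of the CAMKK2-style frameshift
    cds, dup_pos = build_dup_fixture(wild_type_length=556, fs_residue=539, ter_offset=3)
    mutant = apply_single_base_dup(cds, dup_pos)
    print(f"\ntranslation cross-check: dup at CDS position {dup_pos} -> "
          f"{len(mutant)} aa mutant (notation arithmetic gives "
          f"{mutant_protein_length(parse_protein_hgvs('p.Gly539Argfs*3'), 556)})")

    # NMD: new stop at codon 541 of a 1671-nt CDS; the junction can be at
    # most 49 nt downstream of the stop's first base, so the rule says escape
    for exons in ((1500, 171), (1670, 1), (1671,)):
        model = TranscriptModel(exon_lengths=exons)
        print(f"NMD 50-nt rule, exon structure {exons}: PTC codon 541 -> "
              f"{predict_nmd(model, 541)}")


if __name__ == "__main__":
    main()
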