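"""Bundled candidate-variant table: the six variants selected for
postoperative verification in an early-onset obesity exome cohort, with
their external-classifier ACMG evidence tags and reported classes.

Used by the worked examples, the consequence arithmetic, and the ACMG
batch classifier; wild-type protein lengths are filled only where
authoritative (printed for CAMKK2, implied by the stop position for the
two stop-loss extensions).
"""

from __future__ import annotations

from importlib.resources import files
from io import StringIO

import pandas as pd

__all__ = ["load_candidate_table"]


def load_candidate_table() -> pd.DataFrame:
    """The bundled candidate table as a DataFrame ('.' -> NA)."""
    text = files("movscreen").joinpath("data/candidate_variants.tsv").read_text()
    df = pd.read_csv(StringIO(text), sep="\t", na_values=["."])
    return df
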