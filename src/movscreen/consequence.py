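"""Protein-level consequence arithmetic for truncating and extending variants.

Covers the HGVS p. notations that matter for candidate-MOV reporting:

* frameshift ``RefPos Alt fs*N`` — the altered residue is position 1 of the
  shifted frame and the new stop is shifted codon N, so the mutant protein
  has ``pos + N - 2`` residues (the stop is never counted);
* stop-loss extension ``*Pos Alt ext*N`` — translation runs N codons past
  the former stop, giving ``(pos - 1) + N`` residues;
* simple missense ``RefPosAlt`` and nonsense ``RefPos*``.

A translation oracle (``apply_single_base_dup`` over a constructed CDS)
verifies the arithmetic end-to-end, and ``predict_nmd`` implements the
canonical 50-nt rule for nonsense-mediated decay.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "ProteinConsequence",
    "TranscriptModel",
    "HgvsParseError",
    "parse_protein_hgvs",
    "format_protein_hgvs",
    "mutant_protein_length",
    "apply_single_base_dup",
    "build_dup_fixture",
    "predict_nmd",
]

AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val Sec Ter"
).split()
_AA3_RE = "|".join(AA3)

_STOPS = ("TAA", "TAG", "TGA")


class HgvsParseError(ValueError):
    """Unparseable HGVS protein notation; message carries the offending token."""


@dataclass(frozen=True)
class ProteinConsequence:
    """Structured protein-level consequence.

    ``ter_offset`` is the N of ``fs*N`` (codons from the altered residue to
    the new stop, counting the altered residue as 1) or of ``ext*N``
    (codons appended past the former stop).  Lengths exclude the stop codon.
    """

    kind: str  # frameshift | stop_extension | missense | nonsense
    first_changed_residue: int
    ref_aa: str = ""
    alt_aa: str = ""
    ter_offset: Optional[int] = None
    wild_type_length: Optional[int] = None
    mutant_length: Optional[int] = None

    def with_lengths(self, wild_type_length: int) -> "ProteinConsequence":
        return replace(
            self,
            wild_type_length=wild_type_length,
            mutant_length=mutant_protein_length(self, wild_type_length),
        )


_FS_RE = re.compile(rf"^({_AA3_RE})(\d+)({_AA3_RE})?fs\*(\d+)$")
_EXT_RE = re.compile(rf"^\*(\d+)({_AA3_RE})ext\*(\d+)$")
_MIS_RE = re.compile(rf"^({_AA3_RE})(\d+)({_AA3_RE}|\*)$")


def parse_protein_hgvs(text: str) -> ProteinConsequence:
    """Parse ``p.`` notation; whitespace after ``p.`` is tolerated
    (published tables print e.g. ``p. Gly539Argfs*3``)."""
    body = text.strip()
    if body.startswith("p."):
        body = body[2:].strip()
    body = body.replace(" ", "")
    if m := _FS_RE.match(body):
        ref, pos, alt, n = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
        return ProteinConsequence(
            kind="frameshift", first_changed_residue=pos, ref_aa=ref, alt_aa=alt, ter_offset=n
        )
    if m := _EXT_RE.match(body):
        pos, alt, n = int(m.group(1)), m.group(2), int(m.group(3))
        return ProteinConsequence(
            kind="stop_extension", first_changed_residue=pos, ref_aa="Ter", alt_aa=alt, ter_offset=n
        )
    if m := _MIS_RE.match(body):
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        kind = "nonsense" if alt == "*" else "missense"
        return ProteinConsequence(kind=kind, first_changed_residue=pos, ref_aa=ref, alt_aa=alt)
    raise HgvsParseError(f"cannot parse protein HGVS {text!r} (token {body!r})")


def format_protein_hgvs(c: ProteinConsequence) -> str:
    if c.kind == "frameshift":
        return f"p.{c.ref_aa}{c.first_changed_residue}{c.alt_aa}fs*{c.ter_offset}"
    if c.kind == "stop_extension":
        return f"p.*{c.first_changed_residue}{c.alt_aa}ext*{c.ter_offset}"
    return f"p.{c.ref_aa}{c.first_changed_residue}{c.alt_aa}"


def mutant_protein_length(c: ProteinConsequence, wild_type_length: Optional[int] = None) -> int:
    """Mutant protein length (aa, stop excluded) implied by the notation.

    * frameshift ``fs*N``: the new stop is codon ``pos + N - 1``, so the
      protein is ``pos + N - 2`` residues long;
    * extension ``ext*N``: the former stop at ``pos`` means ``pos - 1``
      wild-type residues, plus N appended.
    """
    if c.kind == "frameshift":
        assert c.ter_offset is not None
        return c.first_changed_residue + c.ter_offset - 2
    if c.kind == "stop_extension":
        assert c.ter_offset is not None
        return (c.first_changed_residue - 1) + c.ter_offset
    raise ValueError(
        f"mutant length is only defined by fs*/ext* arithmetic, not for {c.kind!r}"
    )


def apply_single_base_dup(cds_sequence: str, duplicated_position: int) -> str:
    """Duplicate one base of a CDS and translate the result to the first stop.

    The CDS must start with ATG, end with a stop codon, and have length
    divisible by 3.  Returns the mutant protein (one-letter, stop excluded).
    A shifted frame with no stop before the sequence end raises, reported as
    a read-through outcome.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    if cds[-3:] not in _STOPS:
        raise ValueError("CDS does not end with a stop codon")
    if not 1 <= duplicated_position <= len(cds):
        raise ValueError(f"duplicated_position {duplicated_position} outside CDS")
    i = duplicated_position  # 1-based
    mutant = cds[:i] + cds[i - 1] + cds[i:]
    n_codons_available = len(mutant) // 3
    in_frame = mutant[: 3 * n_codons_available]  # drop the dangling partial codon
    protein = str(Seq(in_frame).translate(to_stop=True))
    # translate(to_stop) silently hits the end if no stop; detect read-through
    if len(protein) == n_codons_available:
        raise ValueError(
            "no stop codon in the shifted frame before the end of the sequence "
            "(stop-loss / read-through outcome)"
        )
    return protein


def build_dup_fixture(
    wild_type_length: int, fs_residue: int, ter_offset: int
) -> tuple[str, int]:
    """Construct a CDS in which duplicating the last base of codon
    ``fs_residue - 1`` yields the frameshift ``p.GlyXArgfs*N``.

    Returns ``(cds, duplicated_position)``.  The wild-type CDS encodes
    ``wild_type_length`` residues plus a stop, with Gly at ``fs_residue``;
    after the duplication the shifted frame reads Arg there and terminates
    at shifted codon ``fs_residue + ter_offset - 1``.  Used as the
    translation oracle for the fs*N arithmetic.
    """
    if ter_offset < 2:
        raise ValueError("ter_offset must be >= 2 (the altered residue is not a stop)")
    if not 3 <= fs_residue <= wild_type_length:
        raise ValueError("fs_residue must lie within the coding region (>= 3)")
    if fs_residue + ter_offset - 1 > wild_type_length:
        raise ValueError("shifted stop would fall beyond the wild-type stop")

    codons = ["GCT"] * wild_type_length  # Ala filler
    codons[0] = "ATG"
    codons[fs_residue - 2] = "GCA"  # ends in A: the duplicated base
    if ter_offset == 2:
        codons[fs_residue - 1] = "GGT"  # Gly; trailing T starts the shifted stop
    else:
        codons[fs_residue - 1] = "GGC"  # Gly; trailing C keeps shifted frame open
        # shifted codon j reads (last base of wt codon j-1) + (first 2 of wt codon j):
        # GCC fillers end in C so no shifted stop can form before the target
        for j in range(fs_residue, fs_residue + ter_offset - 3):
            codons[j] = "GCC"
        codons[fs_residue + ter_offset - 3] = "GCT"  # trailing T feeds the stop
    codons[fs_residue + ter_offset - 2] = "AAA"  # TAA in the shifted frame
    cds = "".join(codons) + "TAA"
    dup_position = 3 * (fs_residue - 1)  # last base of codon fs_residue-1
    return cds, dup_position


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of a spliced transcript in CDS coordinates.

    ``exon_lengths`` are the nucleotide lengths of the CDS portion of each
    exon; exon-exon junctions fall at the cumulative sums (all but the last).
    """

    exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exon_lengths or any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def junctions(self) -> tuple[int, ...]:
        """Junction positions: nt index of the last base of each non-terminal exon."""
        out, acc = [], 0
        for l in self.exon_lengths[:-1]:
            acc += l
            out.append(acc)
        return tuple(out)


def predict_nmd(
    model: TranscriptModel, ptc_codon: int, boundary_nt: int = 50
) -> str:
    """Canonical 50-nt rule: ``"degraded"`` iff the premature termination
    codon lies more than ``boundary_nt`` upstream of the last exon-exon
    junction (spliced-transcript coordinates); otherwise ``"escapes"``.

    The boundary is inclusive for escape (exactly 50 nt upstream escapes).
    Single-exon transcripts have no junction and always escape.  Distance is
    measured from the first base of the PTC.
    """
    ptc_start_nt = 3 * (ptc_codon - 1) + 1
    if not 1 <= ptc_start_nt <= model.cds_length:
        raise ValueError(f"PTC codon {ptc_codon} outside the CDS")
    junctions = model.junctions
    if not junctions:
        return "escapes"
    distance = junctions[-1] - ptc_start_nt
    return "degraded" if distance > boundary_nt else "escapes"
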