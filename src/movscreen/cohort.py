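"""Cohort data model: variants, annotations, phenotypes, and their file formats.

The screening pipeline starts from a *called and annotated* variant table,
not from reads.  Three plain-text files describe one cohort:

* a minimal VCF v4.2 (fixed columns plus per-subject ``GT``),
* an annotation sidecar TSV keyed by ``CHROM:POS:REF:ALT`` carrying the gene,
  transcript, HGVS names, consequence class, population allele frequencies
  (1000 Genomes, ExAC) and 13 per-tool damaging/tolerated calls, and
* a phenotype TSV with one row per subject (group, covariates, the weight
  trajectory at months 1/3/6/12 and the lipid panel at baseline/month 12).

Missing values are written as ``.`` (or an empty cell) and round-trip to an
explicit missing state — never to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "PREDICTOR_TOOLS",
    "Call",
    "ConsequenceClass",
    "AnnotationProfile",
    "VariantRecord",
    "SubjectPhenotype",
    "CohortDataset",
    "VcfParseError",
    "ValidationError",
    "read_variants",
    "read_phenotypes",
    "write_variant_files",
    "write_phenotypes",
]

#: Fixed, ordered list of the 13 deleteriousness predictors (dbNSFP tools).
PREDICTOR_TOOLS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "PROVEAN",
    "MetaSVM",
    "MetaLR",
    "M-CAP",
    "CADD",
    "fathmm-MKL",
)

#: Weight follow-up time points, in months after surgery.
TIME_POINTS: tuple[int, ...] = (1, 3, 6, 12)

#: Lipid panel analytes (mmol/L).
LIPIDS: tuple[str, ...] = ("HDL", "LDL", "TC", "TG")


class Call(str, Enum):
    """Ternary per-tool deleteriousness call."""

    DAMAGING = "D"
    TOLERATED = "T"
    MISSING = "."


class ConsequenceClass(str, Enum):
    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    SYNONYMOUS_SNV = "synonymous_snv"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    OTHER = "other"


class VcfParseError(ValueError):
    """Malformed VCF content; the message names the offending line number."""


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


@dataclass(frozen=True)
class AnnotationProfile:
    """Population frequencies and the 13 predictor calls for one variant.

    ``af_1000g`` / ``af_exac`` are alternate-allele frequencies in [0, 1];
    ``None`` means the variant is absent from (or unscored in) that panel.
    """

    af_1000g: Optional[float] = None
    af_exac: Optional[float] = None
    predictor_calls: tuple[Call, ...] = tuple([Call.MISSING] * len(PREDICTOR_TOOLS))

    def __post_init__(self) -> None:
        if len(self.predictor_calls) != len(PREDICTOR_TOOLS):
            raise ValidationError(
                f"expected {len(PREDICTOR_TOOLS)} predictor calls, "
                f"got {len(self.predictor_calls)}"
            )
        for af, name in ((self.af_1000g, "af_1000g"), (self.af_exac, "af_exac")):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValidationError(f"{name}={af} outside [0, 1]")

    @property
    def n_available(self) -> int:
        return sum(c is not Call.MISSING for c in self.predictor_calls)

    @property
    def n_damaging(self) -> int:
        return sum(c is Call.DAMAGING for c in self.predictor_calls)


@dataclass(frozen=True)
class VariantRecord:
    """One variant: identity, consequence, annotation, and carrier set.

    A subject is a carrier iff its genotype contains at least one alternate
    allele; zygosity is retained in ``zygosity`` but no downstream rule
    consumes it (carrier counts in the study never distinguish het/hom).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    cdna_hgvs: str
    protein_hgvs: str
    consequence_class: ConsequenceClass
    annotation: AnnotationProfile
    carriers: frozenset[str] = frozenset()
    zygosity: Mapping[str, int] = field(default_factory=dict)  # subject -> n alt alleles
    acmg_tags: str = ""  # comma-separated evidence codes, optional input

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def variant_id(self) -> str:
        return f"{self.gene}:{self.cdna_hgvs}" if self.gene else self.key


@dataclass
class SubjectPhenotype:
    """One subject's group, covariates, weight trajectory and lipid panel."""

    subject_id: str
    group: str  # "case" (early-onset) | "control" (late-onset)
    sex: str  # "M" | "F"
    age: float
    hypertension: bool = False
    diabetes: bool = False
    bmi: Optional[float] = None
    wc: Optional[float] = None
    whr: Optional[float] = None
    vfl: Optional[float] = None
    pbf: Optional[float] = None
    #: weight (kg) keyed by month; 0 = baseline (always present), 1/3/6/12 follow-up
    weights: dict[int, Optional[float]] = field(default_factory=dict)
    #: lipids (mmol/L) keyed by (analyte, month) with month in {0, 12}
    lipids: dict[tuple[str, int], Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValidationError(f"group must be case|control, got {self.group!r}")
        w0 = self.weights.get(0)
        if w0 is None or w0 <= 0:
            raise ValidationError(f"{self.subject_id}: baseline weight missing or <= 0")
        for m, w in self.weights.items():
            if w is not None and w <= 0:
                raise ValidationError(f"{self.subject_id}: weight_{m}m = {w} <= 0")
        for (lip, m), v in self.lipids.items():
            if v is not None and v <= 0:
                raise ValidationError(f"{self.subject_id}: {lip}_{m}m = {v} <= 0")


@dataclass
class CohortDataset:
    """A cohort: subjects plus the variant table called on them."""

    subjects: list[SubjectPhenotype]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate subject ids in cohort")
        known = set(ids)
        for v in self.variants:
            stray = set(v.carriers) - known
            if stray:
                raise ValidationError(
                    f"variant {v.key}: carriers {sorted(stray)} not in cohort"
                )

    @property
    def case_ids(self) -> frozenset[str]:
        return frozenset(s.subject_id for s in self.subjects if s.group == "case")

    @property
    def control_ids(self) -> frozenset[str]:
        return frozenset(s.subject_id for s in self.subjects if s.group == "control")

    def subject(self, subject_id: str) -> SubjectPhenotype:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_MISSING = ("", ".", "NA", "nan")


def _opt_float(text: str) -> Optional[float]:
    text = text.strip()
    if text in _MISSING:
        return None
    return float(text)


def _fmt_opt(value: Optional[float]) -> str:
    # repr of a float is the shortest string that round-trips exactly
    return "." if value is None else repr(float(value))


def _parse_gt(gt: str) -> Optional[int]:
    """Number of alternate alleles in a GT string, or None if fully missing."""
    alleles = gt.replace("|", "/").split("/")
    n_alt = 0
    seen = False
    for a in alleles:
        if a == ".":
            continue
        seen = True
        if int(a) >= 1:
            n_alt += 1
    return n_alt if seen else None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    ["key", "gene", "transcript", "cdna_hgvs", "protein_hgvs", "consequence_class",
     "af_1000g", "af_exac"]
    + list(PREDICTOR_TOOLS)
    + ["acmg_tags"]
)


def read_variants(vcf_path: str | Path, annotation_tsv_path: str | Path) -> list[VariantRecord]:
    """Read a minimal VCF plus its annotation sidecar into ``VariantRecord``s.

    Every VCF record must have a matching annotation row (keyed by
    ``CHROM:POS:REF:ALT``); annotation rows without a VCF record are dropped
    with a warning.  Genotypes with >= 1 alternate allele make a carrier.
    """
    annotations = _read_annotation_sidecar(annotation_tsv_path)
    records: list[VariantRecord] = []
    samples: list[str] = []
    seen_keys: set[str] = set()

    with open(vcf_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise VcfParseError(f"line {lineno}: malformed #CHROM header")
                samples = cols[9:]
                continue
            if not samples:
                raise VcfParseError(f"line {lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise VcfParseError(
                    f"line {lineno}: expected {9 + len(samples)} columns, got {len(fields)}"
                )
            chrom, pos_s, _vid, ref, alt, _qual, _filt, _info, fmt = fields[:9]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise VcfParseError(f"line {lineno}: POS {pos_s!r} not an integer") from exc
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise VcfParseError(f"line {lineno}: FORMAT lacks GT")
            gt_idx = fmt_keys.index("GT")

            zygosity: dict[str, int] = {}
            for subj, cell in zip(samples, fields[9:]):
                try:
                    n_alt = _parse_gt(cell.split(":")[gt_idx])
                except (ValueError, IndexError) as exc:
                    raise VcfParseError(
                        f"line {lineno}: bad genotype {cell!r} for {subj}"
                    ) from exc
                if n_alt is not None and n_alt > 0:
                    zygosity[subj] = n_alt

            key = f"{chrom}:{pos}:{ref}:{alt}"
            if key not in annotations:
                raise ValidationError(
                    f"line {lineno}: VCF record {key} has no annotation row"
                )
            ann = annotations[key]
            seen_keys.add(key)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=ann["gene"],
                    transcript=ann["transcript"],
                    cdna_hgvs=ann["cdna_hgvs"],
                    protein_hgvs=ann["protein_hgvs"],
                    consequence_class=ConsequenceClass(ann["consequence_class"]),
                    annotation=AnnotationProfile(
                        af_1000g=ann["af_1000g"],
                        af_exac=ann["af_exac"],
                        predictor_calls=ann["calls"],
                    ),
                    carriers=frozenset(zygosity),
                    zygosity=zygosity,
                    acmg_tags=ann["acmg_tags"],
                )
            )

    unmatched = set(annotations) - seen_keys
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} annotation row(s) without a VCF record dropped: "
            f"{sorted(unmatched)[:5]}",
            stacklevel=2,
        )
    return records


def _read_annotation_sidecar(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols - {"acmg_tags"}:
        raise ValidationError(f"annotation TSV lacks columns: {sorted(missing_cols)}")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        calls = tuple(
            Call.MISSING if row[t] in _MISSING else Call(row[t]) for t in PREDICTOR_TOOLS
        )
        out[row["key"]] = {
            "gene": row["gene"],
            "transcript": row["transcript"],
            "cdna_hgvs": row["cdna_hgvs"],
            "protein_hgvs": row["protein_hgvs"],
            "consequence_class": row["consequence_class"],
            "af_1000g": _opt_float(row["af_1000g"]),
            "af_exac": _opt_float(row["af_exac"]),
            "calls": calls,
            "acmg_tags": row.get("acmg_tags", "") if "acmg_tags" in df.columns else "",
        }
    return out


PHENOTYPE_COLUMNS = (
    ["subject_id", "group", "sex", "age", "hypertension", "diabetes",
     "bmi", "wc", "whr", "vfl", "pbf", "weight_0m"]
    + [f"weight_{m}m" for m in TIME_POINTS]
    + [f"{lip}_{m}m" for lip in LIPIDS for m in (0, 12)]
)


def read_phenotypes(tsv_path: str | Path) -> list[SubjectPhenotype]:
    """Read the per-subject phenotype TSV (empty cell or ``.`` = missing)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"phenotype TSV lacks columns: {sorted(missing_cols)}")
    seen: set[str] = set()
    subjects: list[SubjectPhenotype] = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        if sid in seen:
            raise ValidationError(f"duplicate subject id {sid!r}")
        seen.add(sid)
        weights: dict[int, Optional[float]] = {0: _opt_float(row["weight_0m"])}
        for m in TIME_POINTS:
            weights[m] = _opt_float(row[f"weight_{m}m"])
        lipids = {
            (lip, m): _opt_float(row[f"{lip}_{m}m"]) for lip in LIPIDS for m in (0, 12)
        }
        subjects.append(
            SubjectPhenotype(
                subject_id=sid,
                group=row["group"],
                sex=row["sex"],
                age=float(row["age"]),
                hypertension=row["hypertension"] in ("1", "True", "true", "yes"),
                diabetes=row["diabetes"] in ("1", "True", "true", "yes"),
                bmi=_opt_float(row["bmi"]),
                wc=_opt_float(row["wc"]),
                whr=_opt_float(row["whr"]),
                vfl=_opt_float(row["vfl"]),
                pbf=_opt_float(row["pbf"]),
                weights=weights,
                lipids=lipids,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------

def write_variant_files(
    variants: Sequence[VariantRecord],
    subject_ids: Sequence[str],
    vcf_path: str | Path,
    annotation_tsv_path: str | Path,
) -> None:
    """Write variants as minimal VCF + annotation sidecar (lossless round trip)."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = sorted({v.chrom for v in variants})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(subject_ids)
            + "\n"
        )
        for v in variants:
            gts = []
            for s in subject_ids:
                n_alt = v.zygosity.get(s, 1 if s in v.carriers else 0)
                gts.append({0: "0/0", 1: "0/1"}.get(n_alt, "1/1"))
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )

    rows = []
    for v in variants:
        row: dict[str, str] = {
            "key": v.key,
            "gene": v.gene,
            "transcript": v.transcript,
            "cdna_hgvs": v.cdna_hgvs,
            "protein_hgvs": v.protein_hgvs,
            "consequence_class": v.consequence_class.value,
            "af_1000g": _fmt_opt(v.annotation.af_1000g),
            "af_exac": _fmt_opt(v.annotation.af_exac),
            "acmg_tags": v.acmg_tags,
        }
        for tool, call in zip(PREDICTOR_TOOLS, v.annotation.predictor_calls):
            row[tool] = call.value
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        annotation_tsv_path, sep="\t", index=False
    )


def write_phenotypes(subjects: Iterable[SubjectPhenotype], tsv_path: str | Path) -> None:
    rows = []
    for s in subjects:
        row: dict[str, str] = {
            "subject_id": s.subject_id,
            "group": s.group,
            "sex": s.sex,
            "age": format(s.age, "g"),
            "hypertension": "1" if s.hypertension else "0",
            "diabetes": "1" if s.diabetes else "0",
            "bmi": _fmt_opt(s.bmi),
            "wc": _fmt_opt(s.wc),
            "whr": _fmt_opt(s.whr),
            "vfl": _fmt_opt(s.vfl),
            "pbf": _fmt_opt(s.pbf),
            "weight_0m": _fmt_opt(s.weights.get(0)),
        }
        for m in TIME_POINTS:
            row[f"weight_{m}m"] = _fmt_opt(s.weights.get(m))
        for lip in LIPIDS:
            for m in (0, 12):
                row[f"{lip}_{m}m"] = _fmt_opt(s.lipids.get((lip, m)))
        rows.append(row)
    pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
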