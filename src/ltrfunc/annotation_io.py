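"""Data model and readers/writers for chip annotation, intensity matrices,
sample sheets and gene annotation.

The chip targets LTR-retrotransposon (HERV/MaLR) loci at probeset
resolution: accurately annotated "HERV_prototypes" loci carry probesets in
the U3/R/U5 subdomains of each solo, 5' or 3' LTR plus gag/pol/env probesets
for proviruses, while the coarser Dfam-derived repertoires carry LTR-part
and internal probesets.  A small immunity-gene repertoire shares the array.

Conventions
-----------
* Genomic coordinates are 0-based half-open (BED) everywhere; GFF3 input is
  converted on read.
* Intensities are stored and exchanged on the log2 scale, so the activity
  threshold 2**5.5 and the function threshold 2**4.5 become 5.5 and 4.5.
* An "LTR" entity is keyed by ``(locus_id, ltr_role)``: a provirus
  contributes a 5' and a 3' LTR, a solo element a single LTR.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Repertoire",
    "Region",
    "LtrRole",
    "Condition",
    "ProbesetAnnotation",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "annotation_frame",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "read_matrix",
    "write_matrix",
    "read_gene_annotation",
    "attributable_ltrs",
    "ltr_id_frame",
    "locus_intervals",
]

ANNOTATION_COLUMNS = [
    "probeset_id",
    "locus_id",
    "repertoire",
    "group",
    "region",
    "ltr_role",
    "chrom",
    "start",
    "end",
    "strand",
]

SHEET_COLUMNS = ["sample_id", "donor", "condition", "replicate"]


class Repertoire(str, enum.Enum):
    HERV_PROTOTYPES = "HERV_prototypes"
    HERV_DFAM = "HERV_Dfam"
    MALR_DFAM = "MaLR_Dfam"
    GENE = "gene"


class Region(str, enum.Enum):
    U3 = "U3"
    R = "R"
    U5 = "U5"
    GAG = "gag"
    POL = "pol"
    ENV = "env"
    LTR_PART = "LTR_part"
    INTERNAL = "internal"
    GENE_BODY = "gene_body"


class LtrRole(str, enum.Enum):
    SOLO = "solo"
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    NONE = "none"


class Condition(str, enum.Enum):
    NS = "NS"
    LPS = "LPS"
    ET = "ET"
    ET_IFNG = "ET_IFNG"


#: regions that sit on an LTR (as opposed to internal proviral sequence)
LTR_REGIONS = {Region.U3.value, Region.R.value, Region.U5.value, Region.LTR_PART.value}

RETRO_REPERTOIRES = {
    Repertoire.HERV_PROTOTYPES.value,
    Repertoire.HERV_DFAM.value,
    Repertoire.MALR_DFAM.value,
}

#: retrovirus class of each well-defined HERV group used by the synthetic
#: chip; Dfam repertoires are reported as single global entities.
GROUP_CLASS = {
    "HERV-H": "gamma",
    "HERV-W": "gamma",
    "HERV-E": "gamma",
    "HERV-FRD": "gamma",
    "HERV-T": "gamma",
    "HERV-I": "gamma",
    "ERV9": "gamma",
    "PRIMA-41": "gamma",
    "HML-1": "beta",
    "HML-2": "beta",
    "HML-6": "beta",
    "HML-8": "beta",
    "HERV-L": "spuma_epsilon",
    "HERV-F": "gamma",
    "HERV-Fb": "gamma",
}


class AnnotationError(ValueError):
    """Structured parse/validation failure for annotation artefacts."""


@dataclass(frozen=True)
class ProbesetAnnotation:
    """One chip probeset with its locus, repertoire, structural region and
    genome interval (0-based half-open)."""

    probeset_id: str
    locus_id: str
    repertoire: str
    group: str
    region: str
    ltr_role: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        Repertoire(self.repertoire)
        Region(self.region)
        LtrRole(self.ltr_role)
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"probeset {self.probeset_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start < 0:
            raise AnnotationError(f"probeset {self.probeset_id}: negative start")
        if self.end <= self.start:
            raise AnnotationError(
                f"probeset {self.probeset_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.repertoire in RETRO_REPERTOIRES:
            on_ltr = self.region in LTR_REGIONS
            has_role = self.ltr_role != LtrRole.NONE.value
            if on_ltr != has_role:
                raise AnnotationError(
                    f"probeset {self.probeset_id}: region {self.region} "
                    f"inconsistent with ltr_role {self.ltr_role}"
                )
        elif self.ltr_role != LtrRole.NONE.value:
            raise AnnotationError(
                f"probeset {self.probeset_id}: gene probeset cannot carry an LTR role"
            )

    @property
    def ltr_id(self) -> tuple[str, str] | None:
        """(locus_id, ltr_role) key of the LTR this probeset sits on, if any."""
        if self.ltr_role == LtrRole.NONE.value:
            return None
        return (self.locus_id, self.ltr_role)


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

# accepted spelling variants, normalised on read
_ENUM_ALIASES = {
    "repertoire": {
        "herv_prototypes": "HERV_prototypes",
        "herv_dfam": "HERV_Dfam",
        "malr_dfam": "MaLR_Dfam",
        "gene": "gene",
    },
    "ltr_role": {
        "solo": "solo",
        "5'": "five_prime",
        "five_prime": "five_prime",
        "3'": "three_prime",
        "three_prime": "three_prime",
        "none": "none",
        "": "none",
    },
}


def _normalise_enum(column: str, value: str, line: int) -> str:
    aliases = _ENUM_ALIASES.get(column)
    if aliases is not None:
        key = str(value).strip()
        if key.lower() in aliases:
            return aliases[key.lower()]
        raise AnnotationError(f"line {line}: unknown {column} value {value!r}")
    return str(value).strip()


def read_annotation(path) -> list[ProbesetAnnotation]:
    """Read a probeset annotation TSV into validated records.

    The header must name all of ``probeset_id locus_id repertoire group
    region ltr_role chrom start end strand`` (any column order).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise AnnotationError(f"annotation file {path}: missing column(s) {missing}")
    records: list[ProbesetAnnotation] = []
    seen: set[str] = set()
    for i, row in enumerate(table.itertuples(index=False), start=2):  # 1 = header
        row = row._asdict()
        try:
            rec = ProbesetAnnotation(
                probeset_id=row["probeset_id"],
                locus_id=row["locus_id"],
                repertoire=_normalise_enum("repertoire", row["repertoire"], i),
                group=str(row["group"]).strip(),
                region=str(row["region"]).strip(),
                ltr_role=_normalise_enum("ltr_role", row["ltr_role"], i),
                chrom=str(row["chrom"]).strip(),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]).strip(),
            )
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"line {i}: {exc}") from exc
        if rec.probeset_id in seen:
            raise AnnotationError(f"line {i}: duplicate probeset_id {rec.probeset_id!r}")
        seen.add(rec.probeset_id)
        records.append(rec)
    return records


def write_annotation(records: Iterable[ProbesetAnnotation], path) -> None:
    annotation_frame(records).to_csv(path, sep="\t", index=False)


def annotation_frame(records: Iterable[ProbesetAnnotation]) -> pd.DataFrame:
    """Annotation records as a DataFrame in canonical column order."""
    if isinstance(records, pd.DataFrame):
        return records[ANNOTATION_COLUMNS].copy()
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise AnnotationError(f"sample sheet: missing column(s) {missing}")
    for cond in sheet["condition"]:
        Condition(cond)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise AnnotationError(f"sample sheet: duplicate sample_id {dup!r}")
    key = sheet[["donor", "condition", "replicate"]].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        raise AnnotationError("sample sheet: duplicate (donor, condition, replicate)")
    out = sheet[SHEET_COLUMNS].copy()
    out["replicate"] = out["replicate"].astype(int)
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intensity matrix
# ---------------------------------------------------------------------------

def read_matrix(path, sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a log2 intensity TSV (rows = probesets, columns = samples).

    With a sample sheet, matrix columns must be a subset of the sheet's
    sample ids.  NA or non-finite cells are rejected.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    if matrix.index.duplicated().any():
        raise AnnotationError(f"matrix {path}: duplicate probeset ids")
    if matrix.columns.duplicated().any():
        raise AnnotationError(f"matrix {path}: duplicate sample ids")
    if sheet is not None:
        known = set(sheet["sample_id"])
        unknown = [c for c in matrix.columns if c not in known]
        if unknown:
            raise AnnotationError(
                f"matrix {path}: sample(s) {unknown} absent from sample sheet"
            )
    values = matrix.to_numpy(dtype=float, na_value=np.nan)
    if not np.isfinite(values).all():
        bad = matrix.index[np.where(~np.isfinite(values))[0][0]]
        raise AnnotationError(f"matrix {path}: non-finite value in row {bad!r}")
    matrix = matrix.astype(float)
    return matrix


def write_matrix(matrix: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    matrix.to_csv(path, sep="\t", index_label="probeset_id", float_format=float_format)


# ---------------------------------------------------------------------------
# gene annotation (BED6 / GFF3)
# ---------------------------------------------------------------------------

def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene models from BED6 or GFF3 into a 0-based half-open frame.

    Returns columns ``gene_id chrom start end strand feature``; for GFF3 the
    exon rows are retained (feature == "exon", gene_id = parent gene) so
    intron overlap can be computed downstream.  BED6 input yields gene rows
    only.
    """
    import pyranges as pr

    spath = str(path)
    if spath.endswith((".gff", ".gff3", ".gtf")):
        gr = pr.read_gff3(spath) if spath.endswith(("gff", "gff3")) else pr.read_gtf(spath)
        df = gr.df
        keep = df[df["Feature"].isin(["gene", "exon"])].copy()
        if keep.empty:
            raise AnnotationError(f"{path}: no gene/exon features found")
        gene_names = {}
        for _, row in keep[keep["Feature"] == "gene"].iterrows():
            ident = row.get("ID")
            name = row.get("Name") if pd.notna(row.get("Name")) else ident
            gene_names[ident] = name
        rows = []
        for _, row in keep.iterrows():
            if row["Feature"] == "gene":
                gid = gene_names.get(row.get("ID"), row.get("ID"))
            else:
                gid = gene_names.get(row.get("Parent"), row.get("Parent"))
            rows.append(
                (gid, row["Chromosome"], int(row["Start"]), int(row["End"]),
                 row["Strand"], row["Feature"])
            )
        out = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "feature"])
    else:
        df = pr.read_bed(spath).df
        out = pd.DataFrame(
            {
                "gene_id": df["Name"].astype(str),
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "strand": df["Strand"].astype(str),
                "feature": "gene",
            }
        )
    genes = out[out["feature"] == "gene"]
    for _, exon in out[out["feature"] == "exon"].iterrows():
        parent = genes[genes["gene_id"] == exon["gene_id"]]
        if parent.empty:
            raise AnnotationError(f"{path}: exon without parent gene {exon['gene_id']!r}")
        g = parent.iloc[0]
        if exon["start"] < g["start"] or exon["end"] > g["end"]:
            raise AnnotationError(
                f"{path}: exon of {exon['gene_id']!r} outside its gene interval"
            )
    if (out["end"] <= out["start"]).any():
        raise AnnotationError(f"{path}: interval with end <= start")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LTR bookkeeping
# ---------------------------------------------------------------------------

def attributable_ltrs(annotation: Sequence[ProbesetAnnotation] | pd.DataFrame) -> set[tuple[str, str]]:
    """LTRs carrying both a U3 and a U5 probeset on the chip.

    Only such LTRs allow discrimination between U3 and U5 signals, hence
    promoter/polyA function assignment.  Keys are ``(locus_id, ltr_role)``.
    """
    df = annotation_frame(annotation)
    ltr = df[df["ltr_role"] != LtrRole.NONE.value]
    has_u3 = ltr[ltr["region"] == Region.U3.value].groupby(["locus_id", "ltr_role"]).size()
    has_u5 = ltr[ltr["region"] == Region.U5.value].groupby(["locus_id", "ltr_role"]).size()
    return set(has_u3.index) & set(has_u5.index)


def ltr_id_frame(annotation: Sequence[ProbesetAnnotation] | pd.DataFrame) -> pd.DataFrame:
    """Annotation restricted to LTR probesets with an ``ltr_id`` tuple column."""
    df = annotation_frame(annotation)
    ltr = df[df["ltr_role"] != LtrRole.NONE.value].copy()
    ltr["ltr_id"] = list(zip(ltr["locus_id"], ltr["ltr_role"]))
    return ltr


def locus_intervals(annotation: Sequence[ProbesetAnnotation] | pd.DataFrame,
                    by: str = "locus_id") -> pd.DataFrame:
    """Genomic span of each locus (or LTR) as the hull of its probesets."""
    df = annotation_frame(annotation).copy()
    if by == "ltr_id":
        df = df[df["ltr_role"] != LtrRole.NONE.value]
        df["_key"] = list(zip(df["locus_id"], df["ltr_role"]))
    else:
        df["_key"] = df[by]
    agg = df.groupby("_key").agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        strand=("strand", "first"),
        repertoire=("repertoire", "first"),
    )
    agg.index.name = by
    return agg.reset_index()
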