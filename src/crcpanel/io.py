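"""Domain types and readers/writers for mutation, panel, clinical and survival tables.

All tabular interchange is plain TSV.  Genomic coordinates are 1-based
inclusive (MAF convention).  Missing clinical values are represented as
``None`` in memory and as the literal string ``NA`` on disk; they are never
imputed and are excluded pairwise downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "VariantType",
    "VariantRecord",
    "CopyNumberRecord",
    "PanelDefinition",
    "ClinicalRecord",
    "SurvivalRecord",
    "MissingColumnError",
    "read_maf",
    "write_maf",
    "read_panel",
    "write_panel",
    "read_clinical",
    "write_clinical",
    "read_survival",
    "write_survival",
    "write_oncoprint_table",
]

DEFAULT_FOOTPRINT_MB = 1.6
"""Default panel footprint in megabases.

A 415-gene solid-tumor panel covers roughly 1/2000th of a 3.2 Gb genome,
i.e. ~1.6 Mb of coding territory.  Always overridable via the panel file
header or the ``PanelDefinition`` constructor.
"""


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    INFRAME_INDEL = "inframe_indel"
    SILENT = "silent"
    OTHER = "other"


class VariantType(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


#: classes that disrupt the protein beyond a single residue substitution
TRUNCATING_CLASSES = frozenset(
    {VariantClass.NONSENSE, VariantClass.FRAMESHIFT, VariantClass.SPLICE}
)

# MAF Variant_Classification -> internal class
_MAF_CLASS_MAP = {
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonsense": VariantClass.NONSENSE,
    "nonstop_mutation": VariantClass.NONSENSE,
    "frame_shift_del": VariantClass.FRAMESHIFT,
    "frame_shift_ins": VariantClass.FRAMESHIFT,
    "frameshift": VariantClass.FRAMESHIFT,
    "splice_site": VariantClass.SPLICE,
    "splice_region": VariantClass.SPLICE,
    "splice": VariantClass.SPLICE,
    "in_frame_del": VariantClass.INFRAME_INDEL,
    "in_frame_ins": VariantClass.INFRAME_INDEL,
    "inframe_indel": VariantClass.INFRAME_INDEL,
    "silent": VariantClass.SILENT,
    "synonymous": VariantClass.SILENT,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip whitespace, uppercase."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class VariantRecord:
    """One somatic small-variant call for one donor.

    ``pos`` is 1-based.  ``context3``, when present, is the 3-mer reference
    context centered on ``pos`` with the middle base equal to ``ref`` for SNPs.
    ``pop_af`` maps population-database names to allele frequencies.
    """

    donor_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    variant_type: VariantType
    allelic_fraction: float | None = None
    pop_af: Mapping[str, float] | None = None
    context3: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) for {self.donor_id}/{self.gene}")
        if self.variant_type is VariantType.SNP:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNP alleles must have length 1")
            if self.context3 is not None and self.context3[1] != self.ref:
                raise ValueError(
                    f"context3 middle base {self.context3[1]!r} != ref {self.ref!r}"
                )
        if self.context3 is not None:
            if len(self.context3) != 3 or any(b not in "ACGT" for b in self.context3):
                raise ValueError(f"context3 must be a 3-mer over ACGT, got {self.context3!r}")
        if self.allelic_fraction is not None and not (0.0 <= self.allelic_fraction <= 1.0):
            raise ValueError(f"allelic_fraction {self.allelic_fraction} outside [0, 1]")

    @property
    def is_truncating(self) -> bool:
        return self.variant_class in TRUNCATING_CLASSES


@dataclass(frozen=True)
class CopyNumberRecord:
    """A gene-level copy-number call (tumor/normal fold change)."""

    donor_id: str
    gene: str
    fold_change: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")


@dataclass(frozen=True)
class PanelDefinition:
    """A named gene set plus its sequenced footprint in megabases.

    The footprint is the burden denominator (mutations / Mb).
    """

    name: str
    genes: frozenset[str]
    footprint_mb: float = DEFAULT_FOOTPRINT_MB

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel gene set is empty")
        if not self.footprint_mb > 0:
            raise ValueError(f"footprint_mb must be > 0, got {self.footprint_mb}")
        object.__setattr__(self, "genes", frozenset(normalize_symbol(g) for g in self.genes))

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.genes


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-donor clinicopathological covariates; any field but donor_id may be None."""

    donor_id: str
    sex: str | None = None              # M | F
    age: float | None = None
    site: str | None = None             # colon | rectum
    side: str | None = None             # left | right
    lymphatic_invasion: str | None = None   # absence | presence
    vascular_invasion: str | None = None    # absence | presence
    grade: str | None = None            # G1 | G2 | G3
    T: str | None = None                # T1..T4
    N: str | None = None                # N0..N2
    M: str | None = None                # M0 | M1
    stage: str | None = None            # I | II | III | IV
    diameter_mm: float | None = None

    _ENUMS = {
        "sex": {"M", "F"},
        "site": {"colon", "rectum"},
        "side": {"left", "right"},
        "lymphatic_invasion": {"absence", "presence"},
        "vascular_invasion": {"absence", "presence"},
        "grade": {"G1", "G2", "G3"},
        "T": {"T1", "T2", "T3", "T4"},
        "N": {"N0", "N1", "N2"},
        "M": {"M0", "M1"},
        "stage": {"I", "II", "III", "IV"},
    }

    def __post_init__(self) -> None:
        for name, allowed in self._ENUMS.items():
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValueError(f"{name}={value!r} not in {sorted(allowed)}")
        if self.diameter_mm is not None and not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be positive")


@dataclass(frozen=True)
class SurvivalRecord:
    """Progression-free survival and treatment annotations for one donor.

    ``pfs_days`` is the interval from diagnosis of metastatic disease to
    progression (event) or last follow-up (censored).  ``best_response_pct``
    is the signed percent change of measurable lesions at best response and
    is present only if a response assessment occurred.
    """

    donor_id: str
    pfs_days: float
    event: bool
    anti_egfr: bool = False
    surgical_resection: bool = False
    progressed_before_first_assessment: bool = False
    best_response_pct: float | None = None

    def __post_init__(self) -> None:
        if self.pfs_days < 0:
            raise ValueError("pfs_days must be >= 0")


class MissingColumnError(ValueError):
    """A required column is absent from an input table."""

    def __init__(self, column: str, path: str | Path):
        self.column = column
        super().__init__(f"required column {column!r} missing from {path}")


# ---------------------------------------------------------------------------
# MAF-like variant tables
# ---------------------------------------------------------------------------

_MAF_COLUMNS = {
    "donor_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "variant_class": "Variant_Classification",
    "variant_type": "Variant_Type",
    "allelic_fraction": "t_alt_freq",
    "context3": "context3",
}

_MINIMAL_COLUMNS = {
    "donor_id": "donor_id",
    "gene": "gene",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "variant_class": "variant_class",
    "variant_type": "variant_type",
    "allelic_fraction": "allelic_fraction",
    "context3": "context3",
}

_REQUIRED_FIELDS = ("donor_id", "gene", "variant_class")
_POP_AF_PREFIX = "pop_af_"


def _parse_variant_class(raw: str) -> VariantClass:
    key = str(raw).strip().lower()
    if key in _MAF_CLASS_MAP:
        return _MAF_CLASS_MAP[key]
    try:
        return VariantClass(key)
    except ValueError:
        logger.warning("unknown variant class %r mapped to 'other'", raw)
        return VariantClass.OTHER


def _infer_variant_type(ref: str, alt: str, raw: object) -> VariantType:
    if isinstance(raw, str) and raw.strip():
        token = raw.strip().upper()
        if token in ("SNP", "SNV"):
            return VariantType.SNP
        if token in ("INS", "DEL"):
            return VariantType(token)
    if len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-":
        return VariantType.SNP
    return VariantType.INS if len(alt) > len(ref) or ref == "-" else VariantType.DEL


def read_maf(
    path: str | Path, dialect: str = "maf_like"
) -> tuple[list[VariantRecord], list[dict]]:
    """Read a MAF-like TSV of variant calls.

    Returns ``(records, problems)`` where ``problems`` lists rows whose
    required fields could not be parsed (they are reported, never silently
    dropped).  Row order is preserved.
    """
    colmap = {"maf_like": _MAF_COLUMNS, "minimal_tsv": _MINIMAL_COLUMNS}[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and len(df.columns) <= 1:
        logger.warning("variant table %s is empty", path)
        return [], []
    for fieldname in _REQUIRED_FIELDS:
        if colmap[fieldname] not in df.columns:
            raise MissingColumnError(colmap[fieldname], path)

    pop_cols = [c for c in df.columns if c.startswith(_POP_AF_PREFIX)]
    records: list[VariantRecord] = []
    problems: list[dict] = []
    for idx, row in df.iterrows():
        try:
            ref = str(row.get(colmap["ref"], "N")).strip()
            alt = str(row.get(colmap["alt"], "N")).strip()
            af_raw = row.get(colmap["allelic_fraction"])
            af = float(af_raw) if af_raw is not None and not pd.isna(af_raw) else None
            ctx_raw = row.get(colmap["context3"])
            ctx = (
                str(ctx_raw).strip().upper()
                if ctx_raw is not None and not pd.isna(ctx_raw)
                else None
            )
            pop_af = {
                c[len(_POP_AF_PREFIX):]: float(row[c])
                for c in pop_cols
                if not pd.isna(row[c])
            }
            pos_raw = row.get(colmap["pos"])
            records.append(
                VariantRecord(
                    donor_id=str(row[colmap["donor_id"]]).strip(),
                    gene=normalize_symbol(str(row[colmap["gene"]])),
                    chrom=str(row.get(colmap["chrom"], "NA")).strip(),
                    pos=int(float(pos_raw)) if not pd.isna(pos_raw) else 0,
                    ref=ref,
                    alt=alt,
                    variant_class=_parse_variant_class(row[colmap["variant_class"]]),
                    variant_type=_infer_variant_type(ref, alt, row.get(colmap["variant_type"])),
                    allelic_fraction=af,
                    pop_af=pop_af or None,
                    context3=ctx,
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            problems.append({"row": int(idx), "error": str(exc)})
            logger.warning("unparseable row %d in %s: %s", idx, path, exc)
    if problems:
        logger.warning("%d/%d rows of %s unparseable", len(problems), len(df), path)
    return records, problems


def write_maf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write variant records as a minimal-dialect TSV (round-trips read_maf)."""
    rows = []
    pop_dbs: list[str] = []
    records = list(records)
    for rec in records:
        if rec.pop_af:
            for db in rec.pop_af:
                if db not in pop_dbs:
                    pop_dbs.append(db)
    for rec in records:
        row = {
            "donor_id": rec.donor_id,
            "gene": rec.gene,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alt,
            "variant_class": rec.variant_class.value,
            "variant_type": rec.variant_type.value,
            "allelic_fraction": "" if rec.allelic_fraction is None else repr(rec.allelic_fraction),
            "context3": rec.context3 or "",
        }
        for db in pop_dbs:
            af = (rec.pop_af or {}).get(db)
            row[_POP_AF_PREFIX + db] = "" if af is None else repr(af)
        rows.append(row)
    columns = list(_MINIMAL_COLUMNS.values()) + [_POP_AF_PREFIX + db for db in pop_dbs]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Panel definitions
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """Read a panel file: one gene symbol per line, optional ``footprint_mb=<x>`` header.

    Duplicate symbols collapse (set semantics).
    """
    path = Path(path)
    footprint = DEFAULT_FOOTPRINT_MB
    genes: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("footprint_mb="):
            footprint = float(line.split("=", 1)[1])
            continue
        genes.add(normalize_symbol(line))
    if not genes:
        raise ValueError(f"panel file {path} contains no gene symbols")
    return PanelDefinition(name=name or path.stem, genes=frozenset(genes), footprint_mb=footprint)


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    lines = [f"footprint_mb={panel.footprint_mb}"] + sorted(panel.genes)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Clinical and survival tables
# ---------------------------------------------------------------------------

_NA = "NA"


def _opt(value):
    return None if value is None or (isinstance(value, float) and math.isnan(value)) else value


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA], keep_default_na=True)
    if "donor_id" not in df.columns:
        raise MissingColumnError("donor_id", path)
    records = []
    for _, row in df.iterrows():
        kwargs = {k: _opt(row.get(k)) for k in ClinicalRecord._ENUMS}
        for num_field in ("age", "diameter_mm"):
            raw = _opt(row.get(num_field))
            kwargs[num_field] = float(raw) if raw is not None else None
        records.append(ClinicalRecord(donor_id=str(row["donor_id"]), **kwargs))
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    fields = ["donor_id", "sex", "age", "site", "side", "lymphatic_invasion",
              "vascular_invasion", "grade", "T", "N", "M", "stage", "diameter_mm"]
    rows = [{f: (_NA if getattr(r, f) is None else getattr(r, f)) for f in fields}
            for r in records]
    pd.DataFrame(rows, columns=fields).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA])
    if "donor_id" not in df.columns:
        raise MissingColumnError("donor_id", path)
    records = []
    for _, row in df.iterrows():
        brp = _opt(row.get("best_response_pct"))
        records.append(
            SurvivalRecord(
                donor_id=str(row["donor_id"]),
                pfs_days=float(row["pfs_days"]),
                event=str(row["event"]) in ("1", "True", "true"),
                anti_egfr=str(row.get("anti_egfr", "0")) in ("1", "True", "true"),
                surgical_resection=str(row.get("surgical_resection", "0")) in ("1", "True", "true"),
                progressed_before_first_assessment=str(
                    row.get("progressed_before_first_assessment", "0")
                ) in ("1", "True", "true"),
                best_response_pct=float(brp) if brp is not None else None,
            )
        )
    return records


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "donor_id": r.donor_id,
            "pfs_days": repr(r.pfs_days),
            "event": int(r.event),
            "anti_egfr": int(r.anti_egfr),
            "surgical_resection": int(r.surgical_resection),
            "progressed_before_first_assessment": int(r.progressed_before_first_assessment),
            "best_response_pct": _NA if r.best_response_pct is None else repr(r.best_response_pct),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Oncoprint-style alteration matrix
# ---------------------------------------------------------------------------

def write_oncoprint_table(
    variants: Sequence[VariantRecord],
    cnvs: Sequence[CopyNumberRecord],
    genes: Sequence[str],
    path: str | Path | None = None,
    gain_threshold: float = 2.5,
    loss_threshold: float = 0.5,
) -> pd.DataFrame:
    """Build a gene x donor alteration matrix with cells in
    {amplification, deletion, missense, truncating, none}.

    Truncating = nonsense | frameshift | splice.  CNV gains require
    fold_change strictly > ``gain_threshold`` and losses strictly <
    ``loss_threshold``.  When a donor/gene has several alterations the most
    disruptive one wins (amplification/deletion > truncating > missense).
    """
    genes = [normalize_symbol(g) for g in genes]
    donors: list[str] = []
    for rec in list(variants) + list(cnvs):
        if rec.donor_id not in donors:
            donors.append(rec.donor_id)
    matrix = pd.DataFrame("none", index=genes, columns=donors)
    rank = {"none": 0, "missense": 1, "truncating": 2, "deletion": 3, "amplification": 3}

    def place(gene: str, donor: str, label: str) -> None:
        if gene in matrix.index and rank[label] > rank[matrix.at[gene, donor]]:
            matrix.at[gene, donor] = label

    for v in variants:
        if v.is_truncating:
            place(v.gene, v.donor_id, "truncating")
        elif v.variant_class is VariantClass.MISSENSE:
            place(v.gene, v.donor_id, "missense")
    for c in cnvs:
        gene = normalize_symbol(c.gene)
        if c.fold_change > gain_threshold:
            place(gene, c.donor_id, "amplification")
        elif c.fold_change < loss_threshold:
            place(gene, c.donor_id, "deletion")
    if path is not None:
        matrix.to_csv(path, sep="\t", index_label="gene")
    return matrix
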