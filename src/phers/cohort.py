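"""Typed tabular records for cohort inputs.

The phenotype-risk-score pipeline consumes three person-level tables:
demographics, ICD code occurrences and genotypes, plus the intermediate
phecode-occurrence table produced by the ICD-to-phecode mapping step.
This module defines a light schema layer over pandas DataFrames: each
table type declares its columns, how they parse, its canonical sort key
and its deduplication rule, and ``read_table`` / ``write_table`` move the
tables between delimited files and validated frames.

Conventions
-----------
* Dates are calendar dates (day resolution); any time component present
  in the input is truncated on load, because "distinct dates" is a
  calendar concept.
* ICD codes are whitespace-trimmed and upper-cased on load so joins
  against map assets are exact-string.
* Row numbers in error messages are 1-based over data rows (the header
  row is not counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phers")


class PhersError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PhersError):
    """A table's columns do not match the expected schema."""


class ValidationError(PhersError):
    """A table's contents violate a type invariant."""


#: strings treated as missing values in delimited input
MISSING_TOKENS = frozenset({"", "NA", "N/A", "NaN", "nan", ".", "NULL", "null"})


# ---------------------------------------------------------------------------
# column parsing

def parse_column(raw: pd.Series, kind: str, column: str, *, required: bool = True):
    """Parse a string column according to its declared kind.

    Returns the converted series; raises :class:`ValidationError` with
    1-based data-row numbers on unparseable or invalid values.
    """
    s = raw.astype("string").str.strip()
    missing = s.isna() | s.isin(MISSING_TOKENS)
    if required and missing.any() and kind != "allele":
        rows = _rows(missing)
        raise ValidationError(f"column {column!r}: missing value(s) at row(s) {rows}")

    if kind in ("str", "id"):
        return s.astype(str)
    if kind == "icd":
        return s.str.upper().astype(str)
    if kind == "sex":
        out = s.str.lower()
        bad = ~out.isin(["male", "female"]) & ~missing
        if bad.any():
            raise ValidationError(
                f"column {column!r}: sex must be 'male' or 'female', "
                f"bad value(s) at row(s) {_rows(bad)}"
            )
        return out.astype(str)
    if kind == "flag":
        out = pd.to_numeric(s, errors="coerce")
        bad = (~out.isin([9, 10])) & ~missing
        if bad.any():
            raise ValidationError(
                f"column {column!r}: ICD version flag must be 9 or 10, "
                f"bad value(s) at row(s) {_rows(bad)}"
            )
        return out.astype("int64")
    if kind == "date":
        out = pd.to_datetime(s.where(~missing), errors="coerce")
        bad = out.isna() & ~missing
        if bad.any():
            raise ValidationError(
                f"column {column!r}: unparseable date(s) at row(s) {_rows(bad)}"
            )
        return out.dt.normalize()
    if kind == "float":
        out = pd.to_numeric(s.where(~missing), errors="coerce")
        bad = out.isna() & ~missing
        if bad.any():
            raise ValidationError(
                f"column {column!r}: non-numeric value(s) at row(s) {_rows(bad)}"
            )
        return out.astype(float)
    if kind == "allele":
        out = pd.to_numeric(s.where(~missing), errors="coerce").astype("Int64")
        bad = (~out.isin([0, 1, 2])) & out.notna()
        if bad.any():
            raise ValidationError(
                f"column {column!r}: allele count must be 0, 1, 2 or missing, "
                f"bad value(s) at row(s) {_rows(bad)}"
            )
        return out
    if kind == "bool":
        out = s.str.lower().map(
            {"true": True, "t": True, "1": True, "yes": True,
             "false": False, "f": False, "0": False, "no": False}
        )
        bad = out.isna() & ~missing
        if bad.any():
            raise ValidationError(
                f"column {column!r}: expected a boolean, bad value(s) at row(s) {_rows(bad)}"
            )
        return out.fillna(False).astype(bool)
    if kind == "quality":
        out = s.str.lower()
        bad = ~out.isin(["exact", "broader"]) & ~missing
        if bad.any():
            raise ValidationError(
                f"column {column!r}: match_quality must be 'exact' or 'broader', "
                f"bad value(s) at row(s) {_rows(bad)}"
            )
        return out.astype(str)
    if kind == "inherit":
        return s.str.lower().astype(str)
    raise ValueError(f"unknown column kind {kind!r}")


def _rows(mask: pd.Series, limit: int = 5) -> str:
    rows = [str(i + 1) for i in mask[mask].index.tolist()[:limit]]
    more = int(mask.sum()) - len(rows)
    return ", ".join(rows) + (f" (+{more} more)" if more > 0 else "")


# ---------------------------------------------------------------------------
# table schemas

@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[tuple[str, str], ...]
    optional: tuple[tuple[str, str], ...] = ()
    key: tuple[str, ...] = ()
    dedup: bool = False

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.columns)


DEMOGRAPHICS = TableSchema(
    "demographics",
    columns=(("person_id", "id"), ("sex", "sex"),
             ("first_visit_date", "date"), ("last_visit_date", "date")),
    optional=(("birth_date", "date"), ("age_first_visit", "float")),
    key=("person_id",),
)

ICD_OCCURRENCES = TableSchema(
    "icd_occurrences",
    columns=(("person_id", "id"), ("icd_code", "icd"),
             ("flag", "flag"), ("occurrence_date", "date")),
    key=("person_id", "icd_code", "flag", "occurrence_date"),
    dedup=True,
)

PHECODE_OCCURRENCES = TableSchema(
    "phecode_occurrences",
    columns=(("person_id", "id"), ("phecode", "str"), ("occurrence_date", "date")),
    key=("person_id", "phecode", "occurrence_date"),
    dedup=True,
)

GENOTYPES = TableSchema(
    "genotypes",
    columns=(("person_id", "id"), ("variant_id", "str"), ("allele_count", "allele")),
    key=("person_id", "variant_id"),
    dedup=True,
)


def _sep_for(path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_table(path, schema: TableSchema, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a delimited table of the given schema.

    The delimiter is sniffed from the extension (``.csv`` vs ``.tsv``)
    unless ``sep`` overrides it. Header names are matched
    order-insensitively; extra columns are retained (numeric where
    possible). Exact duplicate rows are collapsed for occurrence-style
    tables; the post-load row count is logged.
    """
    raw = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    missing_cols = [c for c in schema.column_names if c not in raw.columns]
    if missing_cols:
        raise SchemaError(
            f"{schema.name}: missing column(s) {missing_cols} in {path} "
            f"(found {list(raw.columns)})"
        )

    df = pd.DataFrame(index=raw.index)
    for col, kind in schema.columns:
        df[col] = parse_column(raw[col], kind, col)
    for col, kind in schema.optional:
        if col in raw.columns:
            df[col] = parse_column(raw[col], kind, col, required=False)
    known = set(df.columns)
    for col in raw.columns:
        if col not in known:
            converted = pd.to_numeric(raw[col].replace(list(MISSING_TOKENS), np.nan),
                                      errors="coerce")
            df[col] = converted if converted.notna().any() else raw[col]

    if schema.dedup:
        before = len(df)
        df = df.drop_duplicates(subset=list(schema.key))
        dropped = before - len(df)
        if dropped:
            logger.info("%s: collapsed %d duplicate row(s)", schema.name, dropped)

    _VALIDATORS.get(schema.name, lambda d: None)(df)

    df = df.sort_values(list(schema.key) or list(df.columns),
                        kind="mergesort").reset_index(drop=True)
    logger.info("%s: loaded %d row(s) from %s", schema.name, len(df), path)
    return df


def _validate_demographics(df: pd.DataFrame) -> None:
    dup = df["person_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(df.loc[dup, "person_id"].unique())[:5]
        raise ValidationError(f"demographics: duplicate person_id(s) {ids}")
    bad = df["last_visit_date"] < df["first_visit_date"]
    if bad.any():
        raise ValidationError(
            "demographics: last_visit_date earlier than first_visit_date "
            f"at row(s) {_rows(bad)}"
        )


def _validate_genotypes(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["person_id", "variant_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["person_id", "variant_id"]].drop_duplicates()
        raise ValidationError(
            "genotypes: conflicting duplicate (person_id, variant_id) pair(s): "
            + "; ".join(f"({p}, {v})" for p, v in pairs.itertuples(index=False))
        )


_VALIDATORS = {
    "demographics": _validate_demographics,
    "genotypes": _validate_genotypes,
}


def write_table(df: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a table with ISO-8601 dates and ``NA`` for missing values."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=_sep_for(path, sep), index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# cohort-level validation

@dataclass
class CohortReport:
    n_persons: int
    n_occurrences: int
    orphan_person_ids: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.orphan_person_ids


def validate_cohort(demos: pd.DataFrame, icd: pd.DataFrame) -> CohortReport:
    """Check that every person with ICD occurrences is in demographics.

    Orphan person ids are a hard error rather than a silent drop: a
    silent drop would change the cohort size N in the weight formula
    invisibly. An empty occurrence table is permitted with a warning.
    """
    known = set(demos["person_id"])
    orphans = sorted(set(icd["person_id"]) - known)
    report = CohortReport(len(known), len(icd), orphans)
    if orphans:
        raise ValidationError(
            f"{len(orphans)} person_id(s) present in ICD occurrences but absent "
            f"from demographics: {orphans[:10]}"
        )
    if icd.empty:
        logger.warning("cohort has zero ICD occurrences")
    return report


# ---------------------------------------------------------------------------
# optional VCF ingestion

def read_genotypes_vcf(path, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Read genotypes from a VCF into the long allele-count table.

    Biallelic sites only; GT is mapped 0/0 -> 0, 0/1 or 1/0 -> 1,
    1/1 -> 2, ./. -> missing. Sample names become person_ids and the
    variant id is the VCF ID field, falling back to chrom:pos:ref:alt.
    Requires cyvcf2 (``pip install phers[vcf]``).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d", v.CHROM, v.POS)
            continue
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        if variant_ids is not None and vid not in variant_ids:
            continue
        counts = v.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        for person, c in zip(samples, counts):
            records.append((person, vid, pd.NA if c == 3 else int(c)))
    df = pd.DataFrame(records, columns=["person_id", "variant_id", "allele_count"])
    df["allele_count"] = df["allele_count"].astype("Int64")
    _validate_genotypes(df)
    return df.sort_values(["person_id", "variant_id"]).reset_index(drop=True)
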