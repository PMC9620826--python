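"""Map assets linking ICD codes, phecodes, HPO terms and Mendelian diseases.

Three maps drive the pipeline: ICD -> phecode (feature mapping),
disease -> phecode (the clinical pattern P_k of each disease), and
diagnostic-ICD -> disease (case assignment). The disease -> phecode map
can be loaded directly or constructed from two annotation tables — a
disease -> HPO-term table carrying gene, inheritance pattern and
provisional status, and an HPO-term -> phecode link table — by the
standard filters: drop multifactorial/somatic/unspecified inheritance and
provisional rows, join on HPO term, and keep diseases with at least three
distinct phecodes.

A small, clearly synthetic set of toy maps is bundled as package data so
the whole pipeline runs with no external downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .cohort import SchemaError, ValidationError, parse_column

logger = logging.getLogger("phers")

DEFAULT_MIN_PHECODES = 3
DEFAULT_EXCLUDED_INHERITANCE = ("multifactorial", "somatic", "unspecified")

#: map kind -> ((column, parse kind), ...); all maps are TSV with these headers
MAP_SCHEMAS: dict[str, tuple[tuple[str, str], ...]] = {
    "icd_phecode": (("icd", "icd"), ("flag", "flag"), ("phecode", "str")),
    "disease_phecode": (("disease_id", "str"), ("phecode", "str")),
    "disease_dx_icd": (("disease_id", "str"), ("icd", "icd"), ("flag", "flag")),
    "hpo_phecode": (("hpo_term_id", "str"), ("phecode", "str"),
                    ("match_quality", "quality")),
    "disease_hpo": (("disease_id", "str"), ("hpo_term_id", "str"),
                    ("gene", "str"), ("inheritance", "inherit"),
                    ("provisional", "bool")),
}


def load_map(path, map_kind: str, sep: str = "\t") -> pd.DataFrame:
    """Load, parse and deduplicate one of the five map kinds.

    Duplicated rows are collapsed with a logged count. A user-supplied
    disease_phecode map containing diseases with fewer than three
    phecodes loads with a warning only — custom maps are allowed to
    break the default construction filter.
    """
    if map_kind not in MAP_SCHEMAS:
        raise ValueError(f"unknown map kind {map_kind!r}; expected one of "
                         f"{sorted(MAP_SCHEMAS)}")
    schema = MAP_SCHEMAS[map_kind]
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c, _ in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"{map_kind} map: missing column(s) {missing} in {path}")
    df = pd.DataFrame(index=raw.index)
    for col, kind in schema:
        required = not (map_kind == "disease_hpo" and col == "gene")
        df[col] = parse_column(raw[col], kind, col, required=required)

    key = [c for c, _ in schema if c != "match_quality"]
    before = len(df)
    df = df.drop_duplicates(subset=key)
    if before - len(df):
        logger.info("%s map: collapsed %d duplicate row(s)", map_kind, before - len(df))

    if map_kind == "disease_phecode":
        counts = df.groupby("disease_id")["phecode"].nunique()
        thin = counts[counts < DEFAULT_MIN_PHECODES]
        if len(thin):
            logger.warning(
                "disease_phecode map: %d disease(s) have fewer than %d phecodes: %s",
                len(thin), DEFAULT_MIN_PHECODES, list(thin.index[:5]))
    return df.sort_values(key, kind="mergesort").reset_index(drop=True)


def build_disease_phecode_map(
    annotations: pd.DataFrame,
    links: pd.DataFrame,
    min_phecodes: int = DEFAULT_MIN_PHECODES,
    excluded_inheritance: tuple[str, ...] = DEFAULT_EXCLUDED_INHERITANCE,
) -> pd.DataFrame:
    """Assemble the disease -> phecode map from annotation tables.

    Parameters
    ----------
    annotations
        disease_hpo table: one row per (disease, HPO term) with gene,
        inheritance pattern and provisional flag. Exclusion is row-level:
        a disease annotated through two genes with different inheritance
        patterns keeps the rows with a retained pattern.
    links
        hpo_phecode table linking HPO terms to phecodes.
    min_phecodes
        Minimum number of distinct phecodes a disease must retain
        (default 3).
    excluded_inheritance
        Inheritance categories dropped before the join, matched
        case-insensitively.

    Returns
    -------
    DataFrame with columns disease_id, phecode, unique on that pair;
    empty (with a warning) if nothing survives the filters.
    """
    if min_phecodes < 1:
        raise ValueError("min_phecodes must be >= 1")
    excluded = {e.strip().lower() for e in excluded_inheritance}

    ann = annotations.copy()
    ann["inheritance"] = ann["inheritance"].astype(str).str.strip().str.lower()
    keep = ~ann["inheritance"].isin(excluded) & ~ann["provisional"].astype(bool)
    n_dropped = int((~keep).sum())
    ann = ann[keep]

    merged = ann.merge(links[["hpo_term_id", "phecode"]], on="hpo_term_id", how="inner")
    pairs = merged[["disease_id", "phecode"]].drop_duplicates()

    counts = pairs.groupby("disease_id")["phecode"].nunique()
    kept_diseases = counts[counts >= min_phecodes].index
    n_thin = int((counts < min_phecodes).sum())
    out = pairs[pairs["disease_id"].isin(kept_diseases)]

    logger.info(
        "build_disease_phecode_map: dropped %d annotation row(s) by "
        "inheritance/provisional filters, %d disease(s) below %d phecodes; "
        "kept %d disease(s), %d pair(s)",
        n_dropped, n_thin, min_phecodes, out["disease_id"].nunique(), len(out))
    if out.empty:
        logger.warning("build_disease_phecode_map: empty map after filtering")
    return (out.sort_values(["disease_id", "phecode"], kind="mergesort")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# bundled toy fixtures

@dataclass(frozen=True)
class BundledMaps:
    """The synthetic toy map fixtures shipped as package data."""
    icd_phecode: pd.DataFrame
    disease_phecode: pd.DataFrame
    disease_dx_icd: pd.DataFrame
    hpo_phecode: pd.DataFrame
    disease_hpo: pd.DataFrame


def bundled_map_path(map_kind: str):
    """Filesystem path of a bundled toy map TSV."""
    if map_kind not in MAP_SCHEMAS:
        raise ValueError(f"unknown map kind {map_kind!r}")
    return resources.files("phers").joinpath("data", f"{map_kind}.tsv")


def load_bundled_maps() -> BundledMaps:
    """Load all five bundled toy maps (synthetic fixtures, not real curation)."""
    return BundledMaps(**{kind: load_map(bundled_map_path(kind), kind)
                          for kind in MAP_SCHEMAS})
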