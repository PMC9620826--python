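"""Inverse-log-prevalence weights for phecodes.

Rare diagnoses are more informative about a Mendelian disease than
common ones, so phecode j receives the weight

    w_j = log10(N / n_j)

where N is the number of individuals in the cohort (everyone in the
demographics table, i.e. everyone with at least one visit) and n_j is
the number of individuals with at least one occurrence of phecode j.
A phecode carried by everyone scores 0; one carried by 1 in 100 people
scores 2. Weights may instead be supplied pre-calculated from a larger
reference cohort, useful when the user's cohort is small or its phecode
prevalences are unrepresentative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import SchemaError, ValidationError

logger = logging.getLogger("phers")

WEIGHT_COLUMNS = ["phecode", "n_persons", "cohort_size", "weight"]


def calc_weights(demos: pd.DataFrame, phe: pd.DataFrame,
                 exclude_persons: set[str] | None = None) -> pd.DataFrame:
    """Compute the weight table from cohort phecode prevalence.

    N counts all demographics rows. Phecodes never observed in the
    cohort are simply absent from the table (log10(N/0) is undefined);
    downstream scoring treats them as weight 0 with a warning.

    ``exclude_persons`` optionally removes a set of person_ids (e.g.
    diagnosed cases) from both N and the n_j counts before computing
    prevalence; default is to use the full cohort.
    """
    if demos.empty:
        raise ValidationError("demographics table is empty; N would be 0")
    persons = set(demos["person_id"])
    orphans = sorted(set(phe["person_id"]) - persons)
    if orphans:
        raise ValidationError(
            "phecode occurrences reference person_id(s) absent from "
            f"demographics (weight denominator integrity): {orphans[:10]}")

    use = phe
    n_total = len(demos)
    if exclude_persons:
        use = phe[~phe["person_id"].isin(exclude_persons)]
        n_total = int((~demos["person_id"].isin(exclude_persons)).sum())
        if n_total == 0:
            raise ValidationError("every person excluded; N would be 0")

    counts = (use.groupby("phecode")["person_id"].nunique()
              .rename("n_persons").reset_index())
    counts["cohort_size"] = n_total
    counts["weight"] = np.log10(n_total / counts["n_persons"])
    out = counts[WEIGHT_COLUMNS].sort_values("phecode",
                                             kind="mergesort").reset_index(drop=True)
    logger.info("calc_weights: N=%d, %d phecode(s) weighted", n_total, len(out))
    return out


def load_weights(path, sep: str | None = None) -> pd.DataFrame:
    """Load a pre-calculated weight table.

    Only ``phecode`` and ``weight`` columns are required; when
    ``n_persons`` / ``cohort_size`` are absent they are filled with
    nullable NA to mark the provenance as external. Duplicate phecodes
    and negative weights are rejected.
    """
    if sep is None:
        sep = "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ("phecode", "weight") if c not in df.columns]
    if missing:
        raise SchemaError(f"weight table: missing column(s) {missing} in {path}")
    df["phecode"] = df["phecode"].astype(str).str.strip()
    df["weight"] = pd.to_numeric(df["weight"], errors="raise").astype(float)

    dup = df["phecode"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"weight table: duplicate phecode(s) {sorted(df.loc[dup, 'phecode'].unique())[:5]}")
    neg = df["weight"] < 0
    if neg.any():
        raise ValidationError(
            f"weight table: negative weight(s) for phecode(s) "
            f"{sorted(df.loc[neg, 'phecode'].unique())[:5]}")

    for col in ("n_persons", "cohort_size"):
        df[col] = (pd.to_numeric(df[col], errors="coerce").astype("Int64")
                   if col in df.columns else pd.array([pd.NA] * len(df), dtype="Int64"))
    out = df[WEIGHT_COLUMNS].sort_values("phecode",
                                         kind="mergesort").reset_index(drop=True)
    logger.info("load_weights: %d phecode weight(s) from %s", len(out), path)
    return out
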