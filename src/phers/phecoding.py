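"""Translate ICD occurrences into phecode occurrences.

Phecodes group ICD-9 and ICD-10 billing codes into clinically meaningful
phenotypes; the score is computed over phecodes, not raw ICD codes. The
join is exact-string on (code, version flag) — phecode maps are
enumerated at code level, so no prefix/rollup matching is attempted.
Diagnostic ICD codes that denote a confirmed genetic diagnosis can be
excluded before mapping, which matters when comparing scores of
diagnosed and undiagnosed individuals.
"""

from __future__ import annotations

import logging

import pandas as pd

from .cohort import ValidationError

logger = logging.getLogger("phers")


def map_icd_to_phecodes(
    icd: pd.DataFrame,
    icd_phecode_map: pd.DataFrame,
    exclude_dx_icd: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Map ICD occurrences to phecode occurrences.

    Parameters
    ----------
    icd
        Validated icd_occurrences table.
    icd_phecode_map
        Map with columns icd, flag, phecode; one ICD code may map to
        several phecodes, in which case one occurrence expands to one
        phecode occurrence per mapped phecode.
    exclude_dx_icd
        Optional disease_dx_icd table; occurrences of any (icd, flag)
        listed there are removed before the join (all diseases pooled).

    Returns
    -------
    phecode_occurrences table, unique on (person_id, phecode,
    occurrence_date). Unmapped ICD codes are not an error — real EHR
    feeds always contain unmappable codes — but are counted and the ten
    most frequent are logged.
    """
    if icd_phecode_map is None or icd_phecode_map.empty:
        raise ValidationError("ICD->phecode map is empty")

    work = icd.copy()
    work["icd_code"] = work["icd_code"].astype(str).str.strip().str.upper()

    if exclude_dx_icd is not None and len(exclude_dx_icd):
        dx = exclude_dx_icd[["icd", "flag"]].drop_duplicates()
        dx = dx.assign(icd=dx["icd"].astype(str).str.strip().str.upper())
        before = len(work)
        work = work.merge(dx.rename(columns={"icd": "icd_code"}),
                          on=["icd_code", "flag"], how="left", indicator=True)
        work = work[work["_merge"] == "left_only"].drop(columns="_merge")
        logger.info("excluded %d occurrence(s) of diagnostic ICD codes",
                    before - len(work))

    m = icd_phecode_map[["icd", "flag", "phecode"]].drop_duplicates()
    m = m.assign(icd=m["icd"].astype(str).str.strip().str.upper())
    joined = work.merge(m.rename(columns={"icd": "icd_code"}),
                        on=["icd_code", "flag"], how="left")

    unmapped = joined[joined["phecode"].isna()]
    if len(unmapped):
        top = (unmapped.groupby(["icd_code", "flag"]).size()
               .sort_values(ascending=False).head(10))
        logger.info(
            "%d ICD occurrence(s) (%d distinct codes) had no phecode mapping; "
            "most frequent: %s",
            len(unmapped), unmapped[["icd_code", "flag"]].drop_duplicates().shape[0],
            [f"{c}({f}): {n}" for (c, f), n in top.items()])

    out = (joined.dropna(subset=["phecode"])
           [["person_id", "phecode", "occurrence_date"]]
           .drop_duplicates()
           .sort_values(["person_id", "phecode", "occurrence_date"],
                        kind="mergesort")
           .reset_index(drop=True))
    if out.empty:
        logger.warning("zero ICD occurrences mapped to phecodes")
    logger.info("mapped %d ICD occurrence(s) to %d phecode occurrence(s)",
                len(icd), len(out))
    return out
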