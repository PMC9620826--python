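"""Case/control assignment from diagnostic ICD codes, and score validation.

For each Mendelian disease with a specific diagnostic ICD code, a person
is a case if any of the disease's diagnostic codes appears on at least
two distinct calendar dates (requiring two dates instead of one improves
positive predictive value), a control if on zero dates, and neither if
on exactly one. Distinct-date counting pools all of a disease's
diagnostic codes: code A on Monday plus code B on Tuesday makes two
dates.

Validation then checks that diagnosed individuals score higher than
undiagnosed ones: per disease, OLS of the score on a case indicator plus
demographic covariates, reporting the case coefficient, its standard
error and two-sided p-value, and the group counts.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ValidationError
from .scoring import covariate_matrix

logger = logging.getLogger("phers")

DEFAULT_CASE_MIN_DATES = 2


def assign_dx_status(icd: pd.DataFrame, demos: pd.DataFrame,
                     dx_map: pd.DataFrame,
                     case_min_dates: int = DEFAULT_CASE_MIN_DATES) -> pd.DataFrame:
    """Assign case/control/neither status per (person, disease).

    Returns the dense grid over all demographics persons and all dx_map
    diseases with columns person_id, disease_id, status, n_dx_dates.
    """
    if dx_map is None or dx_map.empty:
        raise ValidationError("diagnostic-ICD map is empty")
    if case_min_dates < 1:
        raise ValueError("case_min_dates must be >= 1")

    work = icd.copy()
    work["icd_code"] = work["icd_code"].astype(str).str.strip().str.upper()
    dx = dx_map[["disease_id", "icd", "flag"]].drop_duplicates()
    dx = dx.assign(icd=dx["icd"].astype(str).str.strip().str.upper())

    hits = work.merge(dx.rename(columns={"icd": "icd_code"}),
                      on=["icd_code", "flag"], how="inner")
    counts = (hits.groupby(["person_id", "disease_id"])["occurrence_date"]
              .nunique().rename("n_dx_dates"))

    grid = pd.MultiIndex.from_product(
        [sorted(demos["person_id"]), sorted(dx["disease_id"].unique())],
        names=["person_id", "disease_id"])
    n_dates = counts.reindex(grid, fill_value=0).reset_index()

    status = np.where(n_dates["n_dx_dates"] >= case_min_dates, "case",
                      np.where(n_dates["n_dx_dates"] == 0, "control", "neither"))
    n_dates["status"] = status
    out = n_dates[["person_id", "disease_id", "status", "n_dx_dates"]]
    for disease, grp in out.groupby("disease_id"):
        vc = grp["status"].value_counts()
        logger.info("dx status %s: %d case / %d control / %d neither", disease,
                    vc.get("case", 0), vc.get("control", 0), vc.get("neither", 0))
    return out.reset_index(drop=True)


def compare_scores_by_status(scores: pd.DataFrame, status: pd.DataFrame,
                             demos: pd.DataFrame,
                             covariates: Sequence[str] = (),
                             score_column: str = "score",
                             min_cases: int = 2,
                             min_controls: int = 2) -> pd.DataFrame:
    """Per-disease linear model of score on case status.

    Persons with status 'neither' are excluded. Diseases with fewer than
    ``min_cases`` cases (or ``min_controls`` controls) are skipped with a
    warning; the CLI raises this screen to 50 cases by default for
    reporting, mirroring common practice, but status assignment itself is
    never affected.
    """
    if score_column not in scores.columns:
        raise ValidationError(f"score table has no column {score_column!r}")
    C = covariate_matrix(demos, covariates) if covariates else None

    rows = []
    for disease in sorted(status["disease_id"].unique()):
        st = status[(status["disease_id"] == disease) &
                    (status["status"] != "neither")]
        sc = scores[scores["disease_id"] == disease][["person_id", score_column]]
        df = st.merge(sc, on="person_id", how="inner")
        n_case = int((df["status"] == "case").sum())
        n_control = int((df["status"] == "control").sum())
        if n_case < min_cases or n_control < min_controls:
            logger.warning(
                "disease %s skipped: %d case(s) / %d control(s) below threshold",
                disease, n_case, n_control)
            continue

        y = df[score_column].to_numpy(float)
        cols = {"const": np.ones(len(df)),
                "case": (df["status"] == "case").astype(float).to_numpy()}
        if C is not None:
            sub = C.reindex(df["person_id"])
            for c in C.columns:
                cols[c] = sub[c].to_numpy()
        X = pd.DataFrame(cols)
        fit = sm.OLS(y, X).fit()
        rows.append({
            "disease_id": disease,
            "coef": fit.params["case"],
            "se": fit.bse["case"],
            "t": fit.tvalues["case"],
            "p": fit.pvalues["case"],
            "n_case": n_case,
            "n_control": n_control,
        })
    return pd.DataFrame(rows, columns=["disease_id", "coef", "se", "t", "p",
                                       "n_case", "n_control"])
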