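"""Phenotype risk scores and their covariate-adjusted residuals.

The raw score for person i and disease k is

    s_ik = sum over j in P_k of w_j * x_ij

where P_k is the disease's set of phecodes, w_j the phecode weight and
x_ij the binary indicator that person i has at least one occurrence of
phecode j. The person-by-disease grid is dense: every person in the
demographics table gets a row for every disease, with explicit zeros,
so downstream residualization sees the whole cohort including its
zero-inflation.

Residual scores regress the raw score, per disease, on an intercept
plus demographic covariates (by default biological sex, age at first
visit and the time between first and last visits) and rescale the OLS
residuals to unit variance using the sd with denominator (n - p), p
being the number of fitted parameters. Residual scores are therefore
mean-0, variance-1 per disease and more comparable across diseases.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .cohort import ValidationError

logger = logging.getLogger("phers")

#: default covariates for residualization and the downstream model fits
DEFAULT_COVARIATES = ("sex", "age_first_visit", "visit_span")

DAYS_PER_YEAR = 365.25


def covariate_matrix(demos: pd.DataFrame,
                     covariates: Sequence[str]) -> pd.DataFrame:
    """Build the numeric covariate matrix, indexed by person_id.

    Recognized names:

    * ``sex`` — indicator coded against the alphabetically first
      category (female = 0, male = 1).
    * ``age_first_visit`` — taken from the column of that name when
      present, otherwise derived as (first_visit_date - birth_date) /
      365.25 in years.
    * ``visit_span`` — (last_visit_date - first_visit_date) / 365.25
      in years.

    Any other name must be a numeric column of the demographics table.
    """
    idx = pd.Index(demos["person_id"], name="person_id")
    out = {}
    for name in covariates:
        if name == "sex":
            out["sex"] = (demos["sex"].astype(str) == "male").astype(float).to_numpy()
        elif name == "age_first_visit":
            if "age_first_visit" in demos.columns and demos["age_first_visit"].notna().all():
                out[name] = demos["age_first_visit"].astype(float).to_numpy()
            elif "birth_date" in demos.columns and demos["birth_date"].notna().all():
                days = (demos["first_visit_date"] - demos["birth_date"]).dt.days
                out[name] = (days / DAYS_PER_YEAR).to_numpy()
            else:
                raise ValidationError(
                    "covariate 'age_first_visit' needs an age_first_visit or "
                    "birth_date column in demographics")
        elif name == "visit_span":
            days = (demos["last_visit_date"] - demos["first_visit_date"]).dt.days
            out[name] = (days / DAYS_PER_YEAR).to_numpy()
        else:
            if name not in demos.columns:
                raise ValidationError(f"unknown covariate {name!r}")
            vals = pd.to_numeric(demos[name], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"covariate {name!r} is not fully numeric")
            out[name] = vals.astype(float).to_numpy()
    return pd.DataFrame(out, index=idx)


def calc_scores(weights: pd.DataFrame, phe: pd.DataFrame,
                disease_map: pd.DataFrame, demos: pd.DataFrame) -> pd.DataFrame:
    """Compute raw scores on the dense person x disease grid.

    Disease-map phecodes missing from the weight table contribute 0 and
    are warned about once each. Persons with no phecode occurrences get
    explicit zero scores for every disease.
    """
    persons = demos["person_id"].tolist()
    phecodes = sorted(disease_map["phecode"].unique())
    diseases = sorted(disease_map["disease_id"].unique())

    w = weights.set_index("phecode")["weight"]
    missing = [p for p in phecodes if p not in w.index]
    if missing:
        logger.warning(
            "%d disease-map phecode(s) absent from the weight table contribute "
            "0 to scores: %s", len(missing), missing)
    wvec = w.reindex(phecodes).fillna(0.0).to_numpy()

    # X: person x phecode binary indicator matrix
    obs = phe[phe["phecode"].isin(phecodes)][["person_id", "phecode"]].drop_duplicates()
    pi = pd.Index(persons)
    ji = pd.Index(phecodes)
    X = np.zeros((len(pi), len(ji)))
    if len(obs):
        X[pi.get_indexer(obs["person_id"]), ji.get_indexer(obs["phecode"])] = 1.0

    # accumulate per disease over its phecodes in ascending order, so the
    # summation order is reproducible by a sequential per-person oracle
    members = disease_map.groupby("disease_id")["phecode"].apply(
        lambda s: sorted(s.unique()))
    jpos = {j: k for k, j in enumerate(phecodes)}
    S = np.zeros((len(pi), len(diseases)))
    for d, disease in enumerate(diseases):
        col = np.zeros(len(pi))
        for j in members[disease]:
            col += wvec[jpos[j]] * X[:, jpos[j]]
        S[:, d] = col

    out = pd.DataFrame({
        "person_id": np.repeat(persons, len(diseases)),
        "disease_id": np.tile(diseases, len(persons)),
        "score": S.ravel(),
    })
    logger.info("calc_scores: %d person(s) x %d disease(s)", len(persons), len(diseases))
    return out.sort_values(["person_id", "disease_id"],
                           kind="mergesort").reset_index(drop=True)


def calc_residual_scores(demos: pd.DataFrame, scores: pd.DataFrame,
                         covariates: Sequence[str] = DEFAULT_COVARIATES
                         ) -> pd.DataFrame:
    """Fill the residual_score column by per-disease OLS on covariates.

    An empty covariate list reduces to the intercept-only model, i.e. a
    per-disease z-score. Zero-variance covariates are dropped with a
    warning; a disease whose residual variance is numerically zero, or
    a cohort with n <= p, is an error.
    """
    C = covariate_matrix(demos, covariates)
    keep = []
    for col in C.columns:
        if np.std(C[col].to_numpy()) == 0.0:
            logger.warning("covariate %r has zero variance; dropped", col)
        else:
            keep.append(col)
    X = np.column_stack([np.ones(len(C))] + [C[c].to_numpy() for c in keep])
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"cannot residualize: n={n} <= p={p}")

    wide = scores.pivot(index="person_id", columns="disease_id", values="score")
    wide = wide.reindex(C.index)
    if wide.isna().any().any():
        raise ValidationError("score table does not cover the full cohort")
    Y = wide.to_numpy()

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = np.sqrt((resid ** 2).sum(axis=0) / (n - p))
    scale = np.maximum(np.abs(Y).max(axis=0), 1.0)
    degenerate = sd <= 1e-10 * scale
    if degenerate.any():
        bad = list(wide.columns[degenerate])
        raise ValidationError(f"zero residual variance for disease(s) {bad}")

    rs = pd.DataFrame(resid / sd, index=wide.index, columns=wide.columns)
    long = (rs.stack().rename("residual_score").reset_index())
    out = scores.drop(columns=["residual_score"], errors="ignore").merge(
        long, on=["person_id", "disease_id"], how="left")
    return out.sort_values(["person_id", "disease_id"],
                           kind="mergesort").reset_index(drop=True)
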