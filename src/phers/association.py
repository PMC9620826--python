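"""Score-genotype association tests under four inheritance encodings.

For each user-specified (disease, variant) pair the score is regressed
on an encoded genotype term plus an intercept and optional demographic
covariates. Encodings of the alternate-allele count g in {0, 1, 2}:

    additive   [g]                     one term, per-allele slope
    dominant   [1 if g >= 1]           carriers vs non-carriers
    recessive  [1 if g == 2]           homozygotes vs the rest
    genotypic  [1 if g == 1, 1 if g == 2]
                                       het and hom-alt indicators against
                                       the homozygous-reference baseline

Under a recessive Mendelian disease the genotypic model is the
diagnostic readout: the hom-alt coefficient of a pathogenic variant is
strongly positive while the het coefficient and both coefficients of a
benign variant sit near zero.

Missing genotypes are excluded pairwise per variant (each pair uses the
maximal available sample); the reported genotype counts always cover the
full cohort, missing included, and do not depend on the model chosen.
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

MODELS = ("additive", "dominant", "recessive", "genotypic")

#: genetic term names per model, in design-matrix order
MODEL_TERMS = {
    "additive": ("additive",),
    "dominant": ("dominant",),
    "recessive": ("recessive",),
    "genotypic": ("het", "hom_alt"),
}

RESULT_COLUMNS = ["disease_id", "variant_id", "model", "term", "coef", "se",
                  "t", "p", "n_hom_ref", "n_het", "n_hom_alt", "n_missing",
                  "n_used", "estimable"]


def encode_genotype(allele_count: int, model: str) -> list[float]:
    """Encode one non-missing allele count as its predictor vector."""
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    if allele_count not in (0, 1, 2):
        raise ValidationError(f"allele count must be 0, 1 or 2, got {allele_count!r}")
    if model == "additive":
        return [float(allele_count)]
    if model == "dominant":
        return [1.0 if allele_count >= 1 else 0.0]
    if model == "recessive":
        return [1.0 if allele_count == 2 else 0.0]
    return [1.0 if allele_count == 1 else 0.0,
            1.0 if allele_count == 2 else 0.0]


def _encode_array(counts: np.ndarray, model: str) -> np.ndarray:
    """Vectorized encoding; counts must be non-missing. Columns follow MODEL_TERMS."""
    if model == "additive":
        return counts.astype(float)[:, None]
    if model == "dominant":
        return (counts >= 1).astype(float)[:, None]
    if model == "recessive":
        return (counts == 2).astype(float)[:, None]
    return np.column_stack([(counts == 1).astype(float),
                            (counts == 2).astype(float)])


def run_associations(scores: pd.DataFrame, genotypes: pd.DataFrame,
                     demos: pd.DataFrame, pairs: pd.DataFrame,
                     model: str = "additive",
                     covariates: Sequence[str] = (),
                     score_column: str | None = None,
                     adjust: str | None = None,
                     exclude_status: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit the association model for every (disease, variant) pair.

    Parameters
    ----------
    scores
        Dense score table; ``score_column`` defaults to residual_score
        when that column is present and filled (residual scores are more
        comparable across diseases), else the raw score.
    genotypes
        Long allele-count table. Persons absent from it, or with NA
        counts, are counted as missing and excluded from the fit.
    pairs
        Table with disease_id and variant_id columns; duplicates are an
        error.
    adjust
        ``"bonferroni"`` appends a p_adjusted column multiplying each
        p-value by the number of pairs tested.
    exclude_status
        Optional dx-status table; when given, persons whose status for
        the pair's disease is 'case' are dropped from the fit (counts
        still cover the full cohort).

    Rank-deficient designs (e.g. no homozygotes under the recessive
    encoding) yield rows flagged estimable=False with NaN statistics
    rather than an error.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    if adjust not in (None, "bonferroni"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    p_dup = pairs.duplicated(subset=["disease_id", "variant_id"])
    if p_dup.any():
        raise ValidationError("duplicate (disease_id, variant_id) pair(s)")
    if score_column is None:
        score_column = ("residual_score"
                        if "residual_score" in scores.columns
                        and scores["residual_score"].notna().all()
                        else "score")
    if score_column not in scores.columns:
        raise ValidationError(f"score table has no column {score_column!r}")

    known_diseases = set(scores["disease_id"])
    known_variants = set(genotypes["variant_id"])
    persons = demos["person_id"]
    C = covariate_matrix(demos, covariates) if covariates else None

    rows = []
    for disease, variant in pairs[["disease_id", "variant_id"]].itertuples(index=False):
        if disease not in known_diseases:
            raise ValidationError(f"disease {disease!r} absent from score table")
        if variant not in known_variants:
            raise ValidationError(f"variant {variant!r} absent from genotype table")

        g = (genotypes[genotypes["variant_id"] == variant]
             .set_index("person_id")["allele_count"])
        ac = g.reindex(persons)
        counts = {
            "n_hom_ref": int((ac == 0).sum()),
            "n_het": int((ac == 1).sum()),
            "n_hom_alt": int((ac == 2).sum()),
            "n_missing": int(ac.isna().sum()),
        }

        keep = ac.notna().to_numpy()
        if exclude_status is not None:
            st = (exclude_status[exclude_status["disease_id"] == disease]
                  .set_index("person_id")["status"].reindex(persons))
            keep &= (st != "case").to_numpy()
        if not keep.any():
            raise ValidationError(
                f"pair ({disease}, {variant}): no usable genotypes")

        used_persons = persons[keep]
        sc = (scores[scores["disease_id"] == disease]
              .set_index("person_id")[score_column].reindex(used_persons))
        if sc.isna().any():
            raise ValidationError(
                f"pair ({disease}, {variant}): score table does not cover cohort")
        y = sc.to_numpy(float)
        enc = _encode_array(ac[keep].to_numpy(int), model)
        terms = MODEL_TERMS[model]

        cols = {"const": np.ones(keep.sum())}
        for name, col in zip(terms, enc.T):
            cols[name] = col
        if C is not None:
            sub = C.reindex(used_persons)
            for c in C.columns:
                cols[c] = sub[c].to_numpy()
        X = pd.DataFrame(cols)
        n_used = len(X)

        estimable = (n_used > X.shape[1]
                     and np.linalg.matrix_rank(X.to_numpy()) == X.shape[1])
        if estimable:
            fit = sm.OLS(y, X).fit()
            stats = {t: (fit.params[t], fit.bse[t], fit.tvalues[t], fit.pvalues[t])
                     for t in terms}
        else:
            logger.warning("pair (%s, %s): rank-deficient or undersized design; "
                           "flagged non-estimable", disease, variant)
            stats = {t: (np.nan, np.nan, np.nan, np.nan) for t in terms}

        for t in terms:
            coef, se, tval, p = stats[t]
            rows.append({"disease_id": disease, "variant_id": variant,
                         "model": model, "term": t, "coef": coef, "se": se,
                         "t": tval, "p": p, **counts, "n_used": n_used,
                         "estimable": estimable})

    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out
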