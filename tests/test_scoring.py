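"""Raw score computation and covariate residualization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phers import (ValidationError, calc_residual_scores, calc_scores,
                   covariate_matrix)

from conftest import make_demographics


def weight_table(d):
    return pd.DataFrame({"phecode": list(d), "n_persons": 1,
                         "cohort_size": 10, "weight": list(d.values())})


def phe_frame(pairs):
    df = pd.DataFrame(pairs, columns=["person_id", "phecode"])
    df["occurrence_date"] = pd.Timestamp("2015-06-01")
    return df


def dmap(d):
    rows = [(k, p) for k, ps in d.items() for p in ps]
    return pd.DataFrame(rows, columns=["disease_id", "phecode"])


def brute_force_scores(weights, phe, disease_map, demos):
    """Independent double loop over persons x diseases."""
    w = dict(zip(weights["phecode"], weights["weight"]))
    has = set(zip(phe["person_id"], phe["phecode"]))
    out = {}
    for person in demos["person_id"]:
        for disease in disease_map["disease_id"].unique():
            pk = disease_map.loc[disease_map["disease_id"] == disease, "phecode"]
            out[(person, disease)] = sum(w.get(j, 0.0)
                                         for j in sorted(pk.unique())
                                         if (person, j) in has)
    return out


class TestCalcScores:
    def test_direct_substitution(self):
        demos = make_demographics(1)
        wt = weight_table({"a": 2.0, "b": 1.0})
        sc = calc_scores(wt, phe_frame([("H000", "a")]),
                         dmap({"D1": ["a", "b"]}), demos)
        assert sc.loc[0, "score"] == pytest.approx(2.0)

    def test_person_without_occurrences_scores_zero_everywhere(self):
        demos = make_demographics(3)
        wt = weight_table({"a": 2.0})
        sc = calc_scores(wt, phe_frame([("H000", "a")]),
                         dmap({"D1": ["a"], "D2": ["a"]}), demos)
        zeros = sc[sc["person_id"] != "H000"]
        assert (zeros["score"] == 0).all()
        assert len(sc) == 6  # dense person x disease grid

    def test_matches_double_loop_oracle_exactly(self):
        rng = np.random.default_rng(42)
        demos = make_demographics(20, seed=1)
        phecodes = [f"pc{i}" for i in range(12)]
        wt = weight_table({p: w for p, w in
                           zip(phecodes, rng.uniform(0.1, 3.0, 12))})
        pairs = [(f"H{rng.integers(20):03d}", phecodes[rng.integers(12)])
                 for _ in range(60)]
        dm = dmap({f"D{k}": sorted(rng.choice(phecodes, 4, replace=False))
                   for k in range(5)})
        phe = phe_frame(pairs)
        sc = calc_scores(wt, phe, dm, demos)
        oracle = brute_force_scores(wt, phe, dm, demos)
        for _, r in sc.iterrows():
            assert r.score == oracle[(r.person_id, r.disease_id)]

    def test_map_phecode_missing_from_weights_contributes_zero(self, caplog):
        demos = make_demographics(2)
        wt = weight_table({"a": 2.0})
        with caplog.at_level("WARNING", logger="phers"):
            sc = calc_scores(wt, phe_frame([("H000", "a"), ("H000", "zz")]),
                             dmap({"D1": ["a", "zz"]}), demos)
        assert sc.loc[sc["person_id"] == "H000", "score"].iloc[0] == 2.0
        assert "zz" in caplog.text

    def test_adding_occurrence_never_decreases_scores(self):
        demos = make_demographics(5)
        wt = weight_table({"a": 1.0, "b": 0.7, "c": 0.2})
        dm = dmap({"D1": ["a", "b"], "D2": ["b", "c"]})
        base = phe_frame([("H000", "a"), ("H001", "b")])
        s0 = calc_scores(wt, base, dm, demos).set_index(
            ["person_id", "disease_id"])["score"]
        for extra in [("H000", "b"), ("H002", "c"), ("H001", "b")]:
            s1 = calc_scores(wt, pd.concat([base, phe_frame([extra])]),
                             dm, demos).set_index(
                ["person_id", "disease_id"])["score"]
            assert (s1 >= s0 - 1e-12).all()

    def test_score_additivity_over_phecode_partition(self):
        demos = make_demographics(8, seed=2)
        wt = weight_table({p: w for p, w in
                           zip("abcd", [1.5, 0.9, 0.4, 2.2])})
        phe = phe_frame([("H000", "a"), ("H000", "c"), ("H003", "d"),
                         ("H005", "b"), ("H005", "d")])
        full = calc_scores(wt, phe, dmap({"D": list("abcd")}), demos)
        part1 = calc_scores(wt, phe, dmap({"D": list("ab")}), demos)
        part2 = calc_scores(wt, phe, dmap({"D": list("cd")}), demos)
        np.testing.assert_allclose(full["score"],
                                   part1["score"] + part2["score"], atol=1e-12)


class TestResidualScores:
    def scores_with_covariate_effect(self, n=200, seed=5):
        rng = np.random.default_rng(seed)
        demos = make_demographics(n, seed=seed)
        base = (0.8 * demos["age_first_visit"].to_numpy() / 50
                + 0.5 * (demos["sex"] == "male").to_numpy()
                + rng.gamma(2.0, 0.5, n))
        rows = []
        for k in range(3):
            rows.append(pd.DataFrame({
                "person_id": demos["person_id"],
                "disease_id": f"D{k}",
                "score": np.round(base * (k + 1) + rng.normal(0, 0.3, n), 6)}))
        return demos, pd.concat(rows, ignore_index=True).sort_values(
            ["person_id", "disease_id"]).reset_index(drop=True)

    def test_mean_zero_unit_variance_under_nminusp(self):
        demos, scores = self.scores_with_covariate_effect()
        out = calc_residual_scores(demos, scores,
                                   ("sex", "age_first_visit", "visit_span"))
        n, p = len(demos), 4
        for _, grp in out.groupby("disease_id"):
            r = grp["residual_score"].to_numpy()
            assert abs(r.mean()) < 1e-10
            assert (r ** 2).sum() / (n - p) == pytest.approx(1.0, abs=1e-10)

    def test_matches_closed_form_ols_oracle(self):
        demos, scores = self.scores_with_covariate_effect(n=120, seed=9)
        covs = ("sex", "age_first_visit", "visit_span")
        out = calc_residual_scores(demos, scores, covs)
        C = covariate_matrix(demos, covs)
        X = sm.add_constant(C.to_numpy())
        for disease, grp in out.groupby("disease_id"):
            y = grp.sort_values("person_id")["score"].to_numpy()
            fit = sm.OLS(y, X).fit()
            expect = fit.resid / np.sqrt(fit.ssr / (len(y) - X.shape[1]))
            np.testing.assert_allclose(
                grp.sort_values("person_id")["residual_score"], expect,
                atol=1e-10)

    def test_empty_covariates_reduce_to_zscore(self):
        demos, scores = self.scores_with_covariate_effect(n=50)
        out = calc_residual_scores(demos, scores, ())
        one = out[out["disease_id"] == "D0"].sort_values("person_id")
        y = one["score"].to_numpy()
        z = (y - y.mean()) / y.std(ddof=1)
        np.testing.assert_allclose(one["residual_score"], z, atol=1e-10)

    def test_exact_linear_dependence_is_degenerate(self):
        demos = make_demographics(30, seed=3)
        scores = pd.DataFrame({
            "person_id": demos["person_id"], "disease_id": "D0",
            "score": 2.0 * demos["age_first_visit"] + 1.0})
        with pytest.raises(ValidationError, match="zero residual variance"):
            calc_residual_scores(demos, scores, ("age_first_visit",))

    def test_zero_variance_covariate_dropped_with_warning(self, caplog):
        demos, scores = self.scores_with_covariate_effect(n=40)
        demos = demos.assign(constant_col=1.0)
        with caplog.at_level("WARNING", logger="phers"):
            out = calc_residual_scores(demos, scores,
                                       ("sex", "constant_col"))
        assert "constant_col" in caplog.text
        assert out["residual_score"].notna().all()

    def test_too_few_persons_is_error(self):
        demos, scores = self.scores_with_covariate_effect(n=3)
        with pytest.raises(ValidationError, match="n="):
            calc_residual_scores(demos, scores,
                                 ("sex", "age_first_visit", "visit_span"))

    def test_invariant_to_affine_covariate_rescaling(self):
        demos, scores = self.scores_with_covariate_effect(n=80, seed=13)
        out1 = calc_residual_scores(demos, scores, ("age_first_visit",))
        demos2 = demos.assign(
            age_first_visit=demos["age_first_visit"] * 12.0 + 7.0)
        out2 = calc_residual_scores(demos2, scores, ("age_first_visit",))
        np.testing.assert_allclose(out1["residual_score"],
                                   out2["residual_score"], atol=1e-8)


class TestCovariateMatrix:
    def test_sex_indicator_reference_is_female(self):
        demos = make_demographics(4)
        demos["sex"] = ["female", "male", "female", "male"]
        C = covariate_matrix(demos, ("sex",))
        assert C["sex"].tolist() == [0.0, 1.0, 0.0, 1.0]

    def test_age_derived_from_birth_date_when_column_absent(self):
        demos = make_demographics(3).drop(columns=["age_first_visit"])
        demos["birth_date"] = demos["first_visit_date"] - pd.to_timedelta(
            np.round(np.array([10, 20, 40]) * 365.25).astype(int), unit="D")
        C = covariate_matrix(demos, ("age_first_visit",))
        np.testing.assert_allclose(C["age_first_visit"], [10, 20, 40],
                                   atol=0.01)

    def test_unknown_covariate_is_error(self):
        with pytest.raises(ValidationError, match="nope"):
            covariate_matrix(make_demographics(3), ("nope",))
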