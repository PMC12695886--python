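"""Cross-sectional association engine tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from csf_nathist._linmod import multi_ols
from csf_nathist.associate import (apply_filter_cascade,
                                   assign_cell_specificity, enrichment_test,
                                   fit_outcome_model, two_group_test)


def _dataset(rng, n=200, effect=1.5, interaction=0.0, n_null=0):
    idx = [f"S{i}" for i in range(n)]
    outcome = pd.Series(rng.normal(0, 1, n), index=idx, name="y")
    sex = pd.Series(rng.choice(["F", "M"], n), index=idx)
    male = (sex == "M").astype(float)
    cols = {"hit": effect * outcome + interaction * outcome * male
            + rng.normal(0, 0.1, n)}
    for j in range(n_null):
        cols[f"null{j}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols, index=idx), outcome, sex


class TestOutcomeModel:
    def test_recovers_planted_coefficient(self, rng):
        adj, outcome, sex = _dataset(rng, effect=1.5)
        rec = fit_outcome_model(adj, outcome, sex)
        assert rec.at["hit", "coef_outcome"] == pytest.approx(1.5, abs=0.05)
        assert rec.at["hit", "significant"]

    def test_engine_matches_statsmodels(self, rng):
        """Vectorized OLS equals statsmodels coefficient-by-coefficient."""
        n = 50
        y = rng.normal(0, 1, n)
        male = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), y, male, y * male])
        Y = rng.normal(0, 1, (n, 4))
        ours = multi_ols(X, Y)
        for j in range(4):
            ref = sm.OLS(Y[:, j], X).fit()
            assert np.allclose(ours.coef[:, j], ref.params, atol=1e-8)
            assert np.allclose(ours.p[:, j], ref.pvalues, atol=1e-8)
            assert ours.r2[j] == pytest.approx(ref.rsquared, abs=1e-8)
            assert ours.f_p[j] == pytest.approx(ref.f_pvalue, abs=1e-8)

    def test_type_one_error_calibrated_under_null(self, rng):
        adj, outcome, sex = _dataset(rng, n=150, effect=0.0, n_null=400)
        adj = adj.drop(columns="hit")
        rec = fit_outcome_model(adj, outcome, sex)
        frac = (rec["p_outcome"] <= 0.05).mean()
        mc = 2 * np.sqrt(0.05 * 0.95 / 400)
        assert frac <= 0.05 + mc + 0.01

    def test_planted_interaction_detected(self, rng):
        adj, outcome, sex = _dataset(rng, n=200, effect=1.0, interaction=1.0)
        rec = fit_outcome_model(adj, outcome, sex)
        assert rec.at["hit", "p_interaction"] < 0.01

    def test_constant_outcome_rejected(self, rng):
        adj, outcome, sex = _dataset(rng)
        with pytest.raises(ValueError, match="constant"):
            fit_outcome_model(adj, outcome * 0, sex)


class TestFilterCascade:
    def _record(self, p_out, q_mod, p_sex=0.5, p_int=0.5):
        return pd.DataFrame([{"p_outcome": p_out, "model_q": q_mod,
                              "p_sex": p_sex, "p_interaction": p_int}])

    def test_rule_applications(self):
        assert not apply_filter_cascade(
            self._record(0.04, 0.06))["significant"].iloc[0]
        rec = apply_filter_cascade(self._record(0.04, 0.04))
        assert rec["significant"].iloc[0]
        assert not rec["sex_affected"].iloc[0]
        rec = apply_filter_cascade(self._record(0.04, 0.04, p_int=0.01))
        assert rec["sex_affected"].iloc[0]
        # sex flags require significance first
        rec = apply_filter_cascade(self._record(0.5, 0.5, p_sex=0.001))
        assert not rec["sex_affected"].iloc[0]

    def test_matches_brute_force_on_random_records(self, rng):
        rec = pd.DataFrame({
            "p_outcome": rng.uniform(0, 0.1, 500),
            "model_q": rng.uniform(0, 0.1, 500),
            "p_sex": rng.uniform(0, 0.2, 500),
            "p_interaction": rng.uniform(0, 0.2, 500)})
        out = apply_filter_cascade(rec)
        for _, row in out.sample(60, random_state=1).iterrows():
            sig = row["p_outcome"] <= 0.05 and row["model_q"] <= 0.05
            assert row["significant"] == sig
            assert row["sex_affected"] == (
                sig and (row["p_sex"] <= 0.05
                         or row["p_interaction"] <= 0.05))

    def test_idempotent_and_order_independent(self, rng):
        rec = pd.DataFrame({
            "p_outcome": rng.uniform(0, 0.1, 50),
            "model_q": rng.uniform(0, 0.1, 50),
            "p_sex": rng.uniform(0, 0.2, 50),
            "p_interaction": rng.uniform(0, 0.2, 50)})
        once = apply_filter_cascade(rec)
        twice = apply_filter_cascade(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = apply_filter_cascade(rec.sample(frac=1, random_state=3))
        pd.testing.assert_frame_equal(once, shuffled.sort_index(),
                                      check_like=True)


class TestTwoGroup:
    def test_identical_groups_nonsignificant(self, rng):
        vals = rng.normal(0, 1, (40, 5))
        adj = pd.DataFrame(np.vstack([vals, vals]),
                           index=[f"S{i}" for i in range(80)])
        adj.columns = [f"A{j}" for j in range(5)]
        groups = pd.Series(["a"] * 40 + ["b"] * 40, index=adj.index)
        res = two_group_test(adj, groups)
        assert (res["p"] > 0.9).all()

    def test_two_sd_shift_detected(self, rng):
        a = rng.normal(0, 1, (50, 3))
        b = rng.normal(2, 1, (50, 3))
        adj = pd.DataFrame(np.vstack([a, b]),
                           index=[f"S{i}" for i in range(100)],
                           columns=["x", "y", "z"])
        groups = pd.Series(["hc"] * 50 + ["ms"] * 50, index=adj.index)
        res = two_group_test(adj, groups)
        assert (res["q"] < 0.01).all()
        assert (res["direction"] == 1).all()

    def test_q_monotone_in_p(self, rng):
        adj = pd.DataFrame(rng.normal(0, 1, (60, 40)),
                           index=[f"S{i}" for i in range(60)])
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=adj.index)
        res = two_group_test(adj, groups).sort_values("p")
        assert (np.diff(res["q"]) >= -1e-12).all()


class TestCellSpecificity:
    def test_rule_cases(self):
        expr = pd.DataFrame(
            {"T1": [100.0, 4.0, 50.0], "T2": [10.0, 0.1, 50.0],
             "T3": [10.0, 0.1, 50.0]},
            index=["assigned", "low_max", "uniform"])
        out = assign_cell_specificity(expr)
        assert out["assigned"] == "T1"
        assert out["low_max"] == ""       # max must exceed 5
        assert out["uniform"] == ""       # ratio must exceed 5

    def test_boundary_values_excluded(self):
        # exactly 5 fails both strict inequalities
        expr = pd.DataFrame({"T1": [5.0], "T2": [0.0], "T3": [0.0]},
                            index=["edge"])
        assert assign_cell_specificity(expr)["edge"] == ""


class TestEnrichment:
    def _assignments(self):
        ids = [f"G{i}" for i in range(1000)]
        cell = ["Oligodendrocytes"] * 50 + [""] * 950
        return pd.Series(cell, index=ids)

    def test_constructed_strong_enrichment(self):
        assign = self._assignments()
        sig = set(assign.index[:20])      # all 20 positives cell-specific
        res = enrichment_test(assign, {("CEL", "positive"): sig})
        row = res[res["cell_type"] == "Oligodendrocytes"].iloc[0]
        assert row["p"] < 1e-6

    def test_proportional_representation_null(self):
        assign = self._assignments()
        sig = set(assign.index[:5]) | set(assign.index[100:195])
        res = enrichment_test(assign, {("CEL", "positive"): sig})
        row = res[res["cell_type"] == "Oligodendrocytes"].iloc[0]
        assert 0.2 < row["p"] < 0.8

    def test_depletion_gives_one_sided_p_near_one(self):
        assign = self._assignments()
        sig = set(assign.index[100:200])  # no cell-specific member at all
        res = enrichment_test(assign, {("CEL", "negative"): sig})
        row = res[res["cell_type"] == "Oligodendrocytes"].iloc[0]
        assert row["p"] > 0.95
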