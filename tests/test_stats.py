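"""Collation, correlation, sequential OLS, PLS/PRESS and coefficient ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flybait.receptors import RECEPTOR_CLASSES
from flybait.stats import (CatchPLS, CatchStatsError, SequentialExcitationOLS,
                           category_regression, collate, rank_coefficients,
                           spearman_matrix)


def _excitation_table(bait_ids, rng):
    data = {f"E_{c}": rng.uniform(0.05, 0.9, len(bait_ids)) for c in RECEPTOR_CLASSES}
    return pd.DataFrame(data, index=pd.Index(bait_ids, name="bait_id"))


def _records(bait_ids, catches, study="targets", sex="F"):
    return pd.DataFrame({
        "study": study, "species": "Gff", "sex": sex,
        "bait_id": bait_ids, "catch_pct": catches,
        "presentation": range(len(bait_ids)),
    })


class TestCollate:
    def test_single_presentation_log_transform(self):
        rng = np.random.default_rng(0)
        exc = _excitation_table(["b1"], rng)
        table = collate(_records(["b1"], [100.0]), exc)
        assert table.loc[0, "log_catch"] == pytest.approx(np.log10(101.0))
        assert table.loc[0, "log_catch"] == pytest.approx(2.00432, abs=1e-5)

    def test_presentations_average_before_transform(self):
        rng = np.random.default_rng(0)
        exc = _excitation_table(["b1"], rng)
        table = collate(_records(["b1", "b1"], [50.0, 150.0]), exc)
        assert len(table) == 1
        assert table.loc[0, "mean_catch_pct"] == pytest.approx(100.0)

    def test_75_presentations_collapse_to_37_unique_baits(self):
        # presentation multiplicities as in a multi-experiment field design
        rng = np.random.default_rng(1)
        ids = [f"t{i}" for i in range(37)]
        presented = ids * 2 + ["t0"]  # 75 presentations of 37 targets
        exc = _excitation_table(ids, rng)
        table = collate(_records(presented, rng.uniform(10, 200, 75)), exc)
        assert len(table) == 37

    def test_missing_excitations_fail_listing_baits(self):
        rng = np.random.default_rng(2)
        exc = _excitation_table(["known"], rng)
        with pytest.raises(CatchStatsError, match="ghost"):
            collate(_records(["known", "ghost"], [10.0, 20.0]), exc)


class TestSpearman:
    def test_monotone_pairs(self):
        t = pd.DataFrame({"a": [1, 2, 3, 4], "b": [10, 20, 30, 40],
                          "c": [4, 3, 2, 1]})
        m = spearman_matrix(t, ["a", "b", "c"])
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_constant_column_flagged_not_zero(self):
        t = pd.DataFrame({"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="b"):
            m = spearman_matrix(t, ["a", "b"])
        assert np.isnan(m.loc["a", "b"])


def _normal_equations_oracle(X, y):
    """Hand-coded OLS: coefficients, r2, overall F."""
    A = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    k = X.shape[1]
    df2 = len(y) - k - 1
    F = (r2 / k) / ((1 - r2) / df2)
    return beta, r2, F


class TestSequentialOLS:
    TOY = pd.DataFrame({
        "x1": [1.0, 2, 3, 4, 5, 6, 7, 8],
        "x2": [2.0, 1, 4, 3, 6, 5, 8, 7],
        "log_catch": [3.0, 2, 5, 7, 8, 8, 12, 10],
    })

    def test_matches_normal_equations_oracle(self):
        res = SequentialExcitationOLS(self.TOY, sequence=[["x1", "x2"]]).fit()
        step = res.final
        X = self.TOY[["x1", "x2"]].to_numpy()
        y = self.TOY["log_catch"].to_numpy()
        beta, r2, F = _normal_equations_oracle(X, y)
        assert np.allclose(step.params.to_numpy(), beta, atol=1e-8)
        assert step.r2 == pytest.approx(r2, abs=1e-8)
        assert step.f_value == pytest.approx(F, abs=1e-8)

    def test_exact_linear_response_gives_r2_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.uniform(0, 1, 12), "x2": rng.uniform(0, 1, 12)})
        df["log_catch"] = 1.0 + 2.0 * df.x1 - 3.0 * df.x2
        res = SequentialExcitationOLS(df, sequence=[["x1"], ["x2"]]).fit()
        assert res.final.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.final.delta_f_pvalue < 1e-10

    def test_r2_never_decreases_but_adjusted_may(self):
        rng = np.random.default_rng(4)
        n = 30
        df = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(4)})
        df["log_catch"] = df.x0 + rng.normal(size=n)
        res = SequentialExcitationOLS(
            df, sequence=[["x0"], ["x1"], ["x2"], ["x3"]]).fit()
        r2s = [s.r2 for s in res.steps]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
        adj = [s.adj_r2 for s in res.steps]
        assert any(b < a for a, b in zip(adj, adj[1:]))  # pure-noise additions
        for s in res.steps:
            assert s.adj_r2 <= s.r2 + 1e-12

    def test_vif_orthogonal_is_one_near_duplicate_large(self):
        rng = np.random.default_rng(5)
        n = 40
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        b -= a * (a @ b) / (a @ a)  # orthogonalise
        df = pd.DataFrame({"x1": a - a.mean(), "x2": b - b.mean()})
        df["log_catch"] = rng.normal(size=n)
        res = SequentialExcitationOLS(df, sequence=[["x1", "x2"]]).fit()
        assert np.allclose(res.final.vif, 1.0, atol=0.05)

        df["x3"] = df.x1 + rng.normal(scale=1e-3, size=n)
        res2 = SequentialExcitationOLS(df, sequence=[["x1", "x2", "x3"]]).fit()
        assert res2.final.vif["x1"] > 100

    def test_exactly_collinear_design_fails(self):
        df = pd.DataFrame({"x1": [1.0, 2, 3, 4, 5, 6]})
        df["x2"] = 2 * df.x1
        df["log_catch"] = [1.0, 2, 1, 2, 1, 2]
        with pytest.raises(CatchStatsError, match="singular|collinear"):
            SequentialExcitationOLS(df, sequence=[["x1", "x2"]]).fit()

    def test_standardised_coefficients_definition(self):
        res = SequentialExcitationOLS(self.TOY, sequence=[["x1", "x2"]]).fit()
        step = res.final
        sd_y = self.TOY["log_catch"].std(ddof=1)
        for col in ["x1", "x2"]:
            expected = step.params[col] * self.TOY[col].std(ddof=1) / sd_y
            assert step.std_params[col] == pytest.approx(expected)


class TestPLS:
    @staticmethod
    def _random_table(n=25, seed=6, collinear=False):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, 5))
        if collinear:
            X[:, 3] = X[:, 0] * 0.9 + rng.normal(scale=0.05, size=n)
        B = np.array([[1.2, 1.0], [-1.5, -1.7], [-0.8, -1.0],
                      [0.3, 0.2], [-0.1, 0.0]])
        Y = 1.5 + X @ B + rng.normal(scale=0.12, size=(n, 2))
        df = pd.DataFrame(X, columns=[f"E_{c}" for c in RECEPTOR_CLASSES])
        df["log_M"], df["log_F"] = Y[:, 0], Y[:, 1]
        return df

    def test_full_factors_equal_ols_per_response(self):
        df = self._random_table()
        res = CatchPLS(df, ["log_M", "log_F"]).fit(n_factors=5)
        for resp in ["log_M", "log_F"]:
            X = df[[f"E_{c}" for c in RECEPTOR_CLASSES]].to_numpy()
            beta, _, _ = _normal_equations_oracle(X, df[resp].to_numpy())
            fitted = np.concatenate([
                res.coefficients.loc[[f"E_{c}" for c in RECEPTOR_CLASSES], resp],
                [res.coefficients.loc["const", resp]]])
            assert np.allclose(fitted, np.r_[beta[1:], beta[0]], atol=1e-8)

    def test_agrees_with_sklearn_cross_check(self):
        from sklearn.cross_decomposition import PLSRegression

        df = self._random_table(seed=7)
        preds = [f"E_{c}" for c in RECEPTOR_CLASSES]
        for a in (1, 2, 3):
            res = CatchPLS(df, ["log_M", "log_F"]).fit(n_factors=a)
            sk = PLSRegression(n_components=a, scale=True).fit(
                df[preds].to_numpy(), df[["log_M", "log_F"]].to_numpy())
            # sklearn's NIPALS iterates weights only to ~1e-6, so the two
            # dialects agree to ~1e-4 on coefficients
            assert np.allclose(res.coefficients.loc[preds].to_numpy(),
                               sk.coef_.T, atol=1e-4)

    def test_duplicated_predictors_share_loadings(self):
        df = self._random_table(seed=8)
        df["E_dup"] = df["E_R7y"]
        res = CatchPLS(df, ["log_M", "log_F"],
                       predictors=["E_R7y", "E_dup", "E_R8y"]).fit(n_factors=2)
        assert np.allclose(res.std_coefficients.loc["E_R7y"],
                           res.std_coefficients.loc["E_dup"], atol=1e-10)

    def test_predicted_r2_below_r2_every_factor_count(self):
        df = self._random_table(seed=9)
        model = CatchPLS(df, ["log_M", "log_F"])
        press = model.loo_press()
        for a in press.index:
            res = model.fit(n_factors=int(a))
            for resp in ["log_M", "log_F"]:
                assert res.predicted_r2[resp] <= res.r2[resp] + 1e-9

    def test_press_selection_with_parsimony(self):
        df = self._random_table(seed=10)
        res = CatchPLS(df, ["log_M", "log_F"]).fit()
        assert 1 <= res.n_factors <= 5
        totals = res.press["total"]
        # the selected count is never worse than 2% off the PRESS optimum
        assert totals.loc[res.n_factors] <= totals.min() / (1 - 0.021)

    def test_too_many_factors_rejected(self):
        df = self._random_table()
        with pytest.raises(CatchStatsError):
            CatchPLS(df, ["log_M", "log_F"]).fit(n_factors=6)


class TestRankCoefficients:
    def test_distinct_magnitudes_rank_descending(self):
        # standardised coefficients ordered as in a five-receptor analysis
        coeffs = pd.DataFrame({"study": [-1.080, 0.840, 0.798, -0.587, 0.110]},
                              index=["R8y", "R7y", "R8p", "R7p", "R1-6"])
        ranks = rank_coefficients(coeffs)
        assert list(ranks["study"]) == [1, 2, 3, 4, 5]
        assert list(ranks["median_rank"]) == [1, 2, 3, 4, 5]

    def test_all_equal_magnitudes_average_to_three(self):
        coeffs = pd.DataFrame({"s": [0.5, -0.5, 0.5, -0.5, 0.5]},
                              index=list("abcde"))
        assert (rank_coefficients(coeffs)["s"] == 3.0).all()

    def test_random_sets_agree_with_sort_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = rng.normal(size=5)
            coeffs = pd.DataFrame({"s": vals}, index=list("abcde"))
            ranks = rank_coefficients(coeffs)["s"].to_numpy()
            order = np.argsort(-np.abs(vals))
            oracle = np.empty(5)
            oracle[order] = np.arange(1, 6)
            assert np.array_equal(ranks, oracle)

    def test_median_across_studies(self):
        coeffs = pd.DataFrame({
            "s1": [3.0, 2.0, 1.0], "s2": [3.0, 1.0, 2.0], "s3": [1.0, 3.0, 2.0],
        }, index=list("abc"))
        ranks = rank_coefficients(coeffs)
        assert ranks.loc["a", "median_rank"] == 1.0  # ranks (1,1,3)


class TestCategoryRegression:
    def test_identical_group_means_give_zero_dummy(self):
        t = pd.DataFrame({"log_catch": [1.0, 2.0, 1.0, 2.0]})
        cats = pd.Series(["y+p-", "y+p-", "y+p+", "y+p+"], index=t.index)
        res = category_regression(t, cats)
        assert res.params["y+p+"] == pytest.approx(0.0, abs=1e-12)

    def test_coefficients_equal_group_mean_differences(self):
        t = pd.DataFrame({"log_catch": [2.0, 2.2, 1.0, 1.4, 0.5, 0.7]})
        cats = pd.Series(["y+p-", "y+p-", "y+p+", "y+p+", "y-p-", "y-p-"],
                         index=t.index)
        res = category_regression(t, cats)
        assert res.params["const"] == pytest.approx(2.1)
        assert res.params["y+p+"] == pytest.approx(1.2 - 2.1)
        assert res.params["y-p-"] == pytest.approx(0.6 - 2.1)

    def test_overall_f_matches_one_way_anova_oracle(self):
        rng = np.random.default_rng(12)
        groups = ["y+p-"] * 10 + ["y+p+"] * 8 + ["y-p+"] * 7
        y = np.concatenate([rng.normal(2.0, 0.3, 10), rng.normal(1.2, 0.3, 8),
                            rng.normal(0.8, 0.3, 7)])
        t = pd.DataFrame({"log_catch": y})
        res = category_regression(t, pd.Series(groups, index=t.index))
        F, p = sps.f_oneway(y[:10], y[10:18], y[18:])
        assert res.f_value == pytest.approx(F, rel=1e-10)
        assert res.f_pvalue == pytest.approx(p, rel=1e-8)

    def test_single_category_fails(self):
        t = pd.DataFrame({"log_catch": [1.0, 2.0]})
        with pytest.raises(CatchStatsError):
            category_regression(t, pd.Series(["y+p-", "y+p-"], index=t.index))
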