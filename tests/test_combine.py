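"""PCA and stepwise-LDA score combination, with independent oracles."""

import numpy as np
import pandas as pd
import pytest

from ddisim.combine import (
    CombinationError,
    LDACombiner,
    PCAScoreCombiner,
    build_score_table,
    fit_lda_combiner,
    fit_pca_combiner,
    wilks_lambda,
)


def one_factor_table(rng, n=2000, p=6, noise=0.3):
    """Planted single-factor data: x_j = w_j * f + noise."""
    w = rng.uniform(0.5, 1.0, size=p)
    f = rng.normal(size=n)
    X = np.outer(f, w) + noise * rng.normal(size=(n, p))
    return pd.DataFrame(X, columns=[f"m{j}" for j in range(p)]), w


class TestPCACombiner:
    def test_perfectly_correlated_columns_are_rank_one(self, rng):
        base = rng.normal(size=200)
        X = pd.DataFrame({f"m{j}": (j + 1) * base for j in range(6)})
        m = PCAScoreCombiner().fit(X)
        assert m.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_uncorrelated_columns_split_variance_evenly(self, rng):
        X = pd.DataFrame(rng.normal(size=(20000, 6)), columns=list("abcdef"))
        m = PCAScoreCombiner().fit(X)
        np.testing.assert_allclose(m.explained_variance_ratio_, np.full(6, 1 / 6), atol=0.02)

    def test_recovers_planted_factor_direction(self, rng):
        X, w = one_factor_table(rng, noise=0.3)
        m = PCAScoreCombiner().fit(X)
        v = m.loadings_ / np.linalg.norm(m.loadings_)
        # correlation-PCA works on standardized columns, so the planted
        # direction to recover is w_j / sd(x_j) with sd(x_j) = sqrt(w_j²+σ²)
        wn = w / np.sqrt(w**2 + 0.3**2)
        wn /= np.linalg.norm(wn)
        assert min(np.abs(v - wn).max(), np.abs(v + wn).max()) < 0.05

    def test_explained_fractions_sum_to_one(self, rng):
        X, _ = one_factor_table(rng, n=300)
        m = PCAScoreCombiner().fit(X)
        assert m.explained_variance_ratio_.sum() == pytest.approx(1.0)
        assert np.linalg.norm(m.loadings_) == pytest.approx(1.0)

    def test_scores_zero_mean_on_training_rows(self, rng):
        X, _ = one_factor_table(rng, n=500)
        m = PCAScoreCombiner().fit(X)
        assert m.transform(X).mean() == pytest.approx(0.0, abs=1e-10)

    def test_row_at_column_means_scores_zero(self, rng):
        X, _ = one_factor_table(rng, n=100)
        m = PCAScoreCombiner().fit(X)
        row = pd.DataFrame([m.mean_], columns=m.columns_)
        assert m.transform(row)[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_get_identical_scores(self, rng):
        X, _ = one_factor_table(rng, n=50)
        m = PCAScoreCombiner().fit(X)
        dup = pd.concat([X.iloc[[3]], X.iloc[[3]]])
        s = m.transform(dup)
        assert s[0] == s[1]

    def test_orientation_correlates_with_row_mean(self, rng):
        X, _ = one_factor_table(rng)
        m = PCAScoreCombiner().fit(X)
        z = (X - m.mean_) / m.scale_
        r = np.corrcoef(m.transform(X), z.mean(axis=1))[0, 1]
        assert r > 0

    def test_training_recenter_invariance(self, rng):
        X, _ = one_factor_table(rng, n=200)
        shifted = X + 7.0
        a = PCAScoreCombiner().fit(X).transform(X)
        b = PCAScoreCombiner().fit(shifted).transform(shifted)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_matches_sklearn_pca_on_standardized_data(self, rng):
        from sklearn.decomposition import PCA

        X, _ = one_factor_table(rng, n=400)
        m = PCAScoreCombiner().fit(X)
        Z = (X - X.mean()) / X.std(ddof=1)
        ratio = PCA().fit(Z.to_numpy()).explained_variance_ratio_
        np.testing.assert_allclose(np.sort(m.explained_variance_ratio_)[::-1], ratio, atol=1e-8)

    def test_constant_column_named_in_error(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(CombinationError, match="'b'"):
            PCAScoreCombiner().fit(X)

    def test_json_round_trip(self, rng):
        X, _ = one_factor_table(rng, n=100)
        m = PCAScoreCombiner().fit(X)
        back = PCAScoreCombiner.from_dict(m.to_dict())
        np.testing.assert_allclose(back.transform(X), m.transform(X))


def _wilks_oracle(X, y):
    """Independent Wilks' Λ via statsmodels MANOVA."""
    from statsmodels.multivariate.manova import MANOVA

    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(X.shape[1])])
    df["g"] = y
    formula = " + ".join(df.columns[:-1]) + " ~ g"
    res = MANOVA.from_formula(formula, data=df).mv_test()
    tbl = res.results["g"]["stat"]
    return float(tbl.loc["Wilks' lambda", "Value"])


class TestWilksLambda:
    def test_no_separation_gives_lambda_near_one(self, rng):
        X = rng.normal(size=(4000, 3))
        y = rng.integers(0, 2, size=4000)
        U, F, df1, df2, p = wilks_lambda(X, y)
        assert U == pytest.approx(1.0, abs=0.01)

    def test_perfect_separation_drives_lambda_to_zero(self, rng):
        y = np.repeat([0, 1], 50)
        X = (y * 100).reshape(-1, 1) + 0.01 * rng.normal(size=(100, 1))
        U, *_ = wilks_lambda(X, y)
        assert U < 1e-4

    def test_matches_manova_oracle_on_hand_dataset(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 9 + [1] * 11)
        X[y == 1] += [0.8, -0.4, 0.2]
        U, F, df1, df2, p = wilks_lambda(X, y)
        assert U == pytest.approx(_wilks_oracle(X, y), abs=1e-6)
        assert (df1, df2) == (3, 16)

    def test_direct_scatter_determinant_oracle(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 10 + [1] * 10)
        X[y == 1, 0] += 1.0
        W = np.zeros((2, 2))
        for g in (0, 1):
            C = X[y == g] - X[y == g].mean(axis=0)
            W += C.T @ C
        C = X - X.mean(axis=0)
        T = C.T @ C
        expected = np.linalg.det(W) / np.linalg.det(T)
        assert wilks_lambda(X, y)[0] == pytest.approx(expected)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array([0] * 30 + [1] * 30)
        X[y == 1] += 0.5
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        U1 = wilks_lambda(X, y)[0]
        U2 = wilks_lambda(X @ A + [1, 2, 3], y)[0]
        assert U1 == pytest.approx(U2, rel=1e-8)

    def test_singular_scatter_rejected(self):
        X = np.ones((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(CombinationError, match="singular"):
            wilks_lambda(X, y)


class TestLDACombiner:
    def _labeled_table(self, rng, n=300, informative=1):
        y = (rng.random(n) < 0.2).astype(int)
        X = rng.normal(size=(n, 5))
        for j in range(informative):
            X[:, j] += 2.0 * y
        return pd.DataFrame(X, columns=[f"m{j}" for j in range(5)]), y

    def test_stepwise_selects_the_informative_variable_first(self, rng):
        X, y = self._labeled_table(rng)
        m = LDACombiner(mode="stepwise").fit(X, y)
        assert m.selected_[0] == "m0"

    def test_forced_all_columns_matches_wilks_lambda(self, rng):
        X, y = self._labeled_table(rng, informative=2)
        m = LDACombiner(mode="forced").fit(X, y)
        U, F, df1, df2, p = wilks_lambda(X, y)
        assert m.wilks_ == pytest.approx(U)
        assert m.f_stat_ == pytest.approx(F)
        assert m.df_ == (df1, df2)

    def test_discriminant_ranks_match_sklearn_lda(self, rng):
        from scipy.stats import spearmanr
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = self._labeled_table(rng, informative=2)
        ours = LDACombiner(mode="forced").fit(X, y).decision_function(X)
        theirs = LinearDiscriminantAnalysis().fit(X, y).decision_function(X)
        assert spearmanr(ours, theirs).statistic == pytest.approx(1.0)

    def test_positive_class_scores_higher(self, rng):
        X, y = self._labeled_table(rng)
        s = LDACombiner(mode="stepwise").fit(X, y).decision_function(X)
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(CombinationError, match="two classes"):
            LDACombiner(mode="forced").fit(X, np.zeros(20, dtype=int))

    def test_pure_noise_selects_nothing_and_advises_forced(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, size=200)
        # tiny entry threshold: nothing qualifies
        with pytest.raises(CombinationError, match="forced"):
            LDACombiner(mode="stepwise", p_enter=1e-12).fit(X, y)

    def test_stepwise_is_deterministic(self, rng):
        X, y = self._labeled_table(rng, informative=3)
        a = LDACombiner(mode="stepwise").fit(X, y).selected_
        b = LDACombiner(mode="stepwise").fit(X, y).selected_
        assert a == b

    def test_sklearn_param_protocol(self):
        m = LDACombiner(mode="forced", variables=["a"], p_enter=0.1)
        assert m.get_params()["p_enter"] == 0.1
        m.set_params(mode="stepwise")
        assert m.mode == "stepwise"


class TestImbalancedCandidateTable:
    def test_forced_lda_statistics_on_386_row_table(self, rng):
        """Forced LDA on a candidate-sized table (14 positives, 372
        negatives, 5 score columns) reports U = det(W)/det(T) with the
        exact two-class F transform on df (5, 380)."""
        n, p = 386, 5
        y = np.zeros(n, int)
        y[rng.choice(n, size=14, replace=False)] = 1
        X = rng.normal(size=(n, p)) * 0.15 + 0.1
        X[y == 1] += rng.uniform(0.05, 0.2, size=p)
        cols = ["2D", "3D", "TPF", "DDIPF", "ATC"]
        m = LDACombiner(mode="forced", variables=cols).fit(
            pd.DataFrame(X, columns=cols), y
        )
        W = np.zeros((p, p))
        for g in (0, 1):
            C = X[y == g] - X[y == g].mean(axis=0)
            W += C.T @ C
        C = X - X.mean(axis=0)
        T = C.T @ C
        U = np.linalg.det(W) / np.linalg.det(T)
        assert m.wilks_ == pytest.approx(U)
        assert m.df_ == (5, 380)
        assert m.f_stat_ == pytest.approx((380 / 5) * (1 - U) / U)


class TestScoreTable:
    def test_impute_and_drop_policies(self, caplog):
        from ddisim.signals import LabeledCandidate, SignalRecord

        cands = [
            LabeledCandidate(SignalRecord("a", "b", 2, 0.01), 1, scores={"x": 0.5, "y": 0.2}),
            LabeledCandidate(SignalRecord("a", "c", 2, 0.01), 0, scores={"x": 0.1}),
        ]
        with caplog.at_level("WARNING"):
            df, labels = build_score_table(cands, ["x", "y"], missing="impute")
        assert df.loc[1, "y"] == 0.0 and labels.tolist() == [1, 0]
        df2, _ = build_score_table(cands, ["x", "y"], missing="drop")
        assert list(df2.columns) == ["x"]


class TestWrappers:
    def test_module_functions_delegate_to_estimators(self, rng):
        X, _ = one_factor_table(rng, n=100)
        y = (rng.random(100) < 0.3).astype(int)
        X.iloc[:, 0] += 1.5 * y
        assert isinstance(fit_pca_combiner(X), PCAScoreCombiner)
        m = fit_lda_combiner(X, y, mode="forced")
        assert isinstance(m, LDACombiner) and m.selected_ == list(X.columns)
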