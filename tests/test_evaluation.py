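"""Enrichment factor, AUROC/DeLong, precision@k and correlations."""

import numpy as np
import pandas as pd
import pytest

from ddisim.evaluation import (
    EvaluationError,
    auroc,
    bootstrap_auroc_ci,
    delong_ci,
    enrichment_factor,
    evaluate_ranking,
    precision_at_k,
    roc_points,
    score_correlations,
)


def auroc_oracle(scores, labels):
    """Exhaustive concordant-pair fraction with ties counted half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


class TestEnrichmentFactor:
    def test_published_pharmacovigilance_counts(self):
        """14 known DDIs among 386 signal pairs vs 149 among all 13,041."""
        ef, p = enrichment_factor(14, 386, 149, 13041)
        assert ef == pytest.approx(3.17, abs=0.01)
        assert ef >= 3.0  # the "3-fold" claim
        assert 1e-4 < p < 1e-3  # same order as the printed p = .0003

    def test_equal_prevalence_is_unit_enrichment(self):
        assert enrichment_factor(10, 100, 100, 1000)[0] == pytest.approx(1.0)

    def test_zero_hits(self):
        ef, p = enrichment_factor(0, 50, 100, 1000)
        assert ef == 0.0 and p == pytest.approx(1.0)

    def test_algebraic_identity(self):
        ef, _ = enrichment_factor(7, 80, 40, 900)
        assert ef * (40 / 900) == pytest.approx(7 / 80)

    def test_no_population_positives_is_error(self):
        with pytest.raises(EvaluationError):
            enrichment_factor(0, 10, 0, 100)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(EvaluationError):
            enrichment_factor(20, 10, 5, 100)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_interleaved_hand_example(self):
        assert auroc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(3 / 4)

    def test_all_tied_is_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_lower_is_positive_direction(self):
        # small p-values mark positives
        assert auroc([0.001, 0.5, 0.002, 0.9], [1, 0, 1, 0],
                     direction="lower_is_positive") == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auroc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_concordant_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        y = np.zeros(n, int)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        assert auroc(s, y) == pytest.approx(auroc_oracle(s, y))

    def test_complement_identity_under_midranks(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.integers(0, 10, size=100).astype(float)
        assert auroc(s, y) + auroc(-s, y) == pytest.approx(1.0)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]
        s = rng.normal(size=200)
        assert auroc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_dominating_positives_beat_chance(self, rng):
        n = 500
        y = (rng.random(n) < 0.3).astype(int)
        s = rng.normal(size=n) + 1.2 * y
        assert auroc(s, y) > 0.5


class TestDeLong:
    def test_ci_brackets_point_estimate(self, rng):
        y = rng.integers(0, 2, size=120)
        y[:2] = [0, 1]
        s = rng.normal(size=120) + y
        a, lo, hi = delong_ci(s, y)
        assert lo <= a <= hi
        assert a == pytest.approx(auroc(s, y))

    def test_bootstrap_agrees_with_delong(self, rng):
        n = 400
        y = (rng.random(n) < 0.3).astype(int)
        s = rng.normal(size=n) + 1.0 * y
        a1, lo1, hi1 = delong_ci(s, y)
        a2, lo2, hi2 = bootstrap_auroc_ci(s, y, n_boot=500, seed=1)
        assert a1 == pytest.approx(a2)
        assert lo1 == pytest.approx(lo2, abs=0.04)
        assert hi1 == pytest.approx(hi2, abs=0.04)

    def test_ci_narrows_with_sample_size(self, rng):
        def width(n):
            y = np.tile([0, 1], n // 2)
            s = rng.normal(size=n) + 0.8 * y
            _, lo, hi = delong_ci(s, y)
            return hi - lo

        assert width(800) < width(60)


class TestRocPoints:
    def test_endpoints_and_monotonicity(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.integers(0, 6, size=50).astype(float)
        pts = roc_points(s, y)
        assert (pts.iloc[0].fpr, pts.iloc[0].tpr) == (0.0, 0.0)
        assert (pts.iloc[-1].fpr, pts.iloc[-1].tpr) == (1.0, 1.0)
        assert (pts.fpr.diff().dropna() >= 0).all()
        assert (pts.tpr.diff().dropna() >= 0).all()

    def test_trapezoid_area_equals_midrank_auroc(self, rng):
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        s = rng.integers(0, 4, size=80).astype(float)
        pts = roc_points(s, y)
        area = np.trapezoid(pts.tpr, pts.fpr)
        assert area == pytest.approx(auroc(s, y))


class TestPrecisionAtK:
    def test_all_top_positive(self):
        df = precision_at_k([0.9, 0.8, 0.7, 0.1], [1, 1, 1, 0], ks=[3])
        assert df.loc[0, "precision"] == 1.0

    def test_ranked_hand_example(self):
        df = precision_at_k([4, 3, 2, 1], [1, 0, 1, 0], ks=[2])
        assert df.loc[0, "precision"] == 0.5

    def test_precision_at_n_is_prevalence(self, rng):
        y = rng.integers(0, 2, size=40)
        s = rng.normal(size=40)
        df = precision_at_k(s, y, ks=[40])
        assert df.loc[0, "precision"] == pytest.approx(y.mean())

    def test_oversized_k_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            df = precision_at_k([1, 2], [0, 1], ks=[10])
        assert df.loc[0, "k_used"] == 2

    def test_deterministic_tie_order_by_pair_id(self):
        df = precision_at_k([0.5, 0.5], [0, 1], ks=[1], pair_ids=["aa", "ab"])
        assert df.loc[0, "precision"] == 0.0  # "aa" (label 0) ranks first

    def test_nonpositive_k_rejected(self):
        with pytest.raises(EvaluationError):
            precision_at_k([1], [1], ks=[0])


class TestCorrelations:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        c = score_correlations(df)
        assert c.loc["a", "a"] == pytest.approx(1.0)
        assert c.loc["a", "b"] == pytest.approx(c.loc["b", "a"])

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame(rng.normal(size=(10000, 2)), columns=["a", "b"])
        assert abs(score_correlations(df).loc["a", "b"]) < 0.05

    def test_matches_covariance_formula_on_hand_table(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 1, 4, 3, 6]})
        x, y = df["x"], df["y"]
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert score_correlations(df).loc["x", "y"] == pytest.approx(r)

    def test_pair_subset_argument_selects_rows(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        sub = score_correlations(df, pairs=range(10))
        full = score_correlations(df)
        assert sub.loc["a", "b"] != pytest.approx(full.loc["a", "b"], abs=1e-12)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 1, 1]})
        assert np.isnan(score_correlations(df).loc["a", "b"])


class TestEvaluateRanking:
    def test_report_structure(self, rng):
        y = (rng.random(100) < 0.2).astype(int)
        s = rng.normal(size=100) + y
        res = evaluate_ranking(s, y, method="demo", ks=(5, 10))
        d = res.to_dict()
        assert 0 <= d["subset_auroc"] <= 1
        assert d["n_pos"] + d["n_neg"] == 100
        assert len(d["precision_at_k"]) == 2
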