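"""Ranking-performance metrics for DDI candidate lists.

* Enrichment factor — ratio of positive prevalence in a candidate subset to
  prevalence in the full pair universe, with a one-sided hypergeometric
  exact p-value (the natural test for a 2×2 enrichment design).
* AUROC — Mann–Whitney/midrank formulation (equals the trapezoidal area
  under the tie-grouped ROC curve), with a 95% DeLong confidence interval
  and a seeded-bootstrap cross-check option. When metrics are computed on
  the pharmacovigilance candidate subset rather than the whole pair
  universe, outputs call it ``subset_auroc``.
* Precision@k — precision among the top-k ranked candidates, deterministic
  tie order (score descending, then pair id ascending).
* Pearson correlations between measure-score columns over a chosen pair set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class EvaluationError(ValueError):
    pass


def enrichment_factor(k_pos: int, n_sub: int, K_pos: int, N: int) -> tuple[float, float]:
    """Enrichment factor of a subset and its one-sided hypergeometric p.

    EF = (k_pos/n_sub) / (K_pos/N); p = P(X >= k_pos) for X hypergeometric
    with population N, K_pos successes, n_sub draws.
    """
    if not (0 <= k_pos <= n_sub <= N and 0 <= K_pos <= N):
        raise EvaluationError(
            f"inconsistent counts: k_pos={k_pos}, n_sub={n_sub}, K_pos={K_pos}, N={N}"
        )
    if K_pos == 0:
        raise EvaluationError("EF undefined: no positives in the population")
    if n_sub == 0:
        raise EvaluationError("EF undefined: empty subset")
    ef = (k_pos / n_sub) / (K_pos / N)
    p = float(stats.hypergeom.sf(k_pos - 1, N, K_pos, n_sub))
    return float(ef), p


def _prepare(scores, labels, direction: str) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be 1-d arrays of equal length")
    if direction == "lower_is_positive":
        scores = -scores
    elif direction != "higher_is_positive":
        raise EvaluationError(f"unknown direction {direction!r}")
    if labels.min() == labels.max():
        raise EvaluationError("both classes must be present")
    if not np.isin(labels, (0, 1)).all():
        raise EvaluationError("labels must be binary 0/1")
    return scores, labels


def auroc(scores, labels, direction: str = "higher_is_positive") -> float:
    """AUROC via midranks: (R_pos − n_pos(n_pos+1)/2) / (n_pos·n_neg).

    Equivalent to the concordant-pair fraction with ties counted half.
    """
    s, y = _prepare(scores, labels, direction)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10_i = fraction of negatives below positive i (ties half)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos) for q in neg])
    return v10, v01


def delong_ci(scores, labels, direction: str = "higher_is_positive",
              alpha: float = 0.05) -> tuple[float, float, float]:
    """AUROC with its DeLong (1988) normal-theory confidence interval."""
    s, y = _prepare(scores, labels, direction)
    v10, v01 = _placements(s, y)
    a = float(v10.mean())
    var = 0.0
    if len(v10) > 1:
        var += np.var(v10, ddof=1) / len(v10)
    if len(v01) > 1:
        var += np.var(v01, ddof=1) / len(v01)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return a, max(0.0, a - z * se), min(1.0, a + z * se)


def bootstrap_auroc_ci(scores, labels, direction: str = "higher_is_positive",
                       n_boot: int = 2000, alpha: float = 0.05,
                       seed: int = 0) -> tuple[float, float, float]:
    """Percentile-bootstrap AUROC CI (stratified resampling, seeded)."""
    s, y = _prepare(scores, labels, direction)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    stat = []
    for _ in range(n_boot):
        bp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        bn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([bp, bn])
        stat.append(auroc(s[idx], y[idx]))
    a = auroc(s, y)
    lo, hi = np.quantile(stat, [alpha / 2, 1 - alpha / 2])
    return a, float(lo), float(hi)


def roc_points(scores, labels, direction: str = "higher_is_positive") -> pd.DataFrame:
    """Tie-grouped ROC curve points (fpr, tpr, threshold), (0,0) → (1,1)."""
    s, y = _prepare(scores, labels, direction)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    # group ties: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    cut = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y)[cut]
    fps = np.cumsum(1 - y)[cut]
    fpr = np.concatenate([[0.0], fps / n_neg])
    tpr = np.concatenate([[0.0], tps / n_pos])
    thr = np.concatenate([[np.inf], s[cut]])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def precision_at_k(scores, labels, ks: Sequence[int],
                   direction: str = "higher_is_positive",
                   pair_ids: Sequence | None = None) -> pd.DataFrame:
    """Precision among the top-k ranked candidates, for each k.

    Ties are ordered deterministically: score descending, then pair id
    ascending (row index if no pair ids given). k > n is clamped to n.
    """
    import logging

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if direction == "lower_is_positive":
        scores = -scores
    if any(k <= 0 for k in ks):
        raise EvaluationError("k values must be positive")
    ids = list(pair_ids) if pair_ids is not None else list(range(len(scores)))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], ids[i]))
    ranked = labels[order]
    n = len(ranked)
    rows = []
    for k in ks:
        kk = min(k, n)
        if kk < k:
            logging.getLogger(__name__).warning("precision@%d clamped to n=%d", k, n)
        rows.append({"k": k, "k_used": kk, "precision": float(ranked[:kk].mean())})
    return pd.DataFrame(rows)


def score_correlations(table: pd.DataFrame, pairs: Sequence | None = None) -> pd.DataFrame:
    """Pearson r between measure-score columns over a chosen pair set.

    ``pairs``, if given, selects rows by index (the pair set over which the
    correlations are computed is an argument, not a fixed choice). Constant
    columns yield NaN, reported as missing.
    """
    if pairs is not None:
        table = table.loc[list(pairs)]
    if len(table) < 3:
        raise EvaluationError("need at least 3 rows for correlations")
    return table.corr(method="pearson")


@dataclass
class EvaluationResult:
    """One method's ranking performance on a labeled candidate set."""

    method: str
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    roc: pd.DataFrame = field(repr=False)
    precision: pd.DataFrame = field(repr=False)
    enrichment: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "subset_auroc": self.auroc,
            "ci95": [self.ci_low, self.ci_high],
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "precision_at_k": self.precision.to_dict(orient="records"),
        }
        if self.enrichment is not None:
            d["enrichment_factor"], d["enrichment_p"] = self.enrichment
        return d


def evaluate_ranking(scores, labels, method: str = "",
                     direction: str = "higher_is_positive",
                     ks: Sequence[int] = (10, 25, 50, 100)) -> EvaluationResult:
    """Full evaluation of one ranking: AUROC + DeLong CI, ROC, precision@k."""
    a, lo, hi = delong_ci(scores, labels, direction)
    labels = np.asarray(labels, dtype=int)
    return EvaluationResult(
        method=method,
        auroc=a,
        ci_low=lo,
        ci_high=hi,
        n_pos=int(labels.sum()),
        n_neg=int((1 - labels).sum()),
        roc=roc_points(scores, labels, direction),
        precision=precision_at_k(scores, labels, ks, direction),
    )
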