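"""Combining per-measure candidate scores: correlation PCA and stepwise LDA.

Two fusion models turn the per-measure max-similarity scores of a labeled
candidate table into a single ranking:

* :class:`PCAScoreCombiner` — unsupervised. PCA on the correlation matrix of
  the standardized score columns; the first component is the combined score.
  The component sign is oriented so that larger combined score means more
  DDI-like (positively correlated with the row mean of standardized scores);
  a raw eigenvector is sign-arbitrary and rankings are sign-invariant, so
  this is a presentation choice only.

* :class:`LDACombiner` — supervised two-class linear discriminant.
  Forward-stepwise selection enters, at each step, the variable minimizing
  Wilks' Λ, admitting it only when its partial-F (Rao) p-value clears the
  entry threshold; forced mode fits a given variable list directly. Model
  quality is summarized by Wilks' Λ (U), its two-class exact F transform
  F = ((n−p−1)/p)·(1−U)/U with df (p, n−p−1), and the significance level.

Both estimators follow the sklearn fit/transform contract and compose with
sklearn pipelines.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class CombinationError(ValueError):
    pass


def build_score_table(
    candidates: Sequence, columns: Sequence[str], missing: str = "impute"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Score table (rows = labeled candidates, columns = measures) + labels.

    ``missing="impute"`` fills unscored cells with 0 (flagged in the log);
    ``missing="drop"`` drops columns with any missing cell.
    """
    import logging

    logger = logging.getLogger(__name__)
    rows = []
    labels = []
    for c in candidates:
        rows.append({m: c.scores.get(m) for m in columns})
        labels.append(c.label)
    df = pd.DataFrame(rows, columns=list(columns))
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        if missing == "impute":
            logger.warning("score table: imputing %d missing cell(s) with 0", n_missing)
            df = df.fillna(0.0)
        elif missing == "drop":
            dropped = [c for c in df.columns if df[c].isna().any()]
            logger.warning("score table: dropping columns with missing cells: %s", dropped)
            df = df.drop(columns=dropped)
        else:
            raise CombinationError(f"unknown missing policy {missing!r}")
    return df, np.asarray(labels, dtype=int)


def _as_matrix(X, columns=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns) if columns is None else list(columns)
        return X[cols].to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise CombinationError("score table must be 2-dimensional")
    cols = [f"x{i}" for i in range(X.shape[1])] if columns is None else list(columns)
    return X, cols


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class scatter W and total scatter T (sums of squares/products)."""
    classes = np.unique(y)
    if len(classes) != 2:
        raise CombinationError(f"exactly two classes required, got {len(classes)}")
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for c in classes:
        g = X[y == c] - X[y == c].mean(axis=0)
        W += g.T @ g
    return W, T


def wilks_lambda(X, y, columns: Sequence[str] | None = None):
    """Wilks' Λ for a two-class design: U = det(W)/det(T).

    Returns ``(U, F, df1, df2, p)`` using the exact two-class F transform
    F = ((n−p−1)/p)·(1−U)/U with df (p, n−p−1).
    """
    M, cols = _as_matrix(X, columns)
    y = np.asarray(y)
    n, p = M.shape
    if n <= p + 2:
        raise CombinationError(f"need n > p + 2 rows (n={n}, p={p})")
    W, T = _scatter_matrices(M, y)
    detT = np.linalg.det(T)
    if not np.isfinite(detT) or abs(detT) < 1e-300:
        raise CombinationError("singular total scatter matrix (constant or collinear columns)")
    U = float(np.linalg.det(W) / detT)
    U = min(max(U, np.finfo(float).tiny), 1.0)
    df1, df2 = p, n - p - 1
    F = (df2 / df1) * (1.0 - U) / U
    pval = float(stats.f.sf(F, df1, df2))
    return U, float(F), df1, df2, pval


class PCAScoreCombiner(TransformerMixin, BaseEstimator):
    """One-component correlation-matrix PCA over measure score columns.

    Fitted attributes
    -----------------
    columns_ : list of str
        Score columns, in order.
    mean_, scale_ : ndarray
        Per-column mean and standard deviation used for standardization.
    loadings_ : ndarray
        Unit-norm eigenvector of component 1 (after orientation).
    factor_loadings_ : ndarray
        Variable–component correlations, loadings_ · sqrt(eigenvalue).
    explained_variance_ratio_ : ndarray
        Fraction of total variance per component (sums to 1).
    """

    def fit(self, X, y=None):
        M, cols = _as_matrix(X)
        n, p = M.shape
        if p < 2:
            raise CombinationError("need at least 2 score columns to combine")
        if n < 3:
            raise CombinationError("need at least 3 rows")
        scale = M.std(axis=0, ddof=1)
        for j, s in enumerate(scale):
            if s == 0 or not np.isfinite(s):
                raise CombinationError(f"constant column {cols[j]!r} cannot be standardized")
        self.columns_ = cols
        self.mean_ = M.mean(axis=0)
        self.scale_ = scale
        Z = (M - self.mean_) / self.scale_
        R = np.corrcoef(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.explained_variance_ratio_ = np.clip(evals, 0, None) / p
        v1 = evecs[:, 0]
        # orient: combined score correlates positively with the row-mean of Z
        # (cov(Z v1, Z 1/p) ∝ v1' R 1)
        if float(v1 @ R.sum(axis=1)) < 0:
            v1 = -v1
        self.loadings_ = v1
        self.factor_loadings_ = v1 * np.sqrt(max(evals[0], 0.0))
        self.eigenvalues_ = evals
        return self

    def transform(self, X) -> np.ndarray:
        """Component-1 score per row (zero mean on the training rows)."""
        check_is_fitted(self, "loadings_")
        M, cols = _as_matrix(X, getattr(X, "columns", None))
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.columns_ if c not in X.columns]
            if missing:
                raise CombinationError(f"missing score columns: {missing}")
            M = X[self.columns_].to_numpy(dtype=float)
        elif M.shape[1] != len(self.columns_):
            raise CombinationError(
                f"expected {len(self.columns_)} columns, got {M.shape[1]}"
            )
        Z = (M - self.mean_) / self.scale_
        return Z @ self.loadings_

    def to_dict(self) -> dict:
        check_is_fitted(self, "loadings_")
        return {
            "model": "pca",
            "columns": list(self.columns_),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "loadings": self.loadings_.tolist(),
            "factor_loadings": self.factor_loadings_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAScoreCombiner":
        m = cls()
        m.columns_ = list(d["columns"])
        m.mean_ = np.asarray(d["mean"], dtype=float)
        m.scale_ = np.asarray(d["scale"], dtype=float)
        m.loadings_ = np.asarray(d["loadings"], dtype=float)
        m.factor_loadings_ = np.asarray(d["factor_loadings"], dtype=float)
        m.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"], dtype=float)
        return m


class LDACombiner(BaseEstimator):
    """Two-class linear discriminant over measure score columns.

    Parameters
    ----------
    mode : {"stepwise", "forced"}
        ``stepwise`` selects variables forward by minimum Wilks' Λ with a
        partial-F entry test; ``forced`` fits ``variables`` directly.
    variables : sequence of str, optional
        Variable list for forced mode (default: all columns).
    p_enter : float
        Partial-F p-value threshold to admit a variable (stepwise mode).

    Fitted attributes: ``selected_`` (entry order), ``coef_`` (discriminant
    coefficients), ``wilks_``, ``f_stat_``, ``df_``, ``p_value_``,
    ``step_history_``.
    """

    def __init__(self, mode: str = "stepwise", variables: Sequence[str] | None = None,
                 p_enter: float = 0.05):
        self.mode = mode
        self.variables = variables
        self.p_enter = p_enter

    def fit(self, X, y):
        if self.mode not in ("stepwise", "forced"):
            raise CombinationError(f"unknown mode {self.mode!r}")
        M, cols = _as_matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise CombinationError(
                f"two classes required, got {list(classes)}"
            )
        self.classes_ = classes
        self.columns_ = cols
        if self.mode == "forced":
            selected = list(self.variables) if self.variables is not None else list(cols)
            unknown = [v for v in selected if v not in cols]
            if unknown:
                raise CombinationError(f"unknown variables: {unknown}")
            self.step_history_ = []
        else:
            selected = self._stepwise(M, cols, y)
            if not selected:
                raise CombinationError(
                    "stepwise selection admitted no variable; use forced mode"
                )
        self.selected_ = selected
        idx = [cols.index(v) for v in selected]
        Xs = M[:, idx]
        self.wilks_, self.f_stat_, df1, df2, self.p_value_ = wilks_lambda(Xs, y)
        self.df_ = (df1, df2)
        # discriminant direction: pooled within-class covariance inverse times
        # the mean difference; higher score = positive class
        n = len(y)
        W, _ = _scatter_matrices(Xs, y)
        Sw = W / (n - 2)
        mu0 = Xs[y == classes[0]].mean(axis=0)
        mu1 = Xs[y == classes[1]].mean(axis=0)
        try:
            w = np.linalg.solve(Sw, mu1 - mu0)
        except np.linalg.LinAlgError:
            raise CombinationError("degenerate pooled covariance") from None
        self.coef_ = w
        self.intercept_ = -float(w @ ((mu0 + mu1) / 2.0))
        return self

    def _stepwise(self, M: np.ndarray, cols: list[str], y: np.ndarray) -> list[str]:
        n = M.shape[0]
        selected: list[int] = []
        remaining = list(range(M.shape[1]))
        lam_old = 1.0
        history = []
        while remaining:
            best: tuple[float, int] | None = None
            for j in remaining:  # ties broken by column order
                try:
                    lam = wilks_lambda(M[:, selected + [j]], y)[0]
                except CombinationError:
                    continue
                if best is None or lam < best[0]:
                    best = (lam, j)
            if best is None:
                break
            lam_new, j = best
            p_in = len(selected)
            df2 = n - 2 - p_in
            if df2 <= 0 or lam_new <= 0:
                break
            F_enter = (lam_old / lam_new - 1.0) * df2
            p_enter = float(stats.f.sf(F_enter, 1, df2))
            if p_enter >= self.p_enter:
                break
            selected.append(j)
            remaining.remove(j)
            history.append(
                {"variable": cols[j], "wilks": lam_new, "F_enter": F_enter, "p_enter": p_enter}
            )
            lam_old = lam_new
        self.step_history_ = history
        return [cols[j] for j in selected]

    def decision_function(self, X) -> np.ndarray:
        """Discriminant score per row; higher = more DDI-like."""
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            missing = [v for v in self.selected_ if v not in X.columns]
            if missing:
                raise CombinationError(f"missing score columns: {missing}")
            M = X[self.selected_].to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            if M.shape[1] == len(self.columns_):
                idx = [self.columns_.index(v) for v in self.selected_]
                M = M[:, idx]
            elif M.shape[1] != len(self.selected_):
                raise CombinationError(
                    f"expected {len(self.selected_)} selected columns, got {M.shape[1]}"
                )
        return M @ self.coef_ + self.intercept_

    transform = decision_function

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "model": "lda",
            "mode": self.mode,
            "selected": list(self.selected_),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "wilks": self.wilks_,
            "F": self.f_stat_,
            "df": list(self.df_),
            "p_value": self.p_value_,
            "step_history": getattr(self, "step_history_", []),
        }


def fit_pca_combiner(table) -> PCAScoreCombiner:
    return PCAScoreCombiner().fit(table)


def score_pca(model: PCAScoreCombiner, rows) -> np.ndarray:
    return model.transform(rows)


def fit_lda_combiner(table, labels, mode: str = "stepwise",
                     variables: Sequence[str] | None = None,
                     p_enter: float = 0.05) -> LDACombiner:
    return LDACombiner(mode=mode, variables=variables, p_enter=p_enter).fit(table, labels)
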