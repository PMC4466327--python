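"""Reference-standard DDIs and max-similarity candidate scoring.

The reference standard is a set of known interacting drug pairs over a drug
universe of size n, viewed as a binary symmetric n×n matrix M1 with zero
diagonal. Given a similarity matrix M2 for the same universe, every unordered
candidate pair {i, j} is scored by its maximum similarity to a known DDI:

    score(i, j) = max( max_{k in N(i)} M2[k, j],  max_{k in N(j)} M2[k, i] )

where N(x) is the set of reference partners of x. Because the diagonal of M2
is structurally zero, a pair that is itself in the reference standard gains
nothing from its own entry (k = j contributes M2[j, j] = 0) — a leave-one-out
falls out of the formula with no case analysis. Self-pairs {i, i} are
excluded from the output.

Each nonzero score carries provenance: the reference DDI and the matched-drug
correspondence that achieved the maximum, which is what turns a ranked list
into an explainable signal (the macrolide example: candidate
clarithromycin–verapamil generated by reference erythromycin–verapamil
because clarithromycin ≈ erythromycin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .similarity import SimilarityMatrix


class ReferenceError(ValueError):
    pass


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair as a sorted tuple."""
    return (a, b) if a <= b else (b, a)


def n_unordered_pairs(n: int) -> int:
    """Number of unordered drug pairs over an n-drug universe, n(n-1)/2."""
    return n * (n - 1) // 2


@dataclass
class ReferenceStandard:
    """Known-DDI pair set over an ordered drug universe (matrix M1)."""

    drug_ids: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        self.drug_ids = tuple(self.drug_ids)
        ids = set(self.drug_ids)
        if len(ids) != len(self.drug_ids):
            raise ReferenceError("duplicate drug ids in universe")
        canon = set()
        for a, b in self.pairs:
            if a == b:
                raise ReferenceError(f"self-pair ({a}, {b}) is not a valid DDI")
            if a not in ids or b not in ids:
                unknown = [d for d in (a, b) if d not in ids]
                raise ReferenceError(f"pair ({a}, {b}): unknown drug id(s) {unknown}")
            canon.add(canonical_pair(a, b))
        self.pairs = frozenset(canon)

    @property
    def n(self) -> int:
        return len(self.drug_ids)

    @property
    def n_possible_pairs(self) -> int:
        return n_unordered_pairs(self.n)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def partners(self, drug_id: str) -> set[str]:
        return {b if a == drug_id else a for a, b in self.pairs if drug_id in (a, b)}

    def to_matrix(self) -> np.ndarray:
        """Binary symmetric matrix view; two 1-cells per reference pair."""
        idx = {d: i for i, d in enumerate(self.drug_ids)}
        m = np.zeros((self.n, self.n), dtype=np.uint8)
        for a, b in self.pairs:
            m[idx[a], idx[b]] = 1
            m[idx[b], idx[a]] = 1
        return m


def build_reference(
    pairs: Iterable[tuple[str, str]], drug_ids: Sequence[str]
) -> ReferenceStandard:
    """Deduplicated unordered reference pair set over a drug universe."""
    return ReferenceStandard(tuple(drug_ids), frozenset(tuple(p) for p in pairs))


@dataclass(frozen=True)
class Explanation:
    """Why a candidate pair received its score: the generating reference DDI."""

    drug1: str
    drug2: str
    measure: str
    score: float
    ref_drug1: str | None
    ref_drug2: str | None
    matched_drug: str | None  # the reference drug found similar ...
    matched_to: str | None  # ... to this candidate drug

    def as_row(self) -> dict:
        return {
            "drug1": self.drug1,
            "drug2": self.drug2,
            "measure": self.measure,
            "score": self.score,
            "ref_drug1": self.ref_drug1,
            "ref_drug2": self.ref_drug2,
            "matched_drug": self.matched_drug,
            "matched_to": self.matched_to,
        }


class CandidateScores:
    """Max-similarity candidate scores (matrix M3) with provenance."""

    def __init__(self, measure: str, ref: ReferenceStandard, sim: SimilarityMatrix):
        self.measure = measure
        self.ref = ref
        self.sim = sim
        self.drug_ids = ref.drug_ids
        self._idx = {d: i for i, d in enumerate(self.drug_ids)}
        m1 = ref.to_matrix().astype(bool)
        s = sim.values
        n = ref.n
        # asym[i, j] = max over reference partners k of i of sim(k, j)
        asym = np.zeros((n, n))
        for i in range(n):
            nbrs = np.flatnonzero(m1[i])
            if len(nbrs):
                asym[i] = s[nbrs].max(axis=0)
        scores = np.maximum(asym, asym.T)
        np.fill_diagonal(scores, 0.0)
        self.scores = scores

    def get(self, a: str, b: str) -> float:
        if a == b:
            raise ReferenceError("self-pairs are excluded from candidate scoring")
        return float(self.scores[self._idx[a], self._idx[b]])

    def explain(self, pair: tuple[str, str]) -> Explanation:
        """Provenance of one candidate score: the arg-max of the formula.

        Ties are broken by the lexicographically smallest (reference pair,
        matched drug) so provenance is deterministic.
        """
        a, b = pair
        if a == b:
            raise ReferenceError("self-pairs are excluded from candidate scoring")
        if a not in self._idx or b not in self._idx:
            raise ReferenceError(f"pair ({a}, {b}) not in the scored universe")
        score = self.get(a, b)
        best: tuple | None = None
        # N(x) partner k: reference pair (x, k); k is matched to the other drug
        for x, other in ((a, b), (b, a)):
            for k in sorted(self.ref.partners(x)):
                s = self.sim.get(k, other)
                if s != score:
                    continue
                key = (canonical_pair(x, k), k)
                if best is None or key < best[0:2]:
                    best = (key[0], k, other, s)
        if best is None or score == 0.0:
            return Explanation(a, b, self.measure, score, None, None, None, None)
        (r1, r2), k, other, s = best
        return Explanation(a, b, self.measure, s, r1, r2, k, other)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.drug_ids)
        return pd.DataFrame(self.scores, index=ids, columns=ids)

    def ranked_pairs(self, top: int | None = None) -> pd.DataFrame:
        """Ranked unordered-pair list with explanations (report layout)."""
        rows = []
        n = len(self.drug_ids)
        iu, ju = np.triu_indices(n, k=1)
        order = np.argsort(-self.scores[iu, ju], kind="stable")
        if top is not None:
            order = order[:top]
        for t in order:
            a, b = self.drug_ids[iu[t]], self.drug_ids[ju[t]]
            rows.append(self.explain((a, b)).as_row())
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f", index_label="drug")


class MaxSimilarityScorer(BaseEstimator):
    """Estimator wrapper around max-similarity candidate scoring.

    ``fit`` takes the similarity matrix (X) and the reference standard (y);
    ``transform`` maps unordered id pairs to candidate scores. Composes with
    sklearn model selection on the pair level.

    Parameters
    ----------
    aggregation : {"max", "mean_top"}
        How per-reference scores are aggregated. ``max`` keeps the single
        highest similarity against any reference DDI (default, the method's
        definition); ``mean_top`` averages the ``top_t`` highest.
    top_t : int
        Number of top reference links averaged when aggregation="mean_top".
    """

    def __init__(self, aggregation: str = "max", top_t: int = 3):
        self.aggregation = aggregation
        self.top_t = top_t

    def fit(self, X: SimilarityMatrix, y: ReferenceStandard) -> "MaxSimilarityScorer":
        if self.aggregation not in ("max", "mean_top"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        sim = X if tuple(X.drug_ids) == tuple(y.drug_ids) else X.reorder(y.drug_ids)
        if self.aggregation == "max":
            self.candidate_scores_ = CandidateScores(sim.measure, y, sim)
            self.scores_ = self.candidate_scores_.scores
        else:
            self.candidate_scores_ = None
            self.scores_ = self._mean_top(sim, y)
        self.drug_ids_ = y.drug_ids
        self._index_ = {d: i for i, d in enumerate(y.drug_ids)}
        self.measure_ = sim.measure
        return self

    def _mean_top(self, sim: SimilarityMatrix, ref: ReferenceStandard) -> np.ndarray:
        m1 = ref.to_matrix().astype(bool)
        n = ref.n
        asym = np.zeros((n, n))
        for i in range(n):
            nbrs = np.flatnonzero(m1[i])
            if len(nbrs):
                col = np.sort(sim.values[nbrs], axis=0)[::-1][: self.top_t]
                asym[i] = col.mean(axis=0)
        out = np.maximum(asym, asym.T)
        np.fill_diagonal(out, 0.0)
        return out

    def transform(self, pairs: Iterable[tuple[str, str]]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scores_")
        out = []
        for a, b in pairs:
            if a == b:
                raise ReferenceError("self-pairs are excluded from candidate scoring")
            out.append(self.scores_[self._index_[a], self._index_[b]])
        return np.asarray(out)

    def unscorable(self, pairs: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
        """Pairs with neither drug in the reference universe.

        No score can be generated for them (both similarity links are
        undefined); they are reported, never silently scored 0.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scores_")
        known = set(self.drug_ids_)
        return [(a, b) for a, b in pairs if a not in known and b not in known]


def score_candidates(ref: ReferenceStandard, sim: SimilarityMatrix) -> CandidateScores:
    """Max-similarity candidate score matrix M3 with provenance (see module doc)."""
    sim = sim if tuple(sim.drug_ids) == tuple(ref.drug_ids) else sim.reorder(ref.drug_ids)
    return CandidateScores(sim.measure, ref, sim)


def explain_candidate(cs: CandidateScores, pair: tuple[str, str]) -> Explanation:
    return cs.explain(pair)
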