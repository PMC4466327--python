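"""Drug × drug similarity matrices, one per similarity measure.

A similarity matrix is square over an ordered drug universe, symmetric, with
all entries in [0, 1] and a structurally zero diagonal: self-similarity is
never informative for interaction scoring, and the zero diagonal is what
realizes the leave-one-out when candidates are scored downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import Fingerprint

logger = logging.getLogger(__name__)

MEASURES = ("2D", "3D", "ADEPF", "TPF", "DDIPF", "ATC")


class SimilarityMatrixError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    """Symmetric drug–drug similarity values in [0, 1] with a zero diagonal."""

    measure: str
    drug_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = tuple(self.drug_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.drug_ids)
        if len(set(self.drug_ids)) != n:
            raise SimilarityMatrixError(f"[{self.measure}] duplicate drug ids")
        if self.values.shape != (n, n):
            raise SimilarityMatrixError(
                f"[{self.measure}] matrix shape {self.values.shape} != ({n}, {n})"
            )
        if np.any(~np.isfinite(self.values)):
            raise SimilarityMatrixError(f"[{self.measure}] non-finite entries")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            i, j = np.unravel_index(
                np.argmax(np.abs(self.values - np.clip(self.values, 0, 1))),
                self.values.shape,
            )
            raise SimilarityMatrixError(
                f"[{self.measure}] value {self.values[i, j]:g} outside [0, 1] at "
                f"({self.drug_ids[i]}, {self.drug_ids[j]})"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise SimilarityMatrixError(f"[{self.measure}] matrix not symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise SimilarityMatrixError(f"[{self.measure}] diagonal must be exactly 0")

    @property
    def n(self) -> int:
        return len(self.drug_ids)

    def index_of(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"drug {drug_id!r} not in similarity matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def reorder(self, drug_ids: Sequence[str]) -> "SimilarityMatrix":
        """Rows/columns permuted to a new drug order (must be the same set)."""
        if set(drug_ids) != set(self.drug_ids):
            missing = sorted(set(drug_ids) - set(self.drug_ids))
            extra = sorted(set(self.drug_ids) - set(drug_ids))
            raise SimilarityMatrixError(
                f"[{self.measure}] cannot reorder: missing {missing}, extra {extra}"
            )
        idx = [self.index_of(d) for d in drug_ids]
        return SimilarityMatrix(self.measure, tuple(drug_ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.drug_ids), columns=list(self.drug_ids))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f", index_label="drug")


def build_similarity_matrix(
    fingerprints: Sequence[Fingerprint], measure: str
) -> SimilarityMatrix:
    """Pairwise Tanimoto over a fingerprint set; diagonal forced to 0.

    Vectorized as inner products of the bit matrix; agrees with the
    pairwise ``tanimoto`` function entry by entry.
    """
    if not fingerprints:
        raise SimilarityMatrixError("no fingerprints given")
    ids = tuple(fp.drug_id for fp in fingerprints)
    if len(set(ids)) != len(ids):
        raise SimilarityMatrixError("duplicate drug ids among fingerprints")
    u0 = fingerprints[0].universe
    d0 = fingerprints[0].domain
    for fp in fingerprints:
        if fp.universe != u0 or fp.domain != d0:
            raise SimilarityMatrixError(
                f"fingerprint {fp.drug_id!r} is not on the shared {d0} universe"
            )
    B = np.stack([fp.bits for fp in fingerprints]).astype(np.int64)
    inter = B @ B.T
    pop = B.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 0.0)
    n_empty = int((pop == 0).sum())
    if n_empty:
        logger.warning("%s: %d drug(s) with empty fingerprints (all-zero rows)", measure, n_empty)
    return SimilarityMatrix(measure, ids, sim)


def load_external_similarity(
    path, drug_ids: Sequence[str], measure: str = "3D"
) -> SimilarityMatrix:
    """Import an externally computed similarity matrix (e.g. 3D shape scores).

    The file is a labeled square TSV (first row/column are drug ids). Values
    outside [0, 1] are an error; an asymmetric input is symmetrized by the
    elementwise maximum of the two mirror cells; a nonzero diagonal is forced
    to 0 with a warning; rows/columns are reordered to ``drug_ids``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = sorted(set(drug_ids) - set(df.index)) + sorted(set(drug_ids) - set(df.columns))
    if missing:
        raise SimilarityMatrixError(
            f"external matrix {path} is missing drugs: {sorted(set(missing))}"
        )
    df = df.loc[list(drug_ids), list(drug_ids)]
    vals = df.to_numpy(dtype=float)
    bad = np.argwhere((vals < 0.0) | (vals > 1.0) | ~np.isfinite(vals))
    if len(bad):
        i, j = bad[0]
        raise SimilarityMatrixError(
            f"external matrix {path}: value {vals[i, j]!r} outside [0, 1] at "
            f"({drug_ids[i]}, {drug_ids[j]})"
        )
    sym = np.maximum(vals, vals.T)
    if np.any(np.diagonal(sym) != 0.0):
        logger.warning("external matrix %s: nonzero diagonal forced to 0", path)
        np.fill_diagonal(sym, 0.0)
    return SimilarityMatrix(measure, tuple(drug_ids), sym)


def read_similarity_tsv(path, measure: str) -> SimilarityMatrix:
    """Read back a matrix written by :meth:`SimilarityMatrix.write_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(measure, tuple(str(i) for i in df.index), df.to_numpy(dtype=float))
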