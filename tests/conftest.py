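"""Shared fixtures: small drug universes and similarity matrices built by hand."""

from __future__ import annotations

import numpy as np
import pytest

from ddisim.chem import Drug
from ddisim.reference import build_reference
from ddisim.similarity import SimilarityMatrix


def sim_from_pairs(drug_ids, pairs: dict[tuple[str, str], float]) -> SimilarityMatrix:
    """Symmetric similarity matrix with the given off-diagonal entries."""
    idx = {d: i for i, d in enumerate(drug_ids)}
    m = np.zeros((len(drug_ids), len(drug_ids)))
    for (a, b), v in pairs.items():
        m[idx[a], idx[b]] = v
        m[idx[b], idx[a]] = v
    np.fill_diagonal(m, 0.0)
    return SimilarityMatrix("custom", tuple(drug_ids), m)


def random_universe(rng: np.random.Generator, n: int, n_ref: int | None = None):
    """Random drug ids, reference pairs and a random similarity matrix."""
    ids = [f"d{i:02d}" for i in range(n)]
    all_pairs = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    if n_ref is None:
        n_ref = int(rng.integers(1, max(2, len(all_pairs) // 3)))
    chosen = rng.choice(len(all_pairs), size=min(n_ref, len(all_pairs)), replace=False)
    ref = build_reference([all_pairs[i] for i in chosen], ids)
    m = rng.random((n, n)).round(3)
    m = np.maximum(m, m.T)
    np.fill_diagonal(m, 0.0)
    return ids, ref, SimilarityMatrix("custom", tuple(ids), m)


@pytest.fixture
def toy_drugs() -> list[Drug]:
    """Four drugs with overlapping profile features across all domains."""
    return [
        Drug(id="a", name="A", ade_terms=frozenset({"nausea", "dizziness"}),
             target_ids=frozenset({"HERG_HUMAN", "CYP3A4_HUMAN"}),
             partner_ids=frozenset({"x", "y"}), atc_codes=frozenset({"J01FA09"})),
        Drug(id="b", name="B", ade_terms=frozenset({"dizziness", "rash"}),
             target_ids=frozenset({"herg_rat", "SCN5A_HUMAN"}),
             partner_ids=frozenset({"y", "z"}), atc_codes=frozenset({"J01FA10"})),
        Drug(id="c", name="C", ade_terms=frozenset({"headache"}),
             target_ids=frozenset({"OPRM1_HUMAN"}),
             partner_ids=frozenset({"w"}), atc_codes=frozenset({"C01BA01"})),
        Drug(id="d", name="D"),  # empty everywhere
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150612)
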