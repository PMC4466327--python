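"""Per-drug fingerprints and Tanimoto similarity.

A drug is described in up to five binary feature domains:

* ``2D`` — the 166 public MACCS structural keys computed from SMILES;
* ``ADEPF`` — adverse-drug-effect profile (presence/absence of ADE terms);
* ``TPF`` — protein-target profile (targets, enzymes, transporters, carriers);
* ``DDIPF`` — known-interaction-partner profile;
* ``ATC`` — the four upper levels of the drug's ATC codes.

Each domain yields one ordered feature universe shared by all drugs of a run,
and one binary fingerprint per drug. Similarity between two fingerprints is
the Tanimoto coefficient Tc = |A ∩ B| / |A ∪ B| ∈ [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PROFILE_DOMAINS = ("ADEPF", "TPF", "DDIPF", "ATC")
DOMAINS = ("2D",) + PROFILE_DOMAINS

N_MACCS_KEYS = 166
MACCS_UNIVERSE = tuple(f"maccs_{i}" for i in range(1, N_MACCS_KEYS + 1))

# letter, two digits, letter, letter, optionally two digits (full 5-level code)
_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}(\d{2})?$")

# UniProt-style organism suffixes ("HERG_HUMAN") and trailing parentheticals
# ("Cytochrome P450 3A4 (Homo sapiens)") collapse to one feature per protein.
# Organism codes are uppercase and contain a letter; a numeric suffix is part
# of the identifier, not an organism.
_ORGANISM_SUFFIX_RE = re.compile(r"_(?=[A-Z0-9]*[A-Z])[A-Z0-9]+$")
_PARENTHETICAL_RE = re.compile(r"\s*\([^)]*\)\s*$")


class FingerprintError(ValueError):
    """Invalid input to fingerprint construction (bad SMILES, bad code, ...)."""


@dataclass(frozen=True)
class Drug:
    """One pharmaceutical entity with its structure string and feature sets."""

    id: str
    name: str = ""
    smiles: str | None = None
    ade_terms: frozenset[str] = field(default_factory=frozenset)
    target_ids: frozenset[str] = field(default_factory=frozenset)
    partner_ids: frozenset[str] = field(default_factory=frozenset)
    atc_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValueError("drug id must be nonempty")
        for code in self.atc_codes:
            if not _ATC_RE.match(code.strip().upper()):
                raise FingerprintError(
                    f"drug {self.id!r}: ATC code {code!r} does not match the "
                    "ATC pattern (letter, 2 digits, letter, letter[, 2 digits])"
                )

    def features(self, domain: str) -> frozenset[str]:
        """Normalized feature set of this drug in one profile domain."""
        if domain == "ADEPF":
            return frozenset(normalize_feature(t) for t in self.ade_terms)
        if domain == "TPF":
            return frozenset(normalize_target(t) for t in self.target_ids)
        if domain == "DDIPF":
            return frozenset(normalize_feature(t) for t in self.partner_ids)
        if domain == "ATC":
            return frozenset(expand_atc_features(self.atc_codes))
        raise ValueError(f"unknown profile domain {domain!r}")


@dataclass(frozen=True)
class Fingerprint:
    """Binary feature vector for one drug in one feature domain."""

    drug_id: str
    domain: str
    universe: tuple[str, ...]
    bits: np.ndarray  # uint8, aligned to universe

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1 or len(bits) != len(self.universe):
            raise ValueError(
                f"fingerprint for {self.drug_id!r}: bits length {len(bits)} "
                f"!= universe length {len(self.universe)}"
            )
        if self.domain == "2D" and len(self.universe) != N_MACCS_KEYS:
            raise ValueError("2D fingerprints use the fixed 166-key universe")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @property
    def is_empty(self) -> bool:
        return self.popcount == 0


def normalize_feature(label: str) -> str:
    """Case-fold and trim a feature label (heterogeneous-source inputs)."""
    return label.strip().casefold()


def normalize_target(label: str) -> str:
    """Normalize a protein-target identifier.

    The same target from different organisms counts as one feature: an
    organism given as a UniProt-style ``_SUFFIX`` or a trailing parenthetical
    is stripped before case-folding.
    """
    label = label.strip()
    label = _PARENTHETICAL_RE.sub("", label)
    stripped = _ORGANISM_SUFFIX_RE.sub("", label)
    return (stripped if stripped else label).casefold()


def expand_atc_features(atc_codes: Iterable[str]) -> set[str]:
    """Expand ATC codes into their four upper-level prefix features.

    Each code contributes level-1 (anatomical, 1 char), level-2 (therapeutic,
    3 chars), level-3 (pharmacological, 4 chars) and level-4 (chemical,
    5 chars) prefixes. Levels are tagged so identical strings at different
    levels cannot collide. Multi-code drugs take the union over their codes.
    """
    feats: set[str] = set()
    for code in atc_codes:
        code = code.strip().upper()
        if not _ATC_RE.match(code):
            raise FingerprintError(f"lexically invalid ATC code {code!r}")
        feats.add(f"L1:{code[:1]}")
        feats.add(f"L2:{code[:3]}")
        feats.add(f"L3:{code[:4]}")
        feats.add(f"L4:{code[:5]}")
    return feats


def build_structural_fingerprint(smiles: str, drug_id: str = "?") -> Fingerprint:
    """166-key MACCS structural-key fingerprint from a SMILES string.

    Deterministic for a given input string. RDKit's MACCS vector carries a
    dummy bit 0 which is dropped so that positions align with the public
    166-key dictionary.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(
            f"drug {drug_id!r}: SMILES string {smiles!r} could not be parsed"
        )
    keys = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    bits = np.zeros(N_MACCS_KEYS, dtype=np.uint8)
    for b in keys.GetOnBits():
        if b >= 1:
            bits[b - 1] = 1
    return Fingerprint(drug_id=drug_id, domain="2D", universe=MACCS_UNIVERSE, bits=bits)


def build_feature_universe(drugs: Sequence[Drug], domain: str) -> tuple[str, ...]:
    """Ordered (sorted) union of normalized features over a drug table."""
    universe: set[str] = set()
    for d in drugs:
        universe |= d.features(domain)
    return tuple(sorted(universe))


def build_profile_fingerprint(
    features: Iterable[str],
    universe: Sequence[str],
    drug_id: str = "?",
    domain: str = "ADEPF",
) -> Fingerprint:
    """Bit vector with ones exactly at the universe positions of `features`.

    Features must already be normalized consistently with the universe; the
    universe is built first from the whole drug table.
    """
    index = {label: i for i, label in enumerate(universe)}
    if len(index) != len(universe):
        raise ValueError("universe contains duplicate labels")
    bits = np.zeros(len(universe), dtype=np.uint8)
    for f in features:
        try:
            bits[index[f]] = 1
        except KeyError:
            raise FingerprintError(
                f"drug {drug_id!r}: feature {f!r} absent from the {domain} "
                "universe (build the universe from the whole drug table first)"
            ) from None
    return Fingerprint(drug_id=drug_id, domain=domain, universe=tuple(universe), bits=bits)


def build_domain_fingerprints(drugs: Sequence[Drug], domain: str) -> list[Fingerprint]:
    """All fingerprints of one domain over a shared universe.

    Drugs missing the domain entirely get an all-zero fingerprint (callers
    flag these in the run report rather than dropping the drug).
    """
    if domain == "2D":
        out = []
        for d in drugs:
            if d.smiles:
                out.append(build_structural_fingerprint(d.smiles, drug_id=d.id))
            else:
                out.append(
                    Fingerprint(d.id, "2D", MACCS_UNIVERSE, np.zeros(N_MACCS_KEYS, dtype=np.uint8))
                )
        return out
    universe = build_feature_universe(drugs, domain)
    return [
        build_profile_fingerprint(d.features(domain), universe, drug_id=d.id, domain=domain)
        for d in drugs
    ]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a ∧ b| / |a ∨ b|.

    Two all-zero fingerprints score 0, not 1: absence of evidence must not
    produce maximal similarity.
    """
    if a.domain != b.domain or a.universe != b.universe:
        raise ValueError(
            f"cannot compare fingerprints across universes "
            f"({a.domain}/{len(a.universe)} vs {b.domain}/{len(b.universe)})"
        )
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    return inter / union if union else 0.0
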