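"""Synthetic drug universes with planted interaction structure.

The generator emulates the statistical regularity the max-similarity method
exploits: drugs in the same pharmacological class look alike across feature
domains, and when one member of a class interacts with a partner drug, other
members tend to as well. Concretely, a fraction of the universe consists of
"analogs" — near-duplicates of a parent drug with per-domain feature noise —
reference DDIs are planted among parents, and the true signals of the
synthetic pharmacovigilance table are analog–partner pairs of those
reference DDIs. With analog_rate 0 no similarity structure links signals to
the reference standard and ranking collapses to chance.

Synthetic "structures" are abstract feature patterns, not chemistry; the
MACCS path is exercised with the handful of real SMILES strings below.
All randomness flows from one explicit generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .chem import Drug
from .reference import ReferenceStandard, build_reference, canonical_pair, n_unordered_pairs

# Real isomeric SMILES (public structure records) for spot-checking the
# structural-fingerprint path with actual chemistry.
REAL_SMILES = {
    "erythromycin": "CC[C@@H]1[C@@]([C@@H]([C@H](C(=O)[C@@H](C[C@@]([C@@H]([C@H]([C@@H]([C@H](C(=O)O1)C)O[C@H]2C[C@@]([C@H]([C@@H](O2)C)O)(C)OC)C)O[C@H]3[C@@H]([C@H](C[C@H](O3)C)N(C)C)O)(C)O)C)C)C)(C)O",
    "clarithromycin": "CC[C@@H]1[C@@]([C@@H]([C@H](C(=O)[C@@H](C[C@@]([C@@H]([C@H]([C@@H]([C@H](C(=O)O1)C)O[C@H]2C[C@@]([C@H]([C@@H](O2)C)O)(C)OC)C)O[C@H]3[C@@H]([C@H](C[C@H](O3)C)N(C)C)O)(C)OC)C)C)C)(C)O",
    "verapamil": "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC",
    "fluconazole": "OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F",
    "amitriptyline": "CN(C)CCC=C1c2ccccc2CCc2ccccc21",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}

# ATC codes of three macrolides: identical 4-level prefixes for the J01FA
# members, used by the worked examples (Tc_ATC = 1 between them).
REAL_ATC = {
    "erythromycin": "J01FA01",
    "clarithromycin": "J01FA09",
    "azithromycin": "J01FA10",
}

PROFILE_DOMAIN_DEFAULTS = {"ADEPF": 250, "TPF": 150, "DDIPF": 200}
FEATURES_PER_DRUG_DEFAULTS = {"ADEPF": 20, "TPF": 10, "DDIPF": 12}

_ATC_LETTERS = "ABCDGHJLMNPRSV"


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic universe; identical config + seed ⇒ identical output."""

    n_drugs: int = 300
    n_features: dict = dataclass_field(default_factory=lambda: dict(PROFILE_DOMAIN_DEFAULTS))
    features_per_drug: dict = dataclass_field(default_factory=lambda: dict(FEATURES_PER_DRUG_DEFAULTS))
    n_reference_ddis: int = 60
    n_signal_records: int = 400
    signal_positive_fraction: float = 0.25
    signal_reference_fraction: float = 0.035  # known-DDI share among signals
    class_sibling_rate: float = 0.5  # chance a reference DDI has a same-class twin
    analog_rate: float = 0.5
    noise: float = 0.05  # per-feature flip probability for analogs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs <= 3 or self.n_reference_ddis <= 0 or self.n_signal_records <= 0:
            raise SyntheticError("all counts must be positive (and n_drugs > 3)")
        if not (0.0 <= self.analog_rate <= 1.0):
            raise SyntheticError("analog_rate must be in [0, 1]")
        if not (0.0 <= self.noise <= 1.0):
            raise SyntheticError("noise must be in [0, 1]")


def _random_atc(rng: np.random.Generator) -> str:
    return (
        rng.choice(list(_ATC_LETTERS))
        + f"{rng.integers(1, 17):02d}"
        + rng.choice(list("ABCDEF"))
        + rng.choice(list("ABCDEF"))
        + f"{rng.integers(1, 80):02d}"
    )


def _noisy_copy(feats: frozenset[str], pool: list[str], noise: float,
                rng: np.random.Generator) -> frozenset[str]:
    kept = {f for f in feats if rng.random() >= noise}
    n_add = int(rng.binomial(max(len(feats), 1), noise))
    if n_add:
        kept |= set(rng.choice(pool, size=n_add, replace=False))
    return frozenset(kept)


def generate_universe(cfg: SyntheticConfig):
    """Build a synthetic (drug table, reference standard, signal table, truth).

    Returns ``(drugs, ref, signal_df, truth)`` where ``signal_df`` has
    columns drug1/drug2/prr/p_value/event and ``truth`` is the aligned 0/1
    array marking planted true interactions.
    """
    rng = np.random.default_rng(cfg.seed)
    n_analog = int(round(cfg.analog_rate * cfg.n_drugs))
    n_parent = cfg.n_drugs - n_analog
    if n_parent < 3:
        raise SyntheticError("analog_rate leaves too few parent drugs")
    if cfg.n_reference_ddis > n_unordered_pairs(n_parent):
        raise SyntheticError(
            f"cannot plant {cfg.n_reference_ddis} reference DDIs among "
            f"{n_parent} parent drugs"
        )

    pools = {
        dom: [f"{dom.lower()}_{i:04d}" for i in range(cfg.n_features[dom])]
        for dom in PROFILE_DOMAIN_DEFAULTS
    }
    parent_ids = [f"P{i:04d}" for i in range(n_parent)]
    analog_ids = [f"A{i:04d}" for i in range(n_analog)]

    def random_features(dom):
        k = min(cfg.features_per_drug[dom], len(pools[dom]))
        return frozenset(rng.choice(pools[dom], size=k, replace=False))

    drugs: list[Drug] = []
    feat: dict[str, dict[str, frozenset]] = {}
    atc: dict[str, str] = {}
    for pid in parent_ids:
        feat[pid] = {dom: random_features(dom) for dom in pools}
        atc[pid] = _random_atc(rng)
    analog_parent: dict[str, str] = {}
    for aid in analog_ids:
        par = parent_ids[int(rng.integers(0, n_parent))]
        analog_parent[aid] = par
        feat[aid] = {
            dom: _noisy_copy(feat[par][dom], pools[dom], cfg.noise, rng) for dom in pools
        }
        atc[aid] = atc[par] if rng.random() >= cfg.noise else _random_atc(rng)
    for did in parent_ids + analog_ids:
        drugs.append(
            Drug(
                id=did,
                name=did,
                smiles=None,
                ade_terms=feat[did]["ADEPF"],
                target_ids=feat[did]["TPF"],
                partner_ids=feat[did]["DDIPF"],
                atc_codes=frozenset({atc[did]}),
            )
        )

    # plant reference DDIs among parents
    all_parent_pairs = [
        (parent_ids[i], parent_ids[j])
        for i in range(n_parent)
        for j in range(i + 1, n_parent)
    ]
    idx = rng.choice(len(all_parent_pairs), size=cfg.n_reference_ddis, replace=False)
    ref_pairs = [all_parent_pairs[i] for i in sorted(idx)]
    drug_ids = parent_ids + analog_ids
    # same-class twins: reference standards cluster in pharmacological
    # classes, so some known DDIs have a sibling pair with an analog drug —
    # this is what lets a known DDI rank well under leave-one-out
    children: dict[str, list[str]] = {}
    for aid, par in analog_parent.items():
        children.setdefault(par, []).append(aid)
    sibling_pairs = []
    for a, b in ref_pairs:
        if rng.random() < cfg.class_sibling_rate:
            for x, other in ((a, b), (b, a)):
                kids = children.get(x, [])
                if kids:
                    sibling_pairs.append(canonical_pair(kids[0], other))
                    break
    ref = build_reference(list(ref_pairs) + sibling_pairs, drug_ids)

    # novel true signals: analog-of-a with b, for reference pairs (a, b);
    # with no analogs (null universe) random non-reference pairs stand in,
    # carrying no similarity structure by construction
    true_candidates: list[tuple[str, str]] = []
    for a, b in ref.pairs:
        for x, other in ((a, b), (b, a)):
            for child in children.get(x, []):
                if child != other:
                    true_candidates.append(canonical_pair(child, other))
    true_candidates = sorted(set(true_candidates) - ref.pairs)
    n_true_target = int(round(cfg.signal_positive_fraction * cfg.n_signal_records))
    if true_candidates:
        take = min(n_true_target, len(true_candidates))
        sel = rng.choice(len(true_candidates), size=take, replace=False)
        true_pairs = [true_candidates[i] for i in sorted(sel)]
    else:
        true_pairs = []
        while len(true_pairs) < n_true_target:
            i, j = rng.integers(0, cfg.n_drugs, size=2)
            if i == j:
                continue
            p = canonical_pair(drug_ids[i], drug_ids[j])
            if p not in ref.pairs and p not in true_pairs:
                true_pairs.append(p)

    # known-DDI signals: a small share of the signal table is reference
    # pairs themselves (signals whose interaction is already documented)
    n_ref_rows = min(int(round(cfg.signal_reference_fraction * cfg.n_signal_records)),
                     len(ref.pairs))
    ref_sorted = sorted(ref.pairs)
    sel = rng.choice(len(ref_sorted), size=n_ref_rows, replace=False)
    ref_rows = [ref_sorted[i] for i in sorted(sel)]

    # negatives: random pairs carrying no planted structure
    neg_pairs: list[tuple[str, str]] = []
    used = set(true_pairs) | ref.pairs
    n_neg = cfg.n_signal_records - len(true_pairs) - len(ref_rows)
    while len(neg_pairs) < n_neg:
        i, j = rng.integers(0, cfg.n_drugs, size=2)
        if i == j:
            continue
        p = canonical_pair(drug_ids[i], drug_ids[j])
        if p in used:
            continue
        used.add(p)
        neg_pairs.append(p)

    rows = []
    truth = []
    # genuinely interacting pairs: over-reported (log-normal PRR above 1)
    # with small disproportionality p-values (Beta mass near 0). The truth
    # flag marks planted NOVEL interactions only; known reference pairs in
    # the table are labeled downstream via the reference standard itself.
    for p, t in [(p, 1) for p in true_pairs] + [(p, 0) for p in ref_rows]:
        rows.append((p[0], p[1], float(np.exp(rng.normal(np.log(6.0), 0.6))),
                     float(0.05 * rng.beta(0.5, 8.0)), "arrhythmia"))
        truth.append(t)
    for p in neg_pairs:
        rows.append((p[0], p[1], float(np.exp(rng.normal(np.log(1.6), 0.5))),
                     float(0.05 * rng.beta(1.2, 2.0)), "arrhythmia"))
        truth.append(0)
    order = rng.permutation(len(rows))
    signal_df = pd.DataFrame(
        [rows[i] for i in order],
        columns=["drug1", "drug2", "prr", "p_value", "event"],
    )
    truth = np.asarray([truth[i] for i in order], dtype=int)
    return drugs, ref, signal_df, truth


def brute_force_m3(ref_pairs, sim_lookup, drug_ids):
    """Independent double-loop oracle for the max-similarity score map.

    ``sim_lookup(a, b)`` returns the similarity of two drugs (0 diagonal
    assumed). Only for tests; universes above 30 drugs are refused.
    """
    drug_ids = list(drug_ids)
    if len(drug_ids) > 30:
        raise SyntheticError("brute_force_m3 is a test oracle; universe too large (n > 30)")
    ref_pairs = [canonical_pair(a, b) for a, b in ref_pairs]
    scores: dict[tuple[str, str], float] = {}
    for i, di in enumerate(drug_ids):
        for dj in drug_ids[i + 1:]:
            best = 0.0
            for a, b in ref_pairs:
                for x, k in ((a, b), (b, a)):
                    # (x, k) oriented reference link: x's partner k ...
                    if x == di:
                        best = max(best, sim_lookup(k, dj))  # ... matched to dj
                    if x == dj:
                        best = max(best, sim_lookup(k, di))
            scores[canonical_pair(di, dj)] = best
    return scores


def write_fixture_dir(cfg: SyntheticConfig, out_dir) -> dict:
    """Write a full synthetic fixture set in the dialects the tools consume."""
    from pathlib import Path

    from .io import write_drug_table, write_pair_list

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drugs, ref, signal_df, truth = generate_universe(cfg)
    write_drug_table(drugs, out / "drugs.tsv")
    write_pair_list(sorted(ref.pairs), out / "reference_pairs.csv")
    signal_df.to_csv(out / "signals.csv", index=False)
    pd.DataFrame({"drug1": signal_df["drug1"], "drug2": signal_df["drug2"],
                  "truth": truth}).to_csv(out / "truth.csv", index=False)
    return {
        "drugs": str(out / "drugs.tsv"),
        "reference_pairs": str(out / "reference_pairs.csv"),
        "signals": str(out / "signals.csv"),
        "truth": str(out / "truth.csv"),
    }
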