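"""Pharmacovigilance DDI signal tables: parsing, filtering, labeling.

Signal tables are TWOSIDES-style extracts: one row per drug pair flagged for
an adverse event, with a proportional reporting ratio (PRR) and a p-value
from the disproportionality analysis. The standard screen keeps signals with
PRR > 1 and p < .05 (both strict, as conventionally printed), then maps the
surviving pairs into the reference drug universe: a pair is a labeled
candidate only when BOTH drugs are reference-universe drugs, and it is a
positive exactly when the pair is itself a known reference DDI.

An external label source (e.g. interaction compendia with knowledge tiers
such as well-established / probable / theoretical) can relabel the same
candidates at a chosen cumulative knowledge level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import ReferenceStandard, canonical_pair

logger = logging.getLogger(__name__)


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class SignalRecord:
    """One pharmacovigilance signal: a drug pair with PRR and p-value."""

    drug1_id: str
    drug2_id: str
    prr: float
    p_value: float
    event: str | None = None

    def __post_init__(self) -> None:
        if self.drug1_id == self.drug2_id:
            raise SignalError(f"signal pair ({self.drug1_id}, {self.drug2_id}) is a self-pair")
        if not self.prr > 0:
            raise SignalError(f"PRR must be positive, got {self.prr!r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise SignalError(f"p-value must be in [0, 1], got {self.p_value!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.drug1_id, self.drug2_id)


@dataclass
class LabeledCandidate:
    """A signal mapped into the reference universe with a binary label."""

    record: SignalRecord
    label: int  # 1 positive (known DDI), 0 negative
    scores: dict[str, float] = field(default_factory=dict)  # per-measure M3 scores

    @property
    def pair(self) -> tuple[str, str]:
        return self.record.pair


def _normalize_id(drug_id: str, alias_map: Mapping[str, str] | None = None) -> str:
    key = drug_id.strip().casefold()
    if alias_map:
        key = alias_map.get(key, key)
    return key


def read_signal_table(path, skip_bad: bool = False) -> list[SignalRecord]:
    """Read a signal CSV/TSV with columns drug1, drug2, prr, p_value[, event].

    Malformed rows raise by default; with ``skip_bad`` they are skipped with
    a per-row error report in the log.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"drug1", "drug2", "prr", "p_value"}
    if not required.issubset(df.columns):
        raise SignalError(f"signal table {path} missing columns {sorted(required - set(df.columns))}")
    records: list[SignalRecord] = []
    n_bad = 0
    for i, row in df.iterrows():
        try:
            records.append(
                SignalRecord(
                    drug1_id=str(row["drug1"]),
                    drug2_id=str(row["drug2"]),
                    prr=float(row["prr"]),
                    p_value=float(row["p_value"]),
                    event=str(row["event"]) if "event" in df.columns and pd.notna(row.get("event")) else None,
                )
            )
        except (ValueError, TypeError) as e:
            n_bad += 1
            logger.error("signal table %s row %d: %s", path, i, e)
            if not skip_bad:
                raise SignalError(f"signal table {path} row {i}: {e}") from e
    if n_bad:
        logger.warning("signal table %s: skipped %d malformed row(s)", path, n_bad)
    return records


def filter_signals(
    records: Sequence[SignalRecord],
    prr_min: float = 1.0,
    p_max: float = 0.05,
    event: str | None = None,
) -> list[SignalRecord]:
    """Keep signals with PRR strictly above and p strictly below threshold.

    Order is preserved. An optional event string restricts to records whose
    event term matches case-insensitively (pass-through string match).
    """
    if prr_min <= 0 or p_max <= 0:
        raise SignalError("thresholds must be positive")
    out = [r for r in records if r.prr > prr_min and r.p_value < p_max]
    if event is not None:
        ev = event.strip().casefold()
        out = [r for r in out if r.event is not None and r.event.strip().casefold() == ev]
    if not records:
        logger.warning("filter_signals: empty input")
    logger.info("filter_signals: %d in, %d retained", len(records), len(out))
    return out


def label_candidates(
    records: Sequence[SignalRecord],
    ref: ReferenceStandard,
    alias_map: Mapping[str, str] | None = None,
) -> list[LabeledCandidate]:
    """Map signals into the reference universe and label against known DDIs.

    Only records whose BOTH drugs map into the universe are kept; a kept pair
    is positive iff it is a reference DDI. Duplicate unordered pairs keep the
    record with the highest PRR (logged as a collision). Unmapped records are
    counted and reported, never an error.
    """
    alias = {k.strip().casefold(): v.strip().casefold() for k, v in (alias_map or {}).items()}
    universe = {_normalize_id(d): d for d in ref.drug_ids}
    best: dict[tuple[str, str], SignalRecord] = {}
    n_unmapped = 0
    n_collisions = 0
    for r in records:
        a = universe.get(_normalize_id(r.drug1_id, alias))
        b = universe.get(_normalize_id(r.drug2_id, alias))
        if a is None or b is None:
            n_unmapped += 1
            continue
        mapped = replace(r, drug1_id=a, drug2_id=b)
        key = mapped.pair
        if key in best:
            n_collisions += 1
            logger.info("duplicate pair %s: keeping max-PRR record", key)
            if mapped.prr <= best[key].prr:
                continue
        best[key] = mapped
    if n_unmapped:
        logger.warning("label_candidates: %d record(s) outside the reference universe", n_unmapped)
    if n_collisions:
        logger.warning("label_candidates: %d duplicate-pair collision(s) resolved by max PRR", n_collisions)
    return [
        LabeledCandidate(record=r, label=int(r.pair in ref))
        for r in best.values()
    ]


def attach_scores(
    candidates: Sequence[LabeledCandidate], scorers: Mapping[str, "object"]
) -> list[LabeledCandidate]:
    """Attach per-measure candidate scores to each labeled signal.

    ``scorers`` maps measure tag to a fitted object exposing
    ``transform(pairs) -> array`` (a :class:`~ddisim.reference.MaxSimilarityScorer`
    or a :class:`~ddisim.reference.CandidateScores` via its ``get``).
    """
    pairs = [c.pair for c in candidates]
    for measure, scorer in scorers.items():
        if hasattr(scorer, "transform"):
            vals = scorer.transform(pairs)
        else:
            vals = [scorer.get(a, b) for a, b in pairs]
        for c, v in zip(candidates, vals):
            c.scores[measure] = float(v)
    return list(candidates)


# cumulative knowledge tiers, strongest documentation first
TIER_ORDER = ("well-established", "probable", "theoretical")


def relabel_external(
    candidates: Sequence[LabeledCandidate],
    tier_map: Mapping[tuple[str, str], str],
    level: str,
    tier_order: Sequence[str] = TIER_ORDER,
) -> list[LabeledCandidate]:
    """Relabel candidates against an external tiered label source.

    Positives are the pairs whose tier is at or above the requested
    cumulative ``level`` (e.g. level "theoretical" admits well-established,
    probable and theoretical; level "well-established" admits only that
    tier). Pairs absent from the label source are negative (counted in a
    warning). Returns new candidates; per-measure scores are carried over.
    """
    order = [t.strip().casefold() for t in tier_order]
    lvl = level.strip().casefold()
    if lvl not in order:
        raise SignalError(f"unknown knowledge level {level!r}; expected one of {order}")
    admitted = set(order[: order.index(lvl) + 1])
    tiers = {
        canonical_pair(a.strip().casefold(), b.strip().casefold()): v.strip().casefold()
        for (a, b), v in tier_map.items()
    }
    n_missing = 0
    out = []
    for c in candidates:
        tier = tiers.get(canonical_pair(c.pair[0].casefold(), c.pair[1].casefold()))
        if tier is None:
            n_missing += 1
        label = int(tier in admitted) if tier is not None else 0
        out.append(LabeledCandidate(record=c.record, label=label, scores=dict(c.scores)))
    if n_missing:
        logger.warning("relabel_external: %d pair(s) absent from label file -> negative", n_missing)
    n_pos = sum(c.label for c in out)
    logger.info("relabel_external level=%s: %d TP, %d FP", level, n_pos, len(out) - n_pos)
    return out


def read_tier_file(path) -> dict[tuple[str, str], str]:
    """Label file CSV with columns drug1, drug2, tier."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"drug1", "drug2", "tier"}
    if not required.issubset(df.columns):
        raise SignalError(f"label file {path} missing columns {sorted(required - set(df.columns))}")
    return {
        canonical_pair(str(r["drug1"]).strip().casefold(), str(r["drug2"]).strip().casefold()): str(r["tier"])
        for _, r in df.iterrows()
    }


def candidates_to_frame(candidates: Sequence[LabeledCandidate]) -> pd.DataFrame:
    """Tabular view: pair, PRR, p, label, one column per attached measure."""
    rows = []
    for c in candidates:
        row = {
            "drug1": c.pair[0],
            "drug2": c.pair[1],
            "prr": c.record.prr,
            "p_value": c.record.p_value,
            "label": c.label,
        }
        row.update(c.scores)
        rows.append(row)
    return pd.DataFrame(rows)
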