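"""End-to-end orchestration: fingerprints → similarity → candidate scoring
→ signal labeling → combination → evaluation, with a run manifest.

Every stage writes its intermediates in the package's text dialects so a run
is inspectable and bit-reproducible: re-running with the same config and
inputs produces identical CSV/TSV outputs and the same manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chem import build_domain_fingerprints
from .combine import CombinationError, LDACombiner, PCAScoreCombiner, build_score_table
from .evaluation import evaluate_ranking
from .io import read_alias_map, read_drug_table, read_pair_list
from .reference import build_reference, score_candidates
from .signals import (
    attach_scores,
    candidates_to_frame,
    filter_signals,
    label_candidates,
    read_signal_table,
)
from .similarity import build_similarity_matrix, load_external_similarity

logger = logging.getLogger(__name__)

FINGERPRINT_MEASURES = ("2D", "ADEPF", "TPF", "DDIPF", "ATC")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, measures and thresholds of one pipeline run."""

    drugs: str
    reference_pairs: str
    out_dir: str
    measures: list[str] = field(default_factory=lambda: ["ADEPF", "TPF", "DDIPF", "ATC"])
    external_matrices: dict[str, str] = field(default_factory=dict)  # measure -> TSV path
    signals: str | None = None
    alias_map: str | None = None
    prr_min: float = 1.0
    p_max: float = 0.05
    combine: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def validate(self) -> None:
        if not self.measures:
            raise PipelineError("config", "measure list must be nonempty")
        for p in [self.drugs, self.reference_pairs, self.signals, self.alias_map,
                  *self.external_matrices.values()]:
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"input path does not exist: {p}")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full ranking pipeline; returns the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("ddisim").addHandler(collector)
    try:
        return _run(cfg, out, collector)
    finally:
        logging.getLogger("ddisim").removeHandler(collector)


def _run(cfg: RunConfig, out: Path, collector: _WarningCollector) -> dict:
    # --- inputs ---------------------------------------------------------
    try:
        drugs = read_drug_table(cfg.drugs)
        drug_ids = [d.id for d in drugs]
        ref = build_reference(read_pair_list(cfg.reference_pairs), drug_ids)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError("inputs", str(e)) from e

    # --- similarity matrices (M2) --------------------------------------
    sims = {}
    for measure in cfg.measures:
        try:
            if measure in cfg.external_matrices:
                sims[measure] = load_external_similarity(
                    cfg.external_matrices[measure], drug_ids, measure=measure
                )
            elif measure in FINGERPRINT_MEASURES:
                fps = build_domain_fingerprints(drugs, measure)
                sims[measure] = build_similarity_matrix(fps, measure)
            else:
                raise ValueError(
                    f"measure {measure!r} needs an external matrix (no fingerprint domain)"
                )
            sims[measure].write_tsv(out / f"similarity_{measure}.tsv")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"similarity:{measure}", str(e)) from e

    # --- candidate scoring (M3) ----------------------------------------
    candidates_by_measure = {}
    for measure, sim in sims.items():
        try:
            cs = score_candidates(ref, sim)
            candidates_by_measure[measure] = cs
            cs.write_tsv(out / f"candidates_{measure}.tsv")
            cs.ranked_pairs(top=200).to_csv(
                out / f"ranked_{measure}.csv", index=False, float_format="%.6f"
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"scoring:{measure}", str(e)) from e

    manifest = {
        "tool": "ddisim",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_drugs": len(drug_ids),
        "n_reference_pairs": len(ref.pairs),
        "n_possible_pairs": ref.n_possible_pairs,
        "measures": list(sims),
    }

    # --- signals → labeled candidates ----------------------------------
    if cfg.signals is None:
        logger.info("no signal table given: scoring-only mode, evaluation skipped")
        manifest["mode"] = "scoring-only"
    else:
        try:
            records = read_signal_table(cfg.signals)
            kept = filter_signals(records, prr_min=cfg.prr_min, p_max=cfg.p_max)
            alias = read_alias_map(cfg.alias_map) if cfg.alias_map else None
            labeled = label_candidates(kept, ref, alias_map=alias)
            if not labeled:
                raise ValueError("no signal mapped into the reference universe")
            attach_scores(labeled, candidates_by_measure)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("signals", str(e)) from e

        table, labels = build_score_table(labeled, list(sims))
        frame = candidates_to_frame(labeled)

        rankings: dict[str, tuple[np.ndarray, str]] = {
            "PRR": (frame["prr"].to_numpy(), "higher_is_positive"),
            "p_value": (frame["p_value"].to_numpy(), "lower_is_positive"),
        }
        for measure in sims:
            rankings[measure] = (table[measure].to_numpy(), "higher_is_positive")

        if cfg.combine and len(sims) >= 2 and labels.sum() > 0:
            try:
                pca = PCAScoreCombiner().fit(table)
                frame["PCA"] = pca.transform(table)
                rankings["PCA"] = (frame["PCA"].to_numpy(), "higher_is_positive")
                try:
                    lda = LDACombiner(mode="stepwise").fit(table, labels)
                except CombinationError as e:
                    logger.warning("stepwise LDA: %s; falling back to forced mode", e)
                    lda = LDACombiner(mode="forced").fit(table, labels)
                frame["LDA"] = lda.decision_function(table)
                rankings["LDA"] = (frame["LDA"].to_numpy(), "higher_is_positive")
                with open(out / "models.json", "w") as fh:
                    json.dump({"pca": pca.to_dict(), "lda": lda.to_dict()}, fh, indent=2)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("combination", str(e)) from e

        frame.to_csv(out / "labeled_candidates.csv", index=False, float_format="%.6f")

        reports = {}
        if 0 < labels.sum() < len(labels):
            for method, (scores, direction) in rankings.items():
                try:
                    res = evaluate_ranking(scores, labels, method=method, direction=direction)
                    reports[method] = res.to_dict()
                    res.roc.to_csv(out / f"roc_{method}.csv", index=False, float_format="%.6f")
                except Exception as e:  # noqa: BLE001
                    raise PipelineError(f"evaluation:{method}", str(e)) from e
        else:
            logger.warning("single-class labels: evaluation skipped")
        with open(out / "evaluation.json", "w") as fh:
            json.dump(reports, fh, indent=2)
        manifest["mode"] = "full"
        manifest["n_candidates"] = len(labeled)
        manifest["n_positives"] = int(labels.sum())
        manifest["evaluation"] = {m: r.get("subset_auroc") for m, r in reports.items()}

    manifest["warnings"] = collector.messages
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
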