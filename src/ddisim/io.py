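"""File dialects: drug tables, reference pair lists, alias maps.

Drug table: TSV with columns id, name, smiles, ade_terms, target_ids,
partner_ids, atc_codes; multi-valued cells pipe-separated ("|"); an empty
cell is an empty set. A 2-column headerless ``id<TAB>smiles`` file is also
accepted for structure-only runs.
"""

from __future__ import annotations

import csv
from typing import Sequence

import pandas as pd

from .chem import Drug

DRUG_COLUMNS = ("id", "name", "smiles", "ade_terms", "target_ids", "partner_ids", "atc_codes")


def _split_multi(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return frozenset()
    return frozenset(t.strip() for t in str(cell).split("|") if t.strip())


def read_drug_table(path) -> list[Drug]:
    """Read a drug table TSV (or a 2-column headerless SMILES file)."""
    with open(path, newline="") as fh:
        first = fh.readline()
    if "\t" in first and not first.rstrip("\n").split("\t")[0] == "id":
        # headerless id<TAB>smiles
        drugs = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or not row[0].strip():
                    continue
                drugs.append(Drug(id=row[0].strip(), name=row[0].strip(),
                                  smiles=row[1].strip() if len(row) > 1 and row[1].strip() else None))
        return drugs
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("id",) if c not in df.columns]
    if missing:
        raise ValueError(f"drug table {path} missing columns {missing}")
    drugs = []
    for _, r in df.iterrows():
        smiles = r.get("smiles")
        drugs.append(
            Drug(
                id=str(r["id"]).strip(),
                name=str(r.get("name", r["id"])).strip(),
                smiles=None if pd.isna(smiles) or not str(smiles).strip() else str(smiles).strip(),
                ade_terms=_split_multi(r.get("ade_terms")),
                target_ids=_split_multi(r.get("target_ids")),
                partner_ids=_split_multi(r.get("partner_ids")),
                atc_codes=_split_multi(r.get("atc_codes")),
            )
        )
    ids = [d.id for d in drugs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"drug table {path}: duplicate ids {dupes}")
    return drugs


def write_drug_table(drugs: Sequence[Drug], path) -> None:
    rows = []
    for d in drugs:
        rows.append(
            {
                "id": d.id,
                "name": d.name,
                "smiles": d.smiles or "",
                "ade_terms": "|".join(sorted(d.ade_terms)),
                "target_ids": "|".join(sorted(d.target_ids)),
                "partner_ids": "|".join(sorted(d.partner_ids)),
                "atc_codes": "|".join(sorted(d.atc_codes)),
            }
        )
    pd.DataFrame(rows, columns=list(DRUG_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_pair_list(path) -> list[tuple[str, str]]:
    """2-column CSV/TSV of drug-id pairs (header optional)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pairs = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter=sep)):
            if not row or len(row) < 2:
                continue
            a, b = row[0].strip(), row[1].strip()
            if i == 0 and {a.casefold(), b.casefold()} & {"drug1", "drug2", "id1", "id2"}:
                continue  # header
            if a and b:
                pairs.append((a, b))
    return pairs


def write_pair_list(pairs, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["drug1", "drug2"])
        for a, b in pairs:
            w.writerow([a, b])


def read_alias_map(path) -> dict[str, str]:
    """2-column CSV alias → canonical id (case-insensitive keys)."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if len(row) >= 2 and row[0].strip():
                out[row[0].strip().casefold()] = row[1].strip().casefold()
    return out
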