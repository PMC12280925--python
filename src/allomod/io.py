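"""Readers and writers for the package's plain-text dialects.

Assay tables are CSV with explicit unit columns (concentrations declared as
M/mM/uM/nM/pM and converted to molar at the boundary); docking scores and
pose contacts are TSV; molecules travel as ``.smi`` (SMILES<TAB>id); fit
results and reports serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from allomod.datatypes import (
    FitResult,
    FunctionalDataset,
    InteractionBindingDataset,
    MoleculeRecord,
    PoseContacts,
    RankedLibrary,
    SnapshotScores,
)
from allomod.triage import compute_properties, morgan_fingerprint

__all__ = [
    "UNIT_FACTORS",
    "to_molar",
    "read_binding_csv",
    "write_binding_csv",
    "read_functional_csv",
    "write_functional_csv",
    "read_scores_tsv",
    "write_scores_tsv",
    "read_smiles",
    "write_smiles",
    "read_contacts_tsv",
    "write_contacts_tsv",
    "fit_result_to_dict",
    "write_json",
]

UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def to_molar(values, unit: str) -> np.ndarray:
    """Convert concentrations in a declared unit to molar."""

    if unit not in UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}; use one of {list(UNIT_FACTORS)}")
    return np.asarray(values, dtype=float) * UNIT_FACTORS[unit]


def read_binding_csv(path) -> list[InteractionBindingDataset]:
    """Interaction-binding CSV -> one dataset per replicate.

    Columns: replicate, agonist_conc, modulator_conc, response, unit,
    radioligand_conc (radioligand in the same declared unit).
    """

    frame = pd.read_csv(path)
    required = {"replicate", "agonist_conc", "modulator_conc", "response", "unit", "radioligand_conc"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"binding CSV missing columns: {sorted(missing)}")
    out = []
    for rep, grp in frame.groupby("replicate", sort=True):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise ValueError(f"replicate {rep}: mixed units {list(units)}")
        unit = units[0]
        radio = np.unique(to_molar(grp["radioligand_conc"], unit))
        if len(radio) != 1:
            raise ValueError(f"replicate {rep}: radioligand concentration must be constant")
        out.append(
            InteractionBindingDataset(
                radioligand_conc=float(radio[0]),
                agonist_conc=to_molar(grp["agonist_conc"], unit),
                modulator_conc=to_molar(grp["modulator_conc"], unit),
                specific_binding=grp["response"].to_numpy(dtype=float),
                replicate_id=str(rep),
            )
        )
    return out


def write_binding_csv(datasets: Sequence[InteractionBindingDataset], path) -> None:
    rows = []
    for d in datasets:
        for a, b, y in zip(d.agonist_conc, d.modulator_conc, d.specific_binding):
            rows.append(
                {
                    "replicate": d.replicate_id,
                    "agonist_conc": a,
                    "modulator_conc": b,
                    "response": y,
                    "unit": "M",
                    "radioligand_conc": d.radioligand_conc,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_functional_csv(path) -> list[FunctionalDataset]:
    """Functional CSV (replicate, agonist_conc, modulator_conc, response, unit)."""

    frame = pd.read_csv(path)
    required = {"replicate", "agonist_conc", "modulator_conc", "response", "unit"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"functional CSV missing columns: {sorted(missing)}")
    out = []
    for rep, grp in frame.groupby("replicate", sort=True):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise ValueError(f"replicate {rep}: mixed units {list(units)}")
        out.append(
            FunctionalDataset(
                agonist_conc=to_molar(grp["agonist_conc"], units[0]),
                modulator_conc=to_molar(grp["modulator_conc"], units[0]),
                response=grp["response"].to_numpy(dtype=float),
                replicate_id=str(rep),
            )
        )
    return out


def write_functional_csv(datasets: Sequence[FunctionalDataset], path) -> None:
    rows = []
    for d in datasets:
        for a, b, y in zip(d.agonist_conc, d.modulator_conc, d.response):
            rows.append(
                {
                    "replicate": d.replicate_id,
                    "agonist_conc": a,
                    "modulator_conc": b,
                    "response": y,
                    "unit": "M",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scores_tsv(scores_path, labels_path) -> SnapshotScores:
    """Long-format score TSV (molecule_id, snapshot_id, score) + label TSV."""

    long = pd.read_csv(scores_path, sep="\t")
    required = {"molecule_id", "snapshot_id", "score"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"score TSV missing columns: {sorted(missing)}")
    labels = pd.read_csv(labels_path, sep="\t")
    if {"molecule_id", "label"} - set(labels.columns):
        raise ValueError("label TSV needs molecule_id and label columns")
    matrix = long.pivot(index="molecule_id", columns="snapshot_id", values="score")
    label_series = labels.set_index("molecule_id")["label"].reindex(matrix.index)
    return SnapshotScores(scores=matrix, labels=label_series)


def write_scores_tsv(scores: SnapshotScores, scores_path, labels_path) -> None:
    long = (
        scores.scores.stack(future_stack=True)
        .rename("score")
        .dropna()
        .reset_index()
        .rename(columns={"level_1": "snapshot_id"})
    )
    long.to_csv(scores_path, sep="\t", index=False)
    scores.labels.rename("label").reset_index().to_csv(labels_path, sep="\t", index=False)


def read_smiles(path, compute: bool = True) -> list[MoleculeRecord]:
    """``.smi`` file (SMILES<TAB>molecule_id), optionally deriving properties."""

    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed .smi line: {line!r}")
        smiles, mol_id = parts[0], parts[1]
        rec = MoleculeRecord(molecule_id=mol_id, smiles=smiles)
        if compute:
            rec.properties = compute_properties(smiles)
            rec.fingerprint = morgan_fingerprint(smiles)
        out.append(rec)
    return out


def write_smiles(molecules: Sequence[MoleculeRecord], path) -> None:
    Path(path).write_text(
        "".join(f"{m.smiles}\t{m.molecule_id}\n" for m in molecules)
    )


def read_contacts_tsv(path) -> list[PoseContacts]:
    """Pose-contact TSV (molecule_id, snapshot_id, site_label, distance, angle)."""

    frame = pd.read_csv(path, sep="\t")
    required = {"molecule_id", "snapshot_id", "site_label", "distance", "angle"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"contacts TSV missing columns: {sorted(missing)}")
    out = []
    for (mol_id, snap), grp in frame.groupby(["molecule_id", "snapshot_id"], sort=True):
        out.append(
            PoseContacts(
                molecule_id=str(mol_id),
                snapshot_id=str(snap),
                contacts=grp[["site_label", "distance", "angle"]].reset_index(drop=True),
            )
        )
    return out


def write_contacts_tsv(poses: Sequence[PoseContacts], path) -> None:
    rows = []
    for p in poses:
        for _, row in p.contacts.iterrows():
            rows.append(
                {
                    "molecule_id": p.molecule_id,
                    "snapshot_id": p.snapshot_id,
                    "site_label": row["site_label"],
                    "distance": row["distance"],
                    "angle": row["angle"],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fit_result_to_dict(result: FitResult) -> dict:
    """JSON-ready view of a fit: parameters, SEs, RSS, convergence."""

    params = result.params.as_dict() if hasattr(result.params, "as_dict") else None
    return {
        "params": params,
        "standard_errors": {k: float(v) for k, v in result.standard_errors.items()},
        "residual_sum_squares": float(result.residual_sum_squares),
        "converged": bool(result.converged),
        "n_points": int(result.n_points),
        "fixed_params": list(result.fixed_params),
        "reason": result.reason,
    }


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
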