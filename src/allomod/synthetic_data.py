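"""Seeded generators for every input the analysis consumes.

Each generator is a pure function of (spec, seed): interaction-binding and
functional concentration-response families drawn from the ATCM and
operational models with proportional Gaussian noise, replicate-level screen
tables, correlated docking-score libraries with separable active/decoy
distributions, and template-generated molecule tables with pose-contact
records. Defaults mirror the study's assay designs (agonist ladders, 0/3/10/
30 µM modulator, ~1 nM radioligand, n = 4, 5% CV).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from allomod.datatypes import (
    ATCMParams,
    FunctionalDataset,
    InteractionBindingDataset,
    MoleculeRecord,
    OperationalParams,
    PoseContacts,
    ScoreLibrarySpec,
    SimulationDesign,
    SnapshotScores,
)
from allomod.pharm_models import predict_atcm, predict_operational
from allomod.triage import compute_properties, morgan_fingerprint

__all__ = [
    "gen_interaction_binding",
    "gen_functional",
    "gen_screen",
    "gen_score_library",
    "gen_molecule_table",
]


def _add_noise(pred: np.ndarray, design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    y = pred * (1.0 + rng.normal(0.0, design.noise_cv, size=pred.shape))
    if design.additive_sd > 0:
        y = y + rng.normal(0.0, design.additive_sd, size=pred.shape)
    return y


def gen_interaction_binding(
    truth: ATCMParams, design: SimulationDesign
) -> list[InteractionBindingDataset]:
    """Replicate interaction-binding experiments drawn from the ATCM.

    Y = predict_atcm(...) * (1 + ε), ε ~ N(0, noise_cv) independent per point;
    one dataset per replicate, deterministically from ``design.seed``.
    """

    rng = np.random.default_rng(design.seed)
    agonist, modulator = design.grid()
    pred = predict_atcm(truth, design.radioligand_conc, agonist, modulator)
    out = []
    for r in range(design.n_replicates):
        out.append(
            InteractionBindingDataset(
                radioligand_conc=design.radioligand_conc,
                agonist_conc=agonist.copy(),
                modulator_conc=modulator.copy(),
                specific_binding=_add_noise(pred, design, rng),
                replicate_id=f"r{r + 1}",
            )
        )
    return out


def gen_functional(
    truth: OperationalParams, design: SimulationDesign
) -> list[FunctionalDataset]:
    """Replicate functional (cAMP) experiments drawn from the operational model."""

    rng = np.random.default_rng(design.seed)
    agonist, modulator = design.grid()
    pred = predict_operational(truth, agonist, modulator)
    out = []
    for r in range(design.n_replicates):
        out.append(
            FunctionalDataset(
                agonist_conc=agonist.copy(),
                modulator_conc=modulator.copy(),
                response=_add_noise(pred, design, rng),
                replicate_id=f"r{r + 1}",
            )
        )
    return out


def gen_screen(
    truth_map: Mapping[str, tuple[float, float]],
    n_compounds: int = 26,
    n_replicates: int = 4,
    control_pKI: float = 6.5,
    control_pEC50: float = 7.5,
    replicate_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-level control/treated tables for a modulator screen.

    ``truth_map`` assigns (ΔpK_I, ΔpEC50) effects to compound ids; compounds
    absent from the map are nulls. Control and treated pK values carry
    independent Normal(0, ``replicate_sd``) replicate noise. Returns
    (control, treated) frames with columns compound_id, replicate, pKI, pEC50.
    """

    rng = np.random.default_rng(seed)
    compound_ids = [f"C{i + 1:02d}" for i in range(n_compounds)]
    unknown = set(truth_map) - set(compound_ids)
    if unknown:
        raise ValueError(f"truth_map refers to unknown compounds: {sorted(unknown)}")
    ctrl_rows, trt_rows = [], []
    for cid in compound_ids:
        d_pki, d_pec = truth_map.get(cid, (0.0, 0.0))
        if not (np.isfinite(d_pki) and np.isfinite(d_pec)):
            raise ValueError(f"effects for {cid} must be finite")
        for r in range(n_replicates):
            rep = f"r{r + 1}"
            ctrl_rows.append(
                {
                    "compound_id": cid,
                    "replicate": rep,
                    "pKI": control_pKI + rng.normal(0, replicate_sd),
                    "pEC50": control_pEC50 + rng.normal(0, replicate_sd),
                }
            )
            trt_rows.append(
                {
                    "compound_id": cid,
                    "replicate": rep,
                    "pKI": control_pKI + d_pki + rng.normal(0, replicate_sd),
                    "pEC50": control_pEC50 + d_pec + rng.normal(0, replicate_sd),
                }
            )
    return pd.DataFrame(ctrl_rows), pd.DataFrame(trt_rows)


def gen_score_library(spec: ScoreLibrarySpec) -> SnapshotScores:
    """Correlated Gaussian docking scores with actives shifted to better energies.

    score(molecule m, snapshot s) = loc + shift·[m active]
        + scale·(sqrt(ρ)·z_m + sqrt(1−ρ)·e_ms)

    with z and e standard normal, so any two snapshots correlate at ρ for the
    same molecule. Entries are masked missing at ``missing_rate``.
    """

    rng = np.random.default_rng(spec.seed)
    n = spec.n_actives + spec.n_decoys
    ids = [f"A{i:04d}" for i in range(spec.n_actives)] + [
        f"D{i:05d}" for i in range(spec.n_decoys)
    ]
    labels = ["active"] * spec.n_actives + ["decoy"] * spec.n_decoys
    z = rng.normal(size=(n, 1))
    e = rng.normal(size=(n, spec.n_snapshots))
    rho = spec.snapshot_correlation
    noise = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * e
    shift = np.where(np.array(labels) == "active", spec.active_shift, 0.0)[:, None]
    scores = spec.score_loc + shift + spec.score_scale * noise
    if spec.missing_rate > 0:
        mask = rng.random(size=scores.shape) < spec.missing_rate
        scores = np.where(mask, np.nan, scores)
    frame = pd.DataFrame(
        scores,
        index=pd.Index(ids, name="molecule_id"),
        columns=[f"snap{j:03d}" for j in range(spec.n_snapshots)],
    )
    return SnapshotScores(scores=frame, labels=pd.Series(labels, index=frame.index))


# ---------------------------------------------------------------------------
# Molecule tables and pose contacts

# scaffold templates: alkyl chains of varying length decorate each core so the
# library spans the fragment and lead-like MW/LogP windows
_SCAFFOLDS = (
    "{chain}c1csc(N)n1",  # 2-aminothiazole
    "{chain}c1ccc2ccccc2c1",  # naphthalene
    "{chain}c1ccc(-c2csc(N)n2)cc1",  # aryl 2-aminothiazole
    "{chain}c1ccc(Cl)cc1",  # chloroarene
    "{chain}c1ccc(C(=O)c2csc(N)n2)cc1",  # aroyl thiazole
)


def gen_molecule_table(
    n: int,
    seed: int = 0,
    scaffolds: Sequence[str] = _SCAFFOLDS,
    max_chain: int = 8,
    hbond_prob: float = 0.5,
    score_loc: float = -25.0,
    score_scale: float = 5.0,
) -> tuple[list[MoleculeRecord], list[PoseContacts]]:
    """Template-generated molecules with properties, fingerprints, and poses.

    SMILES are drawn from alkylated scaffold templates; properties are
    computed from structure with rdkit; dock scores are Gaussian. Each
    molecule receives a best-pose contact record that satisfies the
    S246/L276 hydrogen-bond predicate with probability ``hbond_prob``
    (in-range geometry at both sites), otherwise one site is missing or
    out of geometric range.
    """

    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= hbond_prob <= 1.0:
        raise ValueError("hbond_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    molecules: list[MoleculeRecord] = []
    poses: list[PoseContacts] = []
    for i in range(n):
        mol_id = f"M{i:05d}"
        template = scaffolds[int(rng.integers(len(scaffolds)))]
        chain = "C" * int(rng.integers(0, max_chain + 1))
        smiles = template.format(chain=chain)
        molecules.append(
            MoleculeRecord(
                molecule_id=mol_id,
                smiles=smiles,
                properties=compute_properties(smiles),
                fingerprint=morgan_fingerprint(smiles),
                dock_score=float(rng.normal(score_loc, score_scale)),
            )
        )
        poses.append(_gen_pose(mol_id, rng, hbond_prob))
    return molecules, poses


def _gen_pose(mol_id: str, rng: np.random.Generator, hbond_prob: float) -> PoseContacts:
    rows = []
    satisfied = rng.random() < hbond_prob
    for site in ("S246_sidechain", "L276_backbone"):
        if satisfied:
            rows.append((site, rng.uniform(2.6, 3.4), rng.uniform(130.0, 175.0)))
        else:
            mode = rng.integers(3)
            if mode == 0:
                continue  # contact absent
            elif mode == 1:
                rows.append((site, rng.uniform(3.8, 6.0), rng.uniform(130.0, 175.0)))
            else:
                rows.append((site, rng.uniform(2.6, 3.4), rng.uniform(60.0, 110.0)))
    # incidental contacts elsewhere
    for _ in range(int(rng.integers(0, 3))):
        rows.append(("other", rng.uniform(2.5, 6.0), rng.uniform(60.0, 175.0)))
    contacts = pd.DataFrame(rows, columns=["site_label", "distance", "angle"])
    return PoseContacts(
        molecule_id=mol_id, snapshot_id=f"snap{int(rng.integers(5)):03d}", contacts=contacts
    )
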