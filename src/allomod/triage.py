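"""The docking-screen triage funnel.

After a large prospective docking screen, candidate PAMs are whittled down in
deterministic stages: partition by molecular-weight/LogP library windows, a
top-fraction rank cut, a hydrogen-bond pose filter against the two anchor
residues of the extrahelical site (S246 side chain, L276 backbone carbonyl),
greedy Tanimoto leader clustering with best-score representatives, and
substructure/similarity analog searches. Every stage returns a subset of its
input; ties are always broken by (score, molecule_id) so runs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

from allomod.datatypes import (
    Cluster,
    MoleculeRecord,
    PoseContacts,
    PropertyVector,
    RankedLibrary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "morgan_fingerprint",
    "compute_properties",
    "partition_library",
    "top_fraction",
    "hbond_filter",
    "tanimoto",
    "leader_cluster",
    "select_representatives",
    "analog_search",
]

#: fragment / lead-like window edges (Da) and shared LogP window
FRAGMENT_MW_MAX = 250.0
LEAD_MW_MAX = 350.0
LOGP_WINDOW = (2.5, 4.5)

FP_RADIUS = 2
FP_NBITS = 2048

_FP_GENERATORS: dict[tuple[int, int], object] = {}


def morgan_fingerprint(smiles_or_mol, radius: int = FP_RADIUS, n_bits: int = FP_NBITS) -> np.ndarray:
    """Radius-2 circular (ECFP4-like) fingerprint as a boolean bit vector."""

    mol = (
        Chem.MolFromSmiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles_or_mol!r}")
    key = (radius, n_bits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_GENERATORS[key].GetFingerprintAsNumPy(mol).astype(bool)


def compute_properties(smiles: str) -> PropertyVector:
    """Physicochemical properties from structure (Crippen cLogP)."""

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        charge=Chem.GetFormalCharge(mol),
        rotatable=rdMolDescriptors.CalcNumRotatableBonds(mol),
    )


def partition_library(
    molecules: Sequence[MoleculeRecord],
) -> dict[str, list[MoleculeRecord]]:
    """Split a library into fragment / lead-like / excluded bins.

    Fragment: MW < 250 Da; lead-like: 250 <= MW < 350 Da (the 250 Da boundary
    goes to lead-like); both require 2.5 <= LogP <= 4.5 inclusive. Molecules
    with missing properties are excluded.
    """

    out: dict[str, list[MoleculeRecord]] = {"fragment": [], "lead_like": [], "excluded": []}
    for mol in molecules:
        props = mol.properties
        if props is None:
            out["excluded"].append(mol)
            continue
        in_logp = LOGP_WINDOW[0] <= props.clogp <= LOGP_WINDOW[1]
        if in_logp and props.mw < FRAGMENT_MW_MAX:
            out["fragment"].append(mol)
        elif in_logp and FRAGMENT_MW_MAX <= props.mw < LEAD_MW_MAX:
            out["lead_like"].append(mol)
        else:
            out["excluded"].append(mol)
    return out


def top_fraction(library: RankedLibrary, fraction: float = 0.005) -> RankedLibrary:
    """The best-scoring ceil(fraction * N) molecules of a ranked library.

    Ties at the cut are admitted in molecule-id order up to the count;
    molecules with missing scores do not compete.
    """

    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    frame = library.frame.dropna(subset=["score"])
    if frame.empty:
        raise ValueError("empty library")
    n = int(np.ceil(fraction * len(frame)))
    ordered = frame.sort_values(["score", "molecule_id"], kind="mergesort")
    return RankedLibrary(frame=ordered.head(n).reset_index(drop=True))


def hbond_filter(
    poses: Iterable[PoseContacts],
    required: Sequence[str] = ("S246_sidechain", "L276_backbone"),
    dmax: float = 3.5,
    amin: float = 120.0,
) -> list[str]:
    """Molecules whose best pose hydrogen-bonds to every required site.

    A site counts as satisfied when at least one contact at that site has
    donor-acceptor heavy-atom distance <= ``dmax`` (Å) and donor-H···acceptor
    angle >= ``amin`` (degrees). Returns retained molecule ids, sorted.
    """

    retained = []
    seen = set()
    for pose in poses:
        if pose.molecule_id in seen:
            raise ValueError(f"duplicate pose record for {pose.molecule_id}")
        seen.add(pose.molecule_id)
        c = pose.contacts
        ok = all(
            (
                (c["site_label"] == site)
                & (c["distance"] <= dmax)
                & (c["angle"] >= amin)
            ).any()
            for site in required
        )
        if ok:
            retained.append(pose.molecule_id)
    return sorted(retained)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two equal-length bit sets.

    Two empty fingerprints are defined as similarity 0.
    """

    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def leader_cluster(
    molecules: Sequence[MoleculeRecord], threshold: float = 0.5
) -> list[Cluster]:
    """Greedy leader clustering of scored, fingerprinted molecules.

    The best-scoring unassigned molecule founds a cluster and absorbs every
    unassigned molecule with Tanimoto >= ``threshold`` to it; clusters are
    emitted in founding order, so representatives are pairwise below the
    threshold.
    """

    for m in molecules:
        if m.fingerprint is None or m.dock_score is None:
            raise ValueError(f"molecule {m.molecule_id}: fingerprint and dock_score required")
    ordered = sorted(molecules, key=lambda m: (m.dock_score, m.molecule_id))
    assigned = np.zeros(len(ordered), dtype=bool)
    clusters: list[Cluster] = []
    for i, leader in enumerate(ordered):
        if assigned[i]:
            continue
        members = [leader.molecule_id]
        assigned[i] = True
        for j in range(i + 1, len(ordered)):
            if assigned[j]:
                continue
            if tanimoto(leader.fingerprint, ordered[j].fingerprint) >= threshold:
                members.append(ordered[j].molecule_id)
                assigned[j] = True
        clusters.append(
            Cluster(
                representative_id=leader.molecule_id,
                member_ids=tuple(members),
                representative_score=float(leader.dock_score),
            )
        )
    return clusters


def select_representatives(
    clusters: Sequence[Cluster],
    molecules: Sequence[MoleculeRecord],
    max_clusters: int = 1000,
) -> list[MoleculeRecord]:
    """Best-scoring representative of each of the first ``max_clusters`` clusters."""

    by_id: Mapping[str, MoleculeRecord] = {m.molecule_id: m for m in molecules}
    return [by_id[c.representative_id] for c in clusters[:max_clusters]]


def analog_search(
    query: MoleculeRecord,
    library: Sequence[MoleculeRecord],
    mode: str = "both",
    tc_min: float = 0.5,
) -> list[MoleculeRecord]:
    """Substructure and/or fingerprint-similarity analogs of a query.

    ``substructure`` returns library members containing the query as a
    substructure; ``similarity`` returns members with Tanimoto >= ``tc_min``
    to the query fingerprint; ``both`` is the union, deduplicated by id and
    returned in id order.
    """

    if mode not in ("substructure", "similarity", "both"):
        raise ValueError(f"unknown mode: {mode!r}")
    query_mol = Chem.MolFromSmiles(query.smiles)
    if query_mol is None:
        raise ValueError(f"unparseable query SMILES: {query.smiles!r}")
    query_fp = (
        query.fingerprint if query.fingerprint is not None else morgan_fingerprint(query_mol)
    )

    hits: dict[str, MoleculeRecord] = {}
    for rec in library:
        if mode in ("substructure", "both"):
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is not None and mol.HasSubstructMatch(query_mol):
                hits[rec.molecule_id] = rec
                continue
        if mode in ("similarity", "both"):
            fp = rec.fingerprint if rec.fingerprint is not None else morgan_fingerprint(rec.smiles)
            if tanimoto(query_fp, fp) >= tc_min:
                hits[rec.molecule_id] = rec
    return [hits[k] for k in sorted(hits)]
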