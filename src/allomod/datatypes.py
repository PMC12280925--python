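"""Domain containers for assay data, model parameters, and screen artifacts.

Concentrations are molar everywhere inside the package; file readers convert
from declared nM/µM units at the boundary (:mod:`allomod.io`). Equilibrium
constants and cooperativities are stored in log10 space (pK, logα, logτ)
because that is the scale on which they are estimated and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionBindingDataset",
    "InteractionBindingDataset",
    "FunctionalDataset",
    "ATCMParams",
    "OperationalParams",
    "HillParams",
    "OneSiteFit",
    "FitResult",
    "RankedLibrary",
    "SnapshotScores",
    "ROCResult",
    "PropertyVector",
    "MoleculeRecord",
    "PoseContacts",
    "Cluster",
    "SimulationDesign",
    "ScoreLibrarySpec",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class CompetitionBindingDataset:
    """Radioligand displacement curve: specific binding vs competitor concentration.

    ``radioligand_conc`` is the fixed tracer concentration [A] (molar);
    ``competitor_concs`` the competitor grid (molar, zeros allowed);
    ``specific_binding`` in % of control (or counts).
    """

    radioligand_conc: float
    competitor_concs: np.ndarray
    specific_binding: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.radioligand_conc <= 0:
            raise ValueError("radioligand_conc must be positive")
        self.competitor_concs = _as_1d(self.competitor_concs, "competitor_concs")
        self.specific_binding = _as_1d(self.specific_binding, "specific_binding")
        if np.any(self.competitor_concs < 0):
            raise ValueError("competitor_concs must be nonnegative")
        if len(self.competitor_concs) != len(self.specific_binding):
            raise ValueError("competitor and binding vectors differ in length")
        if len(np.unique(self.competitor_concs)) < 4:
            raise ValueError("need >= 4 distinct competitor concentrations")


@dataclass
class InteractionBindingDataset:
    """Interaction binding: tracer displacement over an (agonist x modulator) grid.

    One experiment at fixed radioligand concentration [A]; ``agonist_conc`` is
    the orthosteric agonist [I], ``modulator_conc`` the allosteric ligand [B],
    ``specific_binding`` Y in % of control.
    """

    radioligand_conc: float
    agonist_conc: np.ndarray
    modulator_conc: np.ndarray
    specific_binding: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.radioligand_conc <= 0:
            raise ValueError("radioligand_conc must be positive")
        self.agonist_conc = _as_1d(self.agonist_conc, "agonist_conc")
        self.modulator_conc = _as_1d(self.modulator_conc, "modulator_conc")
        self.specific_binding = _as_1d(self.specific_binding, "specific_binding")
        n = len(self.agonist_conc)
        if len(self.modulator_conc) != n or len(self.specific_binding) != n:
            raise ValueError("agonist, modulator and binding vectors differ in length")
        if np.any(self.agonist_conc < 0) or np.any(self.modulator_conc < 0):
            raise ValueError("concentrations must be nonnegative")
        if not np.any(self.modulator_conc == 0):
            raise ValueError("interaction data must include modulator-free (B = 0) controls")
        for b in np.unique(self.modulator_conc):
            if not np.any((self.modulator_conc == b) & (self.agonist_conc == 0)):
                raise ValueError(
                    f"missing agonist-free (I = 0) control at modulator {b:g} M"
                )


@dataclass
class FunctionalDataset:
    """Normalized cAMP responses over an (agonist x modulator) grid.

    Responses are on the forskolin-anchored % scale (0 = full forskolin
    response, 100 = buffer; agonist inhibition raises the value toward 100
    after re-expression as % inhibition).
    """

    agonist_conc: np.ndarray
    modulator_conc: np.ndarray
    response: np.ndarray
    replicate_id: str = "r1"
    forskolin_ref: float | None = None
    buffer_ref: float | None = None

    def __post_init__(self) -> None:
        self.agonist_conc = _as_1d(self.agonist_conc, "agonist_conc")
        self.modulator_conc = _as_1d(self.modulator_conc, "modulator_conc")
        self.response = _as_1d(self.response, "response")
        n = len(self.agonist_conc)
        if len(self.modulator_conc) != n or len(self.response) != n:
            raise ValueError("agonist, modulator and response vectors differ in length")
        if np.any(self.agonist_conc < 0) or np.any(self.modulator_conc < 0):
            raise ValueError("concentrations must be nonnegative")
        if not np.any(self.modulator_conc == 0):
            raise ValueError("functional data must include a modulator-free (B = 0) curve")


@dataclass
class ATCMParams:
    """Allosteric ternary complex model parameters.

    ``pKA``/``pKB``/``pKI``: -log10 molar dissociation constants of the
    radioligand (A), allosteric ligand (B) and orthosteric agonist (I).
    ``log_alpha_A``/``log_alpha_I``: log10 binding cooperativities of the
    modulator with the radioligand and the agonist. ``bmax``: maximal
    specific binding (response units).
    """

    bmax: float
    pKA: float
    pKB: float
    pKI: float
    log_alpha_A: float
    log_alpha_I: float

    def __post_init__(self) -> None:
        for name in ("bmax", "pKA", "pKB", "pKI", "log_alpha_A", "log_alpha_I"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_dict(self) -> dict[str, float]:
        return {
            "bmax": self.bmax,
            "pKA": self.pKA,
            "pKB": self.pKB,
            "pKI": self.pKI,
            "log_alpha_A": self.log_alpha_A,
            "log_alpha_I": self.log_alpha_I,
        }


@dataclass
class OperationalParams:
    """Operational model of allosterism parameters.

    ``em``: system maximal response; ``log_tau_A``/``log_tau_B``: log10
    operational efficacies of agonist and modulator; ``log_alpha`` binding
    cooperativity, ``log_beta`` efficacy modulation; ``n`` transducer slope.
    The reported composite is ``log_alphabeta = log_alpha + log_beta``.
    """

    em: float
    pKA: float
    pKB: float
    log_tau_A: float
    log_tau_B: float
    log_alpha: float
    log_beta: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.em <= 0:
            raise ValueError("em must be positive")
        if self.n <= 0:
            raise ValueError("transducer slope n must be positive")
        for name in ("pKA", "pKB", "log_tau_A", "log_tau_B", "log_alpha", "log_beta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def log_alphabeta(self) -> float:
        return self.log_alpha + self.log_beta

    def as_dict(self) -> dict[str, float]:
        return {
            "em": self.em,
            "pKA": self.pKA,
            "pKB": self.pKB,
            "log_tau_A": self.log_tau_A,
            "log_tau_B": self.log_tau_B,
            "log_alpha": self.log_alpha,
            "log_beta": self.log_beta,
            "n": self.n,
            "log_alphabeta": self.log_alphabeta,
        }


@dataclass
class HillParams:
    """Three-parameter Hill curve: basal, emax, pEC50 (slope fixed at 1)."""

    basal: float
    emax: float
    pEC50: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pEC50):
            raise ValueError("pEC50 must be finite")


@dataclass
class OneSiteFit:
    """One-site inhibitory mass-action curve: top, bottom, log10 IC50 (molar)."""

    top: float
    bottom: float
    log_ic50: float

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")
        if not np.isfinite(self.log_ic50):
            raise ValueError("log_ic50 must be finite")

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``standard_errors`` covers free parameters only; ``fixed_params`` names
    those held constant. Degenerate fits carry ``converged=False`` with a
    ``reason`` code instead of raising.
    """

    params: object
    standard_errors: dict[str, float]
    residual_sum_squares: float
    converged: bool
    n_points: int
    fixed_params: tuple[str, ...] = ()
    reason: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.standard_errors) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"standard errors reported for fixed parameters: {overlap}")


# ---------------------------------------------------------------------------
# Screening / docking containers


@dataclass
class RankedLibrary:
    """Scored molecule library for enrichment. Lower score = better energy."""

    frame: pd.DataFrame  # columns: molecule_id, score, label

    VALID_LABELS = frozenset({"active", "decoy", "inactive", "unknown"})

    def __post_init__(self) -> None:
        required = {"molecule_id", "score", "label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"RankedLibrary missing columns: {sorted(missing)}")
        bad = set(self.frame["label"]) - self.VALID_LABELS
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.frame["molecule_id"].duplicated().any():
            raise ValueError("duplicate molecule ids")

    @property
    def n_actives(self) -> int:
        return int((self.frame["label"] == "active").sum())

    @property
    def n_negatives(self) -> int:
        return int(self.frame["label"].isin(["decoy", "inactive"]).sum())


@dataclass
class SnapshotScores:
    """Docking scores indexed (molecule x snapshot); NaN marks failed docking."""

    scores: pd.DataFrame  # index molecule_id, columns snapshot_id
    labels: pd.Series  # index molecule_id -> label

    def __post_init__(self) -> None:
        if self.scores.shape[1] < 1:
            raise ValueError("need at least one snapshot")
        self.labels = self.labels.reindex(self.scores.index)
        bad = set(self.labels.dropna()) - RankedLibrary.VALID_LABELS
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")


@dataclass
class ROCResult:
    """Stepwise ROC curve with AUC and adjusted logAUC (percent)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    adjusted_logauc: float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        self.fpr = _as_1d(self.fpr, "fpr")
        self.tpr = _as_1d(self.tpr, "tpr")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC points must be nondecreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC must run from (0,0) to (1,1)")


@dataclass(frozen=True)
class PropertyVector:
    """Physicochemical profile used for property-matched decoy selection."""

    mw: float
    clogp: float
    hbd: int
    hba: int
    charge: int
    rotatable: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("MW must be positive")
        for name in ("hbd", "hba", "rotatable"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mw, self.clogp, self.hbd, self.hba, self.charge, self.rotatable],
            dtype=float,
        )


@dataclass
class MoleculeRecord:
    """A library molecule: structure, properties, fingerprint, dock score."""

    molecule_id: str
    smiles: str
    properties: PropertyVector | None = None
    fingerprint: np.ndarray | None = None  # bool/uint8 bit vector
    dock_score: float | None = None

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=bool)


#: contact site labels recognised by the hydrogen-bond pose filter
CONTACT_SITES = ("S246_sidechain", "L276_backbone", "other")


@dataclass
class PoseContacts:
    """Candidate hydrogen-bond geometry for one molecule's best pose."""

    molecule_id: str
    snapshot_id: str
    contacts: pd.DataFrame  # columns: site_label, distance, angle

    def __post_init__(self) -> None:
        required = {"site_label", "distance", "angle"}
        missing = required - set(self.contacts.columns)
        if missing:
            raise ValueError(f"PoseContacts missing columns: {sorted(missing)}")
        if len(self.contacts):
            if (self.contacts["distance"] <= 0).any():
                raise ValueError("distances must be positive")
            if ((self.contacts["angle"] < 0) | (self.contacts["angle"] > 180)).any():
                raise ValueError("angles must lie in [0, 180]")
            bad = set(self.contacts["site_label"]) - set(CONTACT_SITES)
            if bad:
                raise ValueError(f"unknown contact sites: {sorted(bad)}")


@dataclass
class Cluster:
    """Leader-clustering output: representative is the best-scoring member."""

    representative_id: str
    member_ids: tuple[str, ...]
    representative_score: float

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of its cluster")


# ---------------------------------------------------------------------------
# Simulation designs


def half_log_grid(low: float, high: float) -> np.ndarray:
    """Half-log10 concentration ladder from ``low`` to ``high`` inclusive (molar)."""

    n = int(round((np.log10(high) - np.log10(low)) * 2)) + 1
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass
class SimulationDesign:
    """Assay design for synthetic concentration-response experiments.

    Defaults mirror the study conditions: binding agonist ladder 0.3 nM-10 µM
    (half-log), functional ladder 0.01 nM-100 µM, modulator at 0/3/10/30 µM,
    ~1 nM radioligand, n = 4 replicates, 5% proportional noise. Agonist-free
    (zero) points are always appended so allosteric agonism and radioligand
    cooperativity are observable.
    """

    agonist_concs: np.ndarray = field(
        default_factory=lambda: half_log_grid(0.3e-9, 10e-6)
    )
    modulator_concs: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 3e-6, 10e-6, 30e-6])
    )
    radioligand_conc: float = 1e-9
    n_replicates: int = 4
    noise_cv: float = 0.05
    additive_sd: float = 0.0
    include_zero_agonist: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.agonist_concs = _as_1d(self.agonist_concs, "agonist_concs")
        self.modulator_concs = _as_1d(self.modulator_concs, "modulator_concs")
        if len(self.agonist_concs) == 0 or len(self.modulator_concs) == 0:
            raise ValueError("concentration grids must be nonempty")
        if self.noise_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @classmethod
    def functional_default(cls, **kw) -> "SimulationDesign":
        kw.setdefault("agonist_concs", half_log_grid(0.01e-9, 100e-6))
        return cls(**kw)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (agonist, modulator) grid including zero-agonist controls."""

        ag = self.agonist_concs
        if self.include_zero_agonist and not np.any(ag == 0):
            ag = np.concatenate([[0.0], ag])
        a, b = np.meshgrid(ag, self.modulator_concs, indexing="ij")
        return a.ravel(), b.ravel()


@dataclass
class ScoreLibrarySpec:
    """Statistical spec of a synthetic docking score library.

    Scores are Gaussian energies correlated across snapshots; actives are
    shifted by ``active_shift`` (negative = better energy) relative to decoys.
    """

    n_actives: int = 50
    n_decoys: int = 2000
    n_snapshots: int = 10
    active_shift: float = -3.0
    score_loc: float = -20.0
    score_scale: float = 2.0
    snapshot_correlation: float = 0.8
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_actives, self.n_decoys, self.n_snapshots) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.snapshot_correlation <= 1.0:
            raise ValueError("snapshot_correlation must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
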