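"""Virtual-screen enrichment metrics over ensembles of docking snapshots.

Enrichment of known actives over property-matched decoys (or experimentally
verified inactives) is quantified with stepwise ROC curves and the adjusted
logAUC — the area under the ROC curve on a log10 false-positive-rate axis
from a lower bound λ, minus the random-ranking expectation, so that random
selection scores ~0 and early recognition is emphasised. Docking energies
are "lower is better" throughout; pass ``higher_is_better=True`` for generic
scores.

Snapshot ensembles are combined by taking each molecule's best (minimum)
energy across the snapshots where it docked, and snapshots are selected by
their individual adjusted logAUC.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from allomod.datatypes import (
    MoleculeRecord,
    RankedLibrary,
    ROCResult,
    SnapshotScores,
)
from allomod.triage import tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "roc",
    "adjusted_logauc",
    "random_logauc",
    "ensemble_combine",
    "select_snapshots",
    "match_decoys",
    "snapshot_logaucs",
]

_NEGATIVE_LABELS = ("decoy", "inactive")


def _ranked_arrays(library: RankedLibrary, higher_is_better: bool):
    frame = library.frame
    frame = frame[frame["label"] != "unknown"]
    frame = frame.dropna(subset=["score"])
    is_active = (frame["label"] == "active").to_numpy()
    n_act = int(is_active.sum())
    n_neg = int(len(frame) - n_act)
    if n_act == 0 or n_neg == 0:
        raise ValueError("enrichment needs >= 1 active and >= 1 negative")
    score = frame["score"].to_numpy(dtype=float)
    if higher_is_better:
        score = -score
    order = np.lexsort((frame["molecule_id"].to_numpy(), score))
    return score[order], is_active[order], n_act, n_neg


def roc(library: RankedLibrary, higher_is_better: bool = False) -> ROCResult:
    """Stepwise ROC over a scored library (best energy ranked first).

    Tied scores are resolved by letting all tied molecules advance the curve
    simultaneously, tracing a diagonal segment; the resulting AUC equals the
    normalized Mann-Whitney U statistic with ties counted half.
    """

    score, is_active, n_act, n_neg = _ranked_arrays(library, higher_is_better)
    fpr = [0.0]
    tpr = [0.0]
    i = 0
    n = len(score)
    cum_act = 0
    cum_neg = 0
    while i < n:
        j = i
        while j < n and score[j] == score[i]:
            j += 1
        cum_act += int(is_active[i:j].sum())
        cum_neg += (j - i) - int(is_active[i:j].sum())
        fpr.append(cum_neg / n_neg)
        tpr.append(cum_act / n_act)
        i = j
    fpr_arr = np.asarray(fpr)
    tpr_arr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return ROCResult(fpr=fpr_arr, tpr=tpr_arr, auc=auc)


def random_logauc(lam: float = 0.001) -> float:
    """Expected (unadjusted) logAUC %, of a random ranking: TPR = FPR."""

    return 100.0 * (1.0 - lam) / (math.log(10.0) * math.log10(1.0 / lam))


def adjusted_logauc(roc_result: ROCResult, lam: float = 0.001) -> float:
    """Adjusted logAUC (%) of a stepwise ROC curve.

    logAUC = 100 / log10(1/λ) * ∫_λ^1 TPR d(log10 FPR), evaluated exactly
    over the piecewise-linear curve, minus the random-ranking expectation
    (~14.462% at λ = 0.001). FPR below λ contributes nothing; a curve whose
    first nonzero FPR exceeds λ is clamped to λ.
    """

    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    fpr, tpr = roc_result.fpr, roc_result.tpr
    total = 0.0
    for k in range(len(fpr) - 1):
        f1, f2 = fpr[k], fpr[k + 1]
        t1, t2 = tpr[k], tpr[k + 1]
        if f2 <= lam or f2 == f1:
            continue
        slope = (t2 - t1) / (f2 - f1)
        a = max(f1, lam)
        t_a = t1 + slope * (a - f1)
        log_ratio = math.log(f2 / a)
        total += t_a * log_ratio + slope * ((f2 - a) - a * log_ratio)
    logauc = 100.0 * (total / math.log(10.0)) / math.log10(1.0 / lam)
    return logauc - random_logauc(lam)


def ensemble_combine(scores: SnapshotScores, method: str = "best") -> RankedLibrary:
    """Collapse a molecule x snapshot score matrix to one score per molecule.

    ``best`` keeps each molecule's minimum (best) energy over the snapshots
    where it docked. Molecules that docked in no snapshot are excluded with
    a logged count.
    """

    if method != "best":
        raise ValueError(f"unknown combination method: {method!r}")
    best = scores.scores.min(axis=1, skipna=True)
    missing = best.isna()
    if missing.any():
        logger.warning("%d molecules docked in no snapshot; excluded", int(missing.sum()))
    kept = best[~missing]
    frame = pd.DataFrame(
        {
            "molecule_id": kept.index,
            "score": kept.to_numpy(),
            "label": scores.labels.loc[kept.index].to_numpy(),
        }
    ).reset_index(drop=True)
    return RankedLibrary(frame=frame)


def snapshot_logaucs(
    scores: SnapshotScores, lam: float = 0.001, higher_is_better: bool = False
) -> pd.Series:
    """Adjusted logAUC of each snapshot's single-structure ranking."""

    if scores.labels.isna().any():
        raise ValueError("all molecules must be labeled for snapshot selection")
    out = {}
    for snap in scores.scores.columns:
        col = scores.scores[snap]
        frame = pd.DataFrame(
            {
                "molecule_id": col.index,
                "score": col.to_numpy(),
                "label": scores.labels.to_numpy(),
            }
        ).dropna(subset=["score"])
        out[snap] = adjusted_logauc(
            roc(RankedLibrary(frame=frame.reset_index(drop=True)), higher_is_better), lam
        )
    return pd.Series(out, name="adjusted_logauc")


def select_snapshots(
    scores: SnapshotScores,
    k: int,
    lam: float = 0.001,
    higher_is_better: bool = False,
) -> list:
    """Top-``k`` snapshots by per-snapshot adjusted logAUC (descending).

    Ties are broken by snapshot id so selection is deterministic.
    """

    if k > scores.scores.shape[1]:
        raise ValueError("k exceeds the number of snapshots")
    la = snapshot_logaucs(scores, lam=lam, higher_is_better=higher_is_better)
    ranked = sorted(la.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [snap for snap, _ in ranked[:k]]


def match_decoys(
    actives: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    n_per_active: int = 40,
    tc_exclude: float = 0.35,
) -> dict[str, list[str]]:
    """Property-matched decoy assignment in the DUD-E spirit.

    Pool molecules with fingerprint Tanimoto >= ``tc_exclude`` to any active
    are excluded (decoys must be topologically dissimilar); each active then
    takes its ``n_per_active`` nearest remaining pool molecules in z-scored
    property space (MW, cLogP, HBD, HBA, charge, rotatable bonds; z-scores
    over the pool), without reuse across actives, in the order the actives
    are given. Pool exhaustion raises with the per-active shortfall.
    """

    if not actives or not pool:
        raise ValueError("actives and pool must be nonempty")
    for rec in list(actives) + list(pool):
        if rec.properties is None or rec.fingerprint is None:
            raise ValueError(f"molecule {rec.molecule_id}: properties and fingerprint required")

    pool_props = np.array([m.properties.as_array() for m in pool])
    mu = pool_props.mean(axis=0)
    sd = pool_props.std(axis=0)
    sd[sd == 0] = 1.0
    pool_z = (pool_props - mu) / sd

    similar = np.zeros(len(pool), dtype=bool)
    for j, m in enumerate(pool):
        for a in actives:
            if tanimoto(a.fingerprint, m.fingerprint) >= tc_exclude:
                similar[j] = True
                break

    available = ~similar
    pool_ids = np.array([m.molecule_id for m in pool])
    assignment: dict[str, list[str]] = {}
    shortfall: dict[str, int] = {}
    for a in actives:
        a_z = (a.properties.as_array() - mu) / sd
        dist = np.linalg.norm(pool_z - a_z, axis=1)
        order = np.lexsort((pool_ids, dist))
        chosen = []
        for j in order:
            if available[j]:
                chosen.append(j)
                if len(chosen) == n_per_active:
                    break
        if len(chosen) < n_per_active:
            shortfall[a.molecule_id] = n_per_active - len(chosen)
        for j in chosen:
            available[j] = False
        assignment[a.molecule_id] = [pool_ids[j] for j in chosen]
    if shortfall:
        raise ValueError(f"decoy pool exhausted; per-active shortfall: {shortfall}")
    return assignment
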