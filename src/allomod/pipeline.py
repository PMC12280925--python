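"""End-to-end orchestration: simulate -> fit -> report and score -> enrich -> triage.

A :class:`PipelineConfig` carries every tunable with its default; unknown
keys are rejected so typos cannot silently fall back to defaults, and the
effective configuration is echoed into the report. The top-level seed fans
out to per-stage child seeds through ``numpy.random.SeedSequence.spawn`` so
each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from allomod import presets
from allomod.datatypes import ScoreLibrarySpec, SimulationDesign
from allomod.enrichment import (
    adjusted_logauc,
    ensemble_combine,
    roc,
    select_snapshots,
    snapshot_logaucs,
)
from allomod.io import fit_result_to_dict, write_json
from allomod.pharm_models import call_hits, fit_atcm_global, fit_operational_global, screen_deltas
from allomod.synthetic_data import (
    gen_functional,
    gen_interaction_binding,
    gen_molecule_table,
    gen_score_library,
    gen_screen,
)
from allomod.triage import hbond_filter, leader_cluster, select_representatives, top_fraction

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate_fit", "screen_hits", "enrich", "triage")


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults."""

    stages: tuple[str, ...] = _STAGES
    preset: str = "compound12"
    seed: int = 0
    n_replicates: int = 4
    noise_cv: float = 0.05
    alpha: float = 0.05
    lam: float = 0.001
    n_actives: int = 50
    n_decoys: int = 2000
    n_snapshots: int = 10
    active_shift: float = -3.0
    top_snapshots: int = 5
    n_molecules: int = 200
    top_frac: float = 0.005
    hbond_prob: float = 0.5
    tc_cluster: float = 0.5
    max_clusters: int = 1000
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the run report.

    The report echoes the effective configuration, logs per-stage counts and
    estimates, and (when ``out_dir`` is set) is also written to
    ``report.json`` there. A stage failure raises with the stage named;
    previously completed stage outputs remain in the report.
    """

    seeds = dict(zip(_STAGES, _child_seeds(config.seed, len(_STAGES))))
    report: dict = {"config": config.as_dict(), "seeds": seeds, "stages": {}, "warnings": []}
    try:
        for stage in config.stages:
            runner = _STAGE_RUNNERS[stage]
            report["stages"][stage] = runner(config, seeds[stage])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(report, out / "report.json")
    return report


def _run_simulate_fit(config: PipelineConfig, seed: int) -> dict:
    truth_b = presets.atcm_truth(config.preset)
    truth_f = presets.operational_truth(config.preset)
    design_b = SimulationDesign(
        n_replicates=config.n_replicates, noise_cv=config.noise_cv, seed=seed
    )
    design_f = SimulationDesign.functional_default(
        n_replicates=config.n_replicates, noise_cv=config.noise_cv, seed=seed + 1
    )
    binding = gen_interaction_binding(truth_b, design_b)
    functional = gen_functional(truth_f, design_f)
    fit_b = fit_atcm_global(binding, fixed={"pKA": truth_b.pKA}, seed=seed)
    fit_f = fit_operational_global(
        functional,
        fixed={
            "pKA": truth_f.pKA,
            "pKB": fit_b.params.pKB,
            "log_alpha": fit_b.params.log_alpha_I,
        },
        seed=seed,
    )
    return {
        "preset": config.preset,
        "truth_binding": truth_b.as_dict(),
        "truth_functional": truth_f.as_dict(),
        "n_binding_points": int(sum(len(d.specific_binding) for d in binding)),
        "n_functional_points": int(sum(len(d.response) for d in functional)),
        "binding_fit": fit_result_to_dict(fit_b),
        "functional_fit": fit_result_to_dict(fit_f),
    }


def _run_screen_hits(config: PipelineConfig, seed: int) -> dict:
    # three strong PAM effects among 26 compounds, as in the prospective screen
    truth_map = {"C02": (0.5, 0.5), "C12": (0.4, 0.4), "C20": (0.5, 0.4)}
    control, treated = gen_screen(truth_map, seed=seed)
    summary = screen_deltas(control, treated, alpha=config.alpha)
    hits, rate = call_hits(summary, alpha=config.alpha)
    return {
        "n_compounds": int(len(summary)),
        "hits": hits,
        "hit_rate_percent": rate,
        "summary": summary.to_dict(orient="records"),
    }


def _run_enrich(config: PipelineConfig, seed: int) -> dict:
    spec = ScoreLibrarySpec(
        n_actives=config.n_actives,
        n_decoys=config.n_decoys,
        n_snapshots=config.n_snapshots,
        active_shift=config.active_shift,
        seed=seed,
    )
    scores = gen_score_library(spec)
    per_snapshot = snapshot_logaucs(scores, lam=config.lam)
    best = select_snapshots(scores, k=config.top_snapshots, lam=config.lam)
    ensemble = ensemble_combine(
        type(scores)(scores.scores[best], scores.labels), method="best"
    )
    ens_roc = roc(ensemble)
    return {
        "n_actives": spec.n_actives,
        "n_decoys": spec.n_decoys,
        "per_snapshot_logauc": {str(k): float(v) for k, v in per_snapshot.items()},
        "selected_snapshots": [str(s) for s in best],
        "ensemble_auc": float(ens_roc.auc),
        "ensemble_adjusted_logauc": float(adjusted_logauc(ens_roc, lam=config.lam)),
    }


def _run_triage(config: PipelineConfig, seed: int) -> dict:
    import pandas as pd

    from allomod.datatypes import RankedLibrary

    molecules, poses = gen_molecule_table(
        config.n_molecules, seed=seed, hbond_prob=config.hbond_prob
    )
    library = RankedLibrary(
        frame=pd.DataFrame(
            {
                "molecule_id": [m.molecule_id for m in molecules],
                "score": [m.dock_score for m in molecules],
                "label": "unknown",
            }
        )
    )
    cut = top_fraction(library, fraction=config.top_frac)
    cut_ids = set(cut.frame["molecule_id"])
    retained = hbond_filter(p for p in poses if p.molecule_id in cut_ids)
    survivors = [m for m in molecules if m.molecule_id in set(retained)]
    clusters = leader_cluster(survivors, threshold=config.tc_cluster)
    candidates = select_representatives(clusters, survivors, max_clusters=config.max_clusters)
    return {
        "n_input": len(molecules),
        "n_after_rank_cut": len(cut_ids),
        "n_after_hbond_filter": len(retained),
        "n_clusters": len(clusters),
        "candidates": [m.molecule_id for m in candidates],
    }


_STAGE_RUNNERS = {
    "simulate_fit": _run_simulate_fit,
    "screen_hits": _run_screen_hits,
    "enrich": _run_enrich,
    "triage": _run_triage,
}
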