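"""Quantitative pharmacology of allosteric modulation.

Implements the equilibrium and operational models used to quantify positive
allosteric modulator (PAM) activity at a G protein-coupled receptor:

* one-site inhibitory mass-action displacement and the Cheng-Prusoff
  conversion of IC50 to K_I;
* the allosteric ternary complex model (ATCM) for radioligand interaction
  binding, yielding modulator affinity (pK_B) and binding cooperativities
  with the radioligand (α_A) and the orthosteric agonist (α_I);
* the operational model of allosterism (Black-Leff extension), yielding
  operational efficacies (τ_A, τ_B) and the functional cooperativity
  composite αβ;
* three-parameter Hill fits for single-curve potency, cAMP normalization,
  and the screen-level Δ statistics with one-sample t hit calling.

All equilibrium constants are fitted in -log10 molar (pK) space and all
cooperativity/efficacy factors in log10 space with box bounds; global fits
share parameters across replicate experiments.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from allomod._fitting import (
    LOG_FACTOR_BOUNDS,
    PK_BOUNDS,
    MultistartResult,
    multistart_least_squares,
    standard_errors,
)
from allomod.datatypes import (
    ATCMParams,
    CompetitionBindingDataset,
    FitResult,
    FunctionalDataset,
    HillParams,
    InteractionBindingDataset,
    OneSiteFit,
    OperationalParams,
)

__all__ = [
    "predict_one_site",
    "fit_one_site",
    "ki_from_ic50",
    "predict_atcm",
    "fit_atcm_global",
    "predict_operational",
    "fit_operational_global",
    "fit_hill",
    "predict_hill",
    "normalize_camp",
    "screen_deltas",
    "call_hits",
]


# ---------------------------------------------------------------------------
# One-site displacement and Cheng-Prusoff


def predict_one_site(params: OneSiteFit, x) -> np.ndarray:
    """Specific binding at log10 competitor concentration ``x`` (molar).

    ``x = -inf`` (no competitor) returns the top plateau.
    """

    x = np.asarray(x, dtype=float)
    return params.bottom + (params.top - params.bottom) / (
        1.0 + 10.0 ** (x - params.log_ic50)
    )


def log_conc(conc) -> np.ndarray:
    """log10 of molar concentrations, mapping 0 to -inf."""

    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log10(conc)


def fit_one_site(
    data: CompetitionBindingDataset, n_starts: int = 20, seed: int = 0
) -> FitResult:
    """Least-squares fit of the one-site inhibitory mass-action curve."""

    x = log_conc(data.competitor_concs)
    y = data.specific_binding
    span = float(y.max() - y.min())
    if span < 1e-9 * max(1.0, abs(float(y.max()))):
        return FitResult(
            params=None,
            standard_errors={},
            residual_sum_squares=float(np.sum((y - y.mean()) ** 2)),
            converged=False,
            n_points=len(y),
            reason="flat_curve",
        )

    lo = np.array([y.min() - span, y.min() - span, -PK_BOUNDS[1]])
    hi = np.array([y.max() + span, y.max() + span, -PK_BOUNDS[0]])

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, bottom, log_ic50 = theta
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (x - log_ic50))
        return pred - y

    guess = np.array([y.max(), y.min(), np.nanmedian(x[np.isfinite(x)])])
    res = multistart_least_squares(
        residuals, lo, hi, n_starts=n_starts, seed=seed, extra_starts=[guess]
    )
    top, bottom, log_ic50 = res.x
    rss = 2.0 * res.cost
    if top <= bottom or res.at_boundary[2]:
        return FitResult(
            params=None,
            standard_errors={},
            residual_sum_squares=rss,
            converged=False,
            n_points=len(y),
            reason="degenerate" if top <= bottom else "ic50_at_bound",
        )
    se = standard_errors(res.jac, rss, len(y))
    return FitResult(
        params=OneSiteFit(top=top, bottom=bottom, log_ic50=log_ic50),
        standard_errors=dict(zip(("top", "bottom", "log_ic50"), se)),
        residual_sum_squares=rss,
        converged=res.success,
        n_points=len(y),
    )


def ki_from_ic50(ic50: float, radioligand_conc: float, radioligand_kd: float) -> float:
    """Cheng-Prusoff conversion: K_I = IC50 / (1 + [A]/K_D).

    ``radioligand_conc`` may be zero (limit K_I = IC50); IC50 and K_D must be
    positive.
    """

    if ic50 <= 0 or radioligand_kd <= 0:
        raise ValueError("ic50 and radioligand_kd must be positive")
    if radioligand_conc < 0:
        raise ValueError("radioligand_conc must be nonnegative")
    return ic50 / (1.0 + radioligand_conc / radioligand_kd)


# ---------------------------------------------------------------------------
# Allosteric ternary complex model (interaction binding)


def predict_atcm(
    params: ATCMParams,
    radioligand_conc,
    agonist_conc,
    modulator_conc,
) -> np.ndarray:
    """Specific radioligand binding under the allosteric ternary complex model.

    Y = Bmax[A] / ([A] + (K_A K_B / (α_A[B] + K_B)) ·
        (1 + [I]/K_I + [B]/K_B + α_I[I][B]/(K_I K_B)))

    with A the radioligand, B the allosteric ligand and I the orthosteric
    agonist. α > 1 is positive, α < 1 negative, α = 1 neutral cooperativity.
    """

    a = np.asarray(radioligand_conc, dtype=float)
    i = np.asarray(agonist_conc, dtype=float)
    b = np.asarray(modulator_conc, dtype=float)
    if np.any(a < 0) or np.any(i < 0) or np.any(b < 0):
        raise ValueError("concentrations must be nonnegative")
    ka = 10.0 ** (-params.pKA)
    kb = 10.0 ** (-params.pKB)
    ki = 10.0 ** (-params.pKI)
    alpha_a = 10.0 ** params.log_alpha_A
    alpha_i = 10.0 ** params.log_alpha_I
    apparent_ka = ka * kb / (alpha_a * b + kb)
    occupancy_term = 1.0 + i / ki + b / kb + alpha_i * i * b / (ki * kb)
    return params.bmax * a / (a + apparent_ka * occupancy_term)


_ATCM_FREE_ORDER = ("bmax", "pKB", "pKI", "log_alpha_A", "log_alpha_I")


def fit_atcm_global(
    data: Sequence[InteractionBindingDataset],
    fixed: Mapping[str, float],
    n_starts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Global ATCM fit over replicate interaction-binding experiments.

    pK_B, pK_I and the cooperativities are shared across all datasets, as is
    B_max (experiments are assumed normalized to a common control scale).
    The radioligand affinity ``pKA`` must be supplied in ``fixed`` (it is
    constrained to the value determined from saturation binding, as the
    interaction design cannot identify it). Any other parameter named in
    ``fixed`` is held constant; α_A is free by default.
    """

    if "pKA" not in fixed:
        raise ValueError("radioligand pKA must be supplied as a fixed parameter")
    data = list(data)
    if not data:
        raise ValueError("no datasets supplied")
    all_b = np.unique(np.concatenate([d.modulator_conc for d in data]))
    if (all_b > 0).sum() < 2:
        raise ValueError(
            "interaction fit needs >= 2 nonzero modulator concentrations; "
            f"got {sorted(all_b[all_b > 0])}"
        )

    y_all = np.concatenate([d.specific_binding for d in data])
    y_max = float(np.max(np.abs(y_all)))
    bounds_map = {
        "bmax": (0.2 * y_max, 20.0 * y_max),
        "pKB": PK_BOUNDS,
        "pKI": PK_BOUNDS,
        "log_alpha_A": LOG_FACTOR_BOUNDS,
        "log_alpha_I": LOG_FACTOR_BOUNDS,
    }
    free = [name for name in _ATCM_FREE_ORDER if name not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")

    base = {"bmax": 2.0 * y_max, "pKB": 5.0, "pKI": 6.5, "log_alpha_A": 0.0, "log_alpha_I": 1.0}
    base.update(fixed)

    def build(theta: np.ndarray) -> ATCMParams:
        values = dict(base)
        values.update(zip(free, theta))
        return ATCMParams(**values)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = build(theta)
        out = []
        for d in data:
            pred = predict_atcm(p, d.radioligand_conc, d.agonist_conc, d.modulator_conc)
            out.append(pred - d.specific_binding)
        return np.concatenate(out)

    lo = np.array([bounds_map[name][0] for name in free])
    hi = np.array([bounds_map[name][1] for name in free])
    guess = np.array([base[name] for name in free])
    res = multistart_least_squares(
        residuals, lo, hi, n_starts=n_starts, seed=seed, extra_starts=[guess]
    )
    return _package_fit(res, build, free, len(y_all), tuple(sorted(fixed)))


# ---------------------------------------------------------------------------
# Operational model of allosterism (functional interaction)


def predict_operational(params: OperationalParams, agonist_conc, modulator_conc) -> np.ndarray:
    """Functional response under the operational model of allosterism.

    E = E_m (τ_A A (K_B + αβB) + τ_B B K_A)^n /
        ((A K_B + K_A K_B + B K_A + αAB)^n + (τ_A A (K_B + αβB) + τ_B B K_A)^n)

    α is the binding cooperativity, β the modulation of agonist efficacy,
    τ_A/τ_B the operational efficacies, n the transducer slope.
    """

    a = np.asarray(agonist_conc, dtype=float)
    b = np.asarray(modulator_conc, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("concentrations must be nonnegative")
    ka = 10.0 ** (-params.pKA)
    kb = 10.0 ** (-params.pKB)
    tau_a = 10.0 ** params.log_tau_A
    tau_b = 10.0 ** params.log_tau_B
    alpha = 10.0 ** params.log_alpha
    alphabeta = 10.0 ** (params.log_alpha + params.log_beta)
    stim = tau_a * a * (kb + alphabeta * b) + tau_b * b * ka
    denom_lin = a * kb + ka * kb + b * ka + alpha * a * b
    return params.em * stim**params.n / (denom_lin**params.n + stim**params.n)


_OP_FREE_ORDER = ("em", "log_tau_A", "log_tau_B", "log_alpha", "log_beta")


def fit_operational_global(
    data: Sequence[FunctionalDataset],
    fixed: Mapping[str, float],
    n_starts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Global operational-model fit over replicate functional experiments.

    ``fixed`` must supply ``pKA`` and ``pKB`` (affinities constrained to the
    radioligand-binding estimates). The transducer slope ``n`` is fixed at 1
    unless another value is given in ``fixed``. By default ``log_alpha``
    should also be fixed to the binding cooperativity so that the composite
    log(αβ) — reported via ``OperationalParams.log_alphabeta`` — is carried
    by the free ``log_beta``; leave it out of ``fixed`` to fit α as well.
    """

    for req in ("pKA", "pKB"):
        if req not in fixed:
            raise ValueError(f"{req} must be supplied as a fixed parameter")
    data = list(data)
    if not data:
        raise ValueError("no datasets supplied")
    nonzero_b = np.unique(
        np.concatenate([d.modulator_conc[d.modulator_conc > 0] for d in data])
    )
    if len(nonzero_b) < 2:
        raise ValueError(
            "operational fit needs >= 2 nonzero modulator concentrations; "
            f"got {sorted(nonzero_b)}"
        )

    y_all = np.concatenate([d.response for d in data])
    e_max = float(np.max(np.abs(y_all)))
    bounds_map = {
        "em": (0.2 * e_max, 5.0 * e_max),
        "log_tau_A": LOG_FACTOR_BOUNDS,
        "log_tau_B": LOG_FACTOR_BOUNDS,
        "log_alpha": LOG_FACTOR_BOUNDS,
        "log_beta": LOG_FACTOR_BOUNDS,
    }
    free = [name for name in _OP_FREE_ORDER if name not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")

    base = {
        "em": 1.1 * e_max,
        "log_tau_A": 1.0,
        "log_tau_B": 0.0,
        "log_alpha": 0.0,
        "log_beta": 0.0,
        "n": 1.0,
    }
    base.update(fixed)

    def build(theta: np.ndarray) -> OperationalParams:
        values = dict(base)
        values.update(zip(free, theta))
        return OperationalParams(**values)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = build(theta)
        out = []
        for d in data:
            pred = predict_operational(p, d.agonist_conc, d.modulator_conc)
            out.append(pred - d.response)
        return np.concatenate(out)

    lo = np.array([bounds_map[name][0] for name in free])
    hi = np.array([bounds_map[name][1] for name in free])
    guess = np.array([base[name] for name in free])
    res = multistart_least_squares(
        residuals, lo, hi, n_starts=n_starts, seed=seed, extra_starts=[guess]
    )
    return _package_fit(res, build, free, len(y_all), tuple(sorted(fixed)))


def _package_fit(res: MultistartResult, build, free, n_points, fixed_names) -> FitResult:
    rss = 2.0 * res.cost
    params = build(res.x)
    se = standard_errors(res.jac, rss, n_points)
    converged = res.success and not bool(res.at_boundary.any())
    reason = "" if converged else ("boundary" if res.at_boundary.any() else "no_convergence")
    return FitResult(
        params=params,
        standard_errors=dict(zip(free, se)),
        residual_sum_squares=rss,
        converged=converged,
        n_points=n_points,
        fixed_params=fixed_names,
        reason=reason,
    )


# ---------------------------------------------------------------------------
# Hill fits and normalization


def predict_hill(params: HillParams, agonist_conc) -> np.ndarray:
    """Three-parameter Hill curve (unit slope) at molar agonist concentrations."""

    a = np.asarray(agonist_conc, dtype=float)
    ec50 = 10.0 ** (-params.pEC50)
    return params.basal + (params.emax - params.basal) * a / (ec50 + a)


def fit_hill(agonist_conc, response, n_starts: int = 20, seed: int = 0) -> FitResult:
    """Fit basal, E_max and pEC50 to a single concentration-response curve."""

    a = np.asarray(agonist_conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(np.unique(a)) < 4:
        raise ValueError("need >= 4 distinct agonist concentrations")
    span = float(y.max() - y.min())
    if span < 1e-9 * max(1.0, abs(float(y.max()))):
        return FitResult(
            params=None,
            standard_errors={},
            residual_sum_squares=float(np.sum((y - y.mean()) ** 2)),
            converged=False,
            n_points=len(y),
            reason="flat_curve",
        )

    lo = np.array([y.min() - span, y.min() - span, PK_BOUNDS[0]])
    hi = np.array([y.max() + span, y.max() + span, PK_BOUNDS[1]])

    def residuals(theta: np.ndarray) -> np.ndarray:
        basal, emax, pec50 = theta
        pred = basal + (emax - basal) * a / (10.0 ** (-pec50) + a)
        return pred - y

    mid = np.median(np.log10(a[a > 0]))
    guess = np.array([y[np.argmin(a)], y[np.argmax(a)], -mid])
    res = multistart_least_squares(
        residuals, lo, hi, n_starts=n_starts, seed=seed, extra_starts=[guess]
    )
    basal, emax, pec50 = res.x
    rss = 2.0 * res.cost
    converged = res.success and not res.at_boundary[2]
    se = standard_errors(res.jac, rss, len(y))
    return FitResult(
        params=HillParams(basal=basal, emax=emax, pEC50=pec50),
        standard_errors=dict(zip(("basal", "emax", "pEC50"), se)),
        residual_sum_squares=rss,
        converged=converged,
        n_points=len(y),
        reason="" if converged else "ec50_at_bound",
    )


def normalize_camp(raw, forskolin_ref: float, buffer_ref: float) -> np.ndarray:
    """Map raw cAMP readings onto the forskolin-anchored % scale.

    The forskolin reference maps to 0% and buffer alone to 100%, linearly.
    """

    if forskolin_ref == buffer_ref:
        raise ValueError("forskolin and buffer references must differ")
    raw = np.asarray(raw, dtype=float)
    return 100.0 * (raw - forskolin_ref) / (buffer_ref - forskolin_ref)


# ---------------------------------------------------------------------------
# Screen-level hit calling


def screen_deltas(
    control: pd.DataFrame, treated: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-compound Δ statistics for a modulator screen.

    ``control`` and ``treated`` each carry columns ``compound_id``,
    ``replicate``, ``pKI``, ``pEC50``; rows are matched on
    (compound_id, replicate), Δ = treated − control, and each endpoint is
    tested against zero with a two-sided one-sample t test. Compounds need
    >= 3 matched replicates. A zero-variance Δ vector yields an undefined
    t (p = NaN) and cannot be a hit.
    """

    required = {"compound_id", "replicate", "pKI", "pEC50"}
    for name, frame in (("control", control), ("treated", treated)):
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{name} frame missing columns: {sorted(missing)}")
    merged = control.merge(
        treated, on=["compound_id", "replicate"], suffixes=("_ctrl", "_trt"), how="outer"
    )
    if merged[["pKI_ctrl", "pKI_trt", "pEC50_ctrl", "pEC50_trt"]].isna().any().any():
        raise ValueError("control and treated replicates do not match one-to-one")

    rows = []
    for compound_id, grp in merged.groupby("compound_id", sort=True):
        if len(grp) < 3:
            raise ValueError(f"compound {compound_id}: < 3 matched replicates")
        d_pki = (grp["pKI_trt"] - grp["pKI_ctrl"]).to_numpy()
        d_pec = (grp["pEC50_trt"] - grp["pEC50_ctrl"]).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            p_aff = stats.ttest_1samp(d_pki, 0.0).pvalue if np.std(d_pki, ddof=1) > 0 else np.nan
            p_pot = stats.ttest_1samp(d_pec, 0.0).pvalue if np.std(d_pec, ddof=1) > 0 else np.nan
        mean_pki = float(np.mean(d_pki))
        mean_pec = float(np.mean(d_pec))
        hit = (
            np.isfinite(p_aff)
            and np.isfinite(p_pot)
            and p_aff < alpha
            and p_pot < alpha
            and mean_pki > 0
            and mean_pec > 0
        )
        rows.append(
            {
                "compound_id": compound_id,
                "n_replicates": len(grp),
                "delta_pKI": mean_pki,
                "delta_pEC50": mean_pec,
                "p_value_affinity": p_aff,
                "p_value_potency": p_pot,
                "hit_flag": bool(hit),
            }
        )
    return pd.DataFrame(rows)


def call_hits(summary: pd.DataFrame, alpha: float = 0.05) -> tuple[list[str], float]:
    """Hit list and hit rate (%) from a screen summary.

    A hit must show significant (p < alpha) positive enhancement of both
    affinity and potency. The rate is 100 x hits / tested, to one decimal.
    """

    if summary.empty:
        raise ValueError("empty screen summary")
    ok = (
        (summary["p_value_affinity"] < alpha)
        & (summary["p_value_potency"] < alpha)
        & (summary["delta_pKI"] > 0)
        & (summary["delta_pEC50"] > 0)
    )
    hits = sorted(summary.loc[ok.fillna(False), "compound_id"].tolist())
    rate = round(100.0 * len(hits) / len(summary), 1)
    return hits, rate
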