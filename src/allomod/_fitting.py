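"""Shared nonlinear least-squares machinery: seeded multistart with bounds.

All model fits in the package run through :func:`multistart_least_squares`:
a seeded Latin-hypercube scatter of starting points over box bounds, each
polished with ``scipy.optimize.least_squares`` (TRF), the winner chosen by
lowest objective with ties broken by start index. Standard errors come from
the Gauss-Newton approximation ``cov = s^2 (J'J)^-1`` at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

#: box bounds used for log-scale pharmacology parameters
PK_BOUNDS = (3.0, 12.0)
LOG_FACTOR_BOUNDS = (-4.0, 4.0)

#: relative-objective convergence tolerance
FTOL = 1e-10

#: fraction of a bound interval within which a parameter counts as pinned
_BOUNDARY_TOL = 1e-3


@dataclass
class MultistartResult:
    x: np.ndarray
    cost: float  # 0.5 * sum(residuals^2), scipy convention
    jac: np.ndarray
    success: bool
    n_starts_converged: int
    at_boundary: np.ndarray  # bool per parameter


def multistart_least_squares(
    residuals: Callable[[np.ndarray], np.ndarray],
    lower: Sequence[float],
    upper: Sequence[float],
    n_starts: int = 20,
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] = (),
) -> MultistartResult:
    """Minimise ``sum(residuals(x)**2)`` over box bounds from many starts.

    ``extra_starts`` lets callers prepend heuristic initial guesses; they are
    tried before the Latin-hypercube points and share the same tie-break
    (lowest cost, then earliest start).
    """

    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = len(lower)
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    unit = sampler.random(n_starts)
    starts = list(extra_starts) + list(qmc.scale(unit, lower, upper))

    best = None
    best_idx = -1
    n_ok = 0
    for i, x0 in enumerate(starts):
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                method="trf",
                ftol=FTOL,
                xtol=FTOL,
                gtol=1e-12,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        n_ok += res.success
        if best is None or res.cost < best.cost - 1e-15 * max(1.0, best.cost):
            best = res
            best_idx = i
    if best is None:
        raise RuntimeError("no multistart converged to a finite optimum")

    span = upper - lower
    at_boundary = (best.x - lower < _BOUNDARY_TOL * span) | (
        upper - best.x < _BOUNDARY_TOL * span
    )
    return MultistartResult(
        x=best.x,
        cost=best.cost,
        jac=best.jac,
        success=bool(best.success),
        n_starts_converged=n_ok,
        at_boundary=at_boundary,
    )


def standard_errors(jac: np.ndarray, rss: float, n_points: int) -> np.ndarray:
    """Asymptotic SEs from the Jacobian at the optimum; NaN when singular."""

    n_free = jac.shape[1]
    dof = max(n_points - n_free, 1)
    s2 = rss / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_free, np.nan)
    return se
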