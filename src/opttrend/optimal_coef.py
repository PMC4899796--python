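"""The statistic-maximizing heterozygote coefficient.

Given an a-priori effect model (q, Delta, RR, CV_RR, gamma) and a study
design of r cases and s controls, the trend statistic evaluated on the
model-implied expected table is maximized by choosing scores proportional
to the standardized case-control contrasts

    d_i = (p_i - q_i) / nbar_i ,

where p_i, q_i, nbar_i are the expected case, control and pooled genotype
frequencies.  Normalizing the optimal score vector affinely to (0, c, 1)
gives the closed form

    c_optimal = (d_1 - d_0) / (d_2 - d_0).

The coefficient is a function of the a-priori model only — it is never
estimated from the observed table, which would invalidate the chi-square(1)
null of the resulting test.  A bounded numerical maximizer over the
expected table is provided as an independent check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .hetero_model import EffectModel, expected_frequencies
from .trend_tests import trend_chi2

__all__ = [
    "OptimalCoefResult",
    "OptimizationError",
    "optimal_coefficient",
    "optimal_coefficient_numeric",
]

SEARCH_BOUNDS = (-10.0, 11.0)
_GRID_POINTS = 1001


class OptimizationError(ValueError):
    """The optimal coefficient is undefined or the objective is flat."""


@dataclass(frozen=True)
class OptimalCoefResult:
    """Optimal coefficient with the intermediates that produced it."""

    c_optimal: float
    d_scores: tuple[float, float, float]
    model: EffectModel
    design: tuple[int, int]


def optimal_coefficient(model: EffectModel, r: int, s: int) -> OptimalCoefResult:
    """Closed-form optimal heterozygote coefficient for a given model/design."""
    freqs = expected_frequencies(model, r, s)
    p = np.asarray(freqs.cases)
    q = np.asarray(freqs.controls)
    nbar = np.asarray(freqs.pooled)
    if np.any(nbar <= 0):
        raise OptimizationError("pooled expected frequency is zero; coefficient undefined")
    d = (p - q) / nbar
    span = d[2] - d[0]
    if abs(span) <= 1e-14 * max(1.0, np.abs(d).max()):
        raise OptimizationError(
            "optimal coefficient undefined/unbounded: d_2 = d_0 "
            "(optimal scores collapse onto x_0 = x_2)"
        )
    c = (d[1] - d[0]) / span
    return OptimalCoefResult(c_optimal=float(c), d_scores=tuple(float(v) for v in d),
                             model=model, design=(r, s))


def optimal_coefficient_numeric(model: EffectModel, r: int, s: int) -> float:
    """Maximize the trend statistic on the expected table by bounded search.

    Builds the expected 2x3 table (r*p_i, s*q_i) and maximizes the trend
    chi-square over c in [-10, 11], seeding a bounded scalar optimizer with
    a 1001-point grid.  Serves as the independent oracle for
    :func:`optimal_coefficient`.
    """
    freqs = expected_frequencies(model, r, s)
    cases = r * np.asarray(freqs.cases)
    controls = s * np.asarray(freqs.controls)

    def objective(c):
        z = trend_chi2(cases, controls, c)
        return np.where(np.isfinite(z), z, 0.0)

    lo, hi = SEARCH_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = objective(grid)
    best = int(np.argmax(vals))
    if vals[best] <= 1e-12:
        raise OptimizationError("no association to optimize: statistic identically 0")
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(lambda c: -float(objective(c)),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    c = float(res.x)
    if c <= lo + 1e-6 or c >= hi - 1e-6:
        warnings.warn(
            f"optimal coefficient search hit the bound at c = {c:.6g}; "
            "the maximizer may lie outside the search interval",
            RuntimeWarning, stacklevel=2,
        )
    return c
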