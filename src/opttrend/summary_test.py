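"""Weighted multi-coefficient summary test with a chi-square-mixture null.

When a single effect model cannot be pinned down, a researcher may supply m
candidate coefficients c_1..c_m (directly, or via m effect models) with
positive plausibility weights w_1..w_m, and test once with

    W = sum_j w_j * Z(c_j).

Each Z(c_j) is the square of a standardized linear score statistic U_j
which is asymptotically standard normal under the null; the U_j are
correlated because they score the same table.  Writing R for their null
correlation matrix (estimated from the observed pooled genotype
frequencies) and D = diag(w), W is asymptotically distributed as
sum_k lambda_k * chi2_1 with lambda_k the eigenvalues of D^(1/2) R D^(1/2);
the eigenvalues sum to sum_j w_j.  The upper-tail probability of the
mixture is evaluated by the Ruben-Farebrother expansion into central
chi-square tails, which carries a computable truncation bound and is
accurate to ~1e-10 here; Imhof characteristic-function quadrature and a
moment-matched Satterthwaite approximation serve as explicitly labelled
fallbacks.  With m = 1 and unit weight the test reduces to the single
trend test exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .tables import GenotypeCounts, observed_pooled_freqs
from .trend_tests import TestResult, trend_statistic

__all__ = [
    "SummarySpec",
    "SummaryResult",
    "summary_statistic",
    "null_mixture",
    "summary_pvalue",
    "summary_test",
]

_EIG_CLIP = 1e-12
_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class SummarySpec:
    """m heterozygote coefficients with positive weights."""

    coefficients: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        cs = tuple(float(c) for c in self.coefficients)
        ws = tuple(float(w) for w in self.weights)
        if len(cs) < 1:
            raise ValueError("need at least one coefficient")
        if len(ws) != len(cs):
            raise ValueError("coefficients and weights differ in length")
        if not all(np.isfinite(cs)):
            raise ValueError("coefficients must be finite")
        if any(w <= 0 for w in ws):
            raise ValueError("all weights must be > 0")
        object.__setattr__(self, "coefficients", cs)
        object.__setattr__(self, "weights", ws)

    @property
    def m(self) -> int:
        return len(self.coefficients)

    @classmethod
    def from_models(cls, models: Sequence, weights: Sequence[float],
                    r: int, s: int) -> "SummarySpec":
        """Derive the coefficients from effect models via the optimal coefficient."""
        from .optimal_coef import optimal_coefficient

        cs = tuple(optimal_coefficient(m, r, s).c_optimal for m in models)
        return cls(coefficients=cs, weights=tuple(weights))


@dataclass(frozen=True)
class SummaryResult:
    statistic: float
    eigenvalues: tuple[float, ...]
    p_value: float
    per_component: tuple[TestResult, ...]
    method: str
    spec: SummarySpec


def summary_statistic(counts: GenotypeCounts, spec: SummarySpec
                      ) -> tuple[float, tuple[TestResult, ...]]:
    """The weighted sum W = sum_j w_j * Z(c_j) and the component results."""
    components = []
    for c in spec.coefficients:
        try:
            components.append(trend_statistic(counts, c))
        except ValueError as e:
            raise ValueError(f"component c = {c} is degenerate: {e}") from e
    w = np.asarray(spec.weights)
    z = np.array([t.statistic for t in components])
    return float(w @ z), tuple(components)


def _score_vectors(spec: SummarySpec) -> np.ndarray:
    return np.array([[0.0, c, 1.0] for c in spec.coefficients])


def null_mixture(counts: GenotypeCounts, spec: SummarySpec) -> np.ndarray:
    """Eigenvalues of the weighted null correlation of the component scores.

    The null covariance of score x under the pooled multinomial is
    cov(x^j, x^k) = sum_i nbar_i x^j_i x^k_i - (sum_i nbar_i x^j_i)(...^k),
    with nbar the observed pooled genotype frequencies.  Returns the
    eigenvalues of D^(1/2) R D^(1/2) (D = diag(weights)), clipped below
    1e-12 to zero; their sum equals the sum of the weights.
    """
    nbar = observed_pooled_freqs(counts)
    x = _score_vectors(spec)  # (m, 3)
    mean = x @ nbar
    cov = (x * nbar) @ x.T - np.outer(mean, mean)
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise ValueError("degenerate score variance in null mixture")
    corr = cov / np.outer(sd, sd)
    w_half = np.sqrt(np.asarray(spec.weights))
    mat = corr * np.outer(w_half, w_half)
    lam = np.linalg.eigvalsh(mat)
    if lam.min() < -1e-10:
        raise ValueError(f"null correlation not positive semi-definite: {lam}")
    lam = np.where(lam < _EIG_CLIP, 0.0, lam)
    return np.sort(lam)[::-1]


def _ruben_sf(x: float, lam: np.ndarray, eps: float = 1e-11,
              max_terms: int = 20_000) -> tuple[float, float]:
    """Upper tail of sum_k lam_k chi2_1 at x by the Ruben expansion.

    P(Q > x) = sum_k a_k P(chi2_{rho+2k} > x/beta) with beta the smallest
    eigenvalue; all a_k are non-negative and sum to 1, so the truncation
    remainder bounds the absolute error.  Returns (probability, remainder).
    """
    vals, counts = np.unique(lam, return_counts=True)
    beta = vals[0]
    rho = int(counts.sum())
    ratio = 1.0 - beta / vals  # each in [0, 1)
    a = np.empty(max_terms)
    b = np.empty(max_terms)
    a[0] = float(np.prod((beta / vals) ** (counts / 2.0)))
    cum = a[0]
    pw = np.ones_like(ratio)
    k_stop = 0
    for k in range(1, max_terms):
        pw *= ratio
        b[k] = float(counts @ pw)
        a[k] = 0.5 / k * float(b[1:k + 1] @ a[k - 1::-1])
        cum += a[k]
        k_stop = k
        if 1.0 - cum < eps:
            break
    ks = np.arange(k_stop + 1)
    sf = float(a[:k_stop + 1] @ stats.chi2.sf(x / beta, df=rho + 2 * ks))
    return sf, 1.0 - cum


def _imhof_sf(x: float, lam: np.ndarray) -> tuple[float, float]:
    """Upper tail of sum_k lam_k chi2_1 at x by characteristic-function inversion.

    Equal eigenvalues are grouped into multiplicities, which steepens the
    integrand's decay.  Returns (probability, quadrature error estimate).
    """
    vals, counts = np.unique(lam, return_counts=True)

    def integrand(u):
        theta = 0.5 * np.sum(counts * np.arctan(vals * u)) - 0.5 * x * u
        rho = np.prod((1.0 + (vals * u) ** 2) ** (counts / 4.0))
        return np.sin(theta) / (u * rho)

    val, abserr = integrate.quad(integrand, 0.0, np.inf,
                                 epsabs=1e-12, epsrel=1e-10, limit=500)
    return 0.5 + val / np.pi, abserr


def _satterthwaite_sf(x: float, lam: np.ndarray) -> float:
    """Moment-matched scaled chi-square upper tail: W ~ a * chi2_nu."""
    s1 = lam.sum()
    s2 = (lam**2).sum()
    a = s2 / s1
    nu = s1**2 / s2
    return float(stats.chi2.sf(x / a, df=nu))


def summary_pvalue(w_stat: float, eigenvalues) -> tuple[float, str]:
    """Upper-tail probability of the eigenvalue mixture at W.

    Mixtures with a single distinct eigenvalue (after clipping) are scaled
    chi-squares and evaluated in closed form.  Otherwise the Ruben series
    (absolute error below 1e-10, method flag "ruben") is used; should its
    truncation bound not be met, Imhof characteristic-function quadrature
    ("imhof") and then the Satterthwaite approximation ("satterthwaite")
    take over, never silently.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all eigenvalues are zero")
    if w_stat <= 0:
        return 1.0, "ruben"
    distinct = np.unique(lam)
    if distinct.size == 1:
        return float(stats.chi2.sf(w_stat / distinct[0], df=lam.size)), "ruben"
    p, remainder = _ruben_sf(w_stat, lam)
    if np.isfinite(p) and 0.0 <= remainder < 1e-8:
        return float(min(max(p, _P_FLOOR), 1.0)), "ruben"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            p, abserr = _imhof_sf(w_stat, lam)
        if abserr > 1e-6 or not np.isfinite(p):
            raise RuntimeError("quadrature error estimate too large")
    except (RuntimeError, integrate.IntegrationWarning):
        return _satterthwaite_sf(w_stat, lam), "satterthwaite"
    return float(min(max(p, _P_FLOOR), 1.0)), "imhof"


def summary_test(counts: GenotypeCounts, spec: SummarySpec) -> SummaryResult:
    """Run the full summary test: statistic, null mixture and p-value."""
    w_stat, components = summary_statistic(counts, spec)
    lam = null_mixture(counts, spec)
    p, method = summary_pvalue(w_stat, lam)
    return SummaryResult(statistic=w_stat, eigenvalues=tuple(lam), p_value=p,
                         per_component=components, method=method, spec=spec)
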