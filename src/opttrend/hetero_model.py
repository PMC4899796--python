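"""Model-implied genotype frequencies under heterogeneous relative risks.

The five-parameter effect model:

* ``q``      — frequency of the A allele in the non-diseased population;
* ``delta``  — Hardy-Weinberg disequilibrium coefficient (capital Delta) of
  the non-diseased population, so the control genotype frequencies are
  ``((1-q)^2 + Delta, 2q(1-q) - 2*Delta, q^2 + Delta)``;
* ``rr``     — mean per-allele relative risk RR of the A allele, which is
  allowed to vary across diseased individuals (disease subtypes);
* ``cv_rr``  — coefficient of variation of the per-allele relative risk, the
  measure of effect heterogeneity;
* ``gamma``  — genetic model parameter in [0, 1]: genotype relative risks
  are ``(1, RR^(2*gamma), RR^2)``, so 0 is recessive, 0.5 gene dosage
  (multiplicative per allele) and 1 dominant.

Averaging over the random relative risk, the case allele parameter
``p = q*RR / (1 - q + q*RR)`` acquires mean ``p_bar`` (at RR's mean) and a
Taylor-approximation variance ``delta_var = [p_bar*(1-p_bar)*CV_RR]^2``;
that variance re-enters the case genotype distribution as a Hardy-Weinberg
disequilibrium coefficient.  The general (gamma, Delta) case is obtained by
a second-order Taylor expectation of the normalized genotype distribution
``g_i(p) = q_i * GRR_i(RR(p)) / sum_j q_j * GRR_j(RR(p))`` around
``p_bar``, which reduces exactly to the closed-form gene-dosage/HWE
expressions because there the ``g_i`` are quadratic in ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffectModel",
    "CaseAlleleParam",
    "ExpectedFrequencies",
    "ModelAdmissibilityError",
    "control_freqs",
    "case_allele_param",
    "case_freqs_special",
    "case_freqs_general",
    "pooled_freqs_expected",
    "expected_frequencies",
]

_SIMPLEX_TOL = 1e-12


class ModelAdmissibilityError(ValueError):
    """Model parameters imply frequencies outside the probability simplex."""


@dataclass(frozen=True)
class EffectModel:
    """The (q, Delta, RR, CV_RR, gamma) genetic effect model."""

    q: float
    delta: float = 0.0
    rr: float = 1.0
    cv_rr: float = 0.0
    gamma: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ModelAdmissibilityError(f"q must be in (0, 1), got {self.q}")
        if self.rr <= 0.0:
            raise ModelAdmissibilityError(f"RR must be > 0, got {self.rr}")
        if self.cv_rr < 0.0:
            raise ModelAdmissibilityError(f"CV_RR must be >= 0, got {self.cv_rr}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ModelAdmissibilityError(f"gamma must be in [0, 1], got {self.gamma}")
        control_freqs(self.q, self.delta)  # raises if Delta inadmissible

    @property
    def is_null(self) -> bool:
        """True when the model implies no case/control difference."""
        return self.rr == 1.0 and self.cv_rr == 0.0


@dataclass(frozen=True)
class CaseAlleleParam:
    """Mean and Taylor variance of the case allele parameter p."""

    p_bar: float
    delta_var: float


@dataclass(frozen=True)
class ExpectedFrequencies:
    """Model-implied case, control and pooled genotype frequency triples."""

    cases: tuple[float, float, float]
    controls: tuple[float, float, float]
    pooled: tuple[float, float, float]
    design: tuple[int, int]


def _check_simplex(f: np.ndarray, what: str) -> np.ndarray:
    if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
        raise ModelAdmissibilityError(f"{what} outside [0, 1]: {f.tolist()}")
    return np.clip(f, 0.0, 1.0)


def control_freqs(q: float, delta: float = 0.0) -> np.ndarray:
    """Control genotype frequencies ``((1-q)^2 + D, 2q(1-q) - 2D, q^2 + D)``.

    ``delta`` is the Hardy-Weinberg disequilibrium coefficient of the
    non-diseased population; 0 recovers Hardy-Weinberg proportions.
    """
    f = np.array([(1 - q) ** 2 + delta, 2 * q * (1 - q) - 2 * delta, q**2 + delta])
    if np.any(f < 0) or np.any(f > 1):
        raise ModelAdmissibilityError(
            f"Delta out of admissible range for q: q={q}, Delta={delta} -> {f.tolist()}"
        )
    return f


def case_allele_param(q: float, rr: float, cv_rr: float) -> CaseAlleleParam:
    """Mean case allele parameter and its Taylor-approximation variance.

    ``p_bar = q*RR / (1 - q + q*RR)``;
    ``delta_var = [p_bar*(1 - p_bar)*CV_RR]^2``.
    The variance doubles as the Hardy-Weinberg disequilibrium coefficient
    induced in the diseased population by effect heterogeneity.
    """
    if not 0.0 < q < 1.0:
        raise ModelAdmissibilityError(f"q must be in (0, 1), got {q}")
    if rr <= 0.0:
        raise ModelAdmissibilityError(f"RR must be > 0, got {rr}")
    if cv_rr < 0.0:
        raise ModelAdmissibilityError(f"CV_RR must be >= 0, got {cv_rr}")
    p_bar = q * rr / (1.0 - q + q * rr)
    delta_var = (p_bar * (1.0 - p_bar) * cv_rr) ** 2
    if delta_var > p_bar * (1.0 - p_bar):
        raise ModelAdmissibilityError(
            f"variance {delta_var} exceeds p_bar*(1-p_bar); model inadmissible"
        )
    return CaseAlleleParam(p_bar=p_bar, delta_var=delta_var)


def case_freqs_special(q: float, rr: float, cv_rr: float) -> np.ndarray:
    """Case genotype frequencies under HWE controls and gene dosage.

    ``((1-p)^2 + d, 2p(1-p) - 2d, p^2 + d)`` with ``p = p_bar`` and
    ``d = delta_var`` from :func:`case_allele_param`.
    """
    par = case_allele_param(q, rr, cv_rr)
    p, d = par.p_bar, par.delta_var
    f = np.array([(1 - p) ** 2 + d, 2 * p * (1 - p) - 2 * d, p**2 + d])
    return _check_simplex(f, "case frequencies")


def genotype_relative_risks(rr: float, gamma: float) -> np.ndarray:
    """Genotype relative risks ``(1, RR^(2*gamma), RR^2)``."""
    return np.array([1.0, rr ** (2.0 * gamma), rr**2])


def case_freq_curve(p: float, q: float, delta: float, gamma: float) -> np.ndarray:
    """Case genotype distribution as a function of the allele parameter p.

    Inverts the allele-parameter map to ``RR(p) = p(1-q) / (q(1-p))`` and
    weights the control genotype frequencies by the genotype relative risks.
    """
    if not 0.0 < p < 1.0:
        raise ModelAdmissibilityError(f"allele parameter must be in (0, 1), got {p}")
    qf = control_freqs(q, delta)
    rr = p * (1.0 - q) / (q * (1.0 - p))
    w = qf * genotype_relative_risks(rr, gamma)
    return w / w.sum()


# central-difference step for the second derivative of the case-frequency
# curve; 1e-4 balances truncation against cancellation at ~1e-8 accuracy
_FD_STEP = 1e-4


def case_freqs_general(model: EffectModel) -> np.ndarray:
    """Case genotype frequencies for arbitrary (gamma, Delta).

    Second-order Taylor expectation of :func:`case_freq_curve` around
    ``p_bar`` with variance ``delta_var``, renormalised onto the simplex.
    Exactly matches :func:`case_freqs_special` at gamma = 0.5, Delta = 0,
    where the curve is quadratic in p.
    """
    par = case_allele_param(model.q, model.rr, model.cv_rr)
    p, d = par.p_bar, par.delta_var
    h = _FD_STEP * max(1.0, abs(p))
    h = min(h, 0.5 * p, 0.5 * (1.0 - p))
    g0 = case_freq_curve(p, model.q, model.delta, model.gamma)
    if d > 0:
        gp = case_freq_curve(p + h, model.q, model.delta, model.gamma)
        gm = case_freq_curve(p - h, model.q, model.delta, model.gamma)
        g2 = (gp - 2.0 * g0 + gm) / (h * h)
        f = g0 + 0.5 * g2 * d
    else:
        f = g0
    f = _check_simplex(f, "case frequencies (general model)")
    return f / f.sum()


def pooled_freqs_expected(case_f, control_f, r: int, s: int) -> np.ndarray:
    """Expected pooled-sample genotype frequencies ``(r*p_i + s*q_i)/(r+s)``."""
    if r < 1 or s < 1:
        raise ModelAdmissibilityError("need r >= 1 cases and s >= 1 controls")
    case_f = np.asarray(case_f, dtype=float)
    control_f = np.asarray(control_f, dtype=float)
    for f, what in ((case_f, "case"), (control_f, "control")):
        if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
            raise ModelAdmissibilityError(f"{what} frequencies not on the simplex")
    return (r * case_f + s * control_f) / (r + s)


def expected_frequencies(model: EffectModel, r: int, s: int) -> ExpectedFrequencies:
    """All three model-implied frequency triples for a (r cases, s controls) design."""
    qf = control_freqs(model.q, model.delta)
    pf = case_freqs_general(model)
    nf = pooled_freqs_expected(pf, qf, r, s)
    return ExpectedFrequencies(cases=tuple(pf), controls=tuple(qf),
                               pooled=tuple(nf), design=(r, s))
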