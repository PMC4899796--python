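"""Data generators, sample-size calculation and Monte-Carlo power studies.

Two generators of case-control genotype tables are provided.  The primary
one samples cases and controls as multinomials at the model-implied
expected genotype frequencies — the asymptotic regime the trend tests
target.  The individual-level alternative draws a per-subject relative risk
from a lognormal (or gamma) distribution with the model's mean and
coefficient of variation and then draws each case genotype with probability
proportional to ``q_i * GRR_i``; it makes no Taylor approximation, so it
probes the robustness of the expected-frequency construction.  The two
coincide when CV_RR = 0.

The sample-size calculator uses the standard noncentrality form for the
Cochran-Armitage trend test with scores (0, 0.5, 1) and no continuity
correction:

    n per group = (z_{1-alpha/2}*sigma_0 + z_{1-beta}*sigma_1)^2 / e^2

where ``e`` is the expected case-control difference in mean score,
``sigma_0^2`` twice the score variance at the averaged (null) frequencies
and ``sigma_1^2`` the sum of the case and control score variances.

The power engine evaluates fixed-coefficient tests, model-derived optimal
tests (coefficient computed once per scenario from the assumed model, never
re-estimated per replicate) and summary tests, reporting empirical power
with a binomial standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .hetero_model import (EffectModel, ModelAdmissibilityError, case_freqs_general,
                           control_freqs, genotype_relative_risks)
from .optimal_coef import optimal_coefficient
from .summary_test import SummarySpec, null_mixture, summary_pvalue, summary_statistic
from .tables import GenotypeCounts
from .trend_tests import trend_chi2

__all__ = [
    "PowerScenario",
    "SubtypePopulation",
    "SubtypeSummary",
    "sample_counts",
    "sample_counts_individual",
    "sample_size_ca",
    "power_study",
    "subtype_population_summary",
]

TestDescriptor = Union[float, str, tuple, SummarySpec]


@dataclass(frozen=True)
class PowerScenario:
    """One cell of a power study: true model, design, tests and replication."""

    model: EffectModel
    n_cases: int
    n_controls: int
    tests: tuple
    alpha: float = 0.05
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


# -- generators ---------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_counts(model: EffectModel, n_cases: int, n_controls: int,
                  seed=None) -> GenotypeCounts:
    """One table: multinomial draws at the model-implied frequencies."""
    rng = _rng(seed)
    cases = rng.multinomial(n_cases, case_freqs_general(model))
    controls = rng.multinomial(n_controls, control_freqs(model.q, model.delta))
    return GenotypeCounts(tuple(int(v) for v in cases),
                          tuple(int(v) for v in controls))


def sample_counts_batch(model: EffectModel, n_cases: int, n_controls: int,
                        reps: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised replicate tables: (reps, 3) case and control count arrays."""
    rng = _rng(seed)
    cases = rng.multinomial(n_cases, case_freqs_general(model), size=reps)
    controls = rng.multinomial(n_controls, control_freqs(model.q, model.delta),
                               size=reps)
    return cases.astype(float), controls.astype(float)


def draw_relative_risks(rr: float, cv_rr: float, n: int, seed=None,
                        family: str = "lognormal") -> np.ndarray:
    """Per-subject relative risks with mean ``rr`` and CV ``cv_rr``.

    Lognormal: sigma^2 = log(1 + CV^2), mu = log(RR) - sigma^2/2.
    Gamma: shape 1/CV^2, scale RR*CV^2.  CV = 0 returns the constant RR.
    """
    rng = _rng(seed)
    if cv_rr == 0.0:
        return np.full(n, rr)
    if family == "lognormal":
        sigma2 = math.log1p(cv_rr**2)
        mu = math.log(rr) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    if family == "gamma":
        shape = 1.0 / cv_rr**2
        return rng.gamma(shape=shape, scale=rr * cv_rr**2, size=n)
    raise ValueError(f"unknown relative-risk family {family!r}")


def sample_counts_individual(model: EffectModel, n_cases: int, n_controls: int,
                             seed=None, rr_family: str = "lognormal"
                             ) -> GenotypeCounts:
    """One table from the individual-level heterogeneous-risk generator.

    Each case carries its own relative risk drawn from ``rr_family``; the
    case genotype is drawn with probability proportional to
    ``q_i * GRR_i(RR_subject)``.  Controls are multinomial at the control
    frequencies.  No Taylor approximation is involved.
    """
    rng = _rng(seed)
    qf = control_freqs(model.q, model.delta)
    rrs = draw_relative_risks(model.rr, model.cv_rr, n_cases, rng, rr_family)
    # (n_cases, 3) genotype probabilities, one row per subject
    grr = np.stack([np.ones(n_cases), rrs ** (2.0 * model.gamma), rrs**2], axis=1)
    probs = qf * grr
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n_cases)
    cum = np.cumsum(probs, axis=1)
    geno = (u[:, None] > cum).sum(axis=1)
    cases = np.bincount(geno, minlength=3)
    controls = rng.multinomial(n_controls, qf)
    return GenotypeCounts(tuple(int(v) for v in cases),
                          tuple(int(v) for v in controls))


# -- sample size --------------------------------------------------------


def sample_size_ca(model_alt: EffectModel, alpha: float = 0.05,
                   power: float = 0.8) -> int:
    """Cases (= controls) needed for the Cochran-Armitage test.

    Noncentrality-based, scores (0, 0.5, 1), equal arms, no continuity
    correction; rounded up.  A null alternative (zero expected score
    contrast) is an error.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    x = np.array([0.0, 0.5, 1.0])
    pf = case_freqs_general(model_alt)
    qf = control_freqs(model_alt.q, model_alt.delta)
    e = float(x @ (pf - qf))
    if abs(e) < 1e-12:
        raise ValueError("sample size unbounded: zero expected score contrast")

    def score_var(f):
        return float((x**2) @ f - (x @ f) ** 2)

    pooled = (pf + qf) / 2.0
    sigma0 = math.sqrt(2.0 * score_var(pooled))
    sigma1 = math.sqrt(score_var(pf) + score_var(qf))
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = (za * sigma0 + zb * sigma1) ** 2 / e**2
    return int(math.ceil(n))


# -- power study --------------------------------------------------------


def _resolve_test(desc, model: EffectModel, r: int, s: int):
    """Turn a test descriptor into (label, kind, payload).

    Descriptors: a float (fixed coefficient); "ca" (coefficient 0.5);
    "optimal" (coefficient from the scenario model, computed once);
    ("optimal", EffectModel) to derive from another model; a SummarySpec.
    """
    if isinstance(desc, SummarySpec):
        return (f"summary(m={desc.m})", "summary", desc)
    if isinstance(desc, str):
        if desc == "ca":
            return ("ca", "fixed", 0.5)
        if desc == "optimal":
            c = optimal_coefficient(model, r, s).c_optimal
            return ("optimal", "fixed", c)
        raise ValueError(f"unknown test descriptor {desc!r}")
    if isinstance(desc, tuple) and len(desc) == 2 and desc[0] == "optimal":
        c = optimal_coefficient(desc[1], r, s).c_optimal
        return ("optimal", "fixed", c)
    c = float(desc)
    return (f"c={c:g}", "fixed", c)


def _summary_reject(cases: np.ndarray, controls: np.ndarray,
                    spec: SummarySpec, alpha: float) -> np.ndarray:
    """Per-replicate rejection indicator for a summary test (looped)."""
    out = np.zeros(cases.shape[0], dtype=bool)
    for i in range(cases.shape[0]):
        counts = GenotypeCounts(tuple(int(v) for v in cases[i]),
                                tuple(int(v) for v in controls[i]))
        try:
            w_stat, _ = summary_statistic(counts, spec)
            lam = null_mixture(counts, spec)
            p, _ = summary_pvalue(w_stat, lam)
        except ValueError:
            continue  # degenerate replicate counts as non-rejection
        out[i] = p < alpha
    return out


def power_study(scenarios: Sequence[PowerScenario]) -> pd.DataFrame:
    """Empirical power table over scenarios and tests.

    One RNG stream per scenario (seeded by the scenario's own seed), shared
    by all tests within it so they see identical replicate tables.  Returns
    a DataFrame with columns rr, cv, test, power, se, n_cases, n_controls,
    alpha, reps, seed.
    """
    rows = []
    for scen in scenarios:
        rng = np.random.default_rng(scen.seed)
        cases, controls = sample_counts_batch(scen.model, scen.n_cases,
                                              scen.n_controls, scen.reps, rng)
        crit = stats.chi2.ppf(1.0 - scen.alpha, df=1)
        for desc in scen.tests:
            label, kind, payload = _resolve_test(desc, scen.model,
                                                 scen.n_cases, scen.n_controls)
            if kind == "fixed":
                z = trend_chi2(cases, controls, payload)
                if scen.alpha >= 1.0:
                    reject = np.ones(scen.reps, dtype=bool)
                else:
                    reject = np.where(np.isfinite(z), z, 0.0) > crit
            else:
                reject = _summary_reject(cases, controls, payload, scen.alpha)
            pw = float(reject.mean())
            rows.append({
                "rr": scen.model.rr, "cv": scen.model.cv_rr, "test": label,
                "power": pw, "se": math.sqrt(pw * (1.0 - pw) / scen.reps),
                "n_cases": scen.n_cases, "n_controls": scen.n_controls,
                "alpha": scen.alpha, "reps": scen.reps, "seed": scen.seed,
            })
    return pd.DataFrame(rows)


# -- two-subtype population example -------------------------------------


@dataclass(frozen=True)
class SubtypePopulation:
    """A population with per-genotype counts and etiologic disease subtypes.

    Each subtype is a (baseline risk at aa, per-allele risk factor) pair;
    the risk for genotype i is baseline * factor**i.
    """

    genotype_counts: tuple[int, int, int]
    subtypes: tuple[tuple[float, float], ...]

    def risks(self) -> np.ndarray:
        """(n_subtypes, 3) array of per-genotype disease risks."""
        out = np.array([[base * factor**i for i in range(3)]
                        for base, factor in self.subtypes])
        if np.any(out < 0) or np.any(out > 1):
            raise ValueError("subtype risk outside [0, 1] after per-allele scaling")
        return out


@dataclass(frozen=True)
class SubtypeSummary:
    marginal_risks: tuple[float, float, float]
    subtype_shares: tuple[float, ...]
    expected_cases: tuple[tuple[float, float, float], ...]


def subtype_population_summary(pop: SubtypePopulation) -> SubtypeSummary:
    """Marginal genotype risks and per-subtype case shares.

    Expected cases per genotype per subtype are population count times
    risk; the marginal risk for a genotype sums expected cases across
    subtypes and divides by the genotype's population count; shares divide
    each subtype's total expected cases by the grand total.
    """
    n = np.asarray(pop.genotype_counts, dtype=float)
    risks = pop.risks()                      # (k, 3)
    expected = risks * n                     # (k, 3)
    marginal = expected.sum(axis=0) / n
    totals = expected.sum(axis=1)
    shares = totals / totals.sum()
    return SubtypeSummary(
        marginal_risks=tuple(float(v) for v in marginal),
        subtype_shares=tuple(float(v) for v in shares),
        expected_cases=tuple(tuple(float(v) for v in row) for row in expected),
    )
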