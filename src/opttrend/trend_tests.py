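"""Score-based trend tests on 2x3 case-control genotype tables.

The generalized trend statistic assigns scores ``(x_0, x_1, x_2) = (0, c, 1)``
to the genotypes ``aa, Aa, AA`` and contrasts the mean score between cases
and controls, standardised by the pooled-sample score variance:

    Z(c) = n * [n * sum(x_i r_i) - r * sum(x_i n_i)]^2
           / (r * s * [n * sum(x_i^2 n_i) - (sum(x_i n_i))^2])

Under the null hypothesis of no association Z(c) is asymptotically
chi-square with one degree of freedom for any fixed coefficient ``c``.
``c = 0.5`` gives the familiar Cochran-Armitage trend test; ``c = 0`` and
``c = 1`` correspond to recessive and dominant contrasts of the A allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tables import GenotypeCounts

__all__ = [
    "TestResult",
    "DegenerateTableError",
    "trend_statistic",
    "cochran_armitage",
    "pearson_2df",
]

# p-values are floored here rather than reported as exactly zero
_P_FLOOR = np.finfo(float).tiny


class DegenerateTableError(ValueError):
    """The table admits no test (empty margin or zero score variance)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single chi-square test.

    ``df`` describes the reference distribution (upper tail of chi-square
    with that many degrees of freedom); ``p_value`` is always the upper-tail
    probability of ``statistic``, floored at the smallest positive double.
    """

    statistic: float
    df: float
    p_value: float
    method: str
    coefficient: float | None = None
    floored: bool = field(default=False, compare=False)


def _floor_p(p: float) -> tuple[float, bool]:
    if p <= 0.0:
        return _P_FLOOR, True
    return min(p, 1.0), False


def trend_chi2(cases, controls, c) -> np.ndarray:
    """Vectorised trend chi-square.

    ``cases``/``controls`` are arrays with trailing dimension 3 (real-valued
    counts are admitted, e.g. expected tables); ``c`` may be a scalar or an
    array broadcast against the leading dimensions.  Returns NaN where the
    pooled score variance is non-positive.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    c = np.asarray(c, dtype=float)
    r = cases.sum(axis=-1)
    s = controls.sum(axis=-1)
    n = r + s
    tot = cases + controls
    # scores (0, c, 1)
    sxr = c * cases[..., 1] + cases[..., 2]
    sxn = c * tot[..., 1] + tot[..., 2]
    sx2n = c * c * tot[..., 1] + tot[..., 2]
    num = n * (n * sxr - r * sxn) ** 2
    den = r * s * (n * sx2n - sxn**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return z


def trend_statistic(counts: GenotypeCounts, c: float) -> TestResult:
    """Trend test of association with heterozygote coefficient ``c``.

    Raises :class:`DegenerateTableError` for an empty case or control margin
    or when the pooled score variance vanishes (all subjects carry one
    genotype).
    """
    if not np.isfinite(c):
        raise ValueError(f"coefficient must be finite, got {c!r}")
    if counts.r < 1 or counts.s < 1:
        raise DegenerateTableError("need at least one case and one control")
    z = float(trend_chi2(counts.case_array(), counts.control_array(), float(c)))
    if not np.isfinite(z):
        raise DegenerateTableError("degenerate score variance")
    p, floored = _floor_p(stats.chi2.sf(z, df=1))
    return TestResult(statistic=z, df=1, p_value=p, method="trend",
                      coefficient=float(c), floored=floored)


def cochran_armitage(counts: GenotypeCounts) -> TestResult:
    """The Cochran-Armitage trend test: the gene-dosage case ``c = 0.5``."""
    res = trend_statistic(counts, 0.5)
    return TestResult(statistic=res.statistic, df=res.df, p_value=res.p_value,
                      method="cochran_armitage", coefficient=0.5,
                      floored=res.floored)


def pearson_2df(counts: GenotypeCounts) -> TestResult:
    """Pearson chi-square over the 2x3 table, no continuity correction.

    Genotype columns with a zero margin carry no information and are
    dropped; the degrees of freedom reflect the retained columns (2 for a
    full table).  Fewer than two non-empty columns is an error.
    """
    if counts.r < 1 or counts.s < 1:
        raise DegenerateTableError("need at least one case and one control")
    table = np.array([counts.cases, counts.controls], dtype=float)
    keep = table.sum(axis=0) > 0
    if keep.sum() < 2:
        raise DegenerateTableError("fewer than two non-empty genotype columns")
    stat, p, dof, _ = stats.chi2_contingency(table[:, keep], correction=False)
    p, floored = _floor_p(p)
    return TestResult(statistic=float(stat), df=float(dof), p_value=p,
                      method="pearson", coefficient=None, floored=floored)
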