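"""Small built-in example data sets.

These are the published counts and hypothetical populations used in the
package's worked examples and tests.
"""

from __future__ import annotations

from .hetero_model import EffectModel
from .simulate import SubtypePopulation
from .tables import GenotypeCounts

__all__ = ["adprt_lung_cancer", "adprt_example_model", "two_subtype_population"]


def adprt_lung_cancer() -> GenotypeCounts:
    """ADPRT Val762Ala x lung cancer case-control counts.

    1000 cases and 1018 controls; genotypes ordered by copies of the Ala
    allele (Val/Val, Val/Ala, Ala/Ala).
    """
    return GenotypeCounts(cases=(307, 509, 184), controls=(359, 522, 137))


def adprt_example_model() -> EffectModel:
    """The illustrative a-priori effect model for the ADPRT example.

    HWE controls with allele frequency 0.4, gene-dosage model, weak mean
    association RR = 1.25 with moderate heterogeneity CV_RR = 0.4.
    """
    return EffectModel(q=0.4, delta=0.0, rr=1.25, cv_rr=0.4, gamma=0.5)


def two_subtype_population() -> SubtypePopulation:
    """Hypothetical million-person population with two disease subtypes.

    Genotypes aa/Aa/AA number 250k/500k/250k.  Subtype I: baseline risk
    0.0001 at aa, increasing ten-fold per A allele; Subtype II: baseline
    0.0020 at aa, halving per A allele.  Marginally the A allele looks
    protective between aa and Aa even though most cases arise from the
    subtype where it is a strong risk allele.
    """
    return SubtypePopulation(
        genotype_counts=(250_000, 500_000, 250_000),
        subtypes=((0.0001, 10.0), (0.0020, 0.5)),
    )
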