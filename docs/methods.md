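# Methods

## Model and tests

A biallelic marker classifies each subject as *aa*, *Aa* or *AA* (i = 0,
1, 2 copies of the A allele). A case-control study of r cases and s
controls yields a 2×3 table with cell counts rᵢ, sᵢ, column totals
nᵢ = rᵢ + sᵢ and n = r + s.

**Generalized trend statistic.** With genotype scores (0, c, 1),

Z(c) = n[nΣxᵢrᵢ − rΣxᵢnᵢ]² / (rs[nΣxᵢ²nᵢ − (Σxᵢnᵢ)²]).

This is the standard score-based trend chi-square: the squared
case-control contrast in mean score over its pooled-null variance
estimate. It is invariant to affine rescaling of the scores, asymptotically
χ²₁ under the null for any fixed c, and Z(0.5) is the Cochran-Armitage
test. The statistic is continuous in c and converges, as |c| → ∞, to the
heterozygote-versus-homozygotes contrast with scores (0, 1, 0); reversing
the genotype order maps Z(c) to Z(1 − c). Tests are two-sided via the χ²
upper tail; no continuity correction is applied anywhere; p-values are
floored at the smallest positive double and flagged rather than printed as
zero.

**Effect model.** Five parameters describe the alternative:

| parameter | meaning | admissible | default |
|---|---|---|---|
| q | A-allele frequency, non-diseased population | (0, 1) | — |
| Δ | HW disequilibrium coefficient, non-diseased | controls on simplex | 0 |
| RR | mean per-allele relative risk | > 0 | 1 |
| CV_RR | coefficient of variation of RR (heterogeneity) | ≥ 0 | 0 |
| γ | genetic model: genotype RRs (1, RR^2γ, RR²) | [0, 1] | 0.5 |

γ = 0, 0.5, 1 are the recessive, gene-dosage and dominant landmarks; γ is
accepted continuously between them. Control frequencies are
((1−q)² + Δ, 2q(1−q) − 2Δ, q² + Δ). The case allele parameter is
p̄ = qRR/(1 − q + qRR); heterogeneity in RR gives it the Taylor variance
δ = [p̄(1−p̄)CV_RR]², which acts as a HW disequilibrium coefficient in the
diseased population. Under HWE controls and gene dosage the case
frequencies are ((1−p̄)² + δ, 2p̄(1−p̄) − 2δ, p̄² + δ) in closed form.

**General (γ, Δ) construction.** Writing RR(p) = p(1−q)/(q(1−p)) for the
inverse of the allele-parameter map, the case genotype distribution as a
function of p is gᵢ(p) = qᵢ·GRRᵢ(RR(p)) / Σⱼ qⱼ·GRRⱼ(RR(p)). The case
frequencies are the second-order Taylor expectation
pᵢ = gᵢ(p̄) + ½gᵢ″(p̄)·δ, renormalized to the simplex. At γ = 0.5, Δ = 0
the gᵢ are exactly the HWE quadratics ((1−p)², 2p(1−p), p²), the
second-order expansion is exact, and the construction reduces to the
closed form (verified to ≤ 1e-8 in the tests). Inadmissible parameter
combinations (any frequency outside [0, 1], or δ > p̄(1−p̄)) raise hard
errors; nothing is clamped, since silent clamping would corrupt the
optimal coefficient.

**Optimal coefficient.** With dᵢ = (pᵢ − qᵢ)/n̄ᵢ and
n̄ᵢ = (r·pᵢ + s·qᵢ)/n, the maximizer of the expected-table statistic is
c* = (d₁ − d₀)/(d₂ − d₀), the affine normalization of the optimal score
vector to (0, c, 1). A bounded numerical maximizer over c ∈ [−10, 11]
(1001-point grid seed, then golden-section refinement; boundary hits
warn) serves as an independent oracle; closed form and maximizer agree to
1e-4 across a 162-point (q, RR, CV, γ) grid in the tests. The coefficient
is undefined when d₂ = d₀ (reported as an error, not a number). Risk
alleles under growing heterogeneity drive c* below 0; protective alleles
drive it above 1.

**Summary test.** W = Σⱼ wⱼZ(cⱼ) for m coefficients with positive
weights. Each Z(cⱼ) = Uⱼ² for a standardized score statistic Uⱼ; under
the null (U₁…U_m) is asymptotically multivariate normal with correlation
R estimated from the observed pooled frequencies (the same null-consistent
estimate the single-test variance uses), so W is asymptotically
Σₖ λₖχ²₁ with λₖ the eigenvalues of D^½RD^½, D = diag(w). The
eigenvalues sum to Σwⱼ (trace identity); eigenvalues below 1e-12 are
clipped to zero (duplicated coefficients give rank-deficient R). Scaling
all weights rescales W and the eigenvalues together and leaves the
p-value unchanged. With m = 1 the test is exactly the single trend test.

## Numerical evaluation of the mixture tail

The upper tail of Σλₖχ²₁ is computed by the Ruben–Farebrother expansion

P(Q > x) = Σₖ aₖ·P(χ²_{ρ+2k} > x/β),  β = λ_min,

whose coefficients aₖ are non-negative and sum to one, so the truncation
remainder is a hard bound on the absolute error; the series is terminated
at remainder < 1e-11 (cap 20,000 terms). This choice was made after
characteristic-function (Imhof) quadrature proved unable to certify better
than ~1e-4 on this integrand family with adaptive quadrature — the
integrand oscillates with only algebraic decay — while the series agrees
with an independent convolution-integral oracle to ~1e-11. Imhof
quadrature and the Satterthwaite moment-matched scaled chi-square remain
as fallbacks; the result always carries a method label
("ruben" / "imhof" / "satterthwaite") so a degraded approximation is never
silent. Mixtures with a single distinct eigenvalue are evaluated as exact
scaled chi-squares. Second derivatives gᵢ″ use central differences with
step h = 1e-4·max(1, p̄) (kept inside (0, 1)); at this step the combined
truncation and cancellation error in the case frequencies is ~1e-10,
cross-checked against symbolic differentiation in the tests.

## Simulation design

**Generators.** The primary generator draws cases ~
multinomial(n_cases, pᵢ) and controls ~ multinomial(n_controls, qᵢ) at the
model-implied frequencies — the asymptotic regime the tests address. An
individual-level alternative draws each case's relative risk from a
lognormal (or gamma) distribution moment-matched to (RR, CV_RR) and then
the genotype with probability ∝ qᵢ·GRRᵢ; it involves no Taylor
approximation and coincides with the primary generator at CV_RR = 0. At
CV_RR > 0 the two differ by design (an exact mixture versus a second-order
expectation), which is precisely what makes the individual-level generator
a robustness probe. Neither generator emulates genotyping error,
population stratification, covariates or linkage disequilibrium, so
passing tests speak to the statistical model, not to those artefacts of
real data.

**Sample size.** For the Cochran-Armitage test at level α and power 1−β,
with e = Σxᵢ(pᵢ − qᵢ) the expected score contrast, σ₀² twice the score
variance at the averaged case/control frequencies and σ₁² the sum of the
case and control score variances,

n per group = ⌈(z_{1−α/2}σ₀ + z_{1−β}σ₁)² / e²⌉,

without continuity correction. Simulation calibration at RR ∈ {1.5, 2,
0.67, 0.5} (q = 0.4, CV = 0) places empirical power within [0.77, 0.83]
of the 0.8 target at 10,000 replicates, so the uncorrected form is kept.

**Power studies** use one seeded RNG stream per scenario; all tests within
a scenario see identical replicate tables, so power differences are not
inflated by simulation noise. Optimal coefficients are computed once per
scenario from the assumed (true or working) model, never re-estimated from
each replicate. Default replication is 10,000 per scenario (binomial SE
≈ 0.004 at power 0.8); the library exposes `reps` for larger runs. The
power-curve studies in the test suite use 10,000 replicates across RR ∈
{1.25, 1.5, 2, 0.8, 0.67, 0.5} × CV_RR ∈ {0, 0.4, 1.0} at the
CV = 0-calibrated sample sizes; they verify shape properties (optimal ≥
Cochran-Armitage under heterogeneity within Monte-Carlo error, equality at
CV = 0, a > 10-point gap at RR = 1.25, CV = 1) rather than tracing full
curves.

**Two-subtype population.** The motivating example is deterministic
arithmetic: expected cases per genotype per subtype are population count ×
risk with risk(i) = baseline·factorⁱ; marginal risks and subtype case
shares follow by summation. Risks exceeding 1 after per-allele scaling are
rejected.

## Design choices and limitations

- The heterozygote coefficient is an a-priori quantity. Estimating c from
  the data being tested would make Z(ĉ) the maximum of a chi-square
  process and invalidate the χ²₁ reference; the package deliberately
  provides no such mode (the summary test is the supported route to model
  uncertainty).
- Counts must be integers; proportions are rejected rather than rescaled,
  because the variance term is a counts-based estimate.
- Genotype columns with zero margin are dropped by the Pearson test (df
  adjusts accordingly); the trend tests instead error on zero pooled score
  variance, which is the informative failure for a score test.
- The lognormal heterogeneity family is a modelling choice constrained
  only by its first two moments; gamma is offered, and other positive
  families would give slightly different case-frequency mixtures at large
  CV_RR.
- Asymptotic χ²₁/mixture references are used throughout; exact or
  permutation versions, covariate adjustment, stratified variants and
  multi-marker optimization are out of scope.
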