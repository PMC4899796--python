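import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from opttrend.tables import GenotypeCounts, observed_pooled_freqs
from opttrend.summary_test import (SummarySpec, null_mixture, summary_pvalue,
                                   summary_statistic, summary_test)
from opttrend.trend_tests import trend_chi2, trend_statistic

CHI2_95 = 3.841458820694124

def make_spec(cs, ws):
    return SummarySpec(coefficients=tuple(cs), weights=tuple(ws))


def two_component_sf_oracle(x, l1, l2):
    """P(l1*A + l2*B > x), A,B iid chi2_1, by direct convolution."""
    f = lambda a: stats.chi2.pdf(a, 1) * stats.chi2.sf((x - l1 * a) / l2, 1)
    val, _ = integrate.quad(f, 0, x / l1, epsabs=1e-13, limit=400)
    return val + stats.chi2.sf(x / l1, 1)


class TestSummaryStatistic:
    def test_single_component_reduces_to_trend(self, adprt):
        c = 0.3269
        w_stat, comps = summary_statistic(adprt, make_spec([c], [1.0]))
        assert w_stat == trend_statistic(adprt, c).statistic
        assert len(comps) == 1 and comps[0].coefficient == c

    def test_duplicated_component_doubles(self, adprt):
        w_stat, _ = summary_statistic(adprt, make_spec([0.5, 0.5], [1, 1]))
        assert w_stat == pytest.approx(
            2 * trend_statistic(adprt, 0.5).statistic, rel=1e-12)

    def test_equal_rows_gives_zero(self):
        gc = GenotypeCounts((10, 20, 10), (10, 20, 10))
        w_stat, _ = summary_statistic(gc, make_spec([0.5, 1.0, 0.0], [1, 1, 1]))
        assert w_stat == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_component_names_coefficient(self):
        gc = GenotypeCounts((5, 0, 0), (7, 0, 0))
        with pytest.raises(ValueError, match="c = 0.5"):
            summary_statistic(gc, make_spec([0.5], [1.0]))


class TestNullMixture:
    def test_single_component_is_chi2_1(self, adprt):
        lam = null_mixture(adprt, make_spec([0.3269], [1.0]))
        assert lam == pytest.approx([1.0], abs=1e-12)

    def test_duplicated_coefficients_rank_one(self, adprt):
        lam = null_mixture(adprt, make_spec([0.5, 0.5], [1, 1]))
        assert lam == pytest.approx([2.0, 0.0], abs=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(
        cs=st.lists(st.floats(-2, 3), min_size=1, max_size=4),
        ws=st.lists(st.floats(0.1, 5), min_size=4, max_size=4),
    )
    def test_trace_identity(self, cs, ws):
        table = GenotypeCounts((307, 509, 184), (359, 522, 137))
        spec = make_spec(cs, ws[: len(cs)])
        lam = null_mixture(table, spec)
        assert lam.sum() == pytest.approx(sum(spec.weights), abs=1e-8)
        assert np.all(lam >= 0)


class TestSummaryPvalue:
    def test_chi2_1_quantile(self):
        p, method = summary_pvalue(CHI2_95, [1.0])
        assert p == pytest.approx(0.05, abs=1e-10)
        assert method == "ruben"

    def test_scaled_chi2(self):
        p, _ = summary_pvalue(2 * CHI2_95, [2.0, 0.0])
        assert p == pytest.approx(0.05, abs=1e-10)

    def test_two_component_against_convolution_oracle(self):
        p, method = summary_pvalue(5.0, [1.6, 0.4])
        assert method == "ruben"
        assert p == pytest.approx(two_component_sf_oracle(5.0, 1.6, 0.4),
                                  abs=1e-9)

    def test_three_component_against_monte_carlo(self):
        lam = np.array([2.2, 0.6, 0.2])
        p, _ = summary_pvalue(7.0, lam)
        rng = np.random.default_rng(7)
        draws = (rng.chisquare(1, (500_000, 3)) * lam).sum(axis=1)
        mc = (draws > 7.0).mean()
        se = np.sqrt(mc * (1 - mc) / 500_000)
        assert abs(p - mc) < 3 * se

    def test_all_zero_eigenvalues_is_error(self):
        with pytest.raises(ValueError):
            summary_pvalue(1.0, [0.0, 0.0])


class TestSummaryTest:
    def test_weight_scaling_invariance(self, adprt):
        r1 = summary_test(adprt, make_spec([0.8, 0.2], [1, 1]))
        r2 = summary_test(adprt, make_spec([0.8, 0.2], [3, 3]))
        assert r2.statistic == pytest.approx(3 * r1.statistic, rel=1e-12)
        assert np.asarray(r2.eigenvalues) == pytest.approx(
            3 * np.asarray(r1.eigenvalues), rel=1e-9)
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-10)

    def test_discussion_spec_composition(self, adprt):
        res = summary_test(adprt, make_spec([0.5, 1.0, 0.0], [1, 1, 1]))
        expected = sum(trend_statistic(adprt, c).statistic
                       for c in (0.5, 1.0, 0.0))
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert 0 < res.p_value < 1
        assert sum(res.eigenvalues) == pytest.approx(3.0, abs=1e-8)

    def test_null_agrees_with_monte_carlo(self, adprt):
        """Mixture p-value vs a pooled-multinomial Monte-Carlo null."""
        spec = make_spec([0.8, 0.2], [1, 1])
        res = summary_test(adprt, spec)
        nbar = observed_pooled_freqs(adprt)
        rng = np.random.default_rng(41)
        reps = 50_000
        cases = rng.multinomial(adprt.r, nbar, size=reps).astype(float)
        controls = rng.multinomial(adprt.s, nbar, size=reps).astype(float)
        w_null = np.zeros(reps)
        for c, w in zip(spec.coefficients, spec.weights):
            z = trend_chi2(cases, controls, c)
            w_null += w * np.where(np.isfinite(z), z, 0.0)
        mc = (w_null >= res.statistic).mean()
        se = max(np.sqrt(mc * (1 - mc) / reps), 1e-6)
        assert abs(res.p_value - mc) < 3 * se + 5e-4

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            make_spec([], [])
        with pytest.raises(ValueError):
            make_spec([0.5], [0.0])
        with pytest.raises(ValueError):
            make_spec([0.5, 1.0], [1.0])
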