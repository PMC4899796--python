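import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from opttrend.hetero_model import (EffectModel, ModelAdmissibilityError,
                                   case_allele_param, case_freq_curve,
                                   case_freqs_general, case_freqs_special,
                                   control_freqs, expected_frequencies,
                                   pooled_freqs_expected)

model_strategy = st.builds(
    EffectModel,
    q=st.floats(0.05, 0.95),
    delta=st.just(0.0),
    rr=st.floats(0.2, 5.0),
    cv_rr=st.floats(0.0, 1.5),
    gamma=st.floats(0.0, 1.0),
)


class TestControlFreqs:
    @pytest.mark.parametrize("q, delta, expected", [
        (0.4, 0.0, (0.36, 0.48, 0.16)),
        (0.5, 0.0, (0.25, 0.50, 0.25)),
        (0.4, 0.05, (0.41, 0.38, 0.21)),
    ])
    def test_values(self, q, delta, expected):
        assert control_freqs(q, delta) == pytest.approx(expected, abs=1e-12)

    def test_sums_to_one_identically(self):
        f = control_freqs(0.123, -0.01)
        assert f.sum() == pytest.approx(1.0, abs=1e-15)

    def test_inadmissible_delta(self):
        with pytest.raises(ModelAdmissibilityError, match="Delta"):
            control_freqs(0.1, -0.02)  # q^2 + Delta < 0


class TestCaseAlleleParam:
    def test_worked_example(self):
        par = case_allele_param(0.4, 1.25, 0.4)
        assert par.p_bar == pytest.approx(0.5 / 1.1, abs=1e-12)
        assert par.delta_var == pytest.approx(
            (par.p_bar * (1 - par.p_bar) * 0.4) ** 2, abs=1e-15)
        assert round(par.p_bar, 2) == 0.45
        assert round(par.delta_var, 4) == 0.0098

    def test_null_effect_leaves_q(self):
        assert case_allele_param(0.37, 1.0, 0.9).p_bar == pytest.approx(0.37)

    def test_homogeneous_strong_effect(self):
        par = case_allele_param(0.4, 2.0, 0.0)
        assert par.p_bar == pytest.approx(0.8 / 1.4, abs=1e-12)
        assert par.delta_var == 0.0


class TestCaseFreqsSpecial:
    def test_worked_example_full_precision(self):
        f = case_freqs_special(0.4, 1.25, 0.4)
        assert f == pytest.approx((0.307356, 0.476197, 0.216447), abs=5e-7)
        assert tuple(np.round(f, 2)) == (0.31, 0.48, 0.22)

    def test_null_degenerates_to_controls(self):
        assert case_freqs_special(0.4, 1.0, 0.0) == \
            pytest.approx(control_freqs(0.4), abs=1e-15)


class TestCaseFreqsGeneral:
    @pytest.mark.parametrize("rr, cv", [(1.25, 0.4), (2.0, 0.0), (0.67, 1.0),
                                        (1.5, 0.8)])
    def test_reduces_to_special_at_dosage_hwe(self, rr, cv):
        m = EffectModel(q=0.4, delta=0.0, rr=rr, cv_rr=cv, gamma=0.5)
        assert case_freqs_general(m) == \
            pytest.approx(case_freqs_special(0.4, rr, cv), abs=1e-8)

    def test_homogeneous_recessive_is_direct_normalization(self):
        m = EffectModel(q=0.4, rr=2.0, cv_rr=0.0, gamma=0.0)
        target = np.array([0.36, 0.48, 0.16 * 4.0])
        assert case_freqs_general(m) == pytest.approx(target / target.sum(),
                                                      abs=1e-12)

    def test_homogeneous_dominant_is_direct_normalization(self):
        m = EffectModel(q=0.4, rr=2.0, cv_rr=0.0, gamma=1.0)
        target = np.array([0.36, 0.48 * 4.0, 0.16 * 4.0])
        assert case_freqs_general(m) == pytest.approx(target / target.sum(),
                                                      abs=1e-12)
        assert case_freqs_general(m) == pytest.approx((0.1233, 0.6575, 0.2192),
                                                      abs=5e-5)

    @settings(max_examples=80, deadline=None)
    @given(m=model_strategy)
    def test_simplex_invariants(self, m):
        try:
            f = case_freqs_general(m)
        except ModelAdmissibilityError:
            return  # inadmissible corner: rejected, never clamped
        assert abs(f.sum() - 1.0) < 1e-12
        assert np.all(f >= 0) and np.all(f <= 1)

    def test_pbar_monotone_in_rr_and_q(self):
        pbars = [case_allele_param(0.4, rr, 0.0).p_bar
                 for rr in (0.5, 0.8, 1.0, 1.5, 2.0, 4.0)]
        assert np.all(np.diff(pbars) > 0)
        pbars_q = [case_allele_param(q, 1.5, 0.0).p_bar
                   for q in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(pbars_q) > 0)

    @pytest.mark.parametrize("q, delta, gamma, pbar", [
        (0.4, 0.0, 0.5, 0.4545), (0.3, 0.02, 0.0, 0.35),
        (0.5, -0.03, 1.0, 0.6), (0.2, 0.0, 0.3, 0.25),
        (0.6, 0.01, 0.8, 0.55),
    ])
    def test_second_derivative_against_symbolic(self, q, delta, gamma, pbar):
        """The finite-difference g'' agrees with a sympy symbolic derivative."""
        p = sp.symbols("p", positive=True)
        qf = [(1 - q) ** 2 + delta, 2 * q * (1 - q) - 2 * delta, q**2 + delta]
        rr = p * (1 - q) / (q * (1 - p))
        w = [f * g for f, g in zip(qf, [1, rr ** (2 * gamma), rr**2])]
        tot = sum(w)
        sym_d2 = np.array([float(sp.diff(wi / tot, p, 2).subs(p, pbar))
                           for wi in w])
        h = 1e-4
        num_d2 = (case_freq_curve(pbar + h, q, delta, gamma)
                  - 2 * case_freq_curve(pbar, q, delta, gamma)
                  + case_freq_curve(pbar - h, q, delta, gamma)) / h**2
        assert np.max(np.abs(sym_d2 - num_d2)) < 1e-6

    def test_inadmissible_model_is_hard_error(self):
        with pytest.raises(ModelAdmissibilityError):
            EffectModel(q=0.5, rr=0.0)
        with pytest.raises(ModelAdmissibilityError):
            EffectModel(q=1.2, rr=1.5)


class TestPooledFreqs:
    def test_worked_example_design(self, worked_model):
        freqs = expected_frequencies(worked_model, 1000, 1018)
        assert freqs.pooled == pytest.approx((0.33391, 0.47812, 0.18797),
                                             abs=5e-6)

    def test_equal_arms_identical_freqs(self):
        f = control_freqs(0.3)
        assert pooled_freqs_expected(f, f, 250, 250) == pytest.approx(f)

    def test_zero_arm_is_error(self):
        f = control_freqs(0.3)
        with pytest.raises(ModelAdmissibilityError):
            pooled_freqs_expected(f, f, 100, 0)
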