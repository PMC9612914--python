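"""Power-law fitting, analytic inversion, composition and evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mnrelations as mn
from mnrelations.powerlaw import FitError, LawError, PowerLaw


def _ols_oracle(x, y):
    """Normal-equations OLS of ln y on ln x (spreadsheet-style sums)."""
    lx, ly = np.log(x), np.log(y)
    n = len(lx)
    sx, sy = lx.sum(), ly.sum()
    sxx, sxy = (lx * lx).sum(), (lx * ly).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return math.exp(intercept), slope


class TestFit:
    def test_exact_power_data(self):
        b = np.array([1.0, 2.0, 4.0, 8.0])
        law = mn.fit_power(b, 2.0 * b**3)
        assert np.isclose(law.k, 2.0) and np.isclose(law.a, 3.0)
        assert np.isclose(law.r2, 1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 30)
            x = rng.uniform(0.5, 50, n)
            y = rng.uniform(0.5, 50, n)
            law = mn.fit_power(x, y)
            k0, a0 = _ols_oracle(x, y)
            assert np.isclose(law.a, a0, rtol=1e-10)
            assert np.isclose(law.k, k0, rtol=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(FitError):
            mn.fit_power([1, 2], [1, 2])
        with pytest.raises(FitError):
            mn.fit_power([2, 2, 2], [1, 2, 3])
        with pytest.raises(FitError):
            mn.fit_power([1, 2, -3], [1, 2, 3])

    @given(
        k=st.floats(0.01, 100),
        a=st.floats(-4, 4).filter(lambda v: abs(v) > 1e-3),
    )
    def test_exact_recovery_property(self, k, a):
        x = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        law = mn.fit_power(x, k * x**a)
        assert np.isclose(law.a, a, rtol=1e-9, atol=1e-12)
        assert np.isclose(law.k, k, rtol=1e-9)

    def test_r2_symmetric_under_axis_swap(self, rng):
        x = rng.uniform(1, 10, 40)
        y = 3.0 * x**-1.5 * np.exp(rng.normal(0, 0.3, 40))
        assert np.isclose(
            mn.fit_power(x, y).r2, mn.fit_power(y, x).r2, rtol=1e-12
        )

    def test_ci_coverage_near_nominal(self, rng):
        """95% CI on the exponent covers the truth in ~95% of replicates."""
        hits = 0
        reps = 500
        for _ in range(reps):
            x = rng.uniform(1, 10, 100)
            y = 2.0 * x**1.7 * np.exp(rng.normal(0, 0.4, 100))
            lo, hi = mn.fit_power(x, y).a_ci
            hits += lo <= 1.7 <= hi
        assert abs(hits / reps - 0.95) <= 0.03

    def test_serialization_roundtrip(self):
        law = mn.fit_power([1, 2, 4, 9], [3, 5, 11, 20],
                           prop_x="S_MN", prop_y="ACV")
        back = PowerLaw.from_json(law.to_json())
        assert back == law


class TestInvert:
    def test_identity_law(self):
        law = PowerLaw("A", "B", k=1.0, a=1.0)
        inv = mn.invert(law)
        assert inv.k == 1.0 and inv.a == 1.0

    def test_published_resistance_inverse(self):
        # R = 9.6e5 * S^-2.43  ->  S ~= 2.9e2 * R^-0.41
        law = PowerLaw("R", "S_MN", k=9.6e5, a=-2.43)
        inv = mn.invert(law)
        assert np.isclose(inv.k, 2.9e2, rtol=0.01)
        assert np.isclose(inv.a, -0.41, atol=0.005)

    def test_involution_to_machine_precision(self):
        law = PowerLaw("A", "B", k=5.0, a=-1.7, a_ci=(-1.9, -1.5),
                       k_ci=(4.0, 6.0), r2=0.5, p=1e-6, n=40)
        back = mn.invert(mn.invert(law))
        assert np.isclose(back.k, law.k, rtol=1e-14)
        assert np.isclose(back.a, law.a, rtol=1e-14)
        assert np.allclose(back.a_ci, law.a_ci, rtol=1e-14)

    def test_zero_exponent_not_invertible(self):
        with pytest.raises(LawError):
            mn.invert(PowerLaw("A", "B", k=1.0, a=0.0))

    def test_statistics_carried_over(self):
        law = PowerLaw("A", "B", k=2.0, a=0.5, r2=0.4, p=1e-4, n=33)
        inv = mn.invert(law)
        assert (inv.r2, inv.p, inv.n) == (0.4, 1e-4, 33)


class TestCompose:
    def test_identity_chain(self):
        a = PowerLaw("A", "S", k=1.0, a=1.0)
        s = PowerLaw("S", "B", k=1.0, a=1.0)
        out = mn.compose(a, s)
        assert out.k == 1.0 and out.a == 1.0
        assert out.pair == ("A", "B")

    def test_published_rheobase_resistance_chain(self):
        # Ith = 9.4e-4 * S^2.5 composed with S = 2.9e2 * R^-0.4
        ith = PowerLaw("I_th", "S_MN", k=9.4e-4, a=2.5)
        s_of_r = PowerLaw("S_MN", "R", k=2.9e2, a=-0.4)
        out = mn.compose(ith, s_of_r)
        assert np.isclose(out.k, 9.4e-4 * 2.9e2**2.5, rtol=1e-12)
        assert np.isclose(out.k, 1.35e3, rtol=0.01)
        assert np.isclose(out.a, -1.0)

    def test_compose_with_own_inverse_is_identity(self):
        law = PowerLaw("A", "B", k=7.3, a=-2.1)
        out = mn.compose(law, mn.invert(law))
        assert np.isclose(out.k, 1.0, rtol=1e-12)
        assert np.isclose(out.a, 1.0, rtol=1e-12)

    def test_associativity(self):
        f = PowerLaw("A", "B", k=2.0, a=1.5)
        g = PowerLaw("B", "C", k=0.3, a=-0.7)
        h = PowerLaw("C", "D", k=5.0, a=2.0)
        left = mn.compose(mn.compose(f, g), h)
        right = mn.compose(f, mn.compose(g, h))
        assert np.isclose(left.k, right.k, rtol=1e-12)
        assert np.isclose(left.a, right.a, rtol=1e-12)

    def test_variable_mismatch(self):
        with pytest.raises(LawError):
            mn.compose(PowerLaw("A", "S", k=1, a=1),
                       PowerLaw("B", "C", k=1, a=1))

    def test_derived_laws_carry_no_statistics(self):
        f = PowerLaw("A", "B", k=2.0, a=1.5, r2=0.5, p=1e-3, n=20)
        g = PowerLaw("B", "C", k=0.3, a=-0.7, r2=0.6, p=1e-4, n=50)
        out = mn.compose(f, g)
        assert out.r2 is None and out.p is None and out.n == 20


class TestEvaluate:
    def test_scalar(self):
        assert mn.evaluate(PowerLaw("A", "B", k=2, a=3), 2.0) == 16.0

    def test_published_conduction_velocity_constants(self):
        law = PowerLaw("ACV", "D_soma", k=8.1e4, a=0.69, space="absolute")
        assert np.isclose(mn.evaluate(law, 5e-5), 87.0, rtol=0.01)

    def test_vector_preserves_order(self):
        law = PowerLaw("A", "B", k=1.0, a=2.0)
        out = mn.evaluate(law, [3.0, 1.0, 2.0])
        assert np.allclose(out, [9.0, 1.0, 4.0])

    def test_domain_error(self):
        with pytest.raises(LawError):
            mn.evaluate(PowerLaw("A", "B", k=1, a=1), [1.0, -2.0])
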