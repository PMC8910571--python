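"""Closed-form kinetics: allometry, micro/macro conversion, half-lives,
concentration/amount curves, tumor volume."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import aptapk as ap
from aptapk.pk import macro_constants

from conftest import random_individual


def ode_concentration(ind: ap.IndividualParams, dose: float, times) -> np.ndarray:
    """Independent oracle: numerically integrate the two-compartment ODEs."""
    mic = ap.micro_from_primary(ind)

    def rhs(_, a):
        a1, a2 = a
        return [-(mic.k10 + mic.k12) * a1 + mic.k21 * a2,
                mic.k12 * a1 - mic.k21 * a2]

    t = np.atleast_1d(np.asarray(times, dtype=float))
    sol = solve_ivp(rhs, (0.0, float(t.max()) if t.max() > 0 else 1.0),
                    [dose, 0.0], t_eval=t, method="LSODA",
                    rtol=1e-11, atol=1e-14)
    return sol.y[0] / ind.v1


class TestAllometry:
    def test_identity_at_reference_weight(self, ref_pop):
        ind = ap.apply_allometry(ref_pop, 25.0)
        assert ind.cl == pytest.approx(3.29)
        assert ind.v1 == pytest.approx(81.77)
        assert ind.q == pytest.approx(1.78)
        assert ind.v2 == pytest.approx(182.2)

    def test_doubling_body_weight(self, ref_pop):
        ind = ap.apply_allometry(ref_pop, 50.0)
        assert ind.cl == pytest.approx(3.29 * 2**0.75, rel=1e-12)
        assert ind.v1 == pytest.approx(81.77 * 2.0, rel=1e-12)

    def test_zero_exponents_are_inert(self):
        pop = ap.PopPKParams.reference(exp_cl=0.0, exp_v=0.0)
        for bw in (10.0, 25.0, 80.0):
            ind = ap.apply_allometry(pop, bw)
            assert (ind.cl, ind.v1, ind.q, ind.v2) == (3.29, 81.77, 1.78, 182.2)

    @pytest.mark.parametrize("bw", [0.0, -5.0])
    def test_nonpositive_weight_rejected(self, ref_pop, bw):
        with pytest.raises(ValueError):
            ap.apply_allometry(ref_pop, bw)

    @given(bw=st.floats(1.0, 100.0), factor=st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity(self, bw, factor):
        pop = ap.PopPKParams.reference()
        a = ap.apply_allometry(pop, bw)
        b = ap.apply_allometry(pop, bw * factor)
        assert b.cl == pytest.approx(a.cl * factor**0.75, rel=1e-12)
        assert b.q == pytest.approx(a.q * factor**0.75, rel=1e-12)
        assert b.v1 == pytest.approx(a.v1 * factor, rel=1e-12)
        assert b.v2 == pytest.approx(a.v2 * factor, rel=1e-12)


class TestMicroMacro:
    def test_micro_constants(self, ref_ind):
        mic = ap.micro_from_primary(ref_ind)
        assert mic.k10 == pytest.approx(3.29 / 81.77, rel=1e-12)
        assert mic.k10 == pytest.approx(0.04024, rel=1e-3)
        assert mic.k21 == pytest.approx(1.78 / 182.2, rel=1e-12)
        assert mic.k21 == pytest.approx(0.009769, rel=1e-3)

    def test_one_compartment_reduction(self):
        ind = ap.IndividualParams(cl=3.29, v1=81.77, q=0.0, v2=0.0)
        mic = ap.micro_from_primary(ind)
        assert mic.k12 == 0.0 and mic.k21 == 0.0
        mac = macro_constants(ind, 40.0)
        assert mac.alpha == pytest.approx(mic.k10)
        assert mac.coef_b == 0.0
        assert mac.coef_a == pytest.approx(40.0 / 81.77)

    def test_rates_match_characteristic_polynomial(self, ref_ind):
        mic = ap.micro_from_primary(ref_ind)
        mac = ap.macro_from_micro(mic, 40.0, ref_ind.v1)
        # oracle: numpy root-finder on the characteristic quadratic
        roots = np.sort(np.roots(
            [1.0, -(mic.k10 + mic.k12 + mic.k21), mic.k10 * mic.k21]))
        assert mac.beta == pytest.approx(roots[0], rel=1e-10)
        assert mac.alpha == pytest.approx(roots[1], rel=1e-10)
        assert mac.alpha == pytest.approx(0.0658, rel=1e-3)
        assert mac.beta == pytest.approx(0.00597, rel=1e-3)

    def test_intercepts_sum_to_initial_concentration(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ind = random_individual(rng)
            mac = macro_constants(ind, 40.0)
            assert mac.coef_a + mac.coef_b == pytest.approx(40.0 / ind.v1,
                                                            rel=1e-10)

    def test_macro_micro_roundtrip(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            ind = random_individual(rng)
            mic = ap.micro_from_primary(ind)
            mac = ap.macro_from_micro(mic, 40.0, ind.v1)
            back = ap.micro_from_macro(mac)
            assert back.k10 == pytest.approx(mic.k10, rel=1e-10)
            assert back.k12 == pytest.approx(mic.k12, rel=1e-10)
            assert back.k21 == pytest.approx(mic.k21, rel=1e-10)


class TestHalfLives:
    def test_published_disposition_half_lives(self, ref_ind):
        mac = macro_constants(ref_ind, 40.0)
        th_fast, th_slow = ap.half_lives(mac)
        assert th_fast == pytest.approx(10.52, rel=0.01)
        assert th_slow == pytest.approx(115.8, rel=0.01)
        assert th_fast <= th_slow

    def test_unit_rate(self):
        mac = ap.MacroConstants(alpha=math.log(2), beta=math.log(2),
                                coef_a=1.0, coef_b=0.0)
        assert ap.half_lives(mac)[0] == pytest.approx(1.0)

    def test_one_compartment_half_life(self):
        ind = ap.IndividualParams(cl=3.29, v1=81.77, q=0.0, v2=0.0)
        mac = macro_constants(ind, 40.0)
        _, th = ap.half_lives(mac)
        assert th == pytest.approx(math.log(2) * 81.77 / 3.29, rel=1e-12)
        assert th == pytest.approx(17.2, rel=1e-2)


class TestConcentration:
    def test_bolus_initial_condition(self, ref_ind):
        assert ap.concentration(ref_ind, 40.0, 0.0) == pytest.approx(
            40.0 / 81.77, rel=1e-12)

    def test_value_at_60min_vs_ode(self, ref_ind):
        c60 = ap.concentration(ref_ind, 40.0, 60.0)
        assert c60 == pytest.approx(0.0305, rel=2e-3)
        assert c60 == pytest.approx(ode_concentration(ref_ind, 40.0, 60.0)[0],
                                    rel=1e-6)

    def test_matches_ode_on_random_parameters(self):
        rng = np.random.default_rng(3)
        times = np.array([1.0, 10.0, 60.0, 240.0, 1440.0])
        for _ in range(50):
            ind = random_individual(rng)
            closed = ap.concentration(ind, 40.0, times)
            numeric = ode_concentration(ind, 40.0, times)
            # atol floor: the integrator cannot resolve below ~1e-14 of C(0)
            np.testing.assert_allclose(closed, numeric, rtol=1e-6,
                                       atol=1e-14 * 40.0 / ind.v1)

    def test_strictly_decreasing(self, ref_ind):
        t = np.linspace(0, 2880, 400)
        c = ap.concentration(ref_ind, 40.0, t)
        assert np.all(np.diff(c) < 0)

    def test_monoexponential_half_life(self):
        ind = ap.IndividualParams(cl=3.29, v1=81.77, q=0.0, v2=0.0)
        t_half = math.log(2) * ind.v1 / ind.cl
        assert ap.concentration(ind, 40.0, t_half) == pytest.approx(
            0.5 * 40.0 / 81.77, rel=1e-12)

    def test_negative_time_rejected(self, ref_ind):
        with pytest.raises(ValueError):
            ap.concentration(ref_ind, 40.0, -1.0)

    def test_one_compartment_limit(self, ref_ind):
        """As Q -> 0 the biexponential converges to the monoexponential."""
        t = np.array([5.0, 30.0, 120.0])
        mono = 40.0 / ref_ind.v1 * np.exp(-(ref_ind.cl / ref_ind.v1) * t)
        for q in (1e-3, 1e-5, 1e-7):
            ind = ap.IndividualParams(cl=ref_ind.cl, v1=ref_ind.v1, q=q,
                                      v2=ref_ind.v2)
            c = ap.concentration(ind, 40.0, t)
            err = np.max(np.abs(c - mono) / mono)
            assert err < 50 * q  # vanishes linearly with q


class TestAmounts:
    def test_initial_and_asymptotic(self, ref_ind):
        c, p, e = ap.amounts(ref_ind, 40.0, 0.0)
        assert (c, p, e) == pytest.approx((40.0, 0.0, 0.0), abs=1e-10)
        c, p, e = ap.amounts(ref_ind, 40.0, 1e6)
        assert e == pytest.approx(40.0, rel=1e-6)

    def test_components_match_ode(self, ref_ind):
        mic = ap.micro_from_primary(ref_ind)

        def rhs(_, a):
            return [-(mic.k10 + mic.k12) * a[0] + mic.k21 * a[1],
                    mic.k12 * a[0] - mic.k21 * a[1]]

        sol = solve_ivp(rhs, (0, 30.0), [40.0, 0.0], t_eval=[30.0],
                        method="LSODA", rtol=1e-11, atol=1e-14)
        c, p, e = ap.amounts(ref_ind, 40.0, 30.0)
        assert c == pytest.approx(sol.y[0][0], rel=1e-7)
        assert p == pytest.approx(sol.y[1][0], rel=1e-7)
        assert e == pytest.approx(40.0 - sol.y.sum(), rel=1e-6)

    def test_mass_balance_random(self):
        rng = np.random.default_rng(9)
        t = np.array([0.0, 1.0, 15.0, 120.0, 1440.0])
        for _ in range(100):
            ind = random_individual(rng)
            c, p, e = ap.amounts(ind, 40.0, t)
            np.testing.assert_allclose(c + p + e, 40.0, atol=1e-8 * 40.0)


class TestTumorVolume:
    @pytest.mark.parametrize(
        "w, l, expected", [(10.0, 10.0, 500.0), (0.0, 7.0, 0.0), (5.0, 10.0, 125.0)]
    )
    def test_formula(self, w, l, expected):
        assert ap.tumor_volume(ap.TumorDims(w, l)) == pytest.approx(expected)

    def test_caliper_convention(self):
        with pytest.raises(ValueError):
            ap.TumorDims(width_w=11.0, length_l=10.0)
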