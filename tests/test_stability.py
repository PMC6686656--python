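"""Next-generation R0, Jacobians, cubic coefficients and Routh-Hurwitz."""

import numpy as np
import pytest
from hypothesis import given
from numpy.polynomial import polynomial as P

from conftest import finite_difference_jacobian, params_strategy, random_params
from sittr import (Classification, ModelParams, State, classify_free_equilibrium,
                   cubic_coefficients, divergence, free_equilibrium, jacobian,
                   next_generation, rhs, routh_hurwitz)

#: R0 for the three presets at S0 = 15, frozen after computing the
#: closed form and the numeric trace(F K^-1) agree to 1e-12 relative.
FROZEN_R0 = {"fig7": 0.2305706727698531,
             "fig8": 0.32406399121493457,
             "fig9": 0.24360852265434474}


class TestNextGeneration:
    @given(params=params_strategy)
    def test_closed_form_K_inverse_matches_numeric(self, params):
        ngd = next_generation(params, S0=12.0)
        assert np.max(np.abs(ngd.K @ ngd.K_inv - np.eye(3))) <= 1e-10
        np.testing.assert_allclose(ngd.K_inv, ngd.K_inv_numeric,
                                   rtol=1e-10, atol=1e-13)

    @given(params=params_strategy)
    def test_R0_equals_trace_of_F_K_inverse(self, params):
        ngd = next_generation(params, S0=12.0)
        trace = float(np.trace(ngd.F @ ngd.K_inv_numeric))
        assert abs(ngd.R0 - trace) <= 1e-12 * max(1.0, abs(ngd.H))
        assert ngd.R0 == ngd.H

    def test_no_relapse_means_no_reproduction(self, fig7):
        kwargs = fig7.params.as_dict()
        kwargs["beta"] = 0.0
        ngd = next_generation(ModelParams(**kwargs), S0=15.0)
        assert np.all(ngd.F == 0.0)
        assert ngd.R0 == 0.0

    def test_empty_population_means_no_reproduction(self, fig7):
        assert next_generation(fig7.params, S0=0.0).R0 == 0.0

    def test_F_structure_single_relapse_row(self, fig7):
        ngd = next_generation(fig7.params, S0=15.0)
        p = fig7.params
        np.testing.assert_array_equal(
            ngd.F[0], [0.0, p.beta * p.eta * 15.0, p.beta * p.zeta * 15.0])
        assert np.all(ngd.F[1:] == 0.0)

    @pytest.mark.parametrize("preset", sorted(FROZEN_R0))
    def test_preset_reproduction_numbers(self, preset, request):
        sc = request.getfixturevalue(preset)
        assert next_generation(sc.params, 15.0).R0 == pytest.approx(
            FROZEN_R0[preset], rel=1e-12)

    def test_singular_K_rejected(self):
        p = ModelParams(alpha=0.0, gamma=0.1, beta=0.1, lam=0.0, b=0.5,
                        eta=0.1, zeta=0.1, mu1=0.5, mu2=0.5, u1=0.5, u2=0.5)
        with pytest.raises(ZeroDivisionError, match="singular"):
            next_generation(p, 10.0)


class TestJacobian:
    def test_matches_finite_differences_on_random_states(self, fig7):
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.uniform(0, 200, size=6)
            J = jacobian(y, fig7.params)
            fd = finite_difference_jacobian(lambda v: rhs(v, fig7.params), y)
            np.testing.assert_allclose(J, fd, rtol=1e-5, atol=1e-4)

    def test_relapse_entry_at_free_equilibrium(self, fig7):
        S0 = 15.0
        J = jacobian(free_equilibrium(S0), fig7.params)
        p = fig7.params
        assert J[0, 2] == -p.beta * p.eta * S0  # dS'/dT1
        assert J[1, 3] == p.beta * p.zeta * S0  # dI'/dT2

    @given(params=params_strategy)
    def test_trace_equals_divergence(self, params):
        state = State(5, 4, 3, 2, 15, 1)
        assert float(np.trace(jacobian(state, params))) == pytest.approx(
            divergence(state, params), rel=1e-13, abs=1e-13)


class TestCubicCoefficients:
    def test_leading_coefficient_is_one(self, fig7):
        assert cubic_coefficients(fig7.params, 15.0)[0] == 1.0

    def test_a1_closed_form(self, fig7):
        p = fig7.params
        a1 = cubic_coefficients(p, 15.0)[1]
        assert a1 == pytest.approx(3 * p.alpha + p.lam + p.mu1 + p.mu2, rel=1e-14)

    def test_no_relapse_closed_forms(self, fig7):
        kwargs = fig7.params.as_dict()
        kwargs["beta"] = 0.0
        p = ModelParams(**kwargs)
        d1, d2, d3 = p.alpha + p.lam, p.alpha + p.mu1, p.alpha + p.mu2
        _, _, a2, a3 = cubic_coefficients(p, 15.0)
        assert a2 == pytest.approx(d1 * d2 + d3 * d1 + d2 * d3, rel=1e-14)
        assert a3 == pytest.approx(d1 * d2 * d3, rel=1e-14)

    @given(params=params_strategy)
    def test_matches_characteristic_polynomial_of_infected_block(self, params):
        # Independent oracle: the (I, T1, T2) block of the Q0 Jacobian,
        # its characteristic polynomial computed numerically.
        S0 = 9.0
        J3 = jacobian(free_equilibrium(S0), params)[1:4, 1:4]
        # det(xI - J3) = x^3 + a1 x^2 + a2 x + a3
        charpoly = np.poly(J3)  # leading-first coefficients
        a = cubic_coefficients(params, S0)
        scale = max(1.0, float(np.max(np.abs(charpoly))))
        np.testing.assert_allclose(a, charpoly, rtol=1e-8, atol=1e-8 * scale)


class TestRouthHurwitz:
    def test_triple_root_at_minus_one_is_stable(self):
        rh = routh_hurwitz((1.0, 3.0, 3.0, 1.0))
        assert rh.all_roots_negative_real_part
        assert rh.delta3 == rh.delta2 * 1.0

    def test_unstable_cubic_detected(self):
        # roots of x^3 + x^2 + x + 3 include a positive-real-part pair
        rh = routh_hurwitz((1.0, 1.0, 1.0, 3.0))
        assert not rh.all_roots_negative_real_part
        roots = np.roots([1.0, 1.0, 1.0, 3.0])
        assert np.max(roots.real) > 0

    def test_nonpositive_leading_coefficient_rejected(self):
        with pytest.raises(ValueError, match="a0"):
            routh_hurwitz((0.0, 1.0, 1.0, 1.0))

    def test_stable_cubics_built_from_negative_roots(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            if rng.random() < 0.5:
                roots = -rng.uniform(0.05, 5.0, size=3)
            else:
                re, im = -rng.uniform(0.05, 5.0), rng.uniform(0.05, 5.0)
                roots = np.array([complex(re, im), complex(re, -im),
                                  -rng.uniform(0.05, 5.0)])
            coeffs = np.real(P.polyfromroots(roots))[::-1]  # leading first
            assert routh_hurwitz(tuple(coeffs)).all_roots_negative_real_part

    def test_equivalent_to_numeric_root_signs(self):
        rng = np.random.default_rng(37)
        for _ in range(500):
            coeffs = (1.0, *rng.uniform(-4.0, 4.0, size=3))
            roots = np.roots(coeffs)
            expected = bool(np.all(roots.real < 0))
            assert routh_hurwitz(coeffs).all_roots_negative_real_part == expected


class TestClassification:
    def test_growth_exceeds_dropout_stable_not_asymptotic(self, fig7):
        report = classify_free_equilibrium(fig7.params, 15.0)
        assert report.R0 < 1
        assert report.classification is Classification.STABLE_NOT_ASYMPTOTIC

    def test_balanced_rates_unstable(self, fig7):
        kwargs = fig7.params.as_dict()
        kwargs["gamma"] = kwargs["alpha"]
        report = classify_free_equilibrium(ModelParams(**kwargs), 15.0)
        assert report.R0 < 1
        assert report.classification is Classification.UNSTABLE

    def test_dropout_exceeds_growth_asymptotically_stable(self, fig7):
        kwargs = fig7.params.as_dict()
        kwargs["gamma"] = 0.1  # below alpha = 0.3
        report = classify_free_equilibrium(ModelParams(**kwargs), 15.0)
        assert report.R0 < 1
        assert report.classification is Classification.ASYMPTOTICALLY_STABLE
        assert np.max(report.eigenvalues.real) <= 0
        # the cubic's three roots are strictly negative: drop the known
        # explicit eigenvalues -alpha (x2) and gamma - alpha
        cubic_roots = np.roots(report.cubic_coeffs)
        assert np.max(cubic_roots.real) < 0

    def test_reproduction_number_above_one_not_applicable(self, fig7):
        kwargs = fig7.params.as_dict()
        kwargs["beta"] = 2.0  # pushes R0 above 1 at S0 = 15
        report = classify_free_equilibrium(ModelParams(**kwargs), 15.0)
        assert report.R0 >= 1
        assert report.classification is Classification.NOT_APPLICABLE

    def test_explicit_eigenvalues_present(self, fig7):
        report = classify_free_equilibrium(fig7.params, 15.0)
        ev = report.eigenvalues
        p = fig7.params
        assert np.min(np.abs(ev - (-p.alpha))) <= 1e-8
        assert np.min(np.abs(ev - (p.gamma - p.alpha))) <= 1e-8
        # deterministic ordering: descending real part
        assert np.all(np.diff(ev.real) <= 1e-12)

    def test_hurwitz_identity_delta3(self, fig7):
        report = classify_free_equilibrium(fig7.params, 15.0)
        a3 = report.cubic_coeffs[3]
        assert report.delta3 == pytest.approx(a3 * report.delta2, rel=1e-13)

    def test_subunit_reproduction_number_forces_positive_coefficients(self):
        # Whenever R0 < 1: a2 > 0, a3 > 0 and a1 a2 - a0 a3 > 0, so the
        # cubic factor is Hurwitz-stable and the verdict rests entirely
        # on sign(gamma - alpha).
        rng = np.random.default_rng(41)
        checked = 0
        while checked < 200:
            p = random_params(rng)
            S0 = rng.uniform(0.0, 50.0)
            try:
                ngd = next_generation(p, S0)
            except ZeroDivisionError:
                continue
            if ngd.R0 >= 1:
                continue
            _, a1, a2, a3 = cubic_coefficients(p, S0)
            assert a1 > 0 and a2 > 0 and a3 > 0
            assert a1 * a2 - a3 > 0
            checked += 1
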