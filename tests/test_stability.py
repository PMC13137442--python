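"""Reproduction numbers, Jacobian spectra, Routh–Hurwitz determinants
and the empirical global-convergence check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snitr import (
    CharPoly,
    char_poly,
    classify_stability,
    global_convergence_check,
    hurwitz_determinants,
    jacobian,
    next_generation_matrices,
    reproduction_numbers,
)
from snitr.params import SnitrParameters
from snitr.presets import PRESETS

from test_model import valid_params_strategy


class TestReproductionNumbers:
    def test_published_threshold_values(self):
        r = reproduction_numbers(PRESETS["infected_endemic"])
        assert round(r.r01, 2) == 0.27
        assert r.r03 == pytest.approx(0.25 / 0.33, rel=1e-12)
        r = reproduction_numbers(PRESETS["neglected_endemic"])
        assert round(r.r01, 1) == 2.6
        r = reproduction_numbers(PRESETS["transmitter_endemic"])
        assert round(r.r01, 2) == 0.57
        assert round(r.r02, 2) == 0.76
        r = reproduction_numbers(PRESETS["coexistence_it"])
        assert round(r.r03, 2) == 1.65

    @given(params=valid_params_strategy())
    @settings(max_examples=100, deadline=None)
    def test_closed_form_ratios(self, params):
        r = reproduction_numbers(params)
        assert r.r01 == pytest.approx(
            params.alpha1 / (params.epsilon + params.gamma1 + params.mu)
        )
        assert r.r02 == pytest.approx(params.alpha2 / (params.gamma2 + params.mu))
        assert r.r03 == pytest.approx(params.alpha3 / (params.beta3 + params.mu))
        assert r.r0 == max(r.r01, r.r02, r.r03)
        assert min(r.r01, r.r02, r.r03) > 0

    def test_monotone_in_each_rate(self, rumor_free_params):
        """Each pathway threshold rises with its transmission rate and
        falls with its removal rates."""
        base = reproduction_numbers(rumor_free_params)
        up = {"r01": "alpha1", "r02": "alpha2", "r03": "alpha3"}
        down = {"r01": ["epsilon", "gamma1", "mu"], "r02": ["gamma2", "mu"],
                "r03": ["beta3", "mu"]}
        for target, name in up.items():
            bumped = rumor_free_params.with_updates(**{name: getattr(rumor_free_params, name) + 0.05})
            assert getattr(reproduction_numbers(bumped), target) > getattr(base, target)
        for target, names in down.items():
            for name in names:
                bumped = rumor_free_params.with_updates(**{name: getattr(rumor_free_params, name) + 0.05})
                assert getattr(reproduction_numbers(bumped), target) < getattr(base, target)


class TestNextGenerationMatrix:
    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_k_diagonal_equals_reproduction_numbers(self, preset):
        params = PRESETS[preset]
        k = next_generation_matrices(params).k_matrix
        r = reproduction_numbers(params)
        assert np.allclose(np.diag(k), [r.r01, r.r02, r.r03])

    def test_k_lower_triangular_with_single_coupling(self, rumor_free_params):
        p = rumor_free_params
        k = next_generation_matrices(p).k_matrix
        assert np.allclose(np.triu(k, 1), 0.0)
        expected = p.alpha2 * p.epsilon / (
            (p.epsilon + p.gamma1 + p.mu) * (p.gamma2 + p.mu)
        )
        assert k[1, 0] == pytest.approx(expected)
        assert k[2, 0] == k[2, 1] == 0.0

    def test_k_eigenvalues_equal_diagonal(self, infected_endemic_params):
        k = next_generation_matrices(infected_endemic_params).k_matrix
        eig = np.sort(np.linalg.eigvals(k).real)
        assert np.allclose(eig, np.sort(np.diag(k)))

    def test_v_inverse_consistency(self, rumor_free_params):
        m = next_generation_matrices(rumor_free_params)
        assert np.allclose(m.v_matrix @ np.linalg.inv(m.v_matrix), np.eye(3),
                           atol=1e-12)
        assert np.allclose(m.k_matrix @ m.v_matrix, m.f_matrix, atol=1e-12)


class TestJacobian:
    E0 = np.array([1.0, 0.0, 0.0, 0.0])

    @given(params=valid_params_strategy())
    @settings(max_examples=100, deadline=None)
    def test_rumor_free_eigenvalues_closed_form(self, params):
        """At the rumor-free point the spectrum is exactly
        {-mu, a3-b3-mu, a1-eps-g1-mu, a2-g2-mu}."""
        eig = np.sort(np.linalg.eigvals(jacobian(params, self.E0)).real)
        expected = np.sort([
            -params.mu,
            params.alpha3 - params.beta3 - params.mu,
            params.alpha1 - params.epsilon - params.gamma1 - params.mu,
            params.alpha2 - params.gamma2 - params.mu,
        ])
        assert np.allclose(eig, expected, atol=1e-12)

    def test_rumor_free_spectrum_subcritical_preset(self, rumor_free_params):
        eig = np.sort(np.linalg.eigvals(jacobian(rumor_free_params, self.E0)).real)
        assert np.allclose(eig, sorted([-0.28, -0.30, -0.63, -0.23]), atol=1e-12)

    @given(params=valid_params_strategy())
    @settings(max_examples=50, deadline=None)
    def test_matches_finite_differences(self, params):
        from snitr import rhs_reduced

        x = np.array([0.5, 0.2, 0.15, 0.1])
        jac = jacobian(params, x)
        h = 1e-7
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            col = (rhs_reduced(x + e, params) - rhs_reduced(x - e, params)) / (2 * h)
            assert np.allclose(jac[:, j], col, atol=1e-6)

    @given(params=valid_params_strategy())
    @settings(max_examples=100, deadline=None)
    def test_stability_iff_all_thresholds_below_one(self, params):
        """All rumor-free eigenvalues negative <=> R01, R02, R03 < 1."""
        r = reproduction_numbers(params)
        eig = np.linalg.eigvals(jacobian(params, self.E0)).real
        assert (np.max(eig) < 0) == (max(r.r01, r.r02, r.r03) < 1)


class TestHurwitz:
    def test_repeated_root_quartic_hand_values(self):
        # (lambda+1)^4 -> coefficients (4, 6, 4, 1)
        d = hurwitz_determinants(CharPoly(4, 6, 4, 1))
        assert d == (4, 20, 64, 64)

    def test_last_determinant_sign_identity(self):
        cp = CharPoly(1.0, -2.0, 0.5, -3.0)
        d = hurwitz_determinants(cp)
        assert np.sign(d[3]) == np.sign(cp.a0) * np.sign(d[2])

    def test_agrees_with_eigenvalue_signs_on_random_quartics(self, rng):
        """All Hurwitz determinants positive iff every root of the
        quartic has negative real part (1,000 random cases away from
        the marginal band)."""
        checked = 0
        while checked < 1000:
            roots = rng.uniform(-2, 2, 4) + 1j * rng.uniform(-2, 2, 4)
            # make it a real polynomial: two conjugate pairs
            roots[1] = np.conj(roots[0])
            roots[3] = np.conj(roots[2])
            if np.min(np.abs(roots.real)) < 1e-3:
                continue
            coeffs = np.real(np.poly(roots))
            d = hurwitz_determinants(CharPoly(*coeffs[1:]))
            stable = bool(np.all(roots.real < 0))
            assert (all(x > 0 for x in d)) == stable
            checked += 1

    def test_char_poly_from_matrix(self, rumor_free_params):
        jac = jacobian(rumor_free_params, np.array([1.0, 0, 0, 0]))
        cp = char_poly(jac)
        eig = np.linalg.eigvals(jac)
        rebuilt = np.real(np.poly(eig))
        assert np.allclose(cp.as_tuple(), rebuilt[1:], atol=1e-10)


class TestClassification:
    E0 = np.array([1.0, 0.0, 0.0, 0.0])

    def test_subcritical_preset_stable(self, rumor_free_params):
        rep = classify_stability(rumor_free_params, self.E0)
        assert rep.classification == "stable"
        assert rep.hurwitz_agrees
        assert all(d > 0 for d in rep.hurwitz)

    def test_supercritical_preset_unstable(self, neglected_endemic_params):
        rep = classify_stability(neglected_endemic_params, self.E0)
        assert rep.classification == "unstable"
        assert rep.reproduction.r01 > 1

    def test_non_equilibrium_requires_force(self, rumor_free_params):
        with pytest.raises(ValueError):
            classify_stability(rumor_free_params, np.array([0.5, 0.2, 0.2, 0.1]))
        rep = classify_stability(
            rumor_free_params, np.array([0.5, 0.2, 0.2, 0.1]), force=True
        )
        assert rep.classification in ("stable", "unstable", "marginal")

    def test_classification_predicts_long_run_behaviour(self, rng):
        """Eigenvalue classification at the rumor-free point agrees with
        where a slightly perturbed trajectory actually goes."""
        from snitr import StateVector, integrate

        checked = 0
        while checked < 25:
            draw = rng.uniform(0.05, 0.32, size=10)
            p = SnitrParameters(
                mu=draw[0], alpha1=draw[1], alpha2=draw[2], alpha3=draw[3],
                beta1=draw[4], beta2=draw[5], beta3=draw[6],
                gamma1=draw[7], gamma2=draw[8], epsilon=draw[9],
            )
            eig = np.max(np.linalg.eigvals(jacobian(p, self.E0)).real)
            if abs(eig) < 0.01:  # skip near-marginal draws
                continue
            rep = classify_stability(p, self.E0)
            init = StateVector(0.97, 0.01, 0.01, 0.01, 0.0)
            end = integrate(p, init, 600.0, n_points=601).states[-1, :4]
            returned = np.max(np.abs(end - self.E0)) < 1e-3
            assert returned == (rep.classification == "stable")
            checked += 1


class TestGlobalConvergence:
    def test_subcritical_regime_all_starts_return(self, rumor_free_params):
        res = global_convergence_check(rumor_free_params, n_starts=50, seed=7)
        assert res.fraction_converged == 1.0
        assert res.lyapunov_eventually_decreasing == 1.0

    def test_supercritical_regime_escapes(self, neglected_endemic_params):
        res = global_convergence_check(neglected_endemic_params, n_starts=20, seed=7)
        assert res.fraction_converged < 1.0

    def test_start_at_equilibrium_trivially_converges(self, rumor_free_params):
        res = global_convergence_check(
            rumor_free_params, starts=np.array([[1.0, 0, 0, 0, 0]])
        )
        assert res.fraction_converged == 1.0
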