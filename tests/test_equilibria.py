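import numpy as np
import pytest
from scipy.optimize import brentq

from lingslide.equilibria import (
    NotAnEquilibriumError,
    UnsupportedExponentError,
    all_equilibria,
    boundary_inflow_check,
    classify_equilibrium,
    interior_equilibrium,
    interior_equilibrium_general,
    interior_equilibrium_linear,
    jacobian,
    pq_indicators,
    trivial_equilibria,
)
from lingslide.model_core import (
    DomainError,
    InvalidParameterError,
    ReducedCoefficients,
    rhs_reduced,
)

from conftest import random_coeffs


def brute_force_interior(coeffs, a):
    """Independent oracle: dense sign scan plus bracketed root search on the
    stationarity conditions, eliminating x_B through the A-nullcline per
    x_A column (no use of the closed form under test)."""

    def xB_of(xA):
        # g > 0 at x_B ~ 0 and g < 0 on the hypotenuse, so this brackets
        g = lambda xB: rhs_reduced(coeffs, a, (xA, xB))[0]
        return brentq(g, 1e-14, 1.0 - xA, xtol=1e-15)

    def resid(xA):
        return rhs_reduced(coeffs, a, (xA, xB_of(xA)))[1]

    # logarithmic-plus-linear scan: the root can sit very close to either end
    grid = np.unique(np.concatenate([
        np.geomspace(1e-9, 0.5, 200),
        1.0 - np.geomspace(1e-9, 0.5, 200),
    ]))
    vals = np.array([resid(x) for x in grid])
    idx = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    assert idx.size >= 1, "oracle scan found no sign change"
    xA = brentq(resid, grid[idx[0]], grid[idx[0] + 1], xtol=1e-14)
    return (xA, xB_of(xA))


class TestTrivialEquilibria:
    def test_points(self):
        assert set(trivial_equilibria()) == {(0, 0), (0, 1), (1, 0)}

    @pytest.mark.parametrize("a", [1.0, 2.0])
    def test_vector_field_vanishes(self, a, baseline_coeffs, rng):
        for coeffs in (baseline_coeffs, random_coeffs(rng)):
            for pt in trivial_equilibria():
                assert rhs_reduced(coeffs, a, pt) == (0.0, 0.0)


class TestInteriorEquilibrium:
    def test_baseline_matches_printed_coordinates(self, baseline_coeffs):
        x = interior_equilibrium(baseline_coeffs, 1.0)
        assert round(x[0], 4) == 0.0437 and round(x[1], 4) == 0.6993

    def test_full_symmetry_gives_centroid(self):
        c = ReducedCoefficients(0.42, 0.42, 0.42, 0.42)
        for a in (1.0, 1.31, 2.0):
            assert interior_equilibrium(c, a) == pytest.approx((1 / 3, 1 / 3),
                                                               abs=1e-14)

    def test_superlinear_case_against_bracketed_oracle(self):
        c = ReducedCoefficients(10.0, 1.0, 1.0, 1.0)
        x = interior_equilibrium(c, 2.0)
        assert x == pytest.approx((0.2763505, 0.5953790), abs=1e-6)
        assert x == pytest.approx(brute_force_interior(c, 2.0), abs=1e-10)

    def test_general_formula_reduces_to_rational_at_a_1(self, rng):
        for _ in range(200):
            c = random_coeffs(rng)
            g = interior_equilibrium_general(c, 1.0)
            l = interior_equilibrium_linear(c)
            assert g == pytest.approx(l, abs=1e-14)

    def test_ratio_identity(self, rng):
        for _ in range(100):
            c = random_coeffs(rng)
            a = rng.uniform(1.0, 2.5)
            xA, xB = interior_equilibrium(c, a)
            lhs = (xA / xB) ** (2 * a - 1)
            rhs = c.a2 * c.a3 / (c.a1 * c.a4)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_residual_and_oracle_agreement(self, rng):
        for _ in range(25):
            c = random_coeffs(rng, low=0.05)
            a = rng.uniform(1.0, 2.5)
            x = interior_equilibrium(c, a)
            f = rhs_reduced(c, a, x)
            assert max(abs(f[0]), abs(f[1])) < 1e-12
            assert x == pytest.approx(brute_force_interior(c, a), abs=1e-10)

    def test_nonpositive_coefficients_rejected(self):
        with pytest.warns(UserWarning):
            c = ReducedCoefficients(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            interior_equilibrium(c, 1.0)

    def test_exponent_half_unsupported(self, baseline_coeffs):
        with pytest.raises(UnsupportedExponentError):
            interior_equilibrium(baseline_coeffs, 0.5)


class TestJacobian:
    def test_bilingual_corner_linear_case(self):
        c = ReducedCoefficients(0.3, 0.5, 0.7, 0.9)
        J = jacobian(c, 1.0, (0.0, 0.0))
        assert np.allclose(J, [[0.3, 0.0], [0.0, 0.7]])

    def test_bilingual_corner_superlinear_degenerate(self):
        c = ReducedCoefficients(0.3, 0.5, 0.7, 0.9)
        assert np.allclose(jacobian(c, 2.0, (0.0, 0.0)), 0.0)

    def test_monolingual_B_corner_superlinear(self):
        c = ReducedCoefficients(0.3, 0.5, 0.7, 0.9)
        J = jacobian(c, 1.5, (0.0, 1.0))
        assert np.allclose(J, [[-0.5, 0.0], [-0.7, -0.7]])

    def test_monolingual_B_corner_linear(self):
        c = ReducedCoefficients(0.3, 0.5, 0.7, 0.9)
        J = jacobian(c, 1.0, (0.0, 1.0))
        assert np.allclose(J, [[-0.5, 0.0], [-0.7 - 0.9, -0.7]])

    def test_matches_central_finite_differences(self, rng):
        for _ in range(20):
            c = random_coeffs(rng)
            a = rng.uniform(1.0, 2.5)
            x = rng.uniform(0.05, 0.4, 2)
            J = jacobian(c, a, tuple(x))
            h = 1e-6
            num = np.empty((2, 2))
            for j in range(2):
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                fp = rhs_reduced(c, a, tuple(xp))
                fm = rhs_reduced(c, a, tuple(xm))
                num[:, j] = [(fp[0] - fm[0]) / (2 * h), (fp[1] - fm[1]) / (2 * h)]
            assert np.allclose(J, num, atol=1e-8)

    def test_sublinear_boundary_divergence_raises(self):
        c = ReducedCoefficients(1, 1, 1, 1)
        with pytest.raises(DomainError):
            jacobian(c, 0.8, (0.0, 0.5))


class TestPQIndicators:
    def test_diagonal(self):
        p, q = pq_indicators(np.array([[0.3, 0.0], [0.0, 0.7]]))
        assert p == pytest.approx(-1.0) and q == pytest.approx(0.21)

    def test_zero_matrix(self):
        assert pq_indicators(np.zeros((2, 2))) == (0.0, 0.0)

    def test_interior_saddle_values(self, baseline_coeffs):
        # p = a1*xA* + a3*xB* (Jacobian-derived; validated against finite
        # differences), q = -a1a2a3a4/D (rational closed form)
        x = interior_equilibrium(baseline_coeffs, 1.0)
        p, q = pq_indicators(jacobian(baseline_coeffs, 1.0, x))
        a1, a2, a3, a4 = baseline_coeffs.astuple
        D = a1 * a4 + a2 * a3 + a2 * a4
        assert p == pytest.approx(a1 * x[0] + a3 * x[1], rel=1e-12)
        assert p == pytest.approx(0.0034965, abs=1e-7)
        assert q == pytest.approx(-a1 * a2 * a3 * a4 / D, rel=1e-12)
        assert q == pytest.approx(-1.6447552e-5, abs=1e-11)


class TestClassification:
    def test_monolingual_corners_are_stable_nodes(self, rng):
        for _ in range(20):
            c = random_coeffs(rng)
            a = rng.choice([1.0, 1.31, 2.0])
            for pt in ((0.0, 1.0), (1.0, 0.0)):
                rep = classify_equilibrium(c, a, pt)
                assert rep.classification == "stable node"
                assert rep.p > 0 and rep.q > 0 and rep.p**2 >= 4 * rep.q

    def test_interior_is_saddle(self, rng):
        for _ in range(20):
            c = random_coeffs(rng)
            a = rng.uniform(1.0, 2.5)
            rep = classify_equilibrium(c, a, interior_equilibrium(c, a),
                                       residual_tol=1e-9)
            assert rep.classification == "saddle (unstable)"
            assert rep.q < 0

    def test_bilingual_corner_linear_unstable_node(self, baseline_coeffs):
        rep = classify_equilibrium(baseline_coeffs, 1.0, (0.0, 0.0))
        assert rep.classification == "unstable node"

    def test_bilingual_corner_superlinear_degenerate_probe(self, baseline_coeffs):
        # linearization is silent; the perturbation probe detects escape
        rep = classify_equilibrium(baseline_coeffs, 2.0, (0.0, 0.0))
        assert rep.classification == "degenerate/non-hyperbolic"
        assert rep.numerically_unstable is True

    def test_non_equilibrium_rejected(self, baseline_coeffs):
        with pytest.raises(NotAnEquilibriumError):
            classify_equilibrium(baseline_coeffs, 1.0, (0.3, 0.3))

    def test_all_equilibria_labels(self, baseline_coeffs):
        reps = all_equilibria(baseline_coeffs, 1.0)
        assert [r.label for r in reps] == ["E0", "E1", "E2", "E3"]


class TestBoundaryInflow:
    def test_left_edge_values(self):
        c = ReducedCoefficients(1.0, 1.0, 0.5, 1.0)
        rep = boundary_inflow_check(c, 1.0, n_samples=3)
        # at (0, 0.5): dx_A/dt = 0, dx_B/dt = a3 * 0.5 * 0.5 = 0.125
        assert rep["x_A=0"]["max_abs_dxA"] == 0.0
        assert rep["x_A=0"]["passed"]

    def test_hypotenuse_inward_flux(self):
        c = ReducedCoefficients(1.0, 2.0, 1.0, 3.0)
        f = rhs_reduced(c, 1.31, (0.4, 0.6))
        assert f[0] == pytest.approx(-2.0 * 0.4 * 0.6**1.31, rel=1e-12)
        assert f[1] == pytest.approx(-3.0 * 0.6 * 0.4**1.31, rel=1e-12)
        assert boundary_inflow_check(c, 1.31)["hypotenuse"]["passed"]

    @pytest.mark.parametrize("a", [1.0, 1.31, 2.0])
    def test_property_sweep(self, a, rng):
        for _ in range(250):
            c = random_coeffs(rng)
            assert boundary_inflow_check(c, a, n_samples=5)["all_passed"]
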