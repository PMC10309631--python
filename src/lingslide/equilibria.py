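"""Equilibria of the reduced planar system and their p-q stability analysis.

The reduced system on Omega = {x_A >= 0, x_B >= 0, x_A + x_B <= 1} always has
the three trivial fixed points E0(0,0) (everyone bilingual), E1(0,1) (only
language B) and E2(1,0) (only language A), and, for strictly positive
coefficients and exponent a > 1/2, a unique interior fixed point E3
(coexistence of both monolingual groups, unstable).

Stability follows the classical planar trace/determinant criteria with
p = -trace(J) and q = det(J): q < 0 is a saddle; q > 0 with p > 0 is stable
(node when p^2 >= 4q, focus otherwise), with p < 0 unstable; p = q = 0 is
non-hyperbolic (E0 with a > 1), where linearization is silent and a numeric
perturbation probe decides practical (in)stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    OMEGA_TOL,
    DomainError,
    InvalidParameterError,
    ReducedCoefficients,
    _pow,
    _rhs_clamped,
    rhs_reduced,
)

__all__ = [
    "NotAnEquilibriumError",
    "UnsupportedExponentError",
    "EquilibriumReport",
    "trivial_equilibria",
    "interior_equilibrium",
    "interior_equilibrium_general",
    "interior_equilibrium_linear",
    "jacobian",
    "pq_indicators",
    "classify_equilibrium",
    "boundary_inflow_check",
    "all_equilibria",
]

_ZERO_TOL = 1e-12  # tolerance for p, q sign decisions


class NotAnEquilibriumError(ValueError):
    """The supplied point is not an equilibrium of the reduced system."""


class UnsupportedExponentError(InvalidParameterError):
    """The interior closed form is undefined for this exponent (2a - 1 <= 0)."""


@dataclass
class EquilibriumReport:
    """Classification record for one equilibrium of the planar system."""

    point: tuple[float, float]
    jacobian: np.ndarray
    p: float
    q: float
    eigenvalues: tuple[complex, complex]
    classification: str
    #: set by the perturbation probe when the linearization is degenerate
    numerically_unstable: bool | None = None
    label: str | None = None

    @property
    def is_stable(self) -> bool:
        return self.classification.startswith("stable")

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "point": [round(self.point[0], 10), round(self.point[1], 10)],
            "jacobian": [[float(v) for v in row] for row in self.jacobian],
            "p": float(self.p),
            "q": float(self.q),
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "classification": self.classification,
            "numerically_unstable": self.numerically_unstable,
        }


def trivial_equilibria() -> list[tuple[float, float]]:
    """The three boundary fixed points present for every parameterization."""
    return [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0)]


def _require_positive(coeffs: ReducedCoefficients) -> None:
    if not coeffs.all_positive:
        raise InvalidParameterError(
            "interior equilibrium requires all four coefficients strictly positive"
        )


def interior_equilibrium_general(
    coeffs: ReducedCoefficients, a: float
) -> tuple[float, float]:
    """Closed-form interior fixed point for a general exponent a > 1/2.

    Derivation: dividing the two stationarity conditions yields the ratio
    identity ``(x_A/x_B)**(2a-1) = a2*a3/(a1*a4)``; substituting
    ``x_A = rho * x_B`` with ``rho = r**(1/(2a-1))`` back into the second
    condition gives ``x_B = 1 / (rho + 1 + (a4/a3) * rho**a)``.
    """
    _require_positive(coeffs)
    if 2.0 * a - 1.0 <= 0.0:
        raise UnsupportedExponentError(
            f"interior closed form undefined for a = {a} (exponent 2a-1 <= 0)"
        )
    a1, a2, a3, a4 = coeffs.astuple
    r = (a2 * a3) / (a1 * a4)
    rho = r ** (1.0 / (2.0 * a - 1.0))
    x_B = 1.0 / (rho + 1.0 + (a4 / a3) * rho**a)
    x_A = rho * x_B
    assert 0.0 < x_A < 1.0 and 0.0 < x_B < 1.0 and x_A + x_B < 1.0
    return (x_A, x_B)


def interior_equilibrium_linear(coeffs: ReducedCoefficients) -> tuple[float, float]:
    """Rational interior fixed point for the linear case a = 1.

    x_A* = a2 a3 / D and x_B* = a1 a4 / D with D = a1 a4 + a2 a3 + a2 a4.
    """
    _require_positive(coeffs)
    a1, a2, a3, a4 = coeffs.astuple
    D = a1 * a4 + a2 * a3 + a2 * a4
    return (a2 * a3 / D, a1 * a4 / D)


def interior_equilibrium(
    coeffs: ReducedCoefficients, a: float
) -> tuple[float, float]:
    """Interior (coexistence) fixed point E3 of the reduced system.

    Uses the rational a = 1 form when a == 1 and the general closed form
    otherwise; the two agree to machine precision at a = 1.
    """
    if a == 1.0:
        return interior_equilibrium_linear(coeffs)
    return interior_equilibrium_general(coeffs, a)


def _pow_am1(x: float, a: float) -> float:
    """``x**(a-1)`` with the boundary convention used by the Jacobian.

    At x = 0: equals 1 when a = 1, 0 when a > 1; diverges (error) when a < 1.
    """
    if x > 0.0:
        return x ** (a - 1.0)
    if a == 1.0:
        return 1.0
    if a > 1.0:
        return 0.0
    raise DomainError(f"x**(a-1) diverges at x = 0 for a = {a} < 1")


def jacobian(
    coeffs: ReducedCoefficients, a: float, point: tuple[float, float]
) -> np.ndarray:
    """Jacobian matrix of the reduced vector field at ``point``."""
    x_A, x_B = point
    if x_A < -OMEGA_TOL or x_B < -OMEGA_TOL or x_A + x_B > 1.0 + OMEGA_TOL:
        raise DomainError(f"point {point} outside Omega")
    x_A, x_B = max(x_A, 0.0), max(x_B, 0.0)
    a1, a2, a3, a4 = coeffs.astuple
    xAa, xBa = _pow(x_A, a), _pow(x_B, a)
    xAm, xBm = _pow_am1(x_A, a), _pow_am1(x_B, a)
    A11 = (a1 * a - a1 * a * x_B) * xAm - a1 * (a + 1.0) * xAa - a2 * xBa
    A12 = -a1 * xAa - a2 * a * x_A * xBm
    A21 = -a3 * xBa - a4 * a * x_B * xAm
    A22 = (a3 * a - a3 * a * x_A) * xBm - a3 * (a + 1.0) * xBa - a4 * xAa
    return np.array([[A11, A12], [A21, A22]], dtype=float)


def pq_indicators(J: np.ndarray) -> tuple[float, float]:
    """Stability indicators p = -trace(J), q = det(J) of a 2x2 matrix."""
    J = np.asarray(J, dtype=float)
    p = -(J[0, 0] + J[1, 1])
    q = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    return (float(p), float(q))


def _classify_pq(p: float, q: float) -> str:
    if abs(p) <= _ZERO_TOL and abs(q) <= _ZERO_TOL:
        return "degenerate/non-hyperbolic"
    if q < -_ZERO_TOL:
        return "saddle (unstable)"
    if q > _ZERO_TOL:
        if abs(p) <= _ZERO_TOL:
            return "center-like (degenerate)"
        # ties p^2 = 4q (repeated eigenvalue) count as nodes; the relative
        # slack absorbs rounding in the discriminant
        disc = p * p - 4.0 * q
        kind = "node" if disc >= -1e-12 * max(1.0, p * p) else "focus"
        return f"stable {kind}" if p > 0.0 else f"unstable {kind}"
    # q numerically zero, p nonzero: one zero eigenvalue
    return "degenerate/non-hyperbolic"


def _perturbation_probe(
    coeffs: ReducedCoefficients,
    a: float,
    point: tuple[float, float],
    delta: float = 1e-4,
    duration: float = 1e4,
) -> bool:
    """Numeric (in)stability probe for degenerate equilibria.

    Integrates from the point displaced by ``delta`` in 8 directions (probes
    clamped into Omega; those collapsing onto the point are skipped) and
    reports instability when any trajectory moves measurably away.
    """
    from scipy.integrate import solve_ivp

    x0, y0 = point
    unstable = False
    for k in range(8):
        ang = 2.0 * math.pi * k / 8.0
        px = min(max(x0 + delta * math.cos(ang), 0.0), 1.0)
        py = min(max(y0 + delta * math.sin(ang), 0.0), 1.0)
        if px + py > 1.0:
            s = px + py
            px, py = px / s, py / s
        d0 = math.hypot(px - x0, py - y0)
        if d0 < delta * 1e-3:
            continue
        sol = solve_ivp(
            lambda t, y: _rhs_clamped(coeffs, a, y[0], y[1]),
            (0.0, duration),
            [px, py],
            method="LSODA",
            rtol=1e-10,
            atol=1e-14,
        )
        d1 = math.hypot(sol.y[0, -1] - x0, sol.y[1, -1] - y0)
        if d1 > 1.01 * d0:
            unstable = True
            break
    return unstable


def classify_equilibrium(
    coeffs: ReducedCoefficients,
    a: float,
    point: tuple[float, float],
    label: str | None = None,
    residual_tol: float = 1e-10,
) -> EquilibriumReport:
    """Full p-q classification of an equilibrium of the reduced system.

    Raises :class:`NotAnEquilibriumError` when the vector-field residual at
    the point exceeds ``residual_tol``.  For degenerate points (p = q = 0,
    e.g. E0 with a > 1) the analytic classification is silent and the
    ``numerically_unstable`` flag is set by a perturbation probe.
    """
    f = rhs_reduced(coeffs, a, point)
    if max(abs(f[0]), abs(f[1])) > residual_tol:
        raise NotAnEquilibriumError(
            f"residual {f} at {point} exceeds {residual_tol}"
        )
    J = jacobian(coeffs, a, point)
    p, q = pq_indicators(J)
    eig = np.linalg.eigvals(J)
    classification = _classify_pq(p, q)
    numerically_unstable = None
    if classification in ("degenerate/non-hyperbolic", "center-like (degenerate)"):
        numerically_unstable = _perturbation_probe(coeffs, a, point)
    return EquilibriumReport(
        point=(float(point[0]), float(point[1])),
        jacobian=J,
        p=p,
        q=q,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        classification=classification,
        numerically_unstable=numerically_unstable,
        label=label,
    )


def all_equilibria(
    coeffs: ReducedCoefficients, a: float
) -> list[EquilibriumReport]:
    """Classify E0, E1, E2 and (when defined) the interior E3."""
    reports = []
    for label, pt in zip(("E0", "E1", "E2"), trivial_equilibria()):
        reports.append(classify_equilibrium(coeffs, a, pt, label=label))
    try:
        e3 = interior_equilibrium(coeffs, a)
    except InvalidParameterError:
        return reports
    reports.append(
        classify_equilibrium(coeffs, a, e3, label="E3", residual_tol=1e-9)
    )
    return reports


def boundary_inflow_check(
    coeffs: ReducedCoefficients, a: float, n_samples: int = 11
) -> dict:
    """Executable positive-invariance check on the three edges of Omega.

    Samples each edge and verifies: on x_A = 0 the A-component vanishes and
    the B-component is nonnegative; symmetrically on x_B = 0; on the
    hypotenuse x_A + x_B = 1 the total flux dx_A/dt + dx_B/dt is nonpositive
    (the field points into Omega).  Failures are reported, never raised.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    tol = 1e-12
    ts = np.linspace(0.0, 1.0, n_samples)
    report: dict[str, dict] = {}

    fa = [rhs_reduced(coeffs, a, (0.0, t)) for t in ts]
    report["x_A=0"] = {
        "max_abs_dxA": max(abs(f[0]) for f in fa),
        "min_dxB": min(f[1] for f in fa),
    }
    report["x_A=0"]["passed"] = (
        report["x_A=0"]["max_abs_dxA"] <= tol and report["x_A=0"]["min_dxB"] >= -tol
    )

    fb = [rhs_reduced(coeffs, a, (t, 0.0)) for t in ts]
    report["x_B=0"] = {
        "max_abs_dxB": max(abs(f[1]) for f in fb),
        "min_dxA": min(f[0] for f in fb),
    }
    report["x_B=0"]["passed"] = (
        report["x_B=0"]["max_abs_dxB"] <= tol and report["x_B=0"]["min_dxA"] >= -tol
    )

    fh = [rhs_reduced(coeffs, a, (t, 1.0 - t)) for t in ts]
    report["hypotenuse"] = {
        "min_inward_flux": min(-(f[0] + f[1]) for f in fh),
    }
    report["hypotenuse"]["passed"] = report["hypotenuse"]["min_inward_flux"] >= -tol

    report["all_passed"] = all(
        report[e]["passed"] for e in ("x_A=0", "x_B=0", "hypotenuse")
    )
    return report
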