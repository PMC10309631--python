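"""Parameterization and vector field of the bilingual competition model.

The model tracks a closed population split into monolingual speakers of two
competing languages (proportions ``x_A``, ``x_B``) and bilinguals
(``w = 1 - x_A - x_B``).  Monolinguals become bilingual at a rate driven by
the *other* language's status and speaker share; bilinguals lose one language
(becoming monolingual) at a rate driven by that language's own status and
share.  Each flow carries an interaction value weighting how strongly the two
groups are in contact, and the speaker share enters through an attractiveness
exponent ``a`` (empirically about 1.31 across cultures; ``a = 1`` is the
linear case).

On proportions the dynamics close into a planar system on the simplex

    dx_A/dt = a1 (1 - x_A - x_B) x_A^a - a2 x_A x_B^a
    dx_B/dt = a3 (1 - x_A - x_B) x_B^a - a4 x_B x_A^a

with the four positive reduced coefficients

    a1 = mu * I_wA * s_A        a2 = (1 - mu) * I_Aw * s_B
    a3 = mu * I_wB * s_B        a4 = (1 - mu) * I_Bw * s_A

where ``mu`` in (0, 1) weights the bilingual-to-monolingual direction (the
generational turnover channel) against the monolingual-to-bilingual one.
This module owns the parameter containers, the raw transfer rates, the full
vector field and its reduction; everything downstream (equilibria, simulation,
sliding-mode control) works with :class:`ReducedCoefficients`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "InvalidParameterError",
    "DomainError",
    "ModelParameters",
    "TransferRates",
    "ReducedCoefficients",
    "PopulationState",
    "reduced_coefficients",
    "transfer_rates",
    "rhs_full",
    "rhs_reduced",
    "OMEGA_TOL",
    "CLAMP_TOL",
]

#: membership tolerance for the simplex / the planar domain Omega
OMEGA_TOL = 1e-9
#: negative coordinates in [-CLAMP_TOL, 0) are clamped to 0 before
#: exponentiation (guards adaptive-integrator overshoot)
CLAMP_TOL = 1e-12


class InvalidParameterError(ValueError):
    """A model parameter violates its admissible range."""


class DomainError(ValueError):
    """A state coordinate lies outside the admissible domain."""


def _pow(x: float, a: float) -> float:
    """``x ** a`` with the convention ``0 ** a := 0`` for any ``a > 0``.

    Coordinates in ``[-CLAMP_TOL, 0)`` are clamped to 0; anything more
    negative raises :class:`DomainError`.
    """
    if x < -CLAMP_TOL:
        raise DomainError(f"coordinate {x!r} below the clamping guard -{CLAMP_TOL}")
    if x <= 0.0:
        return 0.0
    return float(x) ** a


@dataclass(frozen=True)
class ModelParameters:
    """Full parameterization of the bilingual competition model.

    Parameters
    ----------
    mu : float
        Turnover-rate coefficient weighting the bilingual-to-monolingual
        flows; must lie strictly in (0, 1) so that all four reduced
        coefficients are positive.  (Treated purely as a model coefficient,
        without a demographic interpretation.)
    a : float
        Attractiveness exponent on the speaker share.  ``a >= 1`` is assumed
        by all stability analysis; values in (0, 1) are accepted with a
        warning (sublinear attractiveness).
    s_A, s_B : float
        Status (socio-economic attractiveness weight) of language A, B;
        strictly positive.
    I_wA, I_wB : float
        Interaction value from bilinguals to monolingual A, B; nonnegative.
    I_Aw, I_Bw : float
        Interaction value from monolingual A, B to bilinguals; nonnegative.
    """

    mu: float
    a: float
    s_A: float
    s_B: float
    I_wA: float = 1.0
    I_wB: float = 1.0
    I_Aw: float = 1.0
    I_Bw: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise InvalidParameterError(f"mu must lie in (0, 1), got {self.mu}")
        if not self.a > 0.0:
            raise InvalidParameterError(f"a must be positive, got {self.a}")
        if not (self.s_A > 0.0 and self.s_B > 0.0):
            raise InvalidParameterError(
                f"statuses must be positive, got s_A={self.s_A}, s_B={self.s_B}"
            )
        for name in ("I_wA", "I_wB", "I_Aw", "I_Bw"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(
                    f"interaction value {name} must be nonnegative, got {getattr(self, name)}"
                )
        if self.a < 1.0:
            warnings.warn(
                f"attractiveness exponent a={self.a} < 1: sublinear case, outside "
                "the regime the stability theory assumes (a >= 1)",
                UserWarning,
                stacklevel=3,
            )
        if abs(self.s_A + self.s_B - 1.0) > 1e-9:
            warnings.warn(
                f"statuses are not complementary: s_A + s_B = {self.s_A + self.s_B}",
                UserWarning,
                stacklevel=3,
            )

    @property
    def sublinear(self) -> bool:
        """True when the attractiveness exponent is below 1."""
        return self.a < 1.0


@dataclass(frozen=True)
class TransferRates:
    """Per-capita transfer rates between the three speaker groups.

    ``P_wA``/``P_wB``: bilinguals adopt monolingual A/B.
    ``P_Aw``/``P_Bw``: monolingual A/B become bilingual.
    """

    P_wA: float
    P_wB: float
    P_Aw: float
    P_Bw: float


@dataclass(frozen=True)
class ReducedCoefficients:
    """The four reduced coefficients of the planar system (per unit time)."""

    a1: float
    a2: float
    a3: float
    a4: float

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4"):
            v = getattr(self, name)
            if v < 0.0:
                raise InvalidParameterError(f"{name} must be nonnegative, got {v}")
        if min(self.a1, self.a2, self.a3, self.a4) == 0.0:
            warnings.warn(
                "some reduced coefficients are zero; equilibrium analysis "
                "requires all four strictly positive",
                UserWarning,
                stacklevel=3,
            )

    @property
    def astuple(self) -> tuple[float, float, float, float]:
        return (self.a1, self.a2, self.a3, self.a4)

    @property
    def all_positive(self) -> bool:
        return min(self.astuple) > 0.0


@dataclass(frozen=True)
class PopulationState:
    """A point (x_A, x_B, w) on the population simplex.

    ``w`` is stored redundantly and validated against ``1 - x_A - x_B``
    (the bilingual share has no independent dynamics).
    """

    x_A: float
    x_B: float
    w: float

    def __post_init__(self) -> None:
        for name in ("x_A", "x_B", "w"):
            v = getattr(self, name)
            if v < -CLAMP_TOL:
                raise DomainError(f"{name} = {v} is negative")
            if -CLAMP_TOL <= v < 0.0:
                object.__setattr__(self, name, 0.0)
        total = self.x_A + self.x_B + self.w
        if abs(total - 1.0) > OMEGA_TOL:
            raise DomainError(
                f"proportions must sum to 1 within {OMEGA_TOL}, got {total}"
            )

    @classmethod
    def from_planar(cls, x_A: float, x_B: float) -> "PopulationState":
        """Build a state from the planar coordinates, with w = 1 - x_A - x_B."""
        w = 1.0 - x_A - x_B
        if -CLAMP_TOL <= w < 0.0:
            w = 0.0
        return cls(x_A, x_B, w)

    @classmethod
    def normalized(cls, x_A: float, x_B: float, w: float) -> "PopulationState":
        """Build a state after rescaling the three shares to sum exactly 1."""
        total = x_A + x_B + w
        if total <= 0.0:
            raise DomainError("cannot normalize nonpositive total proportion")
        return cls(x_A / total, x_B / total, w / total)

    @property
    def planar(self) -> tuple[float, float]:
        return (self.x_A, self.x_B)


def reduced_coefficients(params: ModelParameters) -> ReducedCoefficients:
    """Reduce a full parameterization to the four planar coefficients.

    a1 = mu*I_wA*s_A, a2 = (1-mu)*I_Aw*s_B, a3 = mu*I_wB*s_B,
    a4 = (1-mu)*I_Bw*s_A.  All are strictly positive when every interaction
    value is.
    """
    return ReducedCoefficients(
        a1=params.mu * params.I_wA * params.s_A,
        a2=(1.0 - params.mu) * params.I_Aw * params.s_B,
        a3=params.mu * params.I_wB * params.s_B,
        a4=(1.0 - params.mu) * params.I_Bw * params.s_A,
    )


def transfer_rates(params: ModelParameters, state: PopulationState) -> TransferRates:
    """Evaluate the four status-and-share-driven transfer rates at a state.

    A language's pull is proportional to its status times its speaker share
    raised to the attractiveness exponent; a language with no speakers exerts
    no attraction.
    """
    xAa = _pow(state.x_A, params.a)
    xBa = _pow(state.x_B, params.a)
    return TransferRates(
        P_wA=params.I_wA * params.s_A * xAa,
        P_wB=params.I_wB * params.s_B * xBa,
        P_Aw=params.I_Aw * params.s_B * xBa,
        P_Bw=params.I_Bw * params.s_A * xAa,
    )


def rhs_full(
    params: ModelParameters, state: PopulationState
) -> tuple[float, float]:
    """Time derivatives (dx_A/dt, dx_B/dt) of the full model.

    ``dw/dt`` is implied as ``-(dx_A/dt + dx_B/dt)``.
    """
    rates = transfer_rates(params, state)
    mu, om = params.mu, 1.0 - params.mu
    f_A = mu * state.w * rates.P_wA - om * state.x_A * rates.P_Aw
    f_B = mu * state.w * rates.P_wB - om * state.x_B * rates.P_Bw
    return (f_A, f_B)


def rhs_reduced(
    coeffs: ReducedCoefficients,
    a: float,
    point: tuple[float, float],
) -> tuple[float, float]:
    """Time derivatives of the reduced planar system at ``point = (x_A, x_B)``.

    The point must lie in Omega = {x_A >= 0, x_B >= 0, x_A + x_B <= 1}
    within `OMEGA_TOL`; coordinates within the tolerance band below 0 are
    clamped before exponentiation.
    """
    x_A, x_B = point
    if x_A < -OMEGA_TOL or x_B < -OMEGA_TOL or x_A + x_B > 1.0 + OMEGA_TOL:
        raise DomainError(f"point {point} outside Omega beyond tolerance {OMEGA_TOL}")
    x_A = min(max(x_A, 0.0), 1.0)
    x_B = min(max(x_B, 0.0), 1.0)
    slack = max(1.0 - x_A - x_B, 0.0)
    f_A = coeffs.a1 * slack * _pow(x_A, a) - coeffs.a2 * x_A * _pow(x_B, a)
    f_B = coeffs.a3 * slack * _pow(x_B, a) - coeffs.a4 * x_B * _pow(x_A, a)
    return (f_A, f_B)


def _rhs_clamped(
    coeffs: ReducedCoefficients, a: float, x_A: float, x_B: float
) -> tuple[float, float]:
    """Non-validating variant of :func:`rhs_reduced` for integrator callbacks.

    Trial steps of adaptive steppers can leave Omega by more than the public
    tolerance; here coordinates are clamped into [0, 1] without raising.
    """
    x_A = min(max(x_A, 0.0), 1.0)
    x_B = min(max(x_B, 0.0), 1.0)
    slack = max(1.0 - x_A - x_B, 0.0)
    f_A = coeffs.a1 * slack * x_A**a - coeffs.a2 * x_A * x_B**a
    f_B = coeffs.a3 * slack * x_B**a - coeffs.a4 * x_B * x_A**a
    return (f_A, f_B)
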