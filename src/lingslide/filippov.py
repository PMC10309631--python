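"""Threshold (sliding-mode) control of the competition model, Filippov style.

A language-preservation policy is modelled as a parameter switch: while the
endangered language's share ``x_B`` stays at or above an endangerment
threshold ``ET`` the free-regime parameters apply; once ``x_B`` drops below
``ET`` the controlled-regime (policy) parameters take over.  The flow is then
piecewise smooth with switching manifold Sigma = {x_B = ET}.

Where both regimes' fields point toward Sigma the trajectory cannot leave it
and slides along it.  Following Filippov's convex-combination construction,
the sliding field is ``lambda * f_free + (1 - lambda) * f_ctrl`` with the
weight ``lambda = sigma_ctrl / (sigma_ctrl - sigma_free)`` chosen so the
combined x_B-component vanishes (``sigma`` denotes the x_B-component of each
field on Sigma); sliding is admissible exactly when ``lambda`` lies in (0, 1).
A zero of the sliding field inside the sliding segment is a
*pseudo-equilibrium*: a stationary point of the controlled system that is an
equilibrium of neither smooth regime.  Here it represents stable coexistence
of both languages with x_B pinned at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import (
    InvalidParameterError,
    ModelParameters,
    PopulationState,
    ReducedCoefficients,
    _rhs_clamped,
    reduced_coefficients,
)
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    IntegrationFailureError,
    Trajectory,
    _as_state,
    _clamp_states,
)

__all__ = [
    "NotSlidingError",
    "ChatteringError",
    "FilippovModel",
    "SlidingAnalysis",
    "classify_sigma_point",
    "sliding_segment",
    "sliding_field",
    "pseudo_equilibrium",
    "integrate_hybrid",
]

_ROOT_TOL = 1e-13  # endpoint localization on Sigma


class NotSlidingError(ValueError):
    """sliding_field was evaluated outside the sliding segment."""


class ChatteringError(RuntimeError):
    """The hybrid integrator exceeded its regime-switch budget."""


@dataclass(frozen=True)
class FilippovModel:
    """Free-regime / controlled-regime coefficient pair with threshold ET.

    ``free`` applies where x_B >= ET, ``controlled`` where x_B < ET; the
    attractiveness exponent ``a`` is shared by both regimes.
    """

    free: ReducedCoefficients
    controlled: ReducedCoefficients
    a: float
    ET: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ET < 1.0:
            raise InvalidParameterError(f"ET must lie in (0, 1), got {self.ET}")
        if not self.a > 0.0:
            raise InvalidParameterError(f"a must be positive, got {self.a}")

    @classmethod
    def from_parameters(
        cls,
        free: ModelParameters,
        controlled: ModelParameters,
        ET: float,
    ) -> "FilippovModel":
        """Build from two full parameterizations (the controlled one carries
        the post-policy "hat" statuses and interaction values)."""
        if free.a != controlled.a:
            raise InvalidParameterError(
                "free and controlled regimes must share the exponent a"
            )
        return cls(
            free=reduced_coefficients(free),
            controlled=reduced_coefficients(controlled),
            a=free.a,
            ET=ET,
        )

    def field(self, regime: str, x_A: float, x_B: float) -> tuple[float, float]:
        coeffs = self.free if regime == "free" else self.controlled
        return _rhs_clamped(coeffs, self.a, x_A, x_B)

    def sigma(self, x_A: float) -> tuple[float, float]:
        """x_B-components of the free and controlled fields on Sigma."""
        return (
            self.field("free", x_A, self.ET)[1],
            self.field("controlled", x_A, self.ET)[1],
        )


def classify_sigma_point(fm: FilippovModel, x_A: float) -> str:
    """Local behaviour of the piecewise flow at (x_A, ET) on Sigma.

    ``sliding``: both fields point toward Sigma; ``escaping``: both point
    away; ``upward crossing`` / ``downward crossing``: the flow passes
    through; exact zeros are labelled ``tangency``.
    """
    if not 0.0 <= x_A <= 1.0 - fm.ET:
        raise InvalidParameterError(
            f"x_A = {x_A} outside [0, 1 - ET] = [0, {1.0 - fm.ET}]"
        )
    s_free, s_ctrl = fm.sigma(x_A)
    if s_free == 0.0 or s_ctrl == 0.0:
        return "tangency"
    if s_free < 0.0 < s_ctrl:
        return "sliding"
    if s_ctrl < 0.0 < s_free:
        return "escaping"
    if s_free > 0.0 and s_ctrl > 0.0:
        return "upward crossing"
    return "downward crossing"


def _sigma_roots(fm: FilippovModel, n_scan: int = 2048) -> list[float]:
    """All roots of either sigma component on [0, 1-ET], by scan + brentq."""
    xs = np.linspace(0.0, 1.0 - fm.ET, n_scan + 1)
    roots: list[float] = []
    for comp in (0, 1):
        vals = np.array([fm.sigma(x)[comp] for x in xs])
        for i in range(n_scan):
            lo, hi = vals[i], vals[i + 1]
            if lo == 0.0:
                roots.append(float(xs[i]))
            elif lo * hi < 0.0:
                roots.append(
                    float(
                        brentq(
                            lambda x, c=comp: fm.sigma(x)[c],
                            xs[i],
                            xs[i + 1],
                            xtol=_ROOT_TOL,
                        )
                    )
                )
        if vals[-1] == 0.0:
            roots.append(float(xs[-1]))
    return sorted(set(roots))


def sliding_segment(fm: FilippovModel) -> list[tuple[float, float]]:
    """Maximal sub-intervals of Sigma on which the flow slides.

    Endpoints are roots of one of the two sigma components, located by
    bracketed root-finding; an empty list means the two regimes' fields
    never simultaneously point toward the switching line.
    """
    breaks = [0.0] + _sigma_roots(fm) + [1.0 - fm.ET]
    breaks = sorted(set(breaks))
    intervals: list[tuple[float, float]] = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi - lo < 10 * _ROOT_TOL:
            continue
        mid = 0.5 * (lo + hi)
        s_free, s_ctrl = fm.sigma(mid)
        if s_free < 0.0 < s_ctrl:
            if intervals and abs(intervals[-1][1] - lo) < 10 * _ROOT_TOL:
                intervals[-1] = (intervals[-1][0], hi)
            else:
                intervals.append((lo, hi))
    return intervals


def _in_segment(
    x_A: float, segments: list[tuple[float, float]], tol: float = 1e-10
) -> tuple[float, float] | None:
    for lo, hi in segments:
        if lo - tol <= x_A <= hi + tol:
            return (lo, hi)
    return None


def sliding_field(fm: FilippovModel, x_A: float) -> tuple[float, float]:
    """Filippov sliding dynamics at (x_A, ET): returns (dx_A/dt, lambda).

    ``lambda = sigma_ctrl / (sigma_ctrl - sigma_free)`` makes the convex
    combination of the two fields tangent to Sigma; its x_B-component is
    zero by construction and the motion is one-dimensional along Sigma.
    """
    if classify_sigma_point(fm, x_A) != "sliding":
        raise NotSlidingError(f"(x_A, ET) = ({x_A}, {fm.ET}) is not a sliding point")
    s_free, s_ctrl = fm.sigma(x_A)
    lam = s_ctrl / (s_ctrl - s_free)
    fa_free = fm.field("free", x_A, fm.ET)[0]
    fa_ctrl = fm.field("controlled", x_A, fm.ET)[0]
    return (lam * fa_free + (1.0 - lam) * fa_ctrl, lam)


def _H(fm: FilippovModel, x_A: float) -> float:
    """Pseudo-equilibrium function f_A_free*sigma_ctrl - f_A_ctrl*sigma_free.

    Zeros of H inside a sliding segment are exactly the zeros of the sliding
    field (the denominator sigma_ctrl - sigma_free never vanishes there).
    """
    s_free, s_ctrl = fm.sigma(x_A)
    fa_free = fm.field("free", x_A, fm.ET)[0]
    fa_ctrl = fm.field("controlled", x_A, fm.ET)[0]
    return fa_free * s_ctrl - fa_ctrl * s_free


@dataclass
class SlidingAnalysis:
    """Sliding-mode summary of a Filippov model on its switching line."""

    segments: list[tuple[float, float]]
    pseudo_equilibrium: tuple[float, float] | None  # (x_A^s, ET)
    lambda_at_pe: float | None
    candidates: list[tuple[float, float]]  # all admissible (x_A, lambda) roots
    regime_map: list[tuple[float, str]]  # sampled labels along Sigma

    @property
    def pseudo_equilibrium_state(self) -> PopulationState | None:
        if self.pseudo_equilibrium is None:
            return None
        x_A, ET = self.pseudo_equilibrium
        return PopulationState.from_planar(x_A, ET)

    def as_dict(self) -> dict:
        pe = self.pseudo_equilibrium_state
        return {
            "sliding_segments": [[lo, hi] for lo, hi in self.segments],
            "pseudo_equilibrium": None
            if pe is None
            else {"x_A": pe.x_A, "x_B": pe.x_B, "w": pe.w},
            "lambda_at_pe": self.lambda_at_pe,
            "regime_map": [[x, lab] for x, lab in self.regime_map],
        }


def pseudo_equilibrium(
    fm: FilippovModel, n_scan: int = 400, n_map: int = 101
) -> SlidingAnalysis:
    """Locate pseudo-equilibria of the Filippov system on Sigma.

    Scans H on every sliding interval for sign changes, refines each by
    bracketed root search, and keeps roots whose Filippov weight lies in
    (0, 1).  ``pseudo_equilibrium`` is None when no sliding interval
    contains an admissible root (policy fails to pin coexistence).
    """
    segments = sliding_segment(fm)
    candidates: list[tuple[float, float]] = []
    for lo, hi in segments:
        eps = max(1e-12, (hi - lo) * 1e-9)
        xs = np.linspace(lo + eps, hi - eps, n_scan)
        vals = np.array([_H(fm, x) for x in xs])
        for i in range(len(xs) - 1):
            if vals[i] == 0.0:
                root = float(xs[i])
            elif vals[i] * vals[i + 1] < 0.0:
                root = float(brentq(lambda x: _H(fm, x), xs[i], xs[i + 1], xtol=_ROOT_TOL))
            else:
                continue
            try:
                _, lam = sliding_field(fm, root)
            except NotSlidingError:
                continue
            if 0.0 < lam < 1.0:
                candidates.append((root, lam))
    regime_map = [
        (float(x), classify_sigma_point(fm, float(x)))
        for x in np.linspace(0.0, 1.0 - fm.ET, n_map)
    ]
    pe = (candidates[0][0], fm.ET) if candidates else None
    lam = candidates[0][1] if candidates else None
    return SlidingAnalysis(
        segments=segments,
        pseudo_equilibrium=pe,
        lambda_at_pe=lam,
        candidates=candidates,
        regime_map=regime_map,
    )


def _initial_regime(fm: FilippovModel, x_A: float, x_B: float) -> str:
    if abs(x_B - fm.ET) <= 1e-12:
        cls = classify_sigma_point(fm, x_A)
        if cls == "sliding":
            return "sliding"
        if cls == "downward crossing":
            return "controlled"
        return "free"  # upward crossing, escaping or tangency: x_B >= ET rule
    return "free" if x_B > fm.ET else "controlled"


def integrate_hybrid(
    fm: FilippovModel,
    x0,
    t_max: float = 2e4,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_switches: int = 10**4,
) -> Trajectory:
    """Event-detected integration of the piecewise-smooth controlled model.

    Smooth legs run the active regime's field until the trajectory crosses
    x_B = ET (event localized by the stepper); the hit point is classified
    and the run either switches regime (crossing) or continues as
    one-dimensional sliding motion along Sigma.  Sliding ends at a
    pseudo-equilibrium (converged) or at a segment endpoint (tangency), where
    the regime whose field points away from Sigma resumes.  A chattering
    guard aborts after ``max_switches`` regime switches.
    """
    state = _as_state(x0)
    x, y = state.planar
    t = 0.0
    regime = _initial_regime(fm, x, y)
    segments = sliding_segment(fm)
    sa = pseudo_equilibrium(fm)

    times: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    regimes: list[str] = []
    switches = 0
    converged = False

    def emit(ts, xv, yv, lab):
        for tt, xx, yy in zip(ts, xv, yv):
            if times and tt <= times[-1]:
                continue
            times.append(float(tt))
            xs.append(float(xx))
            ys.append(float(yy))
            regimes.append(lab)

    while t < t_max - 1e-9 and not converged:
        if switches > max_switches:
            raise ChatteringError(
                f"more than {max_switches} regime switches before t = {t}: "
                "likely chattering on the switching line"
            )
        if regime in ("free", "controlled"):
            coeffs = fm.free if regime == "free" else fm.controlled

            def hit(tt, yy):
                return yy[1] - fm.ET

            hit.terminal = True
            hit.direction = -1.0 if regime == "free" else 1.0
            n_eval = max(16, int(400 * (t_max - t) / t_max))
            sol = solve_ivp(
                lambda tt, yy: _rhs_clamped(coeffs, fm.a, yy[0], yy[1]),
                (t, t_max),
                [x, y],
                method="LSODA",
                t_eval=np.linspace(t, t_max, n_eval),
                events=[hit],
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise IntegrationFailureError(sol.message)
            emit(sol.t, sol.y[0], sol.y[1], regime)
            if sol.t_events[0].size:
                t = float(sol.t_events[0][0])
                x = float(sol.y_events[0][0][0])
                y = fm.ET
                emit([t], [x], [y], regime)
                cls = classify_sigma_point(fm, min(max(x, 0.0), 1.0 - fm.ET))
                if cls == "sliding":
                    regime = "sliding"
                else:
                    regime = "controlled" if regime == "free" else "free"
                    y = fm.ET + (1e-13 if regime == "free" else -1e-13)
                switches += 1
            else:
                t = float(sol.t[-1])
                x, y = float(sol.y[0, -1]), float(sol.y[1, -1])
                f = _rhs_clamped(coeffs, fm.a, x, y)
                converged = max(abs(f[0]), abs(f[1])) < 1e-8
                break
        else:  # sliding along Sigma
            seg = _in_segment(x, segments)
            if seg is None:
                # landed outside any segment (numerical grazing): fall back
                # to the smooth regime selected by the local classification
                cls = classify_sigma_point(fm, min(max(x, 0.0), 1.0 - fm.ET))
                regime = "free" if cls == "upward crossing" else "controlled"
                y = fm.ET + (1e-13 if regime == "free" else -1e-13)
                switches += 1
                continue
            lo, hi = seg
            x = min(max(x, lo), hi)

            def slide_rhs(tt, yy):
                xi = min(max(yy[0], lo), hi)
                s_free, s_ctrl = fm.sigma(xi)
                denom = s_ctrl - s_free
                lam = s_ctrl / denom if denom != 0.0 else 0.5
                fa_free = fm.field("free", xi, fm.ET)[0]
                fa_ctrl = fm.field("controlled", xi, fm.ET)[0]
                return [lam * fa_free + (1.0 - lam) * fa_ctrl]

            def exit_lo(tt, yy):
                return yy[0] - lo

            def exit_hi(tt, yy):
                return yy[0] - hi

            exit_lo.terminal = True
            exit_lo.direction = -1.0
            exit_hi.terminal = True
            exit_hi.direction = 1.0
            chunk_end = min(t + 2000.0, t_max)
            sol = solve_ivp(
                slide_rhs,
                (t, chunk_end),
                [x],
                method="LSODA",
                t_eval=np.linspace(t, chunk_end, 64),
                events=[exit_lo, exit_hi],
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise IntegrationFailureError(sol.message)
            emit(sol.t, sol.y[0], [fm.ET] * len(sol.t), "sliding")
            hit_lo = sol.t_events[0].size > 0
            hit_hi = sol.t_events[1].size > 0
            if hit_lo or hit_hi:
                t = float((sol.t_events[0] if hit_lo else sol.t_events[1])[0])
                x = lo if hit_lo else hi
                emit([t], [x], [fm.ET], "sliding")
                # tangency exit: resume the regime whose field points away
                s_free, s_ctrl = fm.sigma(x)
                if s_free > 0.0:
                    regime = "free"
                    y = fm.ET + 1e-13
                else:
                    regime = "controlled"
                    y = fm.ET - 1e-13
                switches += 1
            else:
                t = float(sol.t[-1])
                x = float(np.clip(sol.y[0, -1], lo, hi))
                y = fm.ET
                if abs(slide_rhs(t, [x])[0]) < 1e-12:
                    converged = True
                    if sa.pseudo_equilibrium is not None:
                        x = sa.pseudo_equilibrium[0]
                    break

    states = _clamp_states(np.array([xs, ys]))
    final = PopulationState.normalized(*states[-1])
    return Trajectory(
        times=np.asarray(times),
        states=states,
        regimes=regimes,
        converged=converged,
        final_state=final,
    )
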