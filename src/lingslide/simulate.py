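"""Forward integration of the smooth (uncontrolled) competition model.

Error-controlled integration of the reduced planar system, convergence to an
attractor, and first-passage (extinction) timing.  Time units are abstract;
the default horizon and tolerances are chosen so that every built-in scenario
converges comfortably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    OMEGA_TOL,
    PopulationState,
    ReducedCoefficients,
    _rhs_clamped,
    rhs_reduced,
)
from .equilibria import InvalidParameterError, interior_equilibrium, trivial_equilibria

__all__ = [
    "IntegrationFailureError",
    "Trajectory",
    "AttractorResult",
    "integrate_smooth",
    "attractor_of",
    "first_passage_time",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
DEFAULT_T_MAX = 1e4


class IntegrationFailureError(RuntimeError):
    """The adaptive stepper could not meet the requested tolerances."""


@dataclass
class Trajectory:
    """A time-stamped solution path on the population simplex.

    ``regimes`` labels each sample as ``free`` (uncontrolled smooth flow),
    ``controlled`` (below-threshold smooth flow) or ``sliding`` (motion on
    the switching line); smooth runs are all ``free``.
    """

    times: np.ndarray
    states: np.ndarray  # shape (n, 3): columns x_A, x_B, w
    regimes: list[str]
    converged: bool
    final_state: PopulationState

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.times) > 0.0), "times must be strictly increasing"
        sums = self.states.sum(axis=1)
        assert np.all(self.states >= -1e-6) and np.all(np.abs(sums - 1.0) <= 1e-6)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "x_A": self.states[:, 0],
                "x_B": self.states[:, 1],
                "w": self.states[:, 2],
                "regime": self.regimes,
            }
        )


def _as_state(x0) -> PopulationState:
    if isinstance(x0, PopulationState):
        st = x0
    elif len(x0) == 2:
        st = PopulationState.from_planar(*x0)
    else:
        total = sum(x0)
        if abs(total - 1.0) > OMEGA_TOL:
            warnings.warn(
                f"initial proportions sum to {total}; normalizing to 1",
                UserWarning,
                stacklevel=3,
            )
        st = PopulationState.normalized(*x0)
    return st


def _clamp_states(y: np.ndarray) -> np.ndarray:
    """Stack planar samples into (n, 3) simplex states, clamped to Omega."""
    xa = np.clip(y[0], 0.0, 1.0)
    xb = np.clip(y[1], 0.0, 1.0)
    w = np.clip(1.0 - xa - xb, 0.0, 1.0)
    return np.column_stack([xa, xb, w])


def integrate_smooth(
    coeffs: ReducedCoefficients,
    a: float,
    x0,
    t_max: float = DEFAULT_T_MAX,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_samples: int = 501,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate the reduced system from ``x0`` with adaptive error control.

    Returns a dense trajectory (at least ``n_samples`` evenly spaced
    samples); states are clamped to the simplex within tolerance.
    """
    if t_max <= t0:
        raise ValueError("t_max must exceed t0")
    state = _as_state(x0)
    sol = solve_ivp(
        lambda t, y: _rhs_clamped(coeffs, a, y[0], y[1]),
        (t0, t_max),
        list(state.planar),
        method="LSODA",
        t_eval=np.linspace(t0, t_max, max(n_samples, 500)),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationFailureError(sol.message)
    states = _clamp_states(sol.y)
    final = PopulationState.normalized(*states[-1])
    resid = rhs_reduced(coeffs, a, final.planar)
    converged = max(abs(resid[0]), abs(resid[1])) < 1e-10
    return Trajectory(
        times=sol.t,
        states=states,
        regimes=["free"] * len(sol.t),
        converged=converged,
        final_state=final,
    )


@dataclass
class AttractorResult:
    """Outcome of chunked integration until (near-)stationarity."""

    state: PopulationState
    label: str | None  # matched equilibrium: E0/E1/E2/E3, or None
    converged: bool
    t_elapsed: float


def attractor_of(
    coeffs: ReducedCoefficients,
    a: float,
    x0,
    chunk: float = 2000.0,
    t_budget: float = 2e5,
    rhs_tol: float = 1e-10,
    disp_tol: float = 1e-8,
    match_tol: float = 1e-4,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> AttractorResult:
    """Integrate in restartable chunks until the flow is stationary.

    Convergence requires both a small vector field (sup-norm below
    ``rhs_tol``) and small displacement over the last chunk; the limit is
    matched against the known equilibria within ``match_tol``.
    Non-convergence within the time budget is reported, never raised.
    """
    state = _as_state(x0)
    y = list(state.planar)
    t = 0.0
    converged = False
    while t < t_budget:
        sol = solve_ivp(
            lambda tt, yy: _rhs_clamped(coeffs, a, yy[0], yy[1]),
            (t, t + chunk),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationFailureError(sol.message)
        y_new = [
            float(np.clip(sol.y[0, -1], 0.0, 1.0)),
            float(np.clip(sol.y[1, -1], 0.0, 1.0)),
        ]
        t += chunk
        disp = max(abs(y_new[0] - y[0]), abs(y_new[1] - y[1]))
        y = y_new
        f = rhs_reduced(coeffs, a, tuple(y))
        if max(abs(f[0]), abs(f[1])) < rhs_tol and disp < disp_tol:
            converged = True
            break
    limit = PopulationState.from_planar(*y)
    label = None
    candidates = list(zip(("E0", "E1", "E2"), trivial_equilibria()))
    try:
        candidates.append(("E3", interior_equilibrium(coeffs, a)))
    except InvalidParameterError:
        pass
    for name, pt in candidates:
        if max(abs(y[0] - pt[0]), abs(y[1] - pt[1])) < match_tol:
            label = name
            break
    return AttractorResult(state=limit, label=label, converged=converged, t_elapsed=t)


def first_passage_time(
    coeffs: ReducedCoefficients,
    a: float,
    x0,
    component: str = "x_B",
    threshold: float = 0.01,
    t_max: float = 2e5,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float | None:
    """First model time at which a proportion falls below ``threshold``.

    Used as the operational "extinction time" of a language (the trajectories
    approach 0 asymptotically, so a cutoff is needed; 0.01 by default).
    Returns None when the threshold is never reached before ``t_max``.
    """
    idx = {"x_A": 0, "x_B": 1}[component]
    state = _as_state(x0)

    def event(t, y):
        return y[idx] - threshold

    event.terminal = True
    event.direction = -1.0
    sol = solve_ivp(
        lambda t, y: _rhs_clamped(coeffs, a, y[0], y[1]),
        (0.0, t_max),
        list(state.planar),
        method="LSODA",
        events=[event],
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationFailureError(sol.message)
    if sol.t_events[0].size == 0:
        return None
    return float(sol.t_events[0][0])
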