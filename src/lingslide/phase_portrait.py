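"""Nullclines and direction-field grids over the admissible region Omega.

Exports the numeric data behind phase-plane diagrams: a barycentric lattice
of unit direction vectors, the two nullcline curve families (dx_A/dt = 0 and
dx_B/dt = 0, trivial axis branches included) and the classified equilibria.
Rendering is optional and cosmetic; the tested artifact is the numeric data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import InvalidParameterError, ReducedCoefficients, rhs_reduced
from .equilibria import EquilibriumReport, all_equilibria
from .filippov import FilippovModel

__all__ = [
    "NullclineBranch",
    "PortraitData",
    "nullclines",
    "vector_field_grid",
    "portrait",
    "plot_portrait",
]

_ZERO_MAG = 1e-14


@dataclass
class NullclineBranch:
    """One connected piece of a nullcline curve."""

    component: str  # "A" (dx_A/dt = 0) or "B" (dx_B/dt = 0)
    kind: str  # "trivial" (an axis) or "nontrivial"
    points: np.ndarray  # (n, 2) array of (x_A, x_B)


@dataclass
class PortraitData:
    """All numeric ingredients of a phase portrait of Omega."""

    grid: pd.DataFrame
    nullclines: list[NullclineBranch]
    equilibria: list[EquilibriumReport]
    sigma: float | None = None  # switching line x_B = ET, when present

    def nullclines_frame(self) -> pd.DataFrame:
        rows = []
        for i, br in enumerate(self.nullclines):
            for x, y in br.points:
                rows.append(
                    {"branch": i, "component": br.component, "kind": br.kind,
                     "x_A": x, "x_B": y}
                )
        return pd.DataFrame(rows)


def _a_nullcline_root(coeffs, a, x_A):
    """Root in x_B of dx_A/dt(x_A, .) = 0 for fixed x_A in (0, 1)."""

    def f(x_B):
        return rhs_reduced(coeffs, a, (x_A, x_B))[0]

    hi = 1.0 - x_A
    if f(0.0) <= 0.0 or f(hi) >= 0.0:  # no interior sign change
        return None
    return brentq(f, 0.0, hi, xtol=1e-15)


def _b_nullcline_roots(coeffs, a, x_A, n_scan=64):
    """All roots in x_B of the nontrivial factor of dx_B/dt for fixed x_A.

    The nontrivial condition a3 (1 - x_A - x_B) x_B^(a-1) = a4 x_A^a can
    admit zero, one or two roots when a > 1 (the curve folds), so a sign
    scan precedes each bracketed search.
    """
    a1, a2, a3, a4 = coeffs.astuple
    hi = 1.0 - x_A

    def g(x_B):
        # nontrivial factor of f_B (f_B = x_B * g for a = 1; x_B^(a-1)-scaled
        # in general); roots of g in (0, hi] are the nontrivial branch
        return a3 * (1.0 - x_A - x_B) * x_B ** (a - 1.0) - a4 * x_A**a

    xs = np.linspace(hi * 1e-6, hi, n_scan)
    vals = np.array([g(x) for x in xs])
    roots = []
    for i in range(n_scan - 1):
        if vals[i] == 0.0:
            roots.append(float(xs[i]))
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(float(brentq(g, xs[i], xs[i + 1], xtol=1e-15)))
    return roots


def nullclines(
    coeffs: ReducedCoefficients, a: float, resolution: int = 64
) -> list[NullclineBranch]:
    """Nullcline polylines of both components over Omega.

    Nontrivial branches are traced column-by-column in x_A with a bracketed
    root per column; the trivial axis branches are included and labelled.
    Every emitted vertex satisfies |corresponding rhs component| < 1e-10.
    """
    if resolution < 16:
        raise InvalidParameterError("resolution must be >= 16")
    edge = np.linspace(0.0, 1.0, resolution)
    branches = [
        NullclineBranch("A", "trivial", np.column_stack([np.zeros_like(edge), edge])),
        NullclineBranch("B", "trivial", np.column_stack([edge, np.zeros_like(edge)])),
    ]
    cols = np.linspace(0.0, 1.0, resolution + 1)[1:-1]

    pts_a = []
    for x_A in cols:
        x_B = _a_nullcline_root(coeffs, a, x_A)
        if x_B is not None:
            pts_a.append((x_A, x_B))
    if pts_a:
        branches.append(NullclineBranch("A", "nontrivial", np.array(pts_a)))

    # trace the B-curve allowing folds: match roots to open branches
    open_branches: list[list[tuple[float, float]]] = []
    closed: list[list[tuple[float, float]]] = []
    match_tol = 4.0 / resolution
    for x_A in cols:
        roots = _b_nullcline_roots(coeffs, a, x_A)
        used = [False] * len(open_branches)
        next_open: list[list[tuple[float, float]]] = []
        for r in roots:
            best, best_d = None, match_tol
            for j, br in enumerate(open_branches):
                if used[j]:
                    continue
                d = abs(br[-1][1] - r)
                if d < best_d:
                    best, best_d = j, d
            if best is None:
                next_open.append([(x_A, r)])
            else:
                used[best] = True
                open_branches[best].append((x_A, r))
                next_open.append(open_branches[best])
        for j, br in enumerate(open_branches):
            if not used[j]:
                closed.append(br)
        open_branches = next_open
    closed.extend(open_branches)
    for br in closed:
        if len(br) >= 2:
            branches.append(NullclineBranch("B", "nontrivial", np.array(br)))
    return branches


def vector_field_grid(
    model: ReducedCoefficients | FilippovModel,
    a: float | None = None,
    resolution: int = 32,
) -> pd.DataFrame:
    """Unit direction vectors on a barycentric lattice over Omega.

    For a Filippov model the active regime at each lattice point is chosen
    by the x_B >= ET rule.  Zero-magnitude points are flagged as equilibrium
    candidates.  Columns: x_A, x_B, u, v, magnitude, regime, is_equilibrium.
    """
    if resolution < 4:
        raise InvalidParameterError("resolution must be >= 4")
    is_filippov = isinstance(model, FilippovModel)
    if is_filippov:
        a = model.a
    elif a is None:
        raise InvalidParameterError("exponent a is required for a smooth model")
    rows = []
    for i in range(resolution + 1):
        x_A = i / resolution
        for j in range(resolution + 1 - i):
            x_B = j / resolution
            if is_filippov:
                regime = "free" if x_B >= model.ET else "controlled"
                f = model.field(regime, x_A, x_B)
            else:
                regime = "free"
                f = rhs_reduced(model, a, (x_A, x_B))
            mag = float(np.hypot(*f))
            if mag < _ZERO_MAG:
                u = v = 0.0
            else:
                u, v = f[0] / mag, f[1] / mag
            rows.append(
                {"x_A": x_A, "x_B": x_B, "u": u, "v": v, "magnitude": mag,
                 "regime": regime, "is_equilibrium": mag < _ZERO_MAG}
            )
    return pd.DataFrame(rows)


def portrait(
    model: ReducedCoefficients | FilippovModel,
    a: float | None = None,
    resolution: int = 32,
    nullcline_resolution: int = 64,
) -> PortraitData:
    """Assemble the full numeric phase portrait.

    For a Filippov model the equilibria of both regimes are classified and
    labelled with their regime; an equilibrium lying on the wrong side of
    the switching line (hence never realized) keeps its label but can be
    recognized by comparing its x_B with ``sigma``.
    """
    grid = vector_field_grid(model, a, resolution)
    if isinstance(model, FilippovModel):
        eq: list[EquilibriumReport] = []
        for regime, coeffs in (("free", model.free), ("controlled", model.controlled)):
            for rep in all_equilibria(coeffs, model.a):
                rep.label = f"{rep.label}[{regime}]"
                eq.append(rep)
        nc = nullclines(model.free, model.a, nullcline_resolution)
        return PortraitData(grid=grid, nullclines=nc, equilibria=eq, sigma=model.ET)
    return PortraitData(
        grid=grid,
        nullclines=nullclines(model, a, nullcline_resolution),
        equilibria=all_equilibria(model, a),
        sigma=None,
    )


def plot_portrait(data: PortraitData, ax=None):
    """Render a portrait with matplotlib (cosmetic; optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    g = data.grid
    ax.quiver(g.x_A, g.x_B, g.u, g.v, angles="xy", width=0.002, alpha=0.6)
    for br in data.nullclines:
        style = ":" if br.kind == "trivial" else "-"
        ax.plot(br.points[:, 0], br.points[:, 1], style, lw=1.2)
    for rep in data.equilibria:
        fc = "k" if rep.is_stable else "none"
        ax.scatter(*rep.point, s=40, facecolors=fc, edgecolors="k", zorder=5)
    if data.sigma is not None:
        ax.axhline(data.sigma, color="tab:red", lw=1.0, ls="--")
    ax.plot([0, 1, 0, 0], [0, 0, 1, 0], color="gray", lw=0.8)
    ax.set_xlabel("$x_A$")
    ax.set_ylabel("$x_B$")
    return ax
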