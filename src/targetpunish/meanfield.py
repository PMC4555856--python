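"""Mean-field map, fixed points and bifurcation structure.

For the uniform rule with the cooperators punisher pool, every defector is at
fault (``n_f = N - n_c``) and every cooperator punishes (``n_p = n_c``), so
the expected cooperator fraction one step ahead depends on the current state
only through the density ``rho``:

    G(rho) = (1/N) * sum_i (1/2) * [tanh(beta * (pi*rho/(1-rho) - (i-2)/(N-2))) + 1].

Fixed points ``rho*`` solve ``G(rho*) = rho*``; a fixed point is stable when
``|G'(rho*)| < 1`` (map criterion), and the direction of expected drift at any
density is ``sign(G(rho) - rho)``.  As ``rho -> 1`` the punishment pressure
``pi*rho/(1-rho)`` diverges, so for ``pi > 0`` and ``beta > 0`` the map tends
to 1 and full cooperation is an attracting boundary point; it is reported as a
boundary fixed point, not as a numeric root.  ``rho = 0`` is not a root at
finite ``beta`` (``G(0) > 0`` strictly); boundary behaviour there is exposed
through :func:`flow_direction` instead.

This analysis applies only to the uniform strategy: the targeted (single-file
and groups) strategies make the fault count depend on the detailed
configuration, not just on ``rho``, and are studied by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FixedPoint",
    "BifurcationScan",
    "G_discrete",
    "G_continuum",
    "find_fixed_points",
    "flow_direction",
    "bifurcation_scan",
]

#: guard for the pi*rho/(1-rho) singularity at rho = 1
_EDGE = 1e-9
#: central-difference step for the stability derivative
_DERIV_STEP = 1e-6


@dataclass(frozen=True)
class FixedPoint:
    """A solution of ``G(rho) = rho`` with its stability classification."""

    rho: float
    derivative: float
    stable: bool
    boundary: bool = False


@dataclass(frozen=True)
class BifurcationScan:
    """Fixed-point sets along a strictly increasing parameter axis."""

    axis: str  # "beta" | "pi"
    values: np.ndarray
    fixed_points: list[list[FixedPoint]]

    def stable_branches(self) -> list[tuple[float, float]]:
        """(axis value, rho*) pairs of all stable fixed points."""
        return [
            (float(v), fp.rho)
            for v, fps in zip(self.values, self.fixed_points)
            for fp in fps
            if fp.stable
        ]

    def unstable_branches(self) -> list[tuple[float, float]]:
        return [
            (float(v), fp.rho)
            for v, fps in zip(self.values, self.fixed_points)
            for fp in fps
            if not fp.stable
        ]


def _pressure(rho, pi_cap):
    rho = np.asarray(rho, dtype=float)
    return pi_cap * rho / (1.0 - rho)


def G_discrete(rho, beta: float, pi_cap: float, n_players: int):
    """Expected next-step cooperator fraction, exact N-player average.

    Accepts scalar or array ``rho`` in [0, 1]; ``rho = 1`` is handled by
    continuity (1 when ``pi_cap > 0`` and ``beta > 0``, else the ``pi = 0``
    value, i.e. the constant map).
    """
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any((rho_arr < 0) | (rho_arr > 1)):
        raise ValueError("rho must lie in [0, 1]")
    if n_players < 3:
        raise ValueError("need at least 3 players")
    if beta < 0 or pi_cap < 0:
        raise ValueError("beta and punishment capacity must be non-negative")
    h = -(np.arange(1, n_players + 1) - 2.0) / (n_players - 2.0)
    at_edge = rho_arr >= 1.0 - _EDGE
    safe = np.where(at_edge, 0.0, rho_arr)
    c = _pressure(safe, pi_cap)
    out = 0.5 * (np.tanh(beta * (c[:, None] + h[None, :])) + 1.0).mean(axis=1)
    if pi_cap > 0 and beta > 0:
        out = np.where(at_edge, 1.0, out)
    else:
        # map is constant in rho; the edge value is the same constant
        out = np.where(at_edge, 0.5 * (np.tanh(beta * h) + 1.0).mean(), out)
    return out if np.ndim(rho) else float(out[0])


def _log_cosh(x: np.ndarray) -> np.ndarray:
    # overflow-safe: log cosh x = |x| + log1p(exp(-2|x|)) - log 2
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def G_continuum(rho, beta: float, pi_cap: float, n_players: int):
    """Closed-form continuum limit of :func:`G_discrete`.

    Treats the predispositions as uniform on ``[-1, 1/(N-2)]`` and integrates
    the sigmoid exactly; used as an independent analytic cross-check (the two
    agree to O(1/N), a Riemann-sum error).
    """
    if beta == 0:
        return np.full_like(np.asarray(rho, dtype=float), 0.5) if np.ndim(rho) else 0.5
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any((rho_arr < 0) | (rho_arr > 1)):
        raise ValueError("rho must lie in [0, 1]")
    a, b = -1.0, 1.0 / (n_players - 2.0)
    at_edge = rho_arr >= 1.0 - _EDGE
    c = _pressure(np.where(at_edge, 0.0, rho_arr), pi_cap)
    val = 0.5 + (_log_cosh(beta * (c + b)) - _log_cosh(beta * (c + a))) / (
        2.0 * beta * (b - a)
    )
    if pi_cap > 0:
        val = np.where(at_edge, 1.0, val)
    return val if np.ndim(rho) else float(val[0])


def flow_direction(rho: float, beta: float, pi_cap: float, n_players: int, tol: float = 1e-9) -> int:
    """Direction of expected drift at density ``rho``: sign of ``G(rho) - rho``."""
    diff = G_discrete(rho, beta, pi_cap, n_players) - rho
    if diff > tol:
        return 1
    if diff < -tol:
        return -1
    return 0


def _derivative(rho: float, beta: float, pi_cap: float, n_players: int) -> float:
    lo = max(rho - _DERIV_STEP, 0.0)
    hi = min(rho + _DERIV_STEP, 1.0 - _EDGE)
    g = G_discrete(np.array([lo, hi]), beta, pi_cap, n_players)
    return float((g[1] - g[0]) / (hi - lo))


def find_fixed_points(
    beta: float,
    pi_cap: float,
    n_players: int,
    grid_size: int = 2001,
    tol: float = 1e-10,
) -> list[FixedPoint]:
    """All fixed points of the map at given parameters.

    Scans ``G(rho) - rho`` for sign changes on ``[0, 1 - eps]`` (``grid_size``
    points), refines each bracket with Brent's method to ``|G - rho| <= tol``,
    classifies stability by the central-difference derivative, and appends the
    ``rho = 1`` boundary attractor when ``pi_cap > 0`` and ``beta > 0``.
    """
    if grid_size < 100:
        raise ValueError("grid_size must be at least 100")
    if tol <= 0:
        raise ValueError("tol must be positive")
    grid = np.linspace(0.0, 1.0 - _EDGE, grid_size)
    f = G_discrete(grid, beta, pi_cap, n_players) - grid
    roots: list[float] = []
    for k in range(grid_size - 1):
        if f[k] == 0.0:
            roots.append(float(grid[k]))
        elif f[k] * f[k + 1] < 0:
            r = optimize.brentq(
                lambda x: G_discrete(x, beta, pi_cap, n_players) - x,
                grid[k],
                grid[k + 1],
                xtol=tol,
            )
            roots.append(float(r))
    if f[-1] == 0.0:
        roots.append(float(grid[-1]))
    # dedupe near-coincident roots from adjacent brackets
    deduped: list[float] = []
    for r in sorted(roots):
        if not deduped or r - deduped[-1] > 10 * max(tol, 1e-12):
            deduped.append(r)
    points = []
    for r in deduped:
        d = _derivative(r, beta, pi_cap, n_players)
        points.append(FixedPoint(rho=r, derivative=d, stable=abs(d) < 1.0))
    if pi_cap > 0 and beta > 0:
        points.append(
            FixedPoint(rho=1.0, derivative=float("nan"), stable=True, boundary=True)
        )
    return points


def bifurcation_scan(
    axis: str,
    values,
    *,
    beta: float | None = None,
    pi_cap: float | None = None,
    n_players: int = 200,
    grid_size: int = 2001,
    tol: float = 1e-10,
) -> BifurcationScan:
    """Fixed-point sets along a grid of ``beta`` (at fixed ``pi_cap``) or
    ``pi`` (at fixed ``beta``)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.any(np.diff(values) <= 0):
        raise ValueError("axis values must be strictly increasing")
    if axis == "beta":
        if pi_cap is None:
            raise ValueError("scanning beta requires fixed pi_cap")
        sets = [find_fixed_points(float(v), pi_cap, n_players, grid_size, tol) for v in values]
    elif axis == "pi":
        if beta is None:
            raise ValueError("scanning pi requires fixed beta")
        sets = [find_fixed_points(beta, float(v), n_players, grid_size, tol) for v in values]
    else:
        raise ValueError("axis must be 'beta' or 'pi'")
    return BifurcationScan(axis=axis, values=values, fixed_points=sets)
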