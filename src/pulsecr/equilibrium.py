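"""Fixed points of the season map: location, stability, season averages.

The season map Phi takes a post-pulse (beginning-of-season) state to the
next season's post-pulse state.  Since the pulse forces B = 0, the map is
effectively three-dimensional in (R, J, A).  Stable equilibria are found by
forward iteration (with Newton polishing once the iterates settle);
unstable equilibria by Newton's method from an explicit guess.  Stability
is classified from the moduli of the eigenvalues (multipliers) of the map's
Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import Parameters, SeasonState, field_jacobian, make_rhs
from .season_map import (
    DEFAULT_OPTIONS,
    SolverOptions,
    integrate_season,
    reproduction_pulse,
)

__all__ = [
    "Equilibrium",
    "ConvergenceError",
    "NewtonError",
    "season_map",
    "season_map_jacobian",
    "season_map_jacobian_variational",
    "solve_fixed_point",
    "find_attractor",
]

#: classification band around |multiplier| = 1
TOL_EIG = 1e-6

#: consumer biomass above which a fixed point counts as coexistence
COEXISTENCE_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """Forward iteration hit the season cap without converging or dying out.

    Carries the last post-pulse iterate as ``last_state`` — at some
    parameters (notably low mortality) the coexistence attractor is a
    cycle rather than a fixed point, and callers interested in persistence
    rather than equilibria can classify the outcome from that state.
    """

    def __init__(self, message: str, last_state: Optional[SeasonState] = None):
        super().__init__(message)
        self.last_state = last_state


class NewtonError(RuntimeError):
    """Newton iteration on the season map failed (divergence or singular Jacobian)."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the season map.

    ``state`` is the post-pulse state (B = 0 by construction); ``averages``
    are the season averages (Jbar, Abar, Bbar) over the equilibrium season.
    ``stability`` is ``"stable"``, ``"unstable"``, ``"marginal"`` (a
    multiplier within ``TOL_EIG`` of the unit circle) or ``"extinct"`` for
    the resource-only fixed point.  ``multipliers`` are the eigenvalues of
    the 3x3 season-map Jacobian.
    """

    state: SeasonState
    averages: tuple[float, float, float]
    stability: str
    multipliers: np.ndarray
    residual: float

    @property
    def max_multiplier(self) -> float:
        return float(np.max(np.abs(self.multipliers))) if len(self.multipliers) else 0.0

    @property
    def is_coexistence(self) -> bool:
        return self.state.J + self.state.A > COEXISTENCE_TOL


def season_map(
    x: np.ndarray, p: Parameters, opts: SolverOptions = DEFAULT_OPTIONS
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """One application of the season map on the post-pulse state (R, J, A).

    Integrates one season from (R, J, A, 0) and applies the reproduction
    pulse.  Returns the next post-pulse (R, J, A) and the season averages.
    """
    s0 = SeasonState(max(x[0], 0.0), max(x[1], 0.0), max(x[2], 0.0), 0.0)
    res = integrate_season(s0, p, opts)
    post = reproduction_pulse(res.end_state)
    return np.array([post.R, post.J, post.A]), res.averages


def season_map_jacobian(
    x: np.ndarray, p: Parameters, opts: SolverOptions = DEFAULT_OPTIONS
) -> np.ndarray:
    """Central finite-difference Jacobian of the season map at ``x``.

    Step per component: ``1e-6 * (1 + |x_i|)``; the map is smooth away from
    the starvation/maturation switch points so central differences with the
    tight integration tolerances give ~8 accurate digits.
    """
    x = np.asarray(x, dtype=float)
    J = np.zeros((3, 3))
    for i in range(3):
        h = 1e-6 * (1.0 + abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0)
        fp, _ = season_map(xp, p, opts)
        fm, _ = season_map(xm, p, opts)
        J[:, i] = (fp - fm) / (xp[i] - xm[i])
    return J


def season_map_jacobian_variational(
    x: np.ndarray, p: Parameters, opts: SolverOptions = DEFAULT_OPTIONS
) -> np.ndarray:
    """Season-map Jacobian via the variational (matrix) ODE.

    Integrates dY/dt = (df/dy) Y alongside the trajectory, with the analytic
    field Jacobian, then applies the pulse's linearisation (J row picks up
    the B row, B column dropped).  Independent of the finite-difference
    route; used as a cross-check.
    """
    rhs4 = make_rhs(p, averages=False)

    def aug(t, u):
        y = u[:4]
        Y = u[4:].reshape(4, 4)
        dy = rhs4(t, y)
        dY = field_jacobian(y, p) @ Y
        return np.concatenate([dy, dY.ravel()])

    y0 = np.array([x[0], x[1], x[2], 0.0])
    u0 = np.concatenate([y0, np.eye(4).ravel()])
    sol = solve_ivp(aug, (0.0, 1.0), u0, method=opts.method,
                    rtol=opts.rtol, atol=opts.atol)
    if not sol.success:
        raise NewtonError(f"variational integration failed: {sol.message}")
    Y = sol.y[4:, -1].reshape(4, 4)
    # pulse linearisation: (R, J + B, A) as function of initial (R, J, A)
    P = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 1.0], [0, 0, 1.0, 0]])
    return P @ Y[:, :3]


def _classify(multipliers: np.ndarray) -> str:
    mod = np.abs(multipliers)
    if np.any(np.abs(mod - 1.0) <= TOL_EIG):
        return "marginal"
    return "stable" if np.all(mod < 1.0) else "unstable"


def _build_equilibrium(
    x: np.ndarray,
    p: Parameters,
    opts: SolverOptions,
    residual: float,
) -> Equilibrium:
    state = SeasonState(max(x[0], 0.0), max(x[1], 0.0), max(x[2], 0.0), 0.0)
    _, averages = season_map(x, p, opts)
    if state.J + state.A <= COEXISTENCE_TOL:
        state = SeasonState(p.Kr, 0.0, 0.0, 0.0)
        return Equilibrium(state, (0.0, 0.0, 0.0), "extinct", np.array([]), 0.0)
    Jac = season_map_jacobian(x, p, opts)
    multipliers = np.linalg.eigvals(Jac)
    return Equilibrium(state, averages, _classify(multipliers), multipliers, residual)


def solve_fixed_point(
    p: Parameters,
    guess: SeasonState | np.ndarray,
    opts: SolverOptions = DEFAULT_OPTIONS,
    tol: float = 1e-10,
    max_iter: int = 25,
) -> Equilibrium:
    """Newton iteration for a fixed point of the season map.

    Solves F(x) = Phi(x) - x = 0 in the post-pulse variables (R, J, A), with
    a finite-difference Jacobian and step halving when a full step fails to
    reduce the residual.  Raises :class:`NewtonError` (carrying a condition
    estimate when the Jacobian is nearly singular, as near a fold) if the
    iteration does not reach ``tol`` in max-norm.
    """
    if isinstance(guess, SeasonState):
        if guess.B != 0.0:
            raise ValueError("fixed-point guesses use the post-pulse convention B = 0")
        x = np.array([guess.R, guess.J, guess.A])
    else:
        x = np.asarray(guess, dtype=float).copy()
    fx, _ = season_map(x, p, opts)
    res = fx - x
    for _ in range(max_iter):
        rnorm = float(np.max(np.abs(res)))
        if rnorm < tol:
            return _build_equilibrium(x, p, opts, rnorm)
        Jac = season_map_jacobian(x, p, opts)
        A = Jac - np.eye(3)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise NewtonError(
                f"singular season-map Jacobian (cond~{cond:.2e}) near {x}; "
                "likely a fold point"
            )
        step = np.linalg.solve(A, -res)
        lam = 1.0
        for _ in range(8):  # damped step
            x_new = x + lam * step
            if np.all(x_new[:1] >= 0) and np.all(x_new >= -1e-12):
                x_new = np.maximum(x_new, 0.0)
                fx_new, _ = season_map(x_new, p, opts)
                res_new = fx_new - x_new
                if np.max(np.abs(res_new)) < rnorm:
                    break
            lam *= 0.5
        else:
            raise NewtonError(f"Newton stalled at {x} with residual {rnorm:.2e}")
        x, res = x_new, res_new
    rnorm = float(np.max(np.abs(res)))
    if rnorm < tol:
        return _build_equilibrium(x, p, opts, rnorm)
    raise NewtonError(f"Newton did not converge: residual {rnorm:.2e} at {x}")


def find_attractor(
    p: Parameters,
    s0: SeasonState,
    opts: SolverOptions = DEFAULT_OPTIONS,
) -> Equilibrium:
    """Attractor of the season map reached from ``s0`` by forward iteration.

    Forward-iterates seasons; once the iterates settle (max-norm change
    below 1e-3) a Newton polish is attempted every 20 seasons and accepted
    only if it converges to a *stable* coexistence point close to the
    current iterate — a safeguard against jumping basins near the fold,
    where the stable and unstable points approach each other.  On
    extinction the exact resource-only fixed point is returned.
    """
    state = s0 if s0.B == 0.0 else reproduction_pulse(s0)
    prev = state.as_array()
    streak = 0
    for n in range(1, opts.max_seasons + 1):
        res = integrate_season(state, p, opts)
        state = reproduction_pulse(res.end_state)
        cur = state.as_array()
        if state.consumer_biomass < opts.ext_tol:
            return Equilibrium(
                SeasonState(p.Kr, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0),
                "extinct", np.array([]), 0.0,
            )
        diff = float(np.max(np.abs(cur - prev)))
        prev = cur
        streak = streak + 1 if diff < opts.tol_fix else 0
        polish = streak >= opts.fix_window or (diff < 1e-3 and n % 20 == 0)
        if polish:
            x = np.array([state.R, state.J, state.A])
            try:
                eq = solve_fixed_point(p, x, opts)
            except NewtonError:
                if streak >= opts.fix_window:
                    # forward-converged but unpolishable (e.g. at a fold):
                    # report the iterate itself
                    _, averages = season_map(x, p, opts)
                    Jac = season_map_jacobian(x, p, opts)
                    mult = np.linalg.eigvals(Jac)
                    return Equilibrium(state, averages, _classify(mult), mult, diff)
                continue
            if eq.stability == "extinct":
                continue  # keep iterating; extinction test will catch it
            close = np.max(np.abs(eq.state.as_array() - cur)) < 0.02 * (
                1.0 + np.max(np.abs(eq.state.as_array()))
            )
            if eq.stability == "stable" and (close or streak >= opts.fix_window):
                return eq
            if streak >= opts.fix_window:
                return eq
    raise ConvergenceError(
        f"no convergence or extinction within {opts.max_seasons} seasons at {p} "
        f"(last state {state}); possible non-equilibrium attractor",
        last_state=state,
    )
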