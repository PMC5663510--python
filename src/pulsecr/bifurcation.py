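"""Bifurcation analysis in the mortality / intake-ratio plane.

Two organising boundaries in consumer background mortality ``mu``:

* the *persistence boundary* — the highest ``mu`` at which a coexistence
  attractor of the season map still exists (found dynamically, by tracking
  the attractor branch with warm-started forward iteration and bisecting);
* the *invasion boundary* — the ``mu`` at which the dominant multiplier of
  the season map linearised at the resource-only equilibrium crosses 1
  (above it a rare consumer cannot grow).

Where the invasion boundary lies strictly below the persistence boundary the
model is bistable: an established population persists while a rare one dies
out — an (emergent) Allee effect.  The gap opens only for sufficiently large
adult-juvenile intake ratio ``theta``; ``bistability_onset`` locates the
smallest such ``theta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq

from .equilibrium import (
    ConvergenceError,
    Equilibrium,
    NewtonError,
    find_attractor,
    solve_fixed_point,
)
from .model_core import (
    Parameters,
    SeasonState,
    clipped_production,
    maturation_rate,
    net_production,
)
from .season_map import DEFAULT_OPTIONS, SolverOptions

__all__ = [
    "BoundaryPoint",
    "invasion_eigenvalue",
    "invasion_eigenvalue_by_integration",
    "persistence_boundary",
    "invasion_boundary",
    "sweep_mu",
    "two_parameter_diagram",
    "bistability_onset",
]

#: bisection width for both boundaries (matches the precision boundaries are
#: usually quoted at)
TOL_MU = 1e-3

#: minimum persistence-invasion gap declared as bistability; five bisection
#: widths, so the tiny consumer-consumer alternative-stable-state sliver at
#: intermediate theta is not flagged as the headline Allee region
BISTABLE_GAP = 5 * TOL_MU

#: standard high initial condition from which the coexistence attractor is
#: tracked
HIGH_IC = SeasonState(1.0, 0.2, 0.2, 0.0)
LOW_IC = SeasonState(1.0, 0.01, 0.01, 0.0)


@dataclass(frozen=True)
class BoundaryPoint:
    """Persistence and invasion boundaries at one ``theta``."""

    theta: float
    mu_persist: float
    mu_invade: float

    @property
    def bistable(self) -> bool:
        return self.mu_persist - self.mu_invade > BISTABLE_GAP


def _linear_coefficients(p: Parameters) -> np.ndarray:
    """Constant-coefficient matrix of the consumer dynamics at R = Kr."""
    nu_j = net_production(p.Kr, p, "juvenile")
    nu_a = net_production(p.Kr, p, "adult")
    nujp = clipped_production(nu_j)
    nuap = clipped_production(nu_a)
    gam = maturation_rate(nu_j, p.mu, p.z)
    dj = p.mu + (nujp - nu_j)
    da = p.mu + (nuap - nu_a)
    return np.array(
        [
            [nujp - gam - dj, 0.0, 0.0],
            [gam, -da, 0.0],
            [0.0, nuap, -da],
        ]
    )


#: pulse map on (J, A, B): J <- J + B, B <- 0
_PULSE = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])


def invasion_eigenvalue(p: Parameters) -> float:
    """Dominant multiplier of the season map at the resource-only equilibrium.

    With the resource pinned at ``Kr`` the linearised consumer dynamics
    (J, A, B) have constant coefficients over the season; the one-season
    transition matrix is a matrix exponential, followed by the reproduction
    pulse.  A modulus above 1 means a rare consumer cohort grows from season
    to season, i.e. invasion succeeds.
    """
    M = expm(_linear_coefficients(p))
    return float(np.max(np.abs(np.linalg.eigvals(_PULSE @ M))))


def invasion_eigenvalue_by_integration(
    p: Parameters, opts: SolverOptions = DEFAULT_OPTIONS
) -> float:
    """Invasion multiplier by direct integration of the linear season ODEs.

    Numerically integrates the three linear cohort equations for each unit
    basis vector and assembles the monodromy matrix column by column.
    Independent of :func:`invasion_eigenvalue`; the two agree to solver
    tolerance and serve as mutual cross-checks.
    """
    C = _linear_coefficients(p)

    def rhs(t, y):
        return C @ y

    M = np.zeros((3, 3))
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        sol = solve_ivp(rhs, (0.0, 1.0), e, method=opts.method,
                        rtol=opts.rtol, atol=opts.atol)
        if not sol.success:
            raise RuntimeError(f"linear season integration failed: {sol.message}")
        M[:, i] = sol.y[:, -1]
    return float(np.max(np.abs(np.linalg.eigvals(_PULSE @ M))))


def _persistence_probe(
    p: Parameters, start: SeasonState, opts: SolverOptions
) -> tuple[bool, Optional[SeasonState]]:
    """Does the consumer persist from ``start``?  Returns (persists, warm state).

    Persistence is dynamic: convergence to a coexistence fixed point counts,
    but so does a persistent non-equilibrium attractor (at low mortality the
    fixed point can lose stability to a cycle while the population is in no
    danger of extinction).  Extinction, or biomass that has decayed to
    within an order of magnitude of the extinction threshold by the season
    cap, counts as non-persistence.
    """
    try:
        eq = find_attractor(p, start, opts)
    except ConvergenceError as exc:
        last = exc.last_state
        if last is not None and last.consumer_biomass > 1e-6:
            return True, last
        return False, None
    if eq.stability == "extinct" or not eq.is_coexistence:
        return False, None
    return True, eq.state


def persistence_boundary(
    p: Parameters,
    mu_lo: float = 0.1,
    mu_hi: float = 20.0,
    tol_mu: float = TOL_MU,
    opts: SolverOptions = DEFAULT_OPTIONS,
    start: SeasonState = HIGH_IC,
) -> float:
    """Highest ``mu`` at which a coexistence attractor exists, by bisection.

    The attractor branch is tracked dynamically: each persisting ``mu``
    updates the warm-start state, so the bisection follows the coexistence
    branch up to its fold rather than probing cold from the standard initial
    condition.  ``p.mu`` is ignored; the bracket ``[mu_lo, mu_hi]`` must
    contain the boundary (the upper end is expanded if needed).

    Raises ``ValueError`` if no coexistence attractor exists at ``mu_lo``
    (degenerate parameters).
    """
    ok, warm = _persistence_probe(p.with_(mu=mu_lo), start, opts)
    if not ok:
        raise ValueError(f"no persistence at mu={mu_lo} for theta={p.theta}")
    # ensure the upper end is beyond the boundary
    for _ in range(6):
        ok_hi, warm_hi = _persistence_probe(p.with_(mu=mu_hi), warm, opts)
        if not ok_hi:
            break
        mu_lo, mu_hi, warm = mu_hi, 2.0 * mu_hi, warm_hi
    else:
        raise ValueError(f"consumers persist up to mu={mu_hi}; bracket too small")
    while mu_hi - mu_lo > tol_mu:
        mid = 0.5 * (mu_lo + mu_hi)
        ok, warm_mid = _persistence_probe(p.with_(mu=mid), warm, opts)
        if ok:
            mu_lo, warm = mid, warm_mid
        else:
            mu_hi = mid
    return 0.5 * (mu_lo + mu_hi)


def invasion_boundary(
    p: Parameters,
    mu_lo: float = 1e-6,
    mu_hi: float = 20.0,
    tol_mu: float = TOL_MU,
) -> float:
    """``mu`` at which the invasion multiplier crosses 1, by root bracketing.

    The multiplier is monotone decreasing in ``mu`` over the bracket; raises
    ``ValueError`` when there is no sign change in ``[mu_lo, mu_hi]``.
    """

    def f(mu: float) -> float:
        return invasion_eigenvalue(p.with_(mu=mu)) - 1.0

    f_lo, f_hi = f(mu_lo), f(mu_hi)
    for _ in range(6):
        if f_lo * f_hi <= 0:
            break
        mu_lo, mu_hi = mu_hi, 2.0 * mu_hi
        f_lo, f_hi = f_hi, f(mu_hi)
    else:
        raise ValueError(
            f"invasion multiplier does not cross 1 for mu in scanned range "
            f"(theta={p.theta})"
        )
    return float(brentq(f, mu_lo, mu_hi, xtol=min(tol_mu, 1e-6)))


def sweep_mu(
    p: Parameters,
    mu_grid: Sequence[float],
    opts: SolverOptions = DEFAULT_OPTIONS,
    unstable_branch: bool = True,
) -> pd.DataFrame:
    """One-parameter bifurcation sweep of equilibria along ascending ``mu``.

    For each ``mu`` the table gets a coexistence row (attractor from the
    warm-started high initial condition, while it exists), an extinct row,
    and — inside the bistable band — an unstable row continued by Newton
    from a midpoint guess.  Columns: ``mu, branch, stability, R, J, A,
    Jbar, Abar, Bbar, max_multiplier``.
    """
    mu_grid = list(mu_grid)
    if any(b < a for a, b in zip(mu_grid, mu_grid[1:])):
        raise ValueError("mu_grid must be ascending")
    rows = []
    warm: SeasonState = HIGH_IC
    coex: dict[float, Equilibrium] = {}
    for mu in mu_grid:
        pm = p.with_(mu=mu)
        note = ""
        try:
            eq = find_attractor(pm, warm, opts)
            if eq.stability == "extinct" or not eq.is_coexistence:
                eq = None
        except ConvergenceError as exc:
            # persistent non-equilibrium attractor: report the (possibly
            # unstable) fixed point located by Newton from the last iterate
            eq = None
            if exc.last_state is not None and exc.last_state.consumer_biomass > 1e-6:
                try:
                    last = exc.last_state
                    eq = solve_fixed_point(pm, np.array([last.R, last.J, last.A]), opts)
                    note = "non-equilibrium attractor; nearby fixed point reported"
                except NewtonError as exc2:
                    note = f"no fixed point located: {exc2}"
            if eq is None and note:
                rows.append(dict(theta=p.theta, mu=mu, branch="coexistence", stability="failed",
                                 R=np.nan, J=np.nan, A=np.nan, Jbar=np.nan,
                                 Abar=np.nan, Bbar=np.nan, max_multiplier=np.nan,
                                 note=note))
                continue
        if eq is not None:
            coex[mu] = eq
            warm = eq.state
            rows.append(dict(theta=p.theta, mu=mu, branch="coexistence", stability=eq.stability,
                             R=eq.state.R, J=eq.state.J, A=eq.state.A,
                             Jbar=eq.averages[0], Abar=eq.averages[1],
                             Bbar=eq.averages[2],
                             max_multiplier=eq.max_multiplier, note=note))
        rows.append(dict(theta=p.theta, mu=mu, branch="extinct", stability="extinct",
                         R=p.Kr, J=0.0, A=0.0, Jbar=0.0, Abar=0.0, Bbar=0.0,
                         max_multiplier=invasion_eigenvalue(pm), note=""))
    if unstable_branch and coex:
        guess: Optional[np.ndarray] = None
        for mu in mu_grid:
            pm = p.with_(mu=mu)
            if invasion_eigenvalue(pm) >= 1.0 or mu not in coex:
                continue  # unstable branch exists only in the bistable band
            eq = coex[mu]
            if guess is None:
                # the threshold branch emerges from the extinct state at the
                # invasion boundary: seed Newton from a low mixture
                guess = 0.1 * np.array([eq.state.R, eq.state.J, eq.state.A]) \
                    + 0.9 * np.array([p.Kr, 0.0, 0.0])
            try:
                uns = solve_fixed_point(pm, guess, opts)
            except NewtonError:
                guess = None
                continue
            if uns.stability == "unstable":
                guess = np.array([uns.state.R, uns.state.J, uns.state.A])
                rows.append(dict(theta=p.theta, mu=mu, branch="unstable", stability="unstable",
                                 R=uns.state.R, J=uns.state.J, A=uns.state.A,
                                 Jbar=uns.averages[0], Abar=uns.averages[1],
                                 Bbar=uns.averages[2],
                                 max_multiplier=uns.max_multiplier, note=""))
    df = pd.DataFrame(rows)
    return df.sort_values(["branch", "mu"], kind="stable").reset_index(drop=True)


def boundary_point(
    theta: float,
    p: Parameters,
    opts: SolverOptions = DEFAULT_OPTIONS,
    mu_bracket: Optional[tuple[float, float]] = None,
    tol_mu: float = TOL_MU,
) -> BoundaryPoint:
    """Persistence and invasion boundaries at one ``theta``."""
    pt = p.with_(theta=theta)
    if mu_bracket is None:
        mu_bracket = (0.1, max(20.0, 10.0 * theta))
    mu_p = persistence_boundary(pt, *mu_bracket, tol_mu=tol_mu, opts=opts)
    mu_i = invasion_boundary(pt, tol_mu=tol_mu)
    return BoundaryPoint(theta, mu_p, mu_i)


def two_parameter_diagram(
    theta_grid: Sequence[float],
    p: Parameters,
    opts: SolverOptions = DEFAULT_OPTIONS,
    tol_mu: float = TOL_MU,
) -> pd.DataFrame:
    """Persistence/invasion boundary curves over an ascending ``theta`` grid.

    Returns a table with columns ``theta, mu_persist, mu_invade, bistable``.
    The persistence bisection at each ``theta`` is warm-bracketed around the
    previous ``theta``'s boundary.  Per-point failures are recorded as NaN
    rows rather than aborting the scan.
    """
    thetas = list(theta_grid)
    if any(b < a for a, b in zip(thetas, thetas[1:])):
        raise ValueError("theta_grid must be ascending")
    rows = []
    prev_mu: Optional[float] = None
    for theta in thetas:
        bracket = None
        if prev_mu is not None:
            bracket = (max(0.05, prev_mu - 2.0), prev_mu + 2.0)
        try:
            bp = boundary_point(theta, p, opts, mu_bracket=bracket, tol_mu=tol_mu)
        except (ValueError, ConvergenceError):
            try:  # retry with the default wide bracket
                bp = boundary_point(theta, p, opts, tol_mu=tol_mu)
            except (ValueError, ConvergenceError):
                rows.append(dict(theta=theta, mu_persist=np.nan,
                                 mu_invade=np.nan, bistable=False))
                continue
        prev_mu = bp.mu_persist
        rows.append(dict(theta=theta, mu_persist=bp.mu_persist,
                         mu_invade=bp.mu_invade, bistable=bp.bistable))
    return pd.DataFrame(rows, columns=["theta", "mu_persist", "mu_invade", "bistable"])


def bistability_onset(
    p: Parameters,
    theta_lo: float = 0.25,
    theta_hi: float = 0.5,
    tol_theta: float = 0.01,
    opts: SolverOptions = DEFAULT_OPTIONS,
) -> float:
    """Smallest ``theta`` at which the persistence-invasion gap opens.

    Bisects on the sign of ``(mu_persist - mu_invade) - BISTABLE_GAP``.
    The bracket must straddle the onset: no bistability at ``theta_lo``,
    bistability at ``theta_hi``.
    """
    cache: dict[float, float] = {}
    prev_mu: Optional[float] = None

    def gap(theta: float) -> float:
        nonlocal prev_mu
        if theta not in cache:
            bracket = None
            if prev_mu is not None:
                bracket = (max(0.05, prev_mu - 2.0), prev_mu + 2.0)
            try:
                bp = boundary_point(theta, p, opts, mu_bracket=bracket)
            except ValueError:
                bp = boundary_point(theta, p, opts)
            prev_mu = bp.mu_persist
            cache[theta] = bp.mu_persist - bp.mu_invade
        return cache[theta]

    g_lo, g_hi = gap(theta_lo), gap(theta_hi)
    if g_lo > BISTABLE_GAP:
        raise ValueError(f"already bistable at theta={theta_lo}")
    if g_hi <= BISTABLE_GAP:
        raise ValueError(f"not bistable at theta={theta_hi}")
    while theta_hi - theta_lo > tol_theta:
        mid = 0.5 * (theta_lo + theta_hi)
        if gap(mid) > BISTABLE_GAP:
            theta_hi = mid
        else:
            theta_lo = mid
    return 0.5 * (theta_lo + theta_hi)
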