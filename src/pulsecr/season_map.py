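"""One-season integration, the reproduction pulse, and season iteration.

The model is semi-discrete: within a season of fixed unit length the
densities follow the ODEs of :mod:`pulsecr.model_core`; at the season
boundary adults release their entire energy storage as newborn juvenile
biomass (the reproduction pulse).  The composition of the two — integrate
one season, then pulse — is the *season map*, whose fixed points are the
model's equilibria.

Season averages of J, A and B are computed by carrying three extra ODE
components (the running integrals) through the solver rather than by
post-hoc quadrature on dense output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import Parameters, SeasonState, make_rhs

__all__ = [
    "SolverOptions",
    "SeasonResult",
    "IterationResult",
    "SeasonMapError",
    "integrate_season",
    "reproduction_pulse",
    "iterate_seasons",
    "trajectory_frame",
    "summary_frame",
]

SEASON_LENGTH = 1.0


class SeasonMapError(RuntimeError):
    """Raised when the within-season ODE solver fails."""


@dataclass(frozen=True)
class SolverOptions:
    """Numerical options for season integration and iteration.

    The within-season rates reach ~100 per unit time while the season is of
    length 1, and the field has non-smooth switch points (starvation
    clipping, maturation onset); tight tolerances with a stiff-capable
    adaptive method keep the map accurate through both.

    Attributes
    ----------
    rtol, atol : float
        Relative / absolute integration tolerances.
    method : str
        Any ``scipy.integrate.solve_ivp`` method; LSODA switches to a stiff
        integrator automatically when needed.
    ext_tol : float
        Total consumer biomass below which the population is declared
        extinct — far below any meaningful density, above solver round-off.
    tol_fix : float
        Max-norm change of the post-pulse state below which a season is
        counted toward convergence.
    fix_window : int
        Number of consecutive sub-``tol_fix`` seasons required to declare
        convergence (the map contracts slowly near folds).
    max_seasons : int
        Iteration cap before giving up with flag ``"max_iter"``.
    n_dense : int
        Number of equally spaced sample points for dense trajectories.
    """

    rtol: float = 1e-10
    atol: float = 1e-12
    method: str = "LSODA"
    ext_tol: float = 1e-10
    tol_fix: float = 1e-9
    fix_window: int = 10
    max_seasons: int = 2000
    n_dense: int = 201

    def with_(self, **kwargs) -> "SolverOptions":
        return replace(self, **kwargs)


DEFAULT_OPTIONS = SolverOptions()


@dataclass
class SeasonResult:
    """Outcome of integrating one season (before the reproduction pulse)."""

    end_state: SeasonState
    averages: tuple[float, float, float]  # (Jbar, Abar, Bbar)
    trajectory: Optional[np.ndarray] = None  # columns (t, R, J, A, B)
    sol: Optional[object] = field(default=None, repr=False)  # dense interpolant

    @property
    def Jbar(self) -> float:
        return self.averages[0]

    @property
    def Abar(self) -> float:
        return self.averages[1]

    @property
    def Bbar(self) -> float:
        return self.averages[2]


def integrate_season(
    s0: SeasonState,
    p: Parameters,
    opts: SolverOptions = DEFAULT_OPTIONS,
    dense: bool = False,
) -> SeasonResult:
    """Integrate the within-season ODEs from ``s0`` over one unit season.

    Returns the end-of-season state together with the season averages
    (integrals over [0, 1]) of J, A and B.  With ``dense=True`` the result
    also carries a sampled trajectory and the solver's dense interpolant.
    """
    y0 = np.concatenate([s0.as_array(), np.zeros(3)])
    sol = solve_ivp(
        make_rhs(p),
        (0.0, SEASON_LENGTH),
        y0,
        method=opts.method,
        rtol=opts.rtol,
        atol=opts.atol,
        dense_output=dense,
    )
    if not sol.success:
        raise SeasonMapError(
            f"season integration failed from {s0} at {p}: {sol.message}"
        )
    yT = sol.y[:, -1]
    # absorb integrator round-off just below zero
    clip = 100.0 * opts.atol + 10.0 * opts.rtol * float(np.max(np.abs(yT)))
    end_state = SeasonState.from_array(yT[:4], clip_negative_tol=clip)
    averages = tuple(float(max(v, 0.0)) for v in yT[4:7])
    trajectory = None
    if dense:
        ts = np.linspace(0.0, SEASON_LENGTH, opts.n_dense)
        ys = sol.sol(ts)
        trajectory = np.column_stack([ts, ys[:4].T])
    return SeasonResult(end_state, averages, trajectory, sol.sol if dense else None)


def reproduction_pulse(s: SeasonState) -> SeasonState:
    """Apply the between-season reproduction map.

    Adults release all stored reproductive energy as newborn juvenile
    biomass: (R, J, A, B) -> (R, J + B, A, 0).  Total consumer biomass is
    conserved exactly and the resource is untouched.
    """
    return SeasonState(s.R, s.J + s.B, s.A, 0.0)


@dataclass
class IterationResult:
    """Season-by-season iteration record.

    ``states`` holds the post-pulse (beginning-of-season) states, starting
    with the initial condition; ``results`` the per-season integration
    outcomes.  ``flag`` is ``"converged"``, ``"extinct"`` or ``"max_iter"``.
    """

    states: list[SeasonState]
    results: list[SeasonResult]
    flag: str
    n_seasons: int = 0

    @property
    def final_state(self) -> SeasonState:
        return self.states[-1]


def iterate_seasons(
    s0: SeasonState,
    p: Parameters,
    n_max: Optional[int] = None,
    opts: SolverOptions = DEFAULT_OPTIONS,
    keep_results: bool = True,
) -> IterationResult:
    """Iterate the season map from ``s0`` until convergence or extinction.

    Termination:

    * ``"converged"`` — successive post-pulse states changed by less than
      ``opts.tol_fix`` (max-norm) for ``opts.fix_window`` consecutive
      seasons;
    * ``"extinct"`` — total consumer biomass dropped below ``opts.ext_tol``;
    * ``"max_iter"`` — neither happened within ``n_max`` seasons.
    """
    if n_max is None:
        n_max = opts.max_seasons
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    states = [s0]
    results: list[SeasonResult] = []
    prev = s0.as_array()
    streak = 0
    flag = "max_iter"
    n_done = 0
    for _ in range(n_max):
        res = integrate_season(states[-1], p, opts)
        post = reproduction_pulse(res.end_state)
        if keep_results:
            results.append(res)
        states.append(post)
        n_done += 1
        cur = post.as_array()
        if post.consumer_biomass < opts.ext_tol:
            flag = "extinct"
            break
        streak = streak + 1 if np.max(np.abs(cur - prev)) < opts.tol_fix else 0
        if streak >= opts.fix_window:
            flag = "converged"
            break
        prev = cur
    return IterationResult(states, results, flag, n_done)


def trajectory_frame(results: Sequence[SeasonResult]):
    """Stack dense per-season trajectories into a tidy table.

    Columns: ``season, t, R, J, A, B`` with ``t`` the within-season time.
    Seasons integrated without ``dense=True`` are skipped.
    """
    import pandas as pd

    rows = []
    for n, res in enumerate(results, start=1):
        if res.trajectory is None:
            continue
        df = pd.DataFrame(res.trajectory, columns=["t", "R", "J", "A", "B"])
        df.insert(0, "season", n)
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["season", "t", "R", "J", "A", "B"])
    return pd.concat(rows, ignore_index=True)


def summary_frame(it: IterationResult):
    """Per-season summary table.

    Columns: ``season, R_start, J_start, A_start, Jbar, Abar, Bbar`` where
    the ``_start`` values are post-pulse (beginning-of-season) densities.
    """
    import pandas as pd

    rows = []
    for n, res in enumerate(it.results, start=1):
        start = it.states[n - 1]
        rows.append(
            {
                "season": n,
                "R_start": start.R,
                "J_start": start.J,
                "A_start": start.A,
                "Jbar": res.Jbar,
                "Abar": res.Abar,
                "Bbar": res.Bbar,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["season", "R_start", "J_start", "A_start", "Jbar", "Abar", "Bbar"],
    )
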