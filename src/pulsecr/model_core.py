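"""Within-season rate functions and derivative field of the biomass model.

The model tracks a shared resource ``R`` (semi-chemostat growth) and a
consumer population split into juvenile biomass ``J``, adult biomass ``A``
and the adults' reproductive-energy storage ``B``.  Within a growing season
(of fixed unit length) all four densities change continuously:

* juveniles and adults feed on the resource with a linear (type I)
  functional response, adults at ``theta`` times the mass-specific rate of
  juveniles;
* assimilated intake minus maintenance gives the mass-specific net biomass
  production ``nu_j``/``nu_a`` of each stage;
* juveniles grow and mature at a rate derived from a size-structured
  analogue, adults channel their entire net production into storage ``B``;
* when net production is negative the shortfall is taken as extra
  (starvation) mortality so that biomass is conserved.

All functions here are pure and operate on scalars; the derivative field is
consumed by :mod:`pulsecr.season_map` which handles integration and the
between-season reproduction pulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np

__all__ = [
    "Parameters",
    "SeasonState",
    "resource_turnover",
    "net_production",
    "clipped_production",
    "maturation_rate",
    "maturation_rate_derivative",
    "stage_mortality",
    "within_season_derivatives",
    "make_rhs",
]

Stage = Literal["juvenile", "adult"]

#: relative half-width of the removable singularity guard in maturation_rate
_SINGULAR_GUARD = 1e-8


@dataclass(frozen=True)
class Parameters:
    """Model constants.

    ``theta`` (adult:juvenile mass-specific intake ratio) and ``mu``
    (stage-independent background mortality rate) are the two parameters
    varied in every analysis and must be given explicitly; the remaining
    constants default to the standard parameterisation.

    Attributes
    ----------
    theta : float
        Adult-juvenile mass-specific intake ratio (dimensionless, > 0).
    mu : float
        Stage-independent background mortality rate (per unit time, >= 0).
    rho : float
        Resource turn-over rate (per unit time).
    Kr : float
        Maximum resource density (gram/L).
    Imax : float
        Mass-specific attack rate of juveniles (per unit time).
    Q : float
        Mass-specific maintenance rate (per unit time).
    sigma : float
        Conversion efficiency of ingested resource (dimensionless, in (0, 1]).
    z : float
        Newborn-to-adult body-size ratio (dimensionless, in (0, 1)).
    """

    theta: float
    mu: float
    rho: float = 10.0
    Kr: float = 2.0
    Imax: float = 100.0
    Q: float = 10.0
    sigma: float = 0.5
    z: float = 0.1

    def __post_init__(self) -> None:
        for name in ("rho", "Kr", "Imax", "Q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.sigma <= 1:
            raise ValueError("sigma must lie in (0, 1]")
        if not 0 < self.z < 1:
            raise ValueError("z must lie in (0, 1)")
        if not self.theta > 0:
            raise ValueError("theta must be strictly positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    def with_(self, **kwargs) -> "Parameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def starvation_threshold(self) -> float:
        """Resource density Q/(sigma*Imax) below which juveniles starve."""
        return self.Q / (self.sigma * self.Imax)


@dataclass(frozen=True)
class SeasonState:
    """Densities (R, J, A, B) at one time point within a season.

    ``B`` is zero immediately after a reproduction pulse; all components
    are non-negative biomass densities.
    """

    R: float
    J: float
    A: float
    B: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R", "J", "A", "B"):  # normalise numpy scalars
            object.__setattr__(self, name, float(getattr(self, name)))
        arr = (self.R, self.J, self.A, self.B)
        if not all(math.isfinite(x) for x in arr):
            raise ValueError(f"non-finite state component in {arr}")
        if any(x < 0 for x in arr):
            raise ValueError(f"negative state component in {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.J, self.A, self.B], dtype=float)

    @classmethod
    def from_array(cls, y, clip_negative_tol: float = 0.0) -> "SeasonState":
        """Build a state from an array, optionally zeroing tiny negatives.

        ``clip_negative_tol`` allows absorbing integrator round-off: values
        in ``[-tol, 0)`` are set to 0, anything more negative raises.
        """
        y = np.asarray(y, dtype=float)
        if clip_negative_tol:
            if np.any(y < -clip_negative_tol):
                raise ValueError(f"state {y} negative beyond tolerance")
            y = np.maximum(y, 0.0)
        return cls(*map(float, y[:4]))

    @property
    def consumer_biomass(self) -> float:
        """Total consumer biomass J + A + B."""
        return self.J + self.A + self.B


def resource_turnover(R: float, p: Parameters) -> float:
    """Semi-chemostat resource turn-over G(R) = rho * (Kr - R)."""
    if R < 0:
        raise ValueError("resource density must be non-negative")
    return p.rho * (p.Kr - R)


def net_production(R: float, p: Parameters, stage: Stage) -> float:
    """Mass-specific net biomass production nu(R) = sigma * intake - Q.

    Juveniles ingest at rate ``Imax * R`` per unit body mass, adults at
    ``theta * Imax * R``.  Negative values mean maintenance exceeds
    assimilation (starvation regime).
    """
    if R < 0:
        raise ValueError("resource density must be non-negative")
    if stage == "juvenile":
        return p.sigma * p.Imax * R - p.Q
    if stage == "adult":
        return p.sigma * p.theta * p.Imax * R - p.Q
    raise ValueError(f"unknown stage {stage!r}")


def clipped_production(nu: float) -> float:
    """Non-negative part nu+ = max(nu, 0) used for growth/storage gain."""
    return nu if nu > 0 else 0.0


def maturation_rate(nu_j: float, mu: float, z: float) -> float:
    """Per-capita maturation rate gamma(nu_j, mu) of juveniles.

    gamma = (nu_j - mu) / (1 - z**(1 - mu/nu_j)) for nu_j > 0, else 0.

    The formula makes the biomass model consistent with a fully
    size-structured analogue: it accounts for the growth from newborn size
    to maturation size (a factor 1/z in body mass) and for mortality thinning
    the cohort along the way.  The expression has a removable singularity at
    ``nu_j == mu`` where its limit is ``-nu_j / ln(z)``; within a relative
    distance of 1e-8 from the singularity the limit value is used.  Evaluated
    through ``expm1`` to stay accurate near the singularity.
    """
    if not 0 < z < 1:
        raise ValueError("z must lie in (0, 1)")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if nu_j <= 0:
        return 0.0
    lz = math.log(z)
    if abs(nu_j - mu) <= _SINGULAR_GUARD * mu:
        return -nu_j / lz
    w = (1.0 - mu / nu_j) * lz
    if w > 350.0:  # nu_j << mu: 1 - z**(1-mu/nu_j) would overflow
        return (mu - nu_j) * math.exp(-w)
    return (nu_j - mu) / (-math.expm1(w))


def maturation_rate_derivative(nu_j: float, mu: float, z: float) -> float:
    """d gamma / d nu_j, analytic, for the variational equations.

    Zero for ``nu_j < 0`` (gamma is identically 0 there).  Near the removable
    singularity ``nu_j == mu`` the closed form is a 0/0 expression; within a
    relative distance of 1e-6 the limit value ``1/2 - 1/ln(z)`` is used.
    """
    if nu_j <= 0:
        return 0.0
    lz = math.log(z)
    if abs(nu_j - mu) <= 1e-6 * max(mu, 1.0):
        return 0.5 - 1.0 / lz
    w = (1.0 - mu / nu_j) * lz
    if w > 350.0:
        # gamma ~ (mu - nu_j) e^{-w}; differentiate directly
        dw = mu / nu_j**2 * lz
        return (-1.0 - (mu - nu_j) * dw) * math.exp(-w)
    ew = math.exp(w)
    D = -math.expm1(w)  # 1 - z**(1 - mu/nu_j)
    dD = -ew * lz * mu / nu_j**2
    return (D - (nu_j - mu) * dD) / (D * D)


def stage_mortality(R: float, p: Parameters, stage: Stage) -> float:
    """Total per-capita mortality d(R) = mu + (nu+ - nu) for a stage.

    Equals the background rate ``mu`` whenever net production is
    non-negative; when the stage starves the (negative) net production is
    added back as starvation mortality, conserving biomass.
    """
    nu = net_production(R, p, stage)
    return p.mu + (clipped_production(nu) - nu)


def make_rhs(p: Parameters, averages: bool = True) -> Callable:
    """Build the within-season derivative field as a fast ``f(t, y)`` closure.

    With ``averages=True`` the state is 7-dimensional:
    ``(R, J, A, B, Jcum, Acum, Bcum)`` where the last three integrate J, A
    and B over the season, so that season averages fall out of the ODE
    solution itself instead of a post-hoc quadrature.
    """
    rho, Kr, Imax, Q, sigma, theta, mu, z = (
        p.rho, p.Kr, p.Imax, p.Q, p.sigma, p.theta, p.mu, p.z,
    )
    sI = sigma * Imax
    sIt = sigma * theta * Imax
    _gamma = maturation_rate

    if averages:
        def rhs(t, y):
            R, J, A, B = y[0], y[1], y[2], y[3]
            nu_j = sI * R - Q
            nu_a = sIt * R - Q
            nujp = nu_j if nu_j > 0 else 0.0
            nuap = nu_a if nu_a > 0 else 0.0
            gam = _gamma(nu_j, mu, z)
            dj = mu + (nujp - nu_j)
            da = mu + (nuap - nu_a)
            return (
                rho * (Kr - R) - Imax * R * (J + theta * A),
                (nujp - gam - dj) * J,
                gam * J - da * A,
                nuap * A - da * B,
                J,
                A,
                B,
            )
    else:
        def rhs(t, y):
            R, J, A, B = y[0], y[1], y[2], y[3]
            nu_j = sI * R - Q
            nu_a = sIt * R - Q
            nujp = nu_j if nu_j > 0 else 0.0
            nuap = nu_a if nu_a > 0 else 0.0
            gam = _gamma(nu_j, mu, z)
            dj = mu + (nujp - nu_j)
            da = mu + (nuap - nu_a)
            return (
                rho * (Kr - R) - Imax * R * (J + theta * A),
                (nujp - gam - dj) * J,
                gam * J - da * A,
                nuap * A - da * B,
            )

    return rhs


def within_season_derivatives(s: SeasonState, p: Parameters) -> np.ndarray:
    """Derivatives (dR, dJ, dA, dB, dJcum, dAcum, dBcum) at state ``s``.

    The last three components are the averaging accumulators (J, A, B
    themselves), so integrating the full 7-vector over the unit season
    yields the season averages alongside the end-of-season state.
    """
    y = s.as_array()
    return np.array(make_rhs(p, averages=True)(0.0, y), dtype=float)


def field_jacobian(s_arr: np.ndarray, p: Parameters) -> np.ndarray:
    """Analytic 4x4 Jacobian of the (R, J, A, B) derivative field.

    Used by the variational route to the season-map Jacobian.  The field is
    continuous but only piecewise smooth (starvation clipping, maturation
    switch-on); at the switch points the right-sided derivative is returned,
    which the integrator only ever sees on a measure-zero set.
    """
    R, J, A, B = s_arr[:4]
    sI = p.sigma * p.Imax
    sIt = p.sigma * p.theta * p.Imax
    nu_j = sI * R - p.Q
    nu_a = sIt * R - p.Q
    nujp = clipped_production(nu_j)
    nuap = clipped_production(nu_a)
    gam = maturation_rate(nu_j, p.mu, p.z)
    dgam_dR = maturation_rate_derivative(nu_j, p.mu, p.z) * sI
    dj = p.mu + (nujp - nu_j)
    da = p.mu + (nuap - nu_a)
    # d(nu+)/dR and d(d)/dR depend on the starvation branch
    dnujp_dR = sI if nu_j > 0 else 0.0
    dnuap_dR = sIt if nu_a > 0 else 0.0
    ddj_dR = dnujp_dR - sI
    dda_dR = dnuap_dR - sIt

    Jac = np.zeros((4, 4))
    # resource row
    Jac[0, 0] = -p.rho - p.Imax * (J + p.theta * A)
    Jac[0, 1] = -p.Imax * R
    Jac[0, 2] = -p.Imax * p.theta * R
    # juvenile row: dJ/dt = (nujp - gam - dj) J
    Jac[1, 0] = (dnujp_dR - dgam_dR - ddj_dR) * J
    Jac[1, 1] = nujp - gam - dj
    # adult row: dA/dt = gam J - da A
    Jac[2, 0] = dgam_dR * J - dda_dR * A
    Jac[2, 1] = gam
    Jac[2, 2] = -da
    # storage row: dB/dt = nuap A - da B
    Jac[3, 0] = dnuap_dR * A - dda_dR * B
    Jac[3, 2] = nuap
    Jac[3, 3] = -da
    return Jac
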