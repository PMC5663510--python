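# Methods

## Model

`pulsecr` implements a semi-discrete (impulsive) consumer-resource biomass
model. Within a growing season of fixed unit length, four densities evolve
continuously:

- resource `R` with semi-chemostat turnover `G(R) = rho (Kr - R)`;
- juvenile consumer biomass `J`;
- adult consumer biomass `A`;
- the adults' reproductive-energy storage `B`.

Both stages feed on the resource with a linear (type I) functional response,
juveniles at mass-specific attack rate `Imax`, adults at `theta * Imax`.
Net biomass production per unit body mass is intake times conversion
efficiency minus maintenance, `nu_j(R) = sigma Imax R - Q` and
`nu_a(R) = sigma theta Imax R - Q`. Positive net production drives juvenile
somatic growth and adult storage accumulation; negative net production is
clipped out of growth and added to mortality instead (starvation mortality),
so biomass is conserved in either regime: below the starvation threshold
`R = Q / (sigma Imax)` the juvenile equation collapses to
`dJ/dt = (nu_j - mu) J` exactly, and likewise for adults and storage.

Juveniles mature at per-capita rate

    gamma(nu_j, mu) = (nu_j - mu) / (1 - z^(1 - mu/nu_j))   for nu_j > 0,
    gamma = 0                                                otherwise,

where `z` is the newborn:adult body-size ratio. This specific form keeps the
two-stage biomass model consistent with a fully size-structured analogue:
it encodes the body-mass growth from birth size to maturation size and the
mortality thinning of a cohort on the way. The expression has a removable
singularity at `nu_j = mu` with limit `-nu_j / ln(z)`.

At each season boundary adults release their entire storage as newborn
juvenile biomass: `(R, J, A, B) -> (R, J + B, A, 0)`. The composition of a
one-season ODE flow with this pulse is the *season map*; all statements
about "equilibria" refer to its fixed points in the post-pulse variables
`(R, J, A)` (the pulse forces `B = 0`, so the map is three-dimensional).

Season averages of `J`, `A`, `B` are carried as three additional ODE
components (running integrals) rather than recovered by post-hoc quadrature,
so they share the integrator's error control.

## Default parameterisation

| parameter | meaning | unit | default |
|---|---|---|---|
| `rho` | resource turn-over rate | 1/time | 10 |
| `Kr` | maximum resource density | g/L | 2 |
| `Imax` | juvenile mass-specific attack rate | 1/time | 100 |
| `Q` | mass-specific maintenance rate | 1/time | 10 |
| `sigma` | conversion efficiency | – | 0.5 |
| `z` | newborn:adult size ratio | – | 0.1 |
| `theta` | adult:juvenile intake ratio | – | *required* |
| `mu` | background mortality rate | 1/time | *required* |

`theta` and `mu` are the analysis parameters and deliberately have no
defaults: every entry point requires them explicitly (a scenario preset, a
config entry or a flag). Named scenarios cover the canonical settings:
`bistable-high` / `bistable-low` (`theta=2, mu=9`, starting above or below
the Allee threshold), `single-attractor` (`theta=0.25, mu=3.5`), and
`life-history` (`theta=1, mu=8`).

## Numerics

- **Integration.** `scipy.integrate.solve_ivp` with LSODA, `rtol=1e-10`,
  `atol=1e-12`. Rates reach ~100 per unit time over a unit season, so the
  system is moderately stiff; the starvation and maturation switches leave
  the field continuous but non-smooth, which is handled by tolerance
  tightness rather than event detection (the switch manifolds are crossed
  transversally and contribute only isolated non-smooth points).
- **Singularity guard.** `gamma` is evaluated via `expm1`; within a relative
  distance of `1e-8` of `nu_j = mu` the limit `-nu_j/ln(z)` is substituted.
  The two branches agree to ~1e-8 relative at the guard boundary. For
  `nu_j << mu` the equivalent form `(mu - nu_j) e^{-w}` avoids overflow of
  `z^(1 - mu/nu_j)`.
- **Fixed points.** Stable equilibria: forward iteration of the season map
  (convergence when post-pulse states change by `< 1e-9` max-norm for 10
  consecutive seasons), polished by Newton on `Phi(x) - x` with central
  finite-difference Jacobians (step `1e-6 (1 + |x_i|)`); the polish is only
  accepted when Newton converges to a *stable* point close to the current
  iterate, so that basins are never jumped near a fold. Unstable equilibria:
  damped Newton from explicit guesses, continued in `mu` along sweeps.
  A second, independent Jacobian route (variational matrix ODE with the
  analytic field Jacobian) is kept as a cross-check; the two agree to
  better than 1e-5 relative in the tests.
- **Stability.** Eigenvalue moduli of the 3x3 map Jacobian; a `1e-6` band
  around the unit circle is reported as `marginal` rather than silently
  classified.
- **Extinction.** Total consumer biomass below `1e-10` — far below any
  meaningful density, above accumulated solver error.
- **Non-equilibrium attractors.** At low mortality (e.g. `theta=0.25,
  mu=0.1`) the coexistence fixed point loses stability and the model settles
  on a small-amplitude cycle. Forward iteration then hits the season cap;
  the failure carries the last iterate, and *persistence* classification
  (which is about extinction, not about convergence) counts such a state as
  persisting, while `sweep_mu` reports the nearby (unstable) fixed point
  located by Newton, flagged as such. `find_attractor` itself reports
  non-convergence honestly instead of assuming fixed-point dynamics.

## Boundaries and bistability

- **Persistence boundary**: highest `mu` with a persisting consumer,
  by bisection to width `1e-3`, warm-starting each probe from the last
  persisting state so the attractor branch is tracked up to its fold.
- **Invasion boundary**: at the resource-only state `R = Kr` the linearised
  consumer dynamics have constant coefficients; the season transition matrix
  is a matrix exponential, composed with the pulse map, and the boundary is
  the root in `mu` of its spectral radius minus 1 (bracketed bisection).
  A direct-integration construction of the same multiplier serves as an
  independent oracle.
- **Bistability flag**: `mu_persist - mu_invade > 5e-3` (five bisection
  widths). The model also possesses a very small region of two alternative
  *coexistence* states at intermediate `theta`; the deliberately coarse gap
  threshold keeps that sliver from being reported as the headline Allee
  region, which is the bistability between coexistence and the resource-only
  state. The onset of that Allee region in `theta` is located by bisection
  (tolerance 0.01) on the gap criterion, with `mu` brackets warm-started
  across `theta`.

## Life-history functional R0(t_m)

For a newborn at season start, the expected contribution to end-of-season
reproductive output of individuals maturing at time `t_m` is

    R0(t_m) = gamma(t_m) * exp(-mu + Int_0^{t_m} [nu_j - gamma] dtau)
              * Int_{t_m}^1 nu_a dtau

with all rates evaluated along a fixed resource trajectory `R(t)`. The
grouping adopted here reads the exponent as season-long background survival
`e^{-mu}` times the net (mortality-free) growth of the juvenile cohort up to
maturation, with the post-maturation storage integral undiscounted — the
adult survival from `t_m` to `t` and the storage mortality from `t` to 1
combine to exactly `e^{-mu(1 - t_m)}`, which merges into the single factor.
This is the unique grouping consistent with the model's biomass bookkeeping,
and it is verified numerically: the integral of `R0` over all `t_m` equals
the end-of-season storage `B(1)` of a unit juvenile cohort simulated
directly (agreement to ~1e-4, the quadrature error of the 401-point grid).

The within-season cumulants `Int (nu_j - gamma)` and `Int nu_a` are obtained
by one auxiliary ODE integration with dense output, so `R0` is evaluable at
arbitrary `t_m` (the ODE-augmentation approach); curves are reported on a
401-point uniform `t_m` grid, with extrema refined by bounded scalar
optimisation of the exact evaluator and unit crossings by root bracketing.

Two environments are compared at the same parameters: *coupled* (the `R(t)`
of the converged fixed-point season — obtained by running the full model to
its attractor, then freezing one season's dense resource interpolant) and
*decoupled* (`R ≡ Kr`, no consumer feedback), for which `R0` has the closed
form `gamma* e^{-mu} e^{(nu_j* - gamma*) t_m} nu_a* (1 - t_m)` used as an
oracle. Cohort experiments integrate the linear (no-feedback) consumer
equations from one unit of juvenile biomass against either environment.
Where the text reports "all juveniles have matured", the operational
criterion is cohort juvenile biomass falling below 1% of its initial unit.

## Problem sizes

The shipped analyses use: season-map bisections over `mu` in `[0.1, 20]` to
width `1e-3` (~15 probes per boundary, each probe a forward iteration of at
most 2000 seasons, typically 30–300); onset bisection over `theta` in
`[0.25, 0.5]` to width 0.01; 401-point `t_m` and cohort sampling grids.
These sizes resolve every reported landmark well inside its quoted
precision; they are the package defaults, not hard limits.

## Known limitations

- Fixed unit season length, a single reproduction pulse per season, no
  within-season environmental forcing.
- Type I (linear) functional response only.
- Stage-independent background mortality; no size-resolved cohort structure
  (body size enters only through `z` and the maturation-rate form).
- Cycles are detected and reported but not continued or characterised; the
  tiny alternative-coexistence-state region at intermediate `theta` is
  deliberately not charted.
- The multi-season reproductive value of a newborn is not computed; `R0`
  counts contributions to the first reproduction event only.
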