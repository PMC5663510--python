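# pulsecr

Stage-structured consumer-resource biomass dynamics with pulsed seasonal
reproduction.

Many consumer populations — fish stocks are the canonical example — forage
and die year-round but reproduce in a single short burst each year. `pulsecr`
implements a semi-discrete model of such a population: within a growing
season (length fixed to 1) a resource `R`, juvenile biomass `J`, adult
biomass `A` and the adults' reproductive-energy storage `B` follow ODEs,
and at each season boundary the stored energy is released as newborn
juvenile biomass,

    R_{n+1}(0) = R_n(1),   J_{n+1}(0) = J_n(1) + B_n(1),
    A_{n+1}(0) = A_n(1),   B_{n+1}(0) = 0.

Within the season, the resource grows semi-chemostat, `G(R) = ρ(K_r − R)`,
and both consumer stages feed with a linear functional response (adults at
`θ` times the juvenile mass-specific rate). Net biomass production
`ν_j = σ I_max R − Q` and `ν_a = σ θ I_max R − Q` drives juvenile growth and
adult storage when positive and becomes starvation mortality when negative.
Juveniles mature at rate `γ(ν_j, μ) = (ν_j − μ)/(1 − z^{1−μ/ν_j})`, which
ties maturation to both food and mortality, consistently with a fully
size-structured analogue.

The package provides, on top of the season map:

- **Equilibria** — fixed points of the map (stable by forward iteration with
  Newton polish, unstable by Newton continuation), with multipliers and
  season-average biomasses;
- **Bifurcation analysis** — one-parameter sweeps in the mortality rate `μ`,
  persistence and invasion boundaries, and the two-parameter `(θ, μ)`
  bistability diagram. For sufficiently large `θ` the invasion boundary
  separates from the persistence boundary: an established population
  persists where a rare one cannot grow — an Allee effect caused purely by
  the timing of maturation relative to the reproduction pulse;
- **Life history** — the expected end-of-season reproductive output
  `R0(t_m)` of a newborn maturing at time `t_m`, in the *coupled*
  environment (resource trajectory of the population's own fixed-point
  season) and the *decoupled* one (resource pinned at `K_r`), plus
  unit-cohort experiments against both environments.

It is aimed at theoretical population ecologists studying stage structure,
seasonality, biomass overcompensation and population collapse.

## Worked example

The Allee-effect dichotomy at `θ = 2, μ = 9`: the same parameters, started
from high versus low consumer biomass:

```sh
$ pulsecr simulate --scenario bistable-high --out out-high
converged after 30 seasons; final state R=1.13326 J=0.402843 A=0.0294822

$ pulsecr simulate --scenario bistable-low --out out-low
extinct after 31 seasons; final state R=2 J=8.03023e-11 A=5.89535e-13
```

From abundant starting biomass the population settles on a coexistence
equilibrium (post-pulse juvenile biomass 0.40 dominates adult biomass 0.03 —
a development-controlled state); from low biomass the same population dies
out and the resource returns to its maximum `K_r = 2`.

Why: compare the expected reproductive output of a newborn in the two
environments at `θ = 1, μ = 8`:

```sh
$ pulsecr r0 --scenario life-history --out out-r0
coupled: total=0.989895 crossings=[0.5114894252634621, 0.9552032597125465] max at tm=0.7994376516357277
decoupled: total=0.586198 crossings=[0.22538287413616048] max at tm=None
```

In the untouched (decoupled) environment food is abundant, juveniles mature
almost immediately at small size, and `R0` falls below 1 for any maturation
later than `t_m ≈ 0.23` — the rare invader cannot replace itself (total
expected output 0.59). In the population's own (coupled) environment
maturation is delayed to `t_m ≈ 0.8` at larger body size and the total
expected output is ~69% higher, which is what sustains the established
population at a mortality rate where a rare one goes extinct.

Boundaries in `μ` for a given `θ`, and the bistability region:

```sh
pulsecr sweep --theta 2 --mu-min 0.1 --mu-max 11 --out out-sweep
pulsecr boundary --theta-min 0.25 --theta-max 2 --theta-steps 8 --out out-bnd
```

All commands write CSV tables, a JSON summary and the resolved
configuration into the output directory; outputs are deterministic and
byte-stable across runs.

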