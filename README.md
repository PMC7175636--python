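# critrange

Simulation and verification toolkit for critical lattice population models
— the voter model, the contact process, oriented percolation, and critical
branching random walk — equipped with their *ancestral relations*, together
with the computable super-Brownian-motion (SBM) predictions that govern
their diffusive scaling limits.

## Who this is for

Researchers in probability, mathematical biology and epidemic modelling who
want to probe, at desk scale, the quantitative predictions of the SBM limit
theory for critical spatial populations: survival asymptotics, one-arm
(ball-exit) probabilities, Yaglom laws, spatial moments, and moduli of
continuity of ancestral lineages.

## The models and the limit theory

All models start from a single occupied site at the origin of `Z^d` and
move mass through a symmetric finite-range step kernel `D` (uniform on the
box `[-L, L]^d \ {o}` by default) with per-coordinate variance `σ²_D`:

* **voter model** — each site copies the type of a `D`-chosen neighbour at
  rate 1; the set of 1's, `T_t`, has martingale total mass, and tracing
  the most recent arrow backwards yields the *dual coalescing random
  walks* that define every site's unique ancestral path;
* **contact process** — infected sites recover at rate 1 and infect
  `D`-neighbours at rate `λ`; occupancy is recovery-free oriented arrow
  reachability from `(0, o)` in the graphical record;
* **oriented percolation** — discrete generations; the bond
  `((n,x),(n+1,y))` is open with probability `p·D(y−x)`;
* **critical branching random walk** — the tractable surrogate for
  critical lattice trees; mean-one offspring law with variance `γ`,
  independent kernel displacements, ancestral relation = genealogical
  descent on labelled particles.

Each model carries a relation `(s,y) →ᵃ (t,x)` ("y at time s is an
ancestor of x at time t") satisfying equal-time identity, endpoint
occupancy, the root property, transitivity and interpolation — checked at
runtime by `critrange.ancestry.check_ar_axioms` on every back-end.

Under diffusive rescaling `T^(n)_t = T_{nt}/√n`, these critical models
converge (in their respective dimensions) to SBM with branching rate `γ`
and diffusion parameter `σ₀²`; for the voter model
`(γ, σ₀²) = (2β_D, σ²_D)` with `β_D` the walk's no-return probability, and
for the spread-out models `(γ, σ₀²) = (1, σ²_D v)`. The package computes
the SBM side in closed or numerical form:

* canonical survival `N_o(S > s) = 2/(γs)` and the Yaglom exponential law
  of the time-1 mass, density `(2/γ)e^{−(2/γ)x}`;
* the Laplace transform of the integrated mass over `[1,2]` conditioned on
  survival, `2/(2 + γ v₁^{(λ)})`, through the Riccati solution
  `v_t^{(λ)}`;
* `v_d(0)` — the value at the origin of the radial solution of
  `Δv = v²` on the unit ball blowing up at the boundary — by adaptive
  shooting with blow-up extrapolation (`solve_vd0`);
* `β_D` by Fourier inversion of the walk Green function or Monte Carlo
  (`escape_probability`);
* the model-specific one-arm constants, e.g. for the voter model in
  `d > 2`:  `lim r² P(r₀(R) > r) = σ²_D v_d(0) / (2β_D)`.

## Worked example

```python
>>> import numpy as np
>>> from critrange import (uniform_box_kernel, VoterSpec, solve_vd0,
...                        escape_probability, spatial_moment)
>>> K = uniform_box_kernel(2, 1)          # d=2, 8 neighbours
>>> K.sigma2_D
0.75
>>> spec = VoterSpec(K)
>>> est = spatial_moment(spec, t=4.0, p=2, reps=8000, seed=11)
>>> round(est.value, 2), round(est.se, 2)   # duality predicts t*d*sigma2_D = 6.0
(6.32, 0.24)
>>> sol = solve_vd0(3, tol=1e-6)
>>> round(sol.vd0, 4)
15.7179
>>> K3 = uniform_box_kernel(3, 1)
>>> round(escape_probability(K3)["value"], 4)   # beta_D, d=3
0.856
```

The spatial second moment of the voter model equals the single-random-walk
moment `t·d·σ²_D` exactly (coalescing duality); the Monte-Carlo estimate
reproduces it within one standard error. `v_3(0) ≈ 15.718` and
`β_D ≈ 0.856` combine into the predicted voter one-arm constant
`σ²_D·v_3(0)/(2β_D) ≈ 6.36` for `d = 3`.

A command-line interface mirrors the library:

```sh
critrange gw-survival --n 100 --reps 500000 --seed 1 --out results/
critrange vd0 --out results/
critrange verify --level quick
critrange fixture voter_two_arrow
```

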