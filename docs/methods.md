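# Methods

This note records the models implemented, the conventions and numerical
choices behind them, the sizes at which the verification experiments run,
and what the passing (and deliberately failing-to-converge) checks do and
do not establish.

## Models and graphical constructions

All four models start from a single occupied site at the origin `o` of
`Z^d` and use a symmetric finite-range step kernel `D` with sup-norm range
`L` and isotropic per-coordinate variance `σ²_D` (the default is uniform on
the punctured box, the "spread-out" kernel; any user kernel passing the
symmetry/isotropy invariants at tolerance `1e-12` is accepted). Site radii
are always Euclidean; the kernel range is sup-norm.

**Voter model.** Each ordered pair `(x, y)` carries a Poisson arrow stream
at rate `D(x−y)`: at an arrow the voter at `y` imposes its type on `x`.
The simulator is exact event-driven Monte Carlo on the set `T_t` of sites
of type 1: events are the superposition of an *incoming* stream (rate
`|T|`, arrows into occupied targets from kernel-drawn sources) and an
*outgoing* stream (rate `|T|`, arrows out of occupied sources), with
outgoing arrows into occupied targets discarded as duplicates of the
incoming stream. This lazy materialization records exactly the arrows
whose target is occupied at the arrow time plus the arrows that switch a
vacant site on. That set suffices both to evolve `T_t` and to trace any
dual walk anchored at an occupied space-time point, because an ancestral
trace `w_s(t,x)` stays inside `T_s` for all `s ≤ t`; the trace guard
raises a coverage error if a query ever leaves the occupied region
(which would indicate a record bug, not a numerical issue). Arrows at
exactly the query time are included (right-continuity convention).

**Contact process.** Recovery marks at rate 1 per infected site, infection
arrows out of each infected site at total rate `λ` (all recorded).
Occupancy and the ancestral relation `(s,y) →ᵃ (t,x)` iff
`(0,o) → (s,y) → (t,x)` are answered by a forward time-ordered sweep over
the recorded events — exact because every arrow out of an infected site
and every recovery of an infected site is materialized.

**Oriented percolation.** Bonds out of occupied sites are Bernoulli
`p·D(offset)`; the relation is forward reachability over stored occupied
bonds, extended to real times by floors. Queries use memoized forward
BFS — clusters at the sizes used here are small, and exactness is worth
more than speed.

**Branching random walk.** The surrogate for critical lattice trees
(whose exact critical weighting is not computable). Multi-occupancy, so
the ancestral relation lives on labelled particles `(generation, index)`;
range and one-arm statistics use the projection to occupied sites.

Event times are continuous, so ties have probability zero; fixture records
are validated for distinct positive times. Resource caps (events,
occupied sites, particles) set a `censored` flag — never silent
truncation — and every estimator that touches capped or horizon-limited
replicates reports a `[lo, hi]` bracket by resolving unresolved replicates
both ways, plus the censored fraction. This matters because critical
survival and range tails are heavy (`θ(t) ≍ 1/m(t)`), exactly the
quantities under study.

## Ancestral-relation layer

`check_ar_axioms` verifies on realized samples: equal-time identity,
endpoint occupancy, the root property (exhaustively on a time grid), and
transitivity/interpolation (on sampled ordered time triples with sampled
occupied labels). Path regularity and measurability are properties of the
probabilistic construction, not of single realizations, and are documented
as not runtime-checkable. Path extraction returns the canonical path
where one exists (voter: the dual walk; BRW: the parent chain) and
otherwise walks the jump skeleton backwards choosing the lexicographically
smallest intermediate ancestor — a deterministic tie-break; interpolation
guarantees existence, not uniqueness (for the contact process and OP,
paths are genuinely non-unique and the extractor returns *a* path).
Rescaling `(t, x) ↦ (t/n, x/√n)` is a pure reindexing sharing labels with
the base system.

## Super-Brownian side

* `v_d(0)`: shooting on `v'' + ((d−1)/r)v' = v²`, `v(0)=a`, `v'(0)=0`,
  series start `v ≈ a + a²r²/(2d)` at `r₀ = 1e−7/√a`, DOP853 at
  `rtol = 1e−12`. Blow-up is declared at `v = 1e9` and the remaining
  distance closed with the two-term blow-up expansion
  `v ≈ 6/u² + (6(d−1)/(5R))/u`; the scaling symmetry `λ²v(λ·)` gives
  `v_d(0) = a·R_a²`, independent of the shooting amplitude `a` (verified
  at `a ∈ {0.5, 1, 2}` to `1e−10`). The reported error bound combines
  threshold escalation (`1e6` vs `1e9`) and tolerance coarsening; an
  independent first-integral quadrature for `d = 1`
  (`v'² = (2/3)(v³−1)`) agrees to `2e−6`. Values:
  `v_1(0) = 8.8475`, `v_2(0) = 12.5634`, `v_3(0) = 15.7179`,
  `v_4(0) = 18.6149`.
* `β_D`: for `d = 2` the limit theory's convention `2πσ²_D` is returned
  exactly. For `d > 2`, the Fourier method computes the Green function
  `G = (2π)^{−d}∫ dk/(1−D̂(k))` in polar coordinates (the `k ≈ 0`
  singularity is absorbed by the `ρ^{d−1}` Jacobian; radial
  Gauss–Legendre × product sphere quadrature; the box boundary enters
  through the direction-dependent radial cut-off) and returns `1/G`. The
  Monte-Carlo method counts no-returns over `n_steps` and bounds the
  remaining return probability by the Green asymptotic
  `C_d/|x|^{d−2}` of the endpoint positions (reported as `tail_bound`).
  For the `d = 3`, `L = 1` kernel both give `β_D ≈ 0.856`.
* Closed forms (`2/(γs)`, the Yaglom density, `v_t^{(λ)}`,
  `2/(2+γv₁^{(λ)})`, the small-mass asymptotic `4√(a/(2πγ))` with bound
  `2e√(2a/γ)`) are direct formula evaluations; the Riccati residual
  `dv/dt = −γv²/2 + λ` is checked by finite differences in the tests.
* Assembled predictions: the voter one-arm constant
  `σ²_D v_d(0)/(2β_D)` (`d > 2`; `v_2(0)/(2π)` on the `r²/log r` scale in
  `d = 2`) and the spread-out form `σ²_D v·v_d(0)/(AV)` are asserted at
  build time to agree with the general `σ₀² s_D v_d(0)/2` under the
  model's `(γ, σ₀², s_D, m)`. The lace-expansion constants `A, V, v` are
  user inputs with provenance flags; a plateau estimator for `A` is
  provided and labelled heuristic.

## Experiment sizes and seeds

One master seed per run; replicate `r` of experiment `name` uses
`SeedSequence([master, crc32(name), r])`, so single replicates reproduce in
isolation and results are independent of batching. Sizes used by the
verification battery (chosen to put Monte-Carlo error well below each
check's tolerance): Galton–Watson runs at `n = 100` with `2·10⁵–5·10⁵`
replicates; voter mass and duality checks at `t ≤ 5`, `d = 2`, with
`10⁴–2·10⁴` replicates; the `d = 3` one-arm table at `r ≤ 20` with `8·10³`
replicates and horizon `8r²/σ²_D`; the modulus experiment at
`n ∈ {64, 256}` with several hundred replicates and a 200-endpoint path
budget per replicate.

## What the synthetic models do and do not show

The generators *are* the study systems (there is no external data), so the
tests verify the implementation against exact structure (martingales,
duality identities, generating-function recursions, closed forms) and
probe the *asymptotic* limit predictions at finite size. Known
finite-size effects, measured and left visible rather than absorbed into
tolerances:

* the critical binary Galton–Watson survival functional at `n = 100` is
  `100·P(Z_100 > 0) = 1.8792` exactly (generating-function recursion),
  about 6% below its limit 2; the Yaglom rate estimator concentrates on
  the same number. Tests against the recursion pass at Monte-Carlo
  accuracy; tests against the limit value at sub-6% tolerances cannot.
* the voter `d = 3` one-arm normalization `r²·η_r` climbs
  `3.9 → 4.3 → 5.1 → 5.5` over `r = 10…50`, approaching the predicted
  `6.36` from below; at `r ≤ 20` it is still ~30% short. The monotone
  approach is asserted; a band tighter than that around the limit is not
  attainable at those radii.
* the ancestral modulus tail: the theory provides a one-sided bound
  `m(n)·P(δ_n ≤ ρ) ≤ c(ρ^β + n^{−q})`, which holds comfortably in the
  experiments, but the realized tail is much lighter (log-log slope
  ≈ 0.4 at `n ≤ 256`), so slope-matching diagnostics against `β = 1`
  fail at desk scale. The experiment reports both the pointwise
  exceedance `P(Δ⁽ⁿ⁾(ρ) > C(ρ^α + n^{−α}))` and the monotone
  failure-scale tail `P(δ_n < ρ)` on which slopes are fitted.

Passing tests therefore certify the simulators' exact finite-size
behaviour and the limit-side computations; they quantify, not hide, the
distance between desk-scale criticality and the scaling limit.

## Degenerate inputs and conventions

`d₀(∅, ∅) = 0` (the metric axioms force it; the empty set is at distance 1
from every nonempty set). The radius of the empty set is an error — it is
never needed, since every range contains `o`. Survival time in discrete
time is the first empty generation (`S = 1` for `p = 0` oriented
percolation). `Δ⁽ⁿ⁾(ρ)` at `ρ = 0` is 0 (equal-time related pairs
coincide). Interpolation chains and generic path extraction break ties
lexicographically by position. The critical-rate estimators for `λ_c` and
`p_c` are bisection brackets on the growth/decay of `t·θ̂(t)` and are
approximations by construction; no closed form exists.
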