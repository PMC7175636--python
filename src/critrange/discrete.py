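"""Discrete-time models: oriented percolation, branching random walk, and
non-spatial critical Galton-Watson experiments.

Oriented percolation (OP): the bond ((n, x), (n+1, y)) is occupied
independently with probability p * D(y - x); T_n is the set of sites reached
from (0, o) through occupied bonds, and (n, x) ->a (n', x') iff
(0, o) -> (n, x) -> (n', x').

Critical branching random walk (BRW) is the tractable surrogate for critical
lattice trees (whose exact critical weighting is not computable): particles
beget offspring by a finitely supported mean-one law and displace by kernel
steps; the ancestral relation is genealogical descent on labelled particles
(the set-valued view projects to occupied sites).

The pure Galton-Watson experiments drive the canonical-measure checks: for a
critical law with variance gamma, n * P(Z_n > 0) -> 2 / gamma (Kolmogorov),
Z_n / n given survival is asymptotically exponential with rate 2 / gamma
(Yaglom), and the conditioned integrated mass over [1, 2] has the closed
Laplace transform 2 / (2 + gamma * v_1^(lambda)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ancestry import AncestralSystem
from .kernels import StepKernel, sample_step

__all__ = [
    "OffspringLaw",
    "OPRealization",
    "BRWRealization",
    "simulate_op",
    "op_ancestral_system",
    "OPAncestralSystem",
    "simulate_brw",
    "brw_ancestral_system",
    "BRWAncestralSystem",
    "gw_exact_survival",
    "gw_survival_experiment",
    "gw_yaglom_experiment",
    "gw_laplace_experiment",
    "OPSpec",
    "BRWSpec",
    "estimate_p_c",
]


@dataclass(frozen=True)
class DiscreteCaps:
    max_particles: int = 2_000_000


_DEFAULT_CAPS = DiscreteCaps()


# ---------------------------------------------------------------------------
# offspring laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OffspringLaw:
    """Finitely supported offspring distribution on the nonnegative integers."""

    values: tuple
    probs: tuple

    def __post_init__(self):
        vals = tuple(int(v) for v in self.values)
        pr = tuple(float(p) for p in self.probs)
        if len(vals) != len(pr) or not vals:
            raise ValueError("values and probs must align and be nonempty")
        if any(v < 0 for v in vals) or len(set(vals)) != len(vals):
            raise ValueError("values must be distinct nonnegative integers")
        if any(p < 0 for p in pr) or abs(sum(pr) - 1.0) > 1e-12:
            raise ValueError("probs must be nonnegative and sum to 1")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "probs", pr)

    @property
    def mean(self) -> float:
        return sum(v * p for v, p in zip(self.values, self.probs))

    @property
    def variance(self) -> float:
        m = self.mean
        return sum(v * v * p for v, p in zip(self.values, self.probs)) - m * m

    @property
    def is_critical(self) -> bool:
        return abs(self.mean - 1.0) < 1e-12

    @property
    def gamma(self) -> float:
        """Branching-rate parameter of the diffusion limit: the offspring
        variance (meaningful for critical laws)."""
        return self.variance

    def generating_function(self, s: float) -> float:
        return sum(p * s ** v for v, p in zip(self.values, self.probs))

    @classmethod
    def binary_critical(cls) -> "OffspringLaw":
        """0 or 2 children, each with probability 1/2 (gamma = 1)."""
        return cls(values=(0, 2), probs=(0.5, 0.5))

    @classmethod
    def delta(cls, k: int) -> "OffspringLaw":
        return cls(values=(k,), probs=(1.0,))

    @classmethod
    def variance_two(cls) -> "OffspringLaw":
        """A mean-1, variance-2 law: 0 w.p. 5/8, 2 w.p. 1/4, 4 w.p. 1/8."""
        return cls(values=(0, 2, 4), probs=(5 / 8, 1 / 4, 1 / 8))

    def sample_totals(self, rng: np.random.Generator, counts: np.ndarray) -> np.ndarray:
        """Vector of offspring totals: entry i is the sum of counts[i] iid
        draws from the law."""
        counts = np.asarray(counts, dtype=np.int64)
        if self.values == (0, 2):
            # fast path for the critical binary law
            return 2 * rng.binomial(counts, self.probs[1])
        table = rng.multinomial(counts, np.asarray(self.probs))
        return table @ np.asarray(self.values, dtype=np.int64)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        idx = rng.choice(len(self.values), size=size, p=np.asarray(self.probs))
        return np.asarray(self.values, dtype=np.int64)[idx]


# ---------------------------------------------------------------------------
# oriented percolation
# ---------------------------------------------------------------------------

@dataclass
class OPRealization:
    """One oriented-percolation cluster of (0, o).

    ``generations[n]`` is the occupied set T_n (tuples); ``children[n]`` maps
    an occupied site at generation n to the tuple of its generation-(n+1)
    children through occupied bonds (only bonds out of occupied sites are
    materialized -- sufficient for the cluster and its ancestral relation).
    """

    p: float
    d: int
    generations: list
    children: list
    n_max: int
    censored: bool = False
    seed: object = None

    @property
    def t_max(self) -> float:
        return float(self.n_max)

    @property
    def extinction_time(self):
        for n, gen in enumerate(self.generations):
            if not gen:
                return float(n)
        return None

    @property
    def origin(self) -> tuple:
        return (0,) * self.d

    def set_at(self, t) -> frozenset:
        if t < 0:
            raise ValueError("time must be nonnegative")
        n = int(math.floor(t))
        if n >= len(self.generations):
            return frozenset() if self.extinction_time is not None else \
                frozenset(self.generations[-1])
        return frozenset(self.generations[n])

    def size_at(self, t) -> int:
        return len(self.set_at(t))

    def range_sites(self) -> frozenset:
        out = set()
        for gen in self.generations:
            out |= gen
        return frozenset(out)

    def first_exit_time(self, r: float):
        r2 = r * r
        for n, gen in enumerate(self.generations):
            if any(sum(c * c for c in site) > r2 for site in gen):
                return float(n)
        return None

    def reachable(self, n: int, x: tuple, n2: int) -> frozenset:
        """Sites at generation n2 reachable from (n, x) through occupied bonds."""
        frontier = {x} if x in self.generations[n] else set()
        for g in range(n, min(n2, len(self.generations) - 1)):
            nxt = set()
            cmap = self.children[g]
            for site in frontier:
                nxt.update(cmap.get(site, ()))
            frontier = nxt
            if not frontier:
                break
        if n2 >= len(self.generations) and n2 > n:
            return frozenset()
        return frozenset(frontier)


def simulate_op(kernel: StepKernel, p: float, n_max: int, seed=None, *,
                rng=None, caps: DiscreteCaps | None = None) -> OPRealization:
    """Grow the oriented-percolation cluster of (0, o) for n_max generations.

    Bonds out of occupied sites are sampled independently: the bond to
    x + offset is occupied with probability p * D(offset); requires
    p * max(D) <= 1.
    """
    if p < 0 or p * kernel.max_prob() > 1 + 1e-12:
        raise ValueError("need 0 <= p * max D(x) <= 1")
    caps = caps or _DEFAULT_CAPS
    rng = rng if rng is not None else np.random.default_rng(seed)
    d = kernel.d
    offs = [tuple(o) for o in kernel.offsets.tolist()]
    bond_p = np.minimum(p * kernel.probs, 1.0)
    origin = (0,) * d
    generations = [{origin}]
    children = []
    censored = False
    for _n in range(n_max):
        cur = sorted(generations[-1])
        if not cur:
            generations.append(set())
            children.append({})
            continue
        if len(cur) > caps.max_particles:
            censored = True
            break
        nxt = set()
        cmap = {}
        occ_matrix = rng.random((len(cur), len(offs))) < bond_p
        for i, site in enumerate(cur):
            kids = []
            row = occ_matrix[i]
            for j in np.nonzero(row)[0]:
                off = offs[j]
                kid = tuple(site[k] + off[k] for k in range(d))
                kids.append(kid)
                nxt.add(kid)
            if kids:
                cmap[site] = tuple(kids)
        children.append(cmap)
        generations.append(nxt)
    return OPRealization(p=p, d=d, generations=[frozenset(g) for g in generations],
                         children=children, n_max=n_max, censored=censored,
                         seed=seed)


class OPAncestralSystem(AncestralSystem):
    """Forward bond-reachability relation, extended to real times by floors."""

    model = "op"
    time_kind = "discrete"

    def __init__(self, realization: OPRealization):
        self.real = realization
        self.d = realization.d
        self._memo = {}

    def occupied(self, t):
        return tuple(sorted(self.real.set_at(t)))

    def relates(self, s, y, t, x):
        if s > t:
            raise ValueError("relation requires s <= t")
        m, n = int(math.floor(s)), int(math.floor(t))
        occ_m = self.real.set_at(m)
        if y not in occ_m:
            return False
        if m == n:
            return x == y
        key = (m, y, n)
        got = self._memo.get(key)
        if got is None:
            got = self.real.reachable(m, y, n)
            self._memo[key] = got
        return x in got

    def position(self, label):
        return np.asarray(label, dtype=float)

    @property
    def root(self):
        return self.real.origin

    def skeleton(self):
        return [float(n) for n in range(len(self.real.generations))]

    @property
    def horizon(self):
        return float(self.real.n_max)


def op_ancestral_system(realization: OPRealization) -> OPAncestralSystem:
    return OPAncestralSystem(realization)


# ---------------------------------------------------------------------------
# branching random walk
# ---------------------------------------------------------------------------

@dataclass
class BRWRealization:
    """Labelled genealogy of a branching random walk.

    ``positions[g]`` is an (M_g, d) int array; ``parents[g]`` maps each
    generation-g particle to its parent index in generation g-1 (parent of
    the root is -1).  Multi-occupancy: several particles may share a site;
    the ancestral relation lives on particle labels (g, i).
    """

    law: OffspringLaw
    d: int
    positions: list
    parents: list
    n_max: int
    censored: bool = False
    seed: object = None

    @property
    def t_max(self) -> float:
        return float(self.n_max)

    @property
    def extinction_time(self):
        for g, pos in enumerate(self.positions):
            if len(pos) == 0:
                return float(g)
        return None

    @property
    def origin(self) -> tuple:
        return (0,) * self.d

    def mass_at(self, gen: int) -> int:
        """Particle count (with multiplicity) at a generation."""
        if gen >= len(self.positions):
            return 0 if self.extinction_time is not None else len(self.positions[-1])
        return len(self.positions[gen])

    def set_at(self, t) -> frozenset:
        g = int(math.floor(t))
        if g >= len(self.positions):
            if self.extinction_time is not None:
                return frozenset()
            g = len(self.positions) - 1
        return frozenset(map(tuple, self.positions[g].tolist()))

    def size_at(self, t) -> int:
        return len(self.set_at(t))

    def range_sites(self) -> frozenset:
        out = set()
        for pos in self.positions:
            out |= set(map(tuple, pos.tolist()))
        return frozenset(out)

    def first_exit_time(self, r: float):
        r2 = r * r
        for g, pos in enumerate(self.positions):
            if len(pos) and int((pos.astype(np.int64) ** 2).sum(axis=1).max()) > r2:
                return float(g)
        return None

    def ancestor_index(self, gen: int, idx: int, gen_to: int) -> int:
        """Index of the generation-``gen_to`` ancestor of particle (gen, idx)."""
        if gen_to > gen:
            raise ValueError("ancestor generation must not exceed the particle's")
        i = idx
        for g in range(gen, gen_to, -1):
            i = int(self.parents[g][i])
        return i


def simulate_brw(law: OffspringLaw, kernel: StepKernel, n_max: int, seed=None, *,
                 rng=None, caps: DiscreteCaps | None = None) -> BRWRealization:
    """Branching random walk from one particle at the origin.

    Each particle independently begets offspring by ``law``; each child is
    displaced from its parent by an independent kernel step.
    """
    caps = caps or _DEFAULT_CAPS
    rng = rng if rng is not None else np.random.default_rng(seed)
    d = kernel.d
    positions = [np.zeros((1, d), dtype=np.int64)]
    parents = [np.array([-1], dtype=np.int64)]
    censored = False
    for _g in range(n_max):
        cur = positions[-1]
        m = len(cur)
        if m == 0:
            positions.append(np.zeros((0, d), dtype=np.int64))
            parents.append(np.zeros(0, dtype=np.int64))
            continue
        if m > caps.max_particles:
            censored = True
            break
        counts = law.sample(rng, m) if len(law.values) > 1 else \
            np.full(m, law.values[0], dtype=np.int64)
        par = np.repeat(np.arange(m, dtype=np.int64), counts)
        steps = sample_step(kernel, rng, len(par))
        positions.append(cur[par] + steps)
        parents.append(par)
    return BRWRealization(law=law, d=d, positions=positions, parents=parents,
                          n_max=n_max, censored=censored, seed=seed)


class BRWAncestralSystem(AncestralSystem):
    """Genealogical descent on particle labels (generation, index)."""

    model = "brw"
    time_kind = "discrete"

    def __init__(self, realization: BRWRealization):
        self.real = realization
        self.d = realization.d

    def _gen(self, t) -> int:
        g = int(math.floor(t))
        return g

    def occupied(self, t):
        g = self._gen(t)
        if g >= len(self.real.positions):
            return () if self.real.extinction_time is not None else \
                tuple((len(self.real.positions) - 1, i)
                      for i in range(len(self.real.positions[-1])))
        return tuple((g, i) for i in range(len(self.real.positions[g])))

    def relates(self, s, y, t, x):
        if s > t:
            raise ValueError("relation requires s <= t")
        gy, iy = y
        gx, ix = x
        if gy != self._gen(s) or gx != self._gen(t):
            return False
        pos = self.real.positions
        if gy >= len(pos) or iy >= len(pos[gy]):
            return False
        if gx >= len(pos) or ix >= len(pos[gx]):
            return False
        if gy == gx:
            return iy == ix
        if gy > gx:
            return False
        return self.real.ancestor_index(gx, ix, gy) == iy

    def position(self, label):
        g, i = label
        return self.real.positions[g][i].astype(float)

    @property
    def root(self):
        return (0, 0)

    def skeleton(self):
        return [float(g) for g in range(len(self.real.positions))]

    @property
    def horizon(self):
        return float(self.real.n_max)

    def exact_path(self, t, x):
        from .ancestry import AncestralPath
        g, i = x
        labels = []
        j = i
        for gg in range(g, -1, -1):
            labels.append((gg, j))
            if gg > 0:
                j = int(self.real.parents[gg][j])
        labels.reverse()
        bps = tuple((float(gg), lab) for gg, lab in enumerate(labels))
        return AncestralPath(t=t, terminal=x, breakpoints=bps, system=self)


def brw_ancestral_system(realization: BRWRealization) -> BRWAncestralSystem:
    return BRWAncestralSystem(realization)


# ---------------------------------------------------------------------------
# Galton-Watson mass experiments
# ---------------------------------------------------------------------------

def gw_exact_survival(law: OffspringLaw, n: int) -> float:
    """P(Z_n > 0) by iterating the offspring generating function."""
    q = 0.0
    for _ in range(n):
        q = law.generating_function(q)
    return 1.0 - q


def _gw_masses(law: OffspringLaw, n_gens: int, reps: int,
               rng: np.random.Generator, accumulate=None):
    """Evolve ``reps`` independent GW mass processes for n_gens generations.

    ``accumulate``: optional (lo, hi) generation window; returns the sum of
    Z_k over lo <= k <= hi alongside the final masses.
    """
    Z = np.ones(reps, dtype=np.int64)
    acc = np.zeros(reps, dtype=np.int64) if accumulate else None
    lo, hi = accumulate if accumulate else (0, -1)
    if lo == 0 and accumulate:
        acc += Z
    for gen in range(1, n_gens + 1):
        alive = np.nonzero(Z)[0]
        if len(alive):
            Z[alive] = law.sample_totals(rng, Z[alive])
        if accumulate and lo <= gen <= hi:
            acc += Z
    return (Z, acc) if accumulate else Z


@dataclass(frozen=True)
class GWEstimate:
    value: float
    se: float
    reps: int
    meta: dict = field(default_factory=dict)


def gw_survival_experiment(law: OffspringLaw, n: int, reps: int,
                           seed=None, rng=None) -> GWEstimate:
    """Monte-Carlo estimate of n * P(Z_n > 0) with its standard error."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    Z = _gw_masses(law, n, reps, rng)
    frac = float((Z > 0).mean())
    se = n * math.sqrt(max(frac * (1 - frac), 1e-300) / reps)
    return GWEstimate(value=n * frac, se=se, reps=reps,
                      meta={"n": n, "survival_fraction": frac})


def gw_yaglom_experiment(law: OffspringLaw, n: int, reps: int, seed=None,
                         rng=None, min_survivors: int | None = None):
    """Rate (inverse conditional mean) of Z_n / n given Z_n > 0.

    Simulates in batches of ``reps`` until ``min_survivors`` replicates
    survive (one batch if None).  Returns (GWEstimate, conditional sample).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    samples = []
    total = 0
    while True:
        Z = _gw_masses(law, n, reps, rng)
        samples.append(Z[Z > 0] / n)
        total += reps
        if min_survivors is None or sum(len(s) for s in samples) >= min_survivors:
            break
    cond = np.concatenate(samples)
    k = len(cond)
    mean = float(cond.mean())
    rate = 1.0 / mean
    se = rate * float(cond.std(ddof=1)) / (mean * math.sqrt(k))
    return GWEstimate(value=rate, se=se, reps=total,
                      meta={"n": n, "survivors": k, "cond_mean": mean}), cond


def gw_laplace_experiment(law: OffspringLaw, lam: float, n: int, reps: int,
                          seed=None, rng=None) -> GWEstimate:
    """Conditional Laplace functional of the integrated rescaled mass.

    Estimates E[exp(-lam * (1/n) * sum_{k=n}^{2n} Z_k / n) | Z_n > 0], the
    discrete analogue of the integrated super-Brownian mass over [1, 2]
    conditioned on survival past 1.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    Z = np.ones(reps, dtype=np.int64)
    acc = np.zeros(reps, dtype=np.float64)
    alive_at_n = None
    for gen in range(1, 2 * n + 1):
        alive = np.nonzero(Z)[0]
        if len(alive):
            Z[alive] = law.sample_totals(rng, Z[alive])
        if gen == n:
            alive_at_n = Z > 0
            acc[alive_at_n] += Z[alive_at_n]
        elif gen > n:
            acc += Z
    cond = np.exp(-lam * acc[alive_at_n] / (n * n))
    k = int(alive_at_n.sum())
    if k == 0:
        return GWEstimate(value=float("nan"), se=float("nan"), reps=reps,
                          meta={"n": n, "survivors": 0})
    return GWEstimate(value=float(cond.mean()),
                      se=float(cond.std(ddof=1)) / math.sqrt(k),
                      reps=reps, meta={"n": n, "lam": lam, "survivors": k})


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OPSpec:
    """Oriented percolation at bond-strength scale p."""

    kernel: StepKernel
    p: float

    tag = "op"
    time_kind = "discrete"

    def sample(self, horizon, rng, caps=None, keep_record=False):
        return simulate_op(self.kernel, self.p, int(math.ceil(horizon)), rng=rng,
                           caps=caps)

    def system(self, realization):
        return op_ancestral_system(realization)


@dataclass(frozen=True)
class BRWSpec:
    """Branching random walk with a given offspring law and step kernel."""

    law: OffspringLaw
    kernel: StepKernel

    tag = "brw"
    time_kind = "discrete"

    def sample(self, horizon, rng, caps=None, keep_record=False):
        return simulate_brw(self.law, self.kernel, int(math.ceil(horizon)),
                            rng=rng, caps=caps)

    def system(self, realization):
        return brw_ancestral_system(realization)


def estimate_p_c(kernel: StepKernel, bracket=(0.5, 2.0), n_probe: int = 24,
                 reps: int = 1500, seed=0, iters: int = 7, caps=None):
    """Bracket the critical OP bond scale by bisection on n * theta-hat(n).

    Same diagnostic as the contact-process bracketing: subcritical p shows
    n * theta(n) decaying between n_probe/2 and n_probe, supercritical p
    shows it growing.  Approximate by construction (p_c = 1 + O(L^-d) is not
    available in closed form).
    """
    from .seeding import child_seed

    lo, hi = float(bracket[0]), float(bracket[1])
    history = []
    for it in range(iters):
        p = 0.5 * (lo + hi)
        rng = np.random.default_rng(child_seed(seed, "p_c", it))
        alive_half = alive_full = 0
        half = n_probe // 2
        for _ in range(reps):
            real = simulate_op(kernel, p, n_probe, rng=rng, caps=caps)
            ext = real.extinction_time
            if ext is None or ext > half:
                alive_half += 1
            if ext is None:
                alive_full += 1
        g_half = half * alive_half / reps
        g_full = n_probe * alive_full / reps
        history.append({"p": p, "n_theta_half": g_half, "n_theta_full": g_full})
        if g_full > g_half:
            hi = p
        else:
            lo = p
    return {"bracket": (lo, hi), "history": history, "approximate": True}
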