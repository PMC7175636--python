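"""Observables of the scaling-limit theorems.

Survival time and survival probability theta(t), the range and its radius,
the one-arm (ball-exit) probability eta_r, the capped Hausdorff metric d_0,
the ancestral modulus-of-continuity statistic Delta^(n)(rho), spatial and
ancestral-increment moments, and the mass normalization m(t).

Conventions (matching the limit theory): site radii use the Euclidean norm
(the kernel range uses the sup-norm -- do not mix them); the survival time
is S = inf{t : T_t = empty}; the range is the union of all occupied sets.

Censoring policy: every estimator touching capped or horizon-limited
simulations reports a [lo, hi] bracket obtained by resolving unresolved
replicates both ways, plus the censored fraction.  Critical survival and
range tails are heavy, so silent truncation would bias exactly the
quantities under study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .ancestry import extract_ancestral_path, rescale_system
from .graphical import dual_walk
from .seeding import child_seed

__all__ = [
    "MonteCarloEstimate",
    "EmpiricalMeasure",
    "RangeSet",
    "ModulusConfig",
    "survival_time",
    "estimate_survival_prob",
    "range_of",
    "radius",
    "one_arm",
    "hausdorff",
    "modulus_stat",
    "modulus_tail_experiment",
    "spatial_moment",
    "ancestral_increment_moment",
    "local_jump_probe",
    "integrated_mass",
    "m_function",
]


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Point estimate with its standard error and censoring bracket."""

    value: float
    se: float
    reps: int
    censored_fraction: float = 0.0
    lo: float = None
    hi: float = None
    seed: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")
        if not 0.0 <= self.censored_fraction <= 1.0:
            raise ValueError("censored fraction must lie in [0, 1]")
        if self.lo is None:
            object.__setattr__(self, "lo", self.value)
        if self.hi is None:
            object.__setattr__(self, "hi", self.value)


@dataclass(frozen=True)
class EmpiricalMeasure:
    """Rescaled empirical measure X^(n)_t: atoms x/sqrt(n) for x in T_{nt},
    each with weight 1/m(n); total mass |T_{nt}| / m(n)."""

    atoms: np.ndarray
    weight: float
    t: float
    n: float

    @classmethod
    def from_trajectory(cls, traj, t, n, m_of_n) -> "EmpiricalMeasure":
        m_n = m_of_n(n) if callable(m_of_n) else float(m_of_n)
        sites = sorted(traj.set_at(n * t))
        atoms = np.asarray(sites, dtype=float) / math.sqrt(n) if sites else \
            np.zeros((0, traj.d))
        return cls(atoms=atoms, weight=1.0 / m_n, t=float(t), n=float(n))

    @property
    def total_mass(self) -> float:
        return len(self.atoms) * self.weight

    def integrate(self, f) -> float:
        """Integral of a function against the measure: sum_x f(x) / m(n)."""
        return self.weight * float(sum(f(x) for x in self.atoms))


@dataclass(frozen=True)
class RangeSet:
    """Finite point set (lattice or rescaled coordinates) with a scale tag."""

    points: np.ndarray
    scale: str = "lattice"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            pts = pts.reshape(len(pts), -1) if len(pts) else pts.reshape(0, 1)
        object.__setattr__(self, "points", pts)

    def __len__(self):
        return len(self.points)


def survival_time(traj):
    """(S, censored): first time the occupied set is empty; censored if the
    realization was still alive at its horizon (or hit a resource cap)."""
    ext = traj.extinction_time
    if ext is not None:
        return float(ext), False
    return float(traj.t_max), True


def range_of(traj) -> RangeSet:
    sites = sorted(traj.range_sites())
    return RangeSet(points=np.asarray(sites, dtype=float), scale="lattice")


def radius(range_set) -> float:
    """Euclidean radius r_0(K) = sup{|x| : x in K} of a nonempty set."""
    pts = range_set.points if isinstance(range_set, RangeSet) else \
        np.asarray(list(range_set), dtype=float)
    if len(pts) == 0:
        raise ValueError("radius of the empty set is undefined")
    return float(np.sqrt((np.asarray(pts, dtype=float) ** 2).sum(axis=1).max()))


def hausdorff(K, K2) -> float:
    """The capped Hausdorff metric d_0.

    d_1(K, K') = Delta_1(K, K') + Delta_1(K', K) (sum of the two directed
    deviations), d_0 = min(d_1, 1); the empty set is at distance 1 from
    every nonempty set and 0 from itself.
    """
    A = K.points if isinstance(K, RangeSet) else np.asarray(list(K), dtype=float)
    B = K2.points if isinstance(K2, RangeSet) else np.asarray(list(K2), dtype=float)
    na, nb = len(A), len(B)
    if na == 0 and nb == 0:
        return 0.0
    if na == 0 or nb == 0:
        return 1.0
    A = A.reshape(na, -1)
    B = B.reshape(nb, -1)
    dists = cdist(A, B)
    d1 = float(dists.min(axis=1).max() + dists.min(axis=0).max())
    return min(d1, 1.0)


# ---------------------------------------------------------------------------
# survival probability and one-arm experiments
# ---------------------------------------------------------------------------

def _probe_alive(spec, t, rng, caps):
    """'alive' / 'dead' / 'censored' status of one replicate at time t."""
    if hasattr(spec, "simulate_fast"):
        raw = spec.simulate_fast(t, rng, caps=caps)
        if raw["censored"]:
            return "censored"
        return "dead" if raw["extinct_at"] is not None else "alive"
    real = spec.sample(t, rng, caps=caps)
    if real.censored:
        return "censored"
    ext = real.extinction_time
    return "alive" if ext is None or ext > t else "dead"


def estimate_survival_prob(spec, t, reps, seed, caps=None) -> MonteCarloEstimate:
    """Monte-Carlo estimate of theta(t) = P(S > t)."""
    alive = cens = 0
    name = f"theta-{spec.tag}-{t}"
    rng = np.random.default_rng(child_seed(seed, name))
    for _ in range(reps):
        status = _probe_alive(spec, t, rng, caps)
        if status == "alive":
            alive += 1
        elif status == "censored":
            cens += 1
    p = alive / reps
    se = math.sqrt(max(p * (1 - p), 1e-300) / reps)
    return MonteCarloEstimate(value=p, se=se, reps=reps,
                              censored_fraction=cens / reps,
                              lo=p, hi=(alive + cens) / reps, seed=seed,
                              meta={"t": t, "model": spec.tag})


def one_arm(spec, r, reps, seed, caps=None, horizon=None):
    """Monte-Carlo estimate of eta_r = P(range exits the closed ball B(o, r)).

    ``r`` may be a scalar or an increasing grid; grid points share each
    replicate's randomness (the range only grows, so the first-exit times of
    one run resolve every radius -- an exact coupling).  A replicate that
    ends (horizon or cap) alive inside the ball is unresolved and enters the
    censoring bracket [exited, exited + unresolved] / reps.
    """
    r_grid = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(np.diff(r_grid) <= 0) and len(r_grid) > 1:
        raise ValueError("radius grid must be strictly increasing")
    r_max = float(r_grid[-1])
    if horizon is None:
        sig = getattr(getattr(spec, "kernel", None), "sigma2_D", 1.0)
        horizon = max(50.0, 8.0 * r_max * r_max / sig)
    exited = np.zeros(len(r_grid), dtype=int)
    unresolved = np.zeros(len(r_grid), dtype=int)
    name = f"one-arm-{spec.tag}-{r_max}"
    rng = np.random.default_rng(child_seed(seed, name))
    fast = hasattr(spec, "simulate_fast")
    for _ in range(reps):
        if fast:
            raw = spec.simulate_fast(horizon, rng, caps=caps,
                                     stop_radius=r_max, r_grid=list(r_grid))
            exits = raw["exit_times"]
            resolved_dead = raw["extinct_at"] is not None and not raw["censored"]
        else:
            real = spec.sample(horizon, rng, caps=caps)
            exits = [real.first_exit_time(ri) for ri in r_grid]
            resolved_dead = real.extinction_time is not None and not real.censored
        for i, e in enumerate(exits):
            if e is not None:
                exited[i] += 1
            elif not resolved_dead:
                unresolved[i] += 1
    out = {}
    for i, ri in enumerate(r_grid):
        p = exited[i] / reps
        se = math.sqrt(max(p * (1 - p), 1e-300) / reps)
        out[float(ri)] = MonteCarloEstimate(
            value=p, se=se, reps=reps,
            censored_fraction=unresolved[i] / reps,
            lo=p, hi=(exited[i] + unresolved[i]) / reps, seed=seed,
            meta={"r": float(ri), "model": spec.tag, "horizon": horizon})
    if np.isscalar(r):
        return out[float(r)]
    return out


# ---------------------------------------------------------------------------
# spatial and ancestral moments
# ---------------------------------------------------------------------------

def _set_at(spec, t, rng, caps, keep_record=False):
    if hasattr(spec, "simulate_fast") and not keep_record:
        raw = spec.simulate_fast(t, rng, caps=caps, eval_times=[t],
                                 capture_sets=True)
        sites = raw["eval_sets"][0]
        return [] if sites is None else sites
    real = spec.sample(t, rng, caps=caps, keep_record=keep_record)
    return sorted(real.set_at(t))


def spatial_moment(spec, t, p, reps, seed, caps=None) -> MonteCarloEstimate:
    """E[sum_{x in T_t} |x|^p] with the diffusive normalization t^{-p/2}
    reported in the metadata."""
    vals = np.empty(reps)
    rng = np.random.default_rng(child_seed(seed, f"spatmom-{spec.tag}-{t}-{p}"))
    for i in range(reps):
        sites = _set_at(spec, t, rng, caps)
        if sites:
            arr = np.asarray(sites, dtype=float)
            vals[i] = ((arr ** 2).sum(axis=1) ** (p / 2)).sum()
        else:
            vals[i] = 0.0
    mean = float(vals.mean())
    se = float(vals.std(ddof=1)) / math.sqrt(reps) if reps > 1 else 0.0
    norm = mean / t ** (p / 2) if t > 0 else (0.0 if p > 0 else mean)
    return MonteCarloEstimate(value=mean, se=se, reps=reps, seed=seed,
                              meta={"t": t, "p": p, "normalized": norm,
                                    "model": spec.tag})


def ancestral_increment_moment(spec, t, s, p, reps, seed, caps=None) -> MonteCarloEstimate:
    """E[sum_{x in T_t} sum_y 1((t-s, y) ->a (t, x)) |x - y|^p].

    For the voter model the inner sum has exactly one term, the dual-walk
    position at backward time s, and is evaluated from the dual walk
    directly.  Other models scan occupied pairs through the ancestral
    relation.
    """
    if s < 0 or s > t:
        raise ValueError("need 0 <= s <= t")
    vals = np.empty(reps)
    rng = np.random.default_rng(child_seed(seed, f"ancmom-{spec.tag}-{t}-{s}-{p}"))
    for i in range(reps):
        total = 0.0
        if spec.tag == "vm":
            record, traj = spec.simulate(t, rng, caps=caps, keep_record=True)
            for x in traj.set_at(t):
                y = dual_walk(record, t, x, trajectory=traj).w(t - s)
                total += sum((a - b) ** 2 for a, b in zip(x, y)) ** (p / 2)
        else:
            sim = spec.sample(t, rng, caps=caps, keep_record=True)
            sys = spec.system(sim)
            occ_t = sys.occupied(t)
            occ_s = sys.occupied(t - s)
            for x in occ_t:
                px = sys.position(x)
                for y in occ_s:
                    if sys.relates(t - s, y, t, x):
                        total += float(np.linalg.norm(px - sys.position(y))) ** p
        vals[i] = total
    mean = float(vals.mean())
    se = float(vals.std(ddof=1)) / math.sqrt(reps) if reps > 1 else 0.0
    denom = max(s, 1.0) ** (p / 2)
    return MonteCarloEstimate(value=mean, se=se, reps=reps, seed=seed,
                              meta={"t": t, "s": s, "p": p,
                                    "normalized": mean / denom,
                                    "model": spec.tag})


def local_jump_probe(spec, N_grid, reps, seed, caps=None, window=2.0,
                     max_endpoints=200):
    """Tail of the largest ancestral displacement over a window of length 2.

    Per replicate, the maximum of |pos(w_{s2}) - pos(w_{s1})| over ancestral
    paths to occupied endpoints with times in [0, window].  Finite-range
    discrete-time models satisfy a hard bound of 2*sqrt(d)*L per window of
    length 2 (two kernel steps), so tails beyond it vanish identically.
    """
    N_grid = list(N_grid)
    hits = np.zeros(len(N_grid), dtype=int)
    alive_any = 0
    rng = np.random.default_rng(child_seed(seed, f"jump-{spec.tag}"))
    for _ in range(reps):
        sim = spec.sample(window, rng, caps=caps, keep_record=True)
        sys = spec.system(sim)
        skel = [u for u in sys.skeleton() if u <= window]
        endpoints = [(u, lab) for u in skel for lab in sys.occupied(u)]
        if endpoints and sys.occupied(window):
            alive_any += 1
        if len(endpoints) > max_endpoints:
            idx = rng.choice(len(endpoints), max_endpoints, replace=False)
            endpoints = [endpoints[i] for i in idx]
        m = 0.0
        for (u, lab) in endpoints:
            path = extract_ancestral_path(sys, u, lab)
            pos = np.asarray([sys.position(b[1]) for b in path.breakpoints]
                             + [sys.position(lab)])
            if len(pos) > 1:
                diffs = cdist(pos, pos)
                m = max(m, float(diffs.max()))
        for j, N in enumerate(N_grid):
            if m >= N - 1e-12:
                hits[j] += 1
    out = {}
    for j, N in enumerate(N_grid):
        p = hits[j] / reps
        se = math.sqrt(max(p * (1 - p), 1e-300) / reps)
        out[float(N)] = MonteCarloEstimate(value=p, se=se, reps=reps, seed=seed,
                                           meta={"N": N, "window": window,
                                                 "alive_fraction": alive_any / reps})
    return out


# ---------------------------------------------------------------------------
# integrated mass and the normalization m(t)
# ---------------------------------------------------------------------------

def _segments(traj):
    if hasattr(traj, "segments"):
        yield from traj.segments()
        return
    # discrete realizations: piecewise constant on [k, k+1)
    horizon = int(traj.t_max)
    for k in range(horizon + 1):
        yield (float(k), float(k + 1), traj.set_at(k))


def integrated_mass(traj, t0, t1, n, m_of_n) -> float:
    """Exact piecewise-constant integral of |T_{n u}| / m(n) over [t0, t1]."""
    if t1 < t0:
        raise ValueError("need t0 <= t1")
    m_n = m_of_n(n) if callable(m_of_n) else float(m_of_n)
    lo, hi = n * t0, n * t1
    total = 0.0
    for (a, b, occ) in _segments(traj):
        ov = min(b, hi) - max(a, lo)
        if ov > 0:
            total += len(occ) * ov
        if a >= hi:
            break
    return total / (n * m_n)


_E = math.e


def m_function(model_tag: str, t, *, d=None, A=1.0, V=1.0) -> float:
    """The mass normalization m(t) entering theta(t) ~ s_D / m(t).

    Voter model: t v 1 for d > 2 and (t v e)/log(t v e) for d = 2; oriented
    percolation, contact process and lattice trees: A^2 V (t v 1) with the
    model's amplitude A and vertex factor V.
    """
    tag = model_tag.lower()
    if tag in ("vm", "voter"):
        if d is None:
            raise ValueError("the voter normalization needs the dimension d")
        if d > 2:
            return max(float(t), 1.0)
        if d == 2:
            te = max(float(t), _E)
            return te / math.log(te)
        raise ValueError("voter normalization defined for d >= 2")
    if tag in ("op", "cp", "lt", "contact", "brw"):
        return A * A * V * max(float(t), 1.0)
    raise ValueError(f"unknown model tag {model_tag!r}")


# ---------------------------------------------------------------------------
# modulus of continuity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModulusConfig:
    """Exponents of the ancestral-path modulus: alpha in (0, 1/2) (Hoelder
    exponent), beta in (0, 1] (tail exponent), p (increment moment order),
    kappa (local jump exponent).  Validity: (1-2*alpha)/(1+beta) >= 4/p and
    alpha < 1/2 - 2/kappa."""

    alpha: float
    beta: float = 1.0
    p: float = 20.0
    kappa: float = 20.0

    def __post_init__(self):
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 1/2)")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if (1 - 2 * self.alpha) / (1 + self.beta) < 4 / self.p - 1e-12:
            raise ValueError("need (1-2 alpha)/(1+beta) >= 4/p")
        if not self.alpha < 0.5 - 2 / self.kappa:
            raise ValueError("need alpha < 1/2 - 2/kappa")

    @property
    def q(self) -> float:
        return min((self.kappa * (0.5 - self.alpha) - 2) / 2, 1.0)


def _path_pairs(system, u, label):
    """(min time gap, displacement) over value pairs of one ancestral path.

    The path is a step function; two value intervals [a_i, b_i), [a_j, b_j)
    (i < j) admit sample times at distance arbitrarily close to
    max(0, a_j - b_i), so a pair qualifies for window rho iff that infimum
    gap is < rho.
    """
    path = extract_ancestral_path(system, u, label)
    bps = list(path.breakpoints)
    starts = [b[0] for b in bps]
    ends = starts[1:] + [u]
    pos = [system.position(b[1]) for b in bps]
    pairs = []
    for i in range(len(bps)):
        for j in range(i + 1, len(bps)):
            gap = max(0.0, starts[j] - ends[i])
            disp = float(np.linalg.norm(pos[j] - pos[i]))
            if disp > 0:
                pairs.append((gap, disp))
    return pairs


def modulus_stat(rsys, rho, pair_budget=500, rng=None):
    """Delta^(n)(rho): sup of |y_2 - y_1| over sampled ancestrally related
    pairs with time separation at most rho.

    Evaluated on the jump skeleton through ancestral paths (every related
    pair lies on the path of its later endpoint for unique-path models), so
    the value is a lower bound on the true sup unless the budget covers all
    endpoints.  Returns (value, info dict).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    skel = rsys.skeleton()
    endpoints = [(u, lab) for u in skel for lab in rsys.occupied(u)]
    exhaustive = len(endpoints) <= pair_budget
    if not exhaustive:
        idx = rng.choice(len(endpoints), pair_budget, replace=False)
        endpoints = [endpoints[i] for i in idx]
    best = 0.0
    n_pairs = 0
    for (u, lab) in endpoints:
        for gap, disp in _path_pairs(rsys, u, lab):
            n_pairs += 1
            if gap < rho and disp > best:
                best = disp
    return best, {"endpoints": len(endpoints), "pairs": n_pairs,
                  "exhaustive": exhaustive, "rho": rho}


def modulus_tail_experiment(spec, n_grid, rho_grid, cfg: ModulusConfig, C,
                            reps, seed, caps=None, pair_budget=200):
    """Empirical modulus tails at diffusive scale n.

    Per replicate and window scale rho, two events are recorded:

    * pointwise exceedance: Delta^(n)(rho) > C (rho^alpha + n^-alpha);
    * modulus failure: some window scale rho' <= rho already carries a
      violating pair, i.e. delta_n < rho where delta_n is the smallest
      window scale at which the Hoelder bound C (rho'^alpha + n^-alpha)
      fails.  A pair with time gap g and displacement D violates at scales
      rho' in (g, (D/C - n^-alpha)^{1/alpha}), so delta_n is the smallest
      such g over violating-capable pairs.

    The failure probability is monotone in rho by construction and is the
    empirical counterpart of the theorem's tail bound c (rho^beta + n^-q);
    the returned log-log slopes (one per n, with a regression standard
    error) are fitted on it.  Returns (DataFrame, {n: (slope, slope_se)}).
    """
    import pandas as pd

    rho_grid = sorted(float(r) for r in rho_grid)
    rows = []
    slopes = {}
    d = spec.kernel.d if hasattr(spec, "kernel") else None
    for n in n_grid:
        rng = np.random.default_rng(child_seed(seed, f"modulus-{spec.tag}-{n}"))
        n_eps = float(n) ** -cfg.alpha
        exceed = np.zeros(len(rho_grid), dtype=int)
        fail = np.zeros(len(rho_grid), dtype=int)
        for _ in range(reps):
            sim = spec.sample(float(n), rng, caps=caps, keep_record=True)
            sys = spec.system(sim)
            rsys = rescale_system(sys, float(n))
            pairs = []
            skel = rsys.skeleton()
            endpoints = [(u, lab) for u in skel for lab in rsys.occupied(u)]
            if len(endpoints) > pair_budget:
                idx = rng.choice(len(endpoints), pair_budget, replace=False)
                endpoints = [endpoints[i] for i in idx]
            for (u, lab) in endpoints:
                pairs.extend(_path_pairs(rsys, u, lab))
            delta_hat = math.inf
            for gap, disp in pairs:
                excess = disp / C - n_eps
                if excess > 0 and gap < excess ** (1.0 / cfg.alpha):
                    delta_hat = min(delta_hat, gap)
            for k, rho in enumerate(rho_grid):
                thresh = C * (rho ** cfg.alpha + n_eps)
                if any(gap < rho and disp > thresh for gap, disp in pairs):
                    exceed[k] += 1
                if delta_hat < rho:
                    fail[k] += 1
        m_n = m_function(spec.tag, float(n), d=d)
        for k, rho in enumerate(rho_grid):
            p = exceed[k] / reps
            f = fail[k] / reps
            rows.append({"model": spec.tag, "n": n, "rho": rho, "C": C,
                         "alpha": cfg.alpha, "beta": cfg.beta, "reps": reps,
                         "seed": seed, "exceed_prob": p,
                         "se": math.sqrt(max(p * (1 - p), 1e-300) / reps),
                         "fail_prob": f,
                         "fail_se": math.sqrt(max(f * (1 - f), 1e-300) / reps),
                         "m_n": m_n, "m_exceed": m_n * p, "m_fail": m_n * f})
        probs = fail / reps
        pos = [(math.log(r), math.log(p)) for r, p in zip(rho_grid, probs) if p > 0]
        if len(pos) >= 3:
            xs = np.array([q[0] for q in pos])
            ys = np.array([q[1] for q in pos])
            coef, cov = np.polyfit(xs, ys, 1, cov=True)
            slopes[n] = (float(coef[0]), float(math.sqrt(cov[0, 0])))
        else:
            slopes[n] = (float("nan"), float("nan"))
    return pd.DataFrame(rows), slopes
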