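"""Abstract ancestral relations: queries, axiom checks, paths, rescaling.

Each lattice model (voter, contact process, oriented percolation, branching
random walk) carries an ancestral relation  (s, y) ->a (t, x)  declaring
which occupied space-time points descend from which.  This module gives the
model-independent layer: the query interface ``e_{s,t}(y, x)``, runtime
checks of the relation axioms, extraction of ancestral paths (cadlag step
functions through the relation), construction of interpolation chains, and
diffusive rescaling  (t, x) -> (nt, sqrt(n) x).

Axioms checked at runtime on realized samples:

* equal-time identity: ``e_{s,s}(y, x) = 1`` iff ``x = y`` occupied at s;
* endpoint occupancy: a related pair has both endpoints occupied;
* root property: ``(0, root) ->a (t, x)`` iff x occupied at t;
* transitivity;
* interpolation: a related pair at times s1 < s3 admits an intermediate
  ancestor at any s2 in between.

Path regularity and measurability are properties of the probabilistic
construction, not of single realizations, and are deliberately not asserted
here.
"""

from __future__ import annotations

import abc
import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AncestralSystem",
    "AncestralPath",
    "RescaledSystem",
    "AxiomReport",
    "check_ar_axioms",
    "extract_ancestral_path",
    "rescale_system",
    "interpolation_chain",
]


class AncestralSystem(abc.ABC):
    """Queryable ancestral relation over one model realization.

    Labels identify occupied units: lattice sites for single-occupancy
    models, particle ids for the (multi-occupancy) branching random walk.
    ``position`` maps a label to its point in R^d.
    """

    model: str = ""
    time_kind: str = "continuous"  # or "discrete"
    d: int = 1

    @abc.abstractmethod
    def occupied(self, t) -> tuple:
        """Sorted tuple of labels occupied at time t."""

    @abc.abstractmethod
    def relates(self, s, y, t, x) -> bool:
        """e_{s,t}(y, x): is (s, y) an ancestor of (t, x)?  Requires s <= t."""

    @abc.abstractmethod
    def position(self, label) -> np.ndarray:
        """Spatial position of a label (float vector of length d)."""

    @property
    @abc.abstractmethod
    def root(self):
        """Label of the time-0 ancestor at the origin."""

    @abc.abstractmethod
    def skeleton(self) -> list:
        """Sorted times at which the occupied configuration can change,
        including 0 and the horizon; sufficient for piecewise-constant
        trajectories."""

    @property
    @abc.abstractmethod
    def horizon(self):
        """Largest time up to which the realization is defined."""

    # -- optional hook: models with a.s. unique paths override this --------
    def exact_path(self, t, x):
        """Return the model's canonical ancestral path to (t, x), or None to
        fall back on the generic skeleton-based extractor."""
        return None

    def is_occupied(self, t, label) -> bool:
        return label in self.occupied(t)


@dataclass(frozen=True)
class AncestralPath:
    """Cadlag step path s -> w_s ending at (t, x), with w_s = x for s >= t.

    ``breakpoints`` is an ascending list of (time, label); w_s equals the
    label at the last breakpoint time <= s.  The first breakpoint is at
    time 0.
    """

    t: float
    terminal: object
    breakpoints: tuple
    system: AncestralSystem = field(repr=False, default=None, compare=False)

    def __post_init__(self):
        if not self.breakpoints or self.breakpoints[0][0] != 0:
            raise ValueError("path must start with a breakpoint at time 0")
        times = [b[0] for b in self.breakpoints]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")

    def label_at(self, s):
        if s < 0:
            raise ValueError("path is defined for s >= 0")
        if s >= self.t:
            return self.terminal
        times = [b[0] for b in self.breakpoints]
        return self.breakpoints[bisect_right(times, s) - 1][1]

    def position_at(self, s) -> np.ndarray:
        if self.system is None:
            raise ValueError("path has no attached system to resolve positions")
        return self.system.position(self.label_at(s))


class RescaledSystem(AncestralSystem):
    """Diffusive reindexing: T^(n)_t = T_{nt} / sqrt(n), with
    (s, y) ->a,n (t, x)  iff  (ns, sqrt(n) y) ->a (nt, sqrt(n) x).

    Pure coordinate/time change; no resampling.  Labels are shared with the
    base system; only times and positions are scaled.
    """

    def __init__(self, base: AncestralSystem, n: float):
        if n < 1:
            raise ValueError("rescaling parameter n must be >= 1")
        self.base = base
        self.n = float(n)
        self.model = base.model
        self.time_kind = base.time_kind
        self.d = base.d
        self._sqrt_n = math.sqrt(self.n)

    def occupied(self, t):
        return self.base.occupied(self.n * t)

    def relates(self, s, y, t, x):
        return self.base.relates(self.n * s, y, self.n * t, x)

    def position(self, label):
        return self.base.position(label) / self._sqrt_n

    @property
    def root(self):
        return self.base.root

    def skeleton(self):
        return [u / self.n for u in self.base.skeleton()]

    @property
    def horizon(self):
        return self.base.horizon / self.n

    def exact_path(self, t, x):
        path = self.base.exact_path(self.n * t, x)
        if path is None:
            return None
        bps = tuple((u / self.n, lab) for u, lab in path.breakpoints)
        return AncestralPath(t=path.t / self.n, terminal=path.terminal,
                             breakpoints=bps, system=self)


def rescale_system(system: AncestralSystem, n: float) -> AncestralSystem:
    """Rescaled view of ``system``; n = 1 returns the system unchanged."""
    if n == 1:
        return system
    if isinstance(system, RescaledSystem):
        return RescaledSystem(system.base, system.n * n)
    return RescaledSystem(system, n)


# ---------------------------------------------------------------------------
# axiom checking
# ---------------------------------------------------------------------------

_AXIOMS = ("equal_time", "endpoints_occupied", "root_property",
           "transitivity", "interpolation")


@dataclass
class AxiomReport:
    n_checked: dict
    witnesses: dict

    @property
    def passed(self) -> bool:
        return all(len(w) == 0 for w in self.witnesses.values())

    def to_json(self) -> str:
        return json.dumps({
            ax: {"pass": len(self.witnesses[ax]) == 0,
                 "n_checked": self.n_checked[ax],
                 "witnesses": [repr(w) for w in self.witnesses[ax]]}
            for ax in _AXIOMS
        })


def _grid(system: AncestralSystem, time_grid, max_points=10):
    if time_grid is not None:
        return sorted(set(time_grid))
    sk = system.skeleton()
    if len(sk) <= max_points:
        return list(sk)
    idx = np.unique(np.linspace(0, len(sk) - 1, max_points).astype(int))
    return [sk[i] for i in idx]


def check_ar_axioms(system: AncestralSystem, time_grid=None, n_triples=200,
                    rng=None, max_pairs=400, max_witnesses=5) -> AxiomReport:
    """Check the relation axioms on a realized sample.

    Equal-time identity, endpoint occupancy and the root property are
    checked exhaustively on the time grid (occupied-label pairs capped at
    ``max_pairs`` per time, sampled if larger).  Transitivity and
    interpolation are checked on ``n_triples`` sampled ordered time triples
    with all occupied-label combinations subsampled.  Violations are
    reported with witnesses; nothing is raised.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = _grid(system, time_grid)
    counts = {ax: 0 for ax in _AXIOMS}
    wit = {ax: [] for ax in _AXIOMS}

    def note(ax, witness):
        if len(wit[ax]) < max_witnesses:
            wit[ax].append(witness)

    root = system.root

    # equal-time identity + root property on the grid
    for t in grid:
        occ = system.occupied(t)
        labels = list(occ)
        if len(labels) > 20:
            labels = [labels[i] for i in rng.choice(len(labels), 20, replace=False)]
        for a in labels:
            for b in labels:
                counts["equal_time"] += 1
                if system.relates(t, a, t, b) != (a == b):
                    note("equal_time", (t, a, b))
        for b in labels:
            counts["root_property"] += 1
            if not system.relates(0, root, t, b):
                note("root_property", (t, b))

    # endpoint occupancy on sampled ordered pairs
    for _ in range(min(n_triples, 100)):
        if len(grid) < 2:
            break
        i, j = sorted(rng.choice(len(grid), 2, replace=True))
        s, t = grid[i], grid[j]
        occ_s, occ_t = system.occupied(s), system.occupied(t)
        if not occ_t:
            continue
        y = occ_s[rng.integers(len(occ_s))] if occ_s else root
        x = occ_t[rng.integers(len(occ_t))]
        counts["endpoints_occupied"] += 1
        if system.relates(s, y, t, x) and (y not in occ_s or x not in occ_t):
            note("endpoints_occupied", (s, y, t, x))

    # transitivity and interpolation on sampled triples
    for _ in range(n_triples):
        if len(grid) < 3:
            break
        i, j, k = sorted(rng.choice(len(grid), 3, replace=True))
        s1, s2, s3 = grid[i], grid[j], grid[k]
        occ1, occ2, occ3 = (system.occupied(u) for u in (s1, s2, s3))
        if not (occ1 and occ2 and occ3):
            continue
        y1 = occ1[rng.integers(len(occ1))]
        y2 = occ2[rng.integers(len(occ2))]
        y3 = occ3[rng.integers(len(occ3))]
        counts["transitivity"] += 1
        if (system.relates(s1, y1, s2, y2) and system.relates(s2, y2, s3, y3)
                and not system.relates(s1, y1, s3, y3)):
            note("transitivity", (s1, y1, s2, y2, s3, y3))
        counts["interpolation"] += 1
        if system.relates(s1, y1, s3, y3) and s1 < s2 < s3:
            found = any(system.relates(s1, y1, s2, z) and system.relates(s2, z, s3, y3)
                        for z in occ2)
            if not found:
                note("interpolation", (s1, y1, s2, s3, y3))

    return AxiomReport(n_checked=counts, witnesses=wit)


# ---------------------------------------------------------------------------
# path extraction and interpolation chains
# ---------------------------------------------------------------------------

def _lex_key(system, label):
    return (tuple(system.position(label)), repr(label))


def extract_ancestral_path(system: AncestralSystem, t, x) -> AncestralPath:
    """An ancestral path to the occupied point (t, x).

    Models with a.s. unique paths (voter, branching random walk) return the
    canonical one; otherwise the path is built backwards through the jump
    skeleton, choosing at each step the lexicographically smallest
    intermediate ancestor (a deterministic tie-break; interpolation
    guarantees existence).
    """
    if x not in system.occupied(t):
        raise ValueError(f"({t}, {x}) is not occupied")
    exact = system.exact_path(t, x)
    if exact is not None:
        return exact
    times = [u for u in system.skeleton() if u < t]
    points = [(t, x)]
    cur_t, cur_x = t, x
    for s in reversed(times):
        cands = [y for y in system.occupied(s) if system.relates(s, y, cur_t, cur_x)]
        if not cands:
            raise RuntimeError(
                f"interpolation failed between ({s}) and ({cur_t}, {cur_x})")
        y = min(cands, key=lambda lab: _lex_key(system, lab))
        points.append((s, y))
        cur_t, cur_x = s, y
    points.reverse()
    # collapse repeated labels into cadlag breakpoints
    bps = []
    for u, lab in points:
        if not bps or bps[-1][1] != lab:
            bps.append((u, lab))
    if bps[0][0] != 0:
        bps.insert(0, (0.0, system.root))
    return AncestralPath(t=t, terminal=x, breakpoints=tuple(bps), system=system)


def interpolation_chain(system: AncestralSystem, times, start, end) -> list:
    """Intermediate ancestors y_1 ... y_{M-1} for related endpoints.

    ``times`` is an increasing sequence s_0 < ... < s_M; ``start``/``end``
    are labels at s_0 and s_M with (s_0, start) ->a (s_M, end).  Returns the
    chain of intermediate labels, each consecutive pair related.
    """
    times = list(times)
    if any(a >= b for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    s0, sM = times[0], times[-1]
    if not system.relates(s0, start, sM, end):
        raise ValueError("endpoints are not ancestrally related")
    chain = []
    cur_t, cur_x = sM, end
    for s in reversed(times[1:-1]):
        cands = [y for y in system.occupied(s)
                 if system.relates(s0, start, s, y) and system.relates(s, y, cur_t, cur_x)]
        if not cands:
            raise RuntimeError(f"no intermediate ancestor at time {s}")
        y = min(cands, key=lambda lab: _lex_key(system, lab))
        chain.append(y)
        cur_t, cur_x = s, y
    chain.reverse()
    return chain
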