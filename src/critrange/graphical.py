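"""Continuous-time graphical constructions: voter model and contact process.

Both models are built from independent Poisson event streams ("arrows" and,
for the contact process, recovery marks), realized lazily: events are only
materialized where they can affect the cluster of the single initial
occupied site at the origin, or a backward dual trace anchored in it.

Voter model: each site copies the type of a kernel-chosen neighbour at rate
one; started from a single 1 at the origin, the set of 1's is a finite
set-valued Markov process whose total mass is a martingale.  Tracing the
most recent arrow into a site backwards yields the dual coalescing random
walk, which defines the (a.s. unique) ancestral path of every occupied
space-time point.

Contact process: infected sites recover at rate 1 and infect kernel-chosen
neighbours at rate lambda; a site is infected at time t iff the graphical
record contains an oriented, recovery-free arrow path from (0, o) to (t, x).
The ancestral relation is (s,y) ->a (t,x) iff (0,o) -> (s,y) -> (t,x).

Simulation is exact event-driven Monte Carlo (no time discretization); event
times are continuous, so ties have probability zero.  Resource caps mark the
realization as censored rather than silently truncating.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .ancestry import AncestralPath, AncestralSystem
from .kernels import StepKernel

__all__ = [
    "SimCaps",
    "GraphicalRecord",
    "OccupiedTrajectory",
    "DualWalkPath",
    "CoverageError",
    "simulate_voter",
    "replay_voter",
    "dual_walk",
    "voter_ancestral_system",
    "VoterAncestralSystem",
    "simulate_contact",
    "replay_contact",
    "contact_reachable",
    "contact_ancestral_system",
    "ContactAncestralSystem",
    "estimate_lambda_c",
    "VoterSpec",
    "ContactSpec",
    "record_to_json",
    "record_from_json",
]


class CoverageError(RuntimeError):
    """A backward trace left the materialized region of a graphical record."""


@dataclass(frozen=True)
class SimCaps:
    """Resource caps; hitting one flags the realization as censored."""

    max_events: int = 20_000_000
    max_sites: int = 2_000_000


_DEFAULT_CAPS = SimCaps()


# ---------------------------------------------------------------------------
# packed integer site encoding (additive in the offsets, fast in dict/set)
# ---------------------------------------------------------------------------

_B = 1 << 24
_M = 1 << 25


def _enc(site) -> int:
    v = 0
    for c in reversed(site):
        v = v * _M + (c + _B)
    return v


def _dec(v: int, d: int) -> tuple:
    out = []
    for _ in range(d):
        v, r = divmod(v, _M)
        out.append(r - _B)
    return tuple(out)


def _deltas(kernel: StepKernel):
    """Packed encodings of the kernel offsets (site addition = int addition)."""
    out = []
    for off in kernel.offsets:
        v = 0
        for c in reversed(off.tolist()):
            v = v * _M + c
        out.append(v)
    return out


def _radius2(site) -> int:
    return sum(c * c for c in site)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GraphicalRecord:
    """Realized arrows and recovery marks of one graphical construction.

    ``arrows`` are (time, target, source) with sites as integer tuples:
    the source imposes its state on / infects the target.  ``recoveries``
    are (time, site), contact process only.  ``complete`` marks hand-built
    fixtures whose event list is exhaustive; simulated records are lazily
    materialized (sufficient to trace any dual anchored in the cluster).
    """

    model: str
    t_max: float
    arrows: list
    recoveries: list = field(default_factory=list)
    seed: object = None
    complete: bool = False
    _into: dict = field(default=None, repr=False)

    def arrows_into(self, site):
        """(times, sources) of arrows into ``site``, sorted by time."""
        if self._into is None:
            idx = {}
            for (t, tgt, src) in self.arrows:
                idx.setdefault(tgt, []).append((t, src))
            for tgt in idx:
                idx[tgt].sort()
            self._into = idx
        entries = self._into.get(site, [])
        return [e[0] for e in entries], [e[1] for e in entries]

    def validate(self):
        times = [a[0] for a in self.arrows] + [r[0] for r in self.recoveries]
        if any(t <= 0 or t > self.t_max for t in times):
            raise ValueError("event times must lie in (0, t_max]")
        if len(set(times)) != len(times):
            raise ValueError("event times must be mutually distinct")


@dataclass
class OccupiedTrajectory:
    """Cadlag finite-set-valued path t -> T_t with T_0 = {o}.

    Stored as a chronological change log: ``events`` holds
    (time, site, added) toggles.  Once empty the set stays empty (the
    simulators stop at extinction), and every occupied set is finite.
    """

    d: int
    events: list
    t_max: float
    model: str = ""
    censored: bool = False
    extinction_time: float | None = None  # None: alive at t_max
    _intervals: dict = field(default=None, repr=False)

    @property
    def origin(self) -> tuple:
        return (0,) * self.d

    @property
    def jump_times(self) -> list:
        return [e[0] for e in self.events]

    def set_at(self, t) -> frozenset:
        if t < 0:
            raise ValueError("time must be nonnegative")
        occ = {self.origin}
        for (u, site, added) in self.events:
            if u > t:
                break
            (occ.add if added else occ.discard)(site)
        return frozenset(occ)

    def size_at(self, t) -> int:
        return len(self.set_at(t))

    def occupied(self, site, t) -> bool:
        """O(log) occupancy query via per-site toggle indexes."""
        if self._intervals is None:
            idx = {}
            for (u, s, _added) in self.events:
                idx.setdefault(s, []).append(u)
            self._intervals = idx
        toggles = self._intervals.get(site, ())
        n = bisect_right(toggles, t)
        start = site == self.origin
        return bool(start ^ (n % 2))

    def range_sites(self) -> frozenset:
        return frozenset({self.origin} | {s for (_, s, a) in self.events if a})

    def first_exit_time(self, r: float):
        """First time a site with Euclidean |x| > r becomes occupied."""
        r2 = r * r
        for (u, site, added) in self.events:
            if added and _radius2(site) > r2:
                return u
        return None

    def segments(self):
        """Yield (t0, t1, frozenset) constancy pieces covering [0, t_max]."""
        occ = {self.origin}
        t0 = 0.0
        for (u, site, added) in self.events:
            if u > t0:
                yield (t0, u, frozenset(occ))
                t0 = u
            (occ.add if added else occ.discard)(site)
        if t0 < self.t_max or not self.events:
            yield (t0, self.t_max, frozenset(occ))

    @property
    def survived(self) -> bool:
        return self.extinction_time is None


@dataclass(frozen=True)
class DualWalkPath:
    """Backward dual walk W^{t,x}_s of the voter model, s in [0, t].

    ``jumps`` lists (s_k, y_k) in increasing backward time s_k = t - u_k
    (u_k the arrow times); W_s = x for s <= s_1 and y_k for s_k < s <=
    s_{k+1} (left-continuous with right limits).
    """

    t: float
    anchor: tuple
    jumps: tuple

    def value(self, s):
        """W^{t,x}_s for 0 <= s <= t."""
        if s < 0 or s > self.t:
            raise ValueError("dual walk defined on [0, t]")
        stimes = [j[0] for j in self.jumps]
        k = bisect_left(stimes, s)  # number of jump times strictly below s
        # s == s_k belongs to the previous piece (left-continuity)
        while k > 0 and stimes[k - 1] >= s:
            k -= 1
        return self.anchor if k == 0 else self.jumps[k - 1][1]

    def w(self, s):
        """Ancestral path reindexing w_s(t, x) = W^{t,x}_{(t-s)^+}."""
        back = self.t - s
        if back < 0:
            back = 0.0
        return self.value(back)

    def forward_breakpoints(self):
        """Ascending (time, site) cadlag breakpoints of s -> w_s."""
        bps = []
        n = len(self.jumps)
        if n:
            bps.append((0.0, self.jumps[-1][1]))
            for k in range(n - 1, 0, -1):
                bps.append((self.t - self.jumps[k][0], self.jumps[k - 1][1]))
            bps.append((self.t - self.jumps[0][0], self.anchor))
        else:
            bps.append((0.0, self.anchor))
        return bps


# ---------------------------------------------------------------------------
# buffered randomness for the event loops
# ---------------------------------------------------------------------------

class _Rand:
    __slots__ = ("rng", "size", "_u", "_iu", "_e", "_ie", "_s", "_is", "_cum")

    def __init__(self, rng, cum, size=8192):
        self.rng = rng
        self.size = size
        self._cum = np.ascontiguousarray(cum)
        self._u = rng.random(size)
        self._iu = 0
        self._e = rng.standard_exponential(size)
        self._ie = 0
        self._s = np.searchsorted(self._cum, rng.random(size), side="right")
        self._is = 0

    def uniform(self):
        i = self._iu
        if i >= self.size:
            self._u = self.rng.random(self.size)
            i = 0
        self._iu = i + 1
        return self._u[i]

    def expo(self):
        i = self._ie
        if i >= self.size:
            self._e = self.rng.standard_exponential(self.size)
            i = 0
        self._ie = i + 1
        return self._e[i]

    def step_index(self):
        i = self._is
        if i >= self.size:
            self._s = np.searchsorted(self._cum, self.rng.random(self.size), side="right")
            i = 0
        self._is = i + 1
        return int(self._s[i])


class _SetSampler:
    """Uniform sampling / O(1) add / O(1) remove over a dynamic set."""

    __slots__ = ("items", "pos")

    def __init__(self, items):
        self.items = list(items)
        self.pos = {v: i for i, v in enumerate(self.items)}

    def __len__(self):
        return len(self.items)

    def __contains__(self, v):
        return v in self.pos

    def add(self, v):
        self.pos[v] = len(self.items)
        self.items.append(v)

    def remove(self, v):
        i = self.pos.pop(v)
        last = self.items.pop()
        if last != v:
            self.items[i] = last
            self.pos[last] = i

    def pick(self, u):
        return self.items[int(u * len(self.items))]


# ---------------------------------------------------------------------------
# event-driven cores
# ---------------------------------------------------------------------------

def _core(model, kernel, t_max, rng, lam=None, caps=None, stop_radius=None,
          eval_times=None, r_grid=None, keep_record=False, keep_log=True,
          capture_sets=False):
    """Shared Gillespie loop for voter ('voter') and contact ('contact').

    Voter events are a superposition of an "incoming" stream (rate |T|:
    arrows into occupied targets from kernel-drawn sources) and an
    "outgoing" stream (rate |T|: arrows out of occupied sources), thinned
    by discarding outgoing arrows whose target is occupied (those are
    already covered by the incoming stream).  This materializes exactly the
    arrows whose target is occupied at the arrow time plus the arrows that
    turn a vacant site on -- sufficient both to evolve T_t and to trace any
    dual walk anchored at an occupied space-time point, since dual traces
    stay inside the occupied sets.

    Contact events: recovery marks at rate 1 per infected site, infection
    arrows out of each infected site at total rate lambda (all recorded).
    """
    caps = caps or _DEFAULT_CAPS
    d = kernel.d
    deltas = _deltas(kernel)
    rnd = _Rand(rng, kernel._cum)
    occ = _SetSampler([_enc((0,) * d)])
    is_voter = model == "voter"
    p_recover = None if is_voter else 1.0 / (1.0 + lam)

    stop_r2 = None if stop_radius is None else float(stop_radius) ** 2
    r2_grid = None
    exit_times = None
    if r_grid is not None:
        r2_grid = [float(r) ** 2 for r in r_grid]
        exit_times = [None] * len(r2_grid)
        next_exit = 0
    evals = sorted(eval_times) if eval_times else []
    k_eval = 0
    eval_sizes = [None] * len(evals)
    eval_sets = [None] * len(evals) if capture_sets else None

    log = [] if keep_log else None
    arrows = [] if keep_record else None
    recoveries = [] if (keep_record and not is_voter) else None

    t = 0.0
    n_events = 0
    censored = False
    extinct_at = None
    exited = False

    def _capture(up_to):
        nonlocal k_eval
        while k_eval < len(evals) and evals[k_eval] < up_to:
            eval_sizes[k_eval] = len(occ)
            if capture_sets:
                eval_sets[k_eval] = [_dec(v, d) for v in occ.items]
            k_eval += 1

    while True:
        n = len(occ)
        if n == 0:
            _capture(math.inf)
            break
        rate = 2.0 * n if is_voter else (1.0 + lam) * n
        t_new = t + rnd.expo() / rate
        if t_new > t_max:
            # state is constant on [t, t_max]; resolve all remaining evals
            _capture(math.inf)
            t = t_max
            break
        _capture(t_new)
        n_events += 1
        if n_events > caps.max_events or n > caps.max_sites:
            censored = True
            t = t_new
            break
        t = t_new
        u_kind = rnd.uniform()
        site = occ.pick(rnd.uniform())
        if is_voter:
            delta = deltas[rnd.step_index()]
            if u_kind < 0.5:
                # incoming arrow: site is the target, source drawn from D
                source = site + delta
                if keep_record:
                    arrows.append((t, site, source))
                if source not in occ:
                    occ.remove(site)
                    if keep_log:
                        log.append((t, site, False))
                    if len(occ) == 0:
                        extinct_at = t
                        _capture(math.inf)
                        break
            else:
                # outgoing arrow: site is the source
                target = site + delta
                if target not in occ:
                    if keep_record:
                        arrows.append((t, target, site))
                    occ.add(target)
                    if keep_log:
                        log.append((t, target, True))
                    if stop_r2 is not None or r2_grid is not None:
                        r2 = _radius2(_dec(target, d))
                        if r2_grid is not None:
                            while next_exit < len(r2_grid) and r2 > r2_grid[next_exit]:
                                exit_times[next_exit] = t
                                next_exit += 1
                        if stop_r2 is not None and r2 > stop_r2:
                            exited = True
                            break
                # occupied target: thinned duplicate of the incoming stream
        else:
            if u_kind < p_recover:
                if keep_record:
                    recoveries.append((t, site))
                occ.remove(site)
                if keep_log:
                    log.append((t, site, False))
                if len(occ) == 0:
                    extinct_at = t
                    _capture(math.inf)
                    break
            else:
                delta = deltas[rnd.step_index()]
                target = site + delta
                if keep_record:
                    arrows.append((t, target, site))
                if target not in occ:
                    occ.add(target)
                    if keep_log:
                        log.append((t, target, True))
                    if stop_r2 is not None or r2_grid is not None:
                        r2 = _radius2(_dec(target, d))
                        if r2_grid is not None:
                            while next_exit < len(r2_grid) and r2 > r2_grid[next_exit]:
                                exit_times[next_exit] = t
                                next_exit += 1
                        if stop_r2 is not None and r2 > stop_r2:
                            exited = True
                            break

    return {
        "extinct_at": extinct_at,
        "censored": censored,
        "exited": exited,
        "t_end": t,
        "n_events": n_events,
        "final_size": len(occ),
        "eval_sizes": eval_sizes,
        "eval_sets": eval_sets,
        "exit_times": exit_times,
        "log": log,
        "arrows": arrows,
        "recoveries": recoveries,
    }


def _wrap(model, kernel, t_max, seed, raw, keep_record):
    d = kernel.d
    events = [(t, _dec(v, d), added) for (t, v, added) in raw["log"]]
    traj = OccupiedTrajectory(d=d, events=events, t_max=t_max, model=model,
                             censored=raw["censored"],
                             extinction_time=raw["extinct_at"])
    record = None
    if keep_record:
        arrows = [(t, _dec(tgt, d), _dec(src, d)) for (t, tgt, src) in raw["arrows"]]
        recov = [(t, _dec(s, d)) for (t, s) in (raw["recoveries"] or [])]
        record = GraphicalRecord(model=model, t_max=t_max, arrows=arrows,
                                 recoveries=recov, seed=seed, complete=False)
    return record, traj


def _as_rng(seed=None, rng=None):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_voter(kernel: StepKernel, t_max: float, seed=None, *, rng=None,
                   caps: SimCaps | None = None, keep_record: bool = True,
                   stop_radius=None):
    """Simulate the voter model from T_0 = {o} up to t_max.

    Returns (GraphicalRecord, OccupiedTrajectory); the record retains every
    arrow needed to trace dual walks anchored at occupied space-time points.
    Set ``keep_record=False`` for bulk statistics (record is then None).
    """
    if t_max < 0:
        raise ValueError("t_max must be nonnegative")
    rng = _as_rng(seed, rng)
    raw = _core("voter", kernel, t_max, rng, caps=caps, stop_radius=stop_radius,
                keep_record=keep_record)
    return _wrap("voter", kernel, t_max, seed, raw, keep_record)


def simulate_contact(kernel: StepKernel, lam: float, t_max: float, seed=None, *,
                     rng=None, caps: SimCaps | None = None,
                     keep_record: bool = True, stop_radius=None):
    """Simulate the contact process (recovery rate 1, infection rate
    lambda * D) from T_0 = {o} up to t_max."""
    if lam < 0:
        raise ValueError("infection rate must be nonnegative")
    if t_max < 0:
        raise ValueError("t_max must be nonnegative")
    rng = _as_rng(seed, rng)
    raw = _core("contact", kernel, t_max, rng, lam=lam, caps=caps,
                stop_radius=stop_radius, keep_record=keep_record)
    return _wrap("contact", kernel, t_max, seed, raw, keep_record)


# ---------------------------------------------------------------------------
# replay (fixture records) and dual walks
# ---------------------------------------------------------------------------

def replay_voter(record: GraphicalRecord, t_max=None) -> OccupiedTrajectory:
    """Trajectory determined by a voter record's flip rule: at each arrow
    (u, x, y) with differing types, target x adopts the source y's type."""
    t_max = record.t_max if t_max is None else t_max
    arrows = sorted(record.arrows)
    if not arrows:
        d = 1
    else:
        d = len(arrows[0][1])
    origin = (0,) * d
    occ = {origin}
    events = []
    for (u, tgt, src) in arrows:
        if u > t_max:
            break
        st, tt = src in occ, tgt in occ
        if st and not tt:
            occ.add(tgt)
            events.append((u, tgt, True))
        elif tt and not st:
            occ.discard(tgt)
            events.append((u, tgt, False))
        if not occ:
            return OccupiedTrajectory(d=d, events=events, t_max=t_max,
                                      model="voter", extinction_time=u)
    return OccupiedTrajectory(d=d, events=events, t_max=t_max, model="voter")


def replay_contact(record: GraphicalRecord, t_max=None,
                   arrow_keep=None) -> OccupiedTrajectory:
    """Trajectory of the contact process on a record: forward sweep of
    recovery-free arrow reachability from (0, o).

    ``arrow_keep``: optional predicate on arrow index (for coupled
    thinning constructions in tests); kept arrows transmit infection.
    """
    t_max = record.t_max if t_max is None else t_max
    tagged = [(a[0], 0, i, a) for i, a in enumerate(record.arrows)]
    tagged += [(r[0], 1, i, r) for i, r in enumerate(record.recoveries)]
    tagged.sort()
    d = None
    for (_, kind, _, ev) in tagged:
        d = len(ev[1])
        break
    d = d or 1
    origin = (0,) * d
    occ = {origin}
    events = []
    ext = None
    for (u, kind, i, ev) in tagged:
        if u > t_max:
            break
        if kind == 1:
            site = ev[1]
            if site in occ:
                occ.discard(site)
                events.append((u, site, False))
                if not occ:
                    ext = u
                    break
        else:
            _, tgt, src = ev
            if arrow_keep is not None and not arrow_keep(i):
                continue
            if src in occ and tgt not in occ:
                occ.add(tgt)
                events.append((u, tgt, True))
    return OccupiedTrajectory(d=d, events=events, t_max=t_max, model="contact",
                              extinction_time=ext)


def dual_walk(record: GraphicalRecord, t: float, x: tuple,
              trajectory: OccupiedTrajectory | None = None) -> DualWalkPath:
    """Backward dual walk W^{t,x} traced through the record's arrows.

    At the most recent arrow into the current site the walk jumps to the
    arrow's source (arrows at exactly time t are included; subsequent
    lookups are strictly before the previous arrow).  If a trajectory is
    supplied and the record is lazily materialized, the trace is checked to
    stay inside the occupied sets; leaving them raises CoverageError.
    """
    if t < 0 or t > record.t_max:
        raise ValueError("anchor time outside the record horizon")
    jumps = []
    cur = x
    hi = t
    first = True
    guard = trajectory is not None and not record.complete
    while True:
        if guard and not trajectory.occupied(cur, hi):
            raise CoverageError(
                f"dual trace reached ({hi}, {cur}) outside the occupied region")
        times, sources = record.arrows_into(cur)
        if first:
            i = bisect_right(times, hi) - 1
        else:
            i = bisect_left(times, hi) - 1
        if i < 0:
            break
        u = times[i]
        cur = sources[i]
        jumps.append((t - u, cur))
        hi = u
        first = False
    return DualWalkPath(t=t, anchor=x, jumps=tuple(jumps))


# ---------------------------------------------------------------------------
# ancestral systems
# ---------------------------------------------------------------------------

class _TrajectorySystem(AncestralSystem):
    """Shared plumbing for trajectory-backed continuous-time systems."""

    def __init__(self, record, trajectory):
        self.record = record
        self.trajectory = trajectory
        self.d = trajectory.d
        self._occ_cache = {}

    def occupied(self, t):
        key = round(float(t), 12)
        got = self._occ_cache.get(key)
        if got is None:
            got = tuple(sorted(self.trajectory.set_at(t)))
            self._occ_cache[key] = got
        return got

    def position(self, label):
        return np.asarray(label, dtype=float)

    @property
    def root(self):
        return self.trajectory.origin

    def skeleton(self):
        times = [0.0] + self.trajectory.jump_times
        if times[-1] < self.trajectory.t_max:
            times.append(self.trajectory.t_max)
        return times

    @property
    def horizon(self):
        return self.trajectory.t_max


class VoterAncestralSystem(_TrajectorySystem):
    """(s,y) ->a (t,x) iff x occupied at t and y = W^{t,x}_{(t-s)^+}."""

    model = "vm"
    time_kind = "continuous"

    def __init__(self, record, trajectory):
        super().__init__(record, trajectory)
        self._walks = {}

    def _walk(self, t, x):
        key = (round(float(t), 12), x)
        walk = self._walks.get(key)
        if walk is None:
            walk = dual_walk(self.record, t, x, trajectory=self.trajectory)
            self._walks[key] = walk
        return walk

    def relates(self, s, y, t, x):
        if s > t:
            raise ValueError("relation requires s <= t")
        if not self.trajectory.occupied(x, t):
            return False
        return self._walk(t, x).w(s) == y

    def exact_path(self, t, x):
        bps = tuple(self._walk(t, x).forward_breakpoints())
        return AncestralPath(t=t, terminal=x, breakpoints=bps, system=self)


def voter_ancestral_system(record, trajectory) -> VoterAncestralSystem:
    return VoterAncestralSystem(record, trajectory)


def contact_reachable(record: GraphicalRecord, s: float, y: tuple,
                      t: float, x: tuple) -> bool:
    """(s, y) -> (t, x): recovery-free oriented arrow path on the record.

    Equal times: reachable iff x == y.  Arrows at exactly time t count;
    recovery marks strictly after s and up to the relevant interval end cut
    the path.
    """
    if s > t:
        raise ValueError("reachability requires s <= t")
    if s == t:
        return x == y
    tagged = [(a[0], 0, a) for a in record.arrows]
    tagged += [(r[0], 1, r) for r in record.recoveries]
    tagged.sort(key=lambda e: (e[0], e[1]))
    alive = {y}
    for (u, kind, ev) in tagged:
        if u <= s:
            continue
        if u > t:
            break
        if kind == 1:
            alive.discard(ev[1])
        else:
            _, tgt, src = ev
            if src in alive:
                alive.add(tgt)
    return x in alive


class ContactAncestralSystem(_TrajectorySystem):
    """(s,y) ->a (t,x) iff (0,o) -> (s,y) and (s,y) -> (t,x) on the record."""

    model = "cp"
    time_kind = "continuous"

    def relates(self, s, y, t, x):
        if s > t:
            raise ValueError("relation requires s <= t")
        if not self.trajectory.occupied(y, s):
            return False
        return contact_reachable(self.record, s, y, t, x)


def contact_ancestral_system(record, trajectory) -> ContactAncestralSystem:
    return ContactAncestralSystem(record, trajectory)


# ---------------------------------------------------------------------------
# model specs (uniform handles for the statistics layer)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoterSpec:
    """Voter model with a given step kernel."""

    kernel: StepKernel

    tag = "vm"
    time_kind = "continuous"

    def simulate(self, t_max, rng, caps=None, keep_record=True):
        return simulate_voter(self.kernel, t_max, rng=rng, caps=caps,
                              keep_record=keep_record)

    def simulate_fast(self, t_max, rng, caps=None, **kw):
        return _core("voter", self.kernel, t_max, rng, caps=caps,
                     keep_log=False, **kw)

    def sample(self, horizon, rng, caps=None, keep_record=False):
        record, traj = self.simulate(horizon, rng, caps=caps,
                                     keep_record=keep_record)
        traj.record = record
        return traj

    def system(self, sim):
        return voter_ancestral_system(sim.record, sim)

    def ancestral_system(self, record, trajectory):
        return voter_ancestral_system(record, trajectory)


@dataclass(frozen=True)
class ContactSpec:
    """Contact process with a given kernel and infection rate lambda."""

    kernel: StepKernel
    lam: float

    tag = "cp"
    time_kind = "continuous"

    def simulate(self, t_max, rng, caps=None, keep_record=True):
        return simulate_contact(self.kernel, self.lam, t_max, rng=rng,
                                caps=caps, keep_record=keep_record)

    def simulate_fast(self, t_max, rng, caps=None, **kw):
        return _core("contact", self.kernel, t_max, rng, lam=self.lam,
                     caps=caps, keep_log=False, **kw)

    def sample(self, horizon, rng, caps=None, keep_record=False):
        record, traj = self.simulate(horizon, rng, caps=caps,
                                     keep_record=keep_record)
        traj.record = record
        return traj

    def system(self, sim):
        return contact_ancestral_system(sim.record, sim)

    def ancestral_system(self, record, trajectory):
        return contact_ancestral_system(record, trajectory)


# ---------------------------------------------------------------------------
# critical-rate bracketing (documented approximation, not exact lambda_c)
# ---------------------------------------------------------------------------

def estimate_lambda_c(kernel: StepKernel, bracket=(0.5, 4.0), t_probe=16.0,
                      reps=1500, seed=0, iters=7, caps=None):
    """Bisect for the infection rate at which t * theta(t) stops decaying.

    At each candidate lambda the survival fraction is estimated at t_probe
    and t_probe/2; subcritical rates show t*theta(t) decreasing in t,
    supercritical rates increasing.  Returns the final bracket with the
    per-probe Monte-Carlo estimates.  This is a desk-scale approximation to
    the critical rate, not the exact value.
    """
    from .seeding import child_seed

    lo, hi = float(bracket[0]), float(bracket[1])
    history = []
    for it in range(iters):
        lam = 0.5 * (lo + hi)
        rng = np.random.default_rng(child_seed(seed, "lambda_c", it))
        alive_half = alive_full = 0
        for _ in range(reps):
            raw = _core("contact", kernel, t_probe, rng, lam=lam, caps=caps,
                        keep_log=False, eval_times=[t_probe / 2.0])
            if raw["extinct_at"] is None and not raw["censored"]:
                alive_full += 1
            if raw["eval_sizes"][0] and raw["eval_sizes"][0] > 0:
                alive_half += 1
        g_half = (t_probe / 2.0) * alive_half / reps
        g_full = t_probe * alive_full / reps
        history.append({"lambda": lam, "t_theta_half": g_half,
                        "t_theta_full": g_full})
        if g_full > g_half:
            hi = lam  # growing mass: supercritical side
        else:
            lo = lam
    se = math.sqrt(1.0 / max(reps, 1))
    return {"bracket": (lo, hi), "history": history,
            "mc_uncertainty": t_probe * se, "approximate": True}


# ---------------------------------------------------------------------------
# fixture serialization
# ---------------------------------------------------------------------------

def record_to_json(record: GraphicalRecord, d: int) -> str:
    return json.dumps({
        "model": record.model,
        "d": d,
        "t_max": record.t_max,
        "arrows": [[t, *tgt, *src] for (t, tgt, src) in record.arrows],
        "recoveries": [[t, *site] for (t, site) in record.recoveries],
    })


def record_from_json(text: str) -> GraphicalRecord:
    obj = json.loads(text)
    d = int(obj["d"])
    arrows = [(row[0], tuple(int(c) for c in row[1:1 + d]),
               tuple(int(c) for c in row[1 + d:1 + 2 * d]))
              for row in obj["arrows"]]
    recov = [(row[0], tuple(int(c) for c in row[1:1 + d]))
             for row in obj.get("recoveries", [])]
    return GraphicalRecord(model=obj["model"], t_max=float(obj["t_max"]),
                           arrows=arrows, recoveries=recov, complete=True)
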