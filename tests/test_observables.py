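"""Survival, range, one-arm, Hausdorff metric, moments, modulus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from critrange.ancestry import rescale_system
from critrange.discrete import BRWSpec, OffspringLaw, OPSpec, simulate_op
from critrange.graphical import (ContactSpec, OccupiedTrajectory, VoterSpec,
                                 simulate_voter)
from critrange.observables import (ModulusConfig, MonteCarloEstimate,
                                   RangeSet, ancestral_increment_moment,
                                   estimate_survival_prob, hausdorff,
                                   integrated_mass, local_jump_probe,
                                   m_function, modulus_stat, one_arm, radius,
                                   range_of, spatial_moment, survival_time)


# ---------------------------------------------------------------------------
# survival time and theta(t)
# ---------------------------------------------------------------------------

def test_survival_time_conventions(k1d, k2d):
    # contact process without infection: survival = origin's recovery time
    cp = ContactSpec(k2d, 0.0)
    sim = cp.sample(50.0, np.random.default_rng(1))
    s, censored = survival_time(sim)
    assert not censored and s > 0
    # eventless voter record: censored at the horizon
    _, traj = simulate_voter(k2d, 0.5, seed=2)
    if traj.extinction_time is None:
        s, censored = survival_time(traj)
        assert censored and s == 0.5
    # OP with p = 0: first empty generation is 1
    real = simulate_op(k1d, 0.0, 4, seed=3)
    s, censored = survival_time(real)
    assert (s, censored) == (1.0, False)


def test_theta_zero_is_one_and_exponential_death(k2d):
    cp = ContactSpec(k2d, 0.0)
    est0 = estimate_survival_prob(cp, 0.0, 200, seed=4)
    assert est0.value == 1.0
    est1 = estimate_survival_prob(cp, 1.0, 10_000, seed=4)
    assert abs(est1.value - math.exp(-1)) < 3 * est1.se


def test_voter_condition1_mass_normalization_flatness(k3d):
    # t * theta(t) for the voter model (d = 3, m(t) = t) drifts slowly
    # toward s_D = 1/beta_D; at t in {8, 16, 32} it is flat within a
    # documented 25% convergence band plus Monte-Carlo error.
    spec = VoterSpec(k3d)
    ests = {t: estimate_survival_prob(spec, t, 6000, seed=41)
            for t in (8.0, 16.0, 32.0)}
    prods = {t: t * e.value for t, e in ests.items()}
    ses = {t: t * e.se for t, e in ests.items()}
    for a in prods:
        for b in prods:
            band = 3 * math.hypot(ses[a], ses[b]) + 0.25 * max(prods.values())
            assert abs(prods[a] - prods[b]) <= band


# ---------------------------------------------------------------------------
# range, radius, Hausdorff
# ---------------------------------------------------------------------------

def test_radius_examples():
    assert radius(RangeSet(np.array([[0.0, 0.0]]))) == 0.0
    assert radius(RangeSet(np.array([[3.0, 4.0]]))) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        radius(RangeSet(np.zeros((0, 2))))


def test_range_of_two_arrow_fixture():
    from critrange.experiments import make_fixture
    from critrange.graphical import replay_voter

    traj = replay_voter(make_fixture("voter_two_arrow"))
    R = range_of(traj)
    assert radius(R) == pytest.approx(0.0)  # only the origin was ever of type 1


def test_hausdorff_conventions_and_example():
    assert hausdorff([], []) == 0.0
    assert hausdorff([], [(0.0,)]) == 1.0
    assert hausdorff([(0.0,)], []) == 1.0
    assert hausdorff([(0.0,), (1.0,)], [(0.0,), (1.0,)]) == 0.0
    # d = 1, K = {0}, K' = {0.3}: each directed deviation 0.3, sum 0.6 < 1
    assert hausdorff([(0.0,)], [(0.3,)]) == pytest.approx(0.6)
    # capping
    assert hausdorff([(0.0,)], [(5.0,)]) == 1.0


_coord = st.floats(-3, 3).map(lambda x: round(x, 6))
_point_set = st.lists(st.tuples(_coord, _coord), min_size=1, max_size=6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_point_set, _point_set, _point_set)
def test_hausdorff_metric_axioms(A, B, C):
    dAB, dBA = hausdorff(A, B), hausdorff(B, A)
    assert dAB == pytest.approx(dBA)          # symmetry
    assert dAB >= 0
    if dAB == 0:
        # identity of indiscernibles up to set equality
        assert {tuple(a) for a in A} == {tuple(b) for b in B}
    # triangle inequality survives the cap at 1
    assert hausdorff(A, C) <= hausdorff(A, B) + hausdorff(B, C) + 1e-9


# ---------------------------------------------------------------------------
# one-arm
# ---------------------------------------------------------------------------

def test_one_arm_zero_radius_pure_death(k2d):
    cp = ContactSpec(k2d, 0.0)
    est = one_arm(cp, 0.5, 500, seed=7)
    assert est.value == 0.0  # a lone recovering site never leaves the ball


def test_one_arm_monotone_in_radius_by_coupling(k2d):
    spec = VoterSpec(k2d)
    ests = one_arm(spec, [2.0, 4.0, 6.0], 2000, seed=9)
    vals = [ests[r].value for r in (2.0, 4.0, 6.0)]
    assert vals[0] >= vals[1] >= vals[2]
    for e in ests.values():
        assert isinstance(e, MonteCarloEstimate)
        assert e.lo <= e.value <= e.hi


# ---------------------------------------------------------------------------
# m(t) and integrated mass
# ---------------------------------------------------------------------------

def test_m_function_branches():
    assert m_function("vm", 0.5, d=3) == 1.0
    assert m_function("vm", math.e, d=2) == pytest.approx(math.e)
    assert m_function("vm", 100.0, d=2) == pytest.approx(100.0 / math.log(100.0))
    assert m_function("op", 7.0, A=1.0, V=1.0) == 7.0
    assert m_function("op", 7.0, A=2.0, V=3.0) == pytest.approx(84.0)
    with pytest.raises(ValueError):
        m_function("vm", 1.0)  # missing dimension


def test_empirical_measure_mass_and_integration():
    from critrange.observables import EmpiricalMeasure

    two_jump = OccupiedTrajectory(
        d=1, events=[(1.0, (1,), True), (3.0, (1,), False)], t_max=8.0)
    mu = EmpiricalMeasure.from_trajectory(two_jump, t=0.5, n=4.0,
                                          m_of_n=lambda n: n)
    # T_2 = {0, 1}, atoms at x/2, weight 1/4
    assert mu.total_mass == pytest.approx(2 / 4)
    assert mu.integrate(lambda x: 1.0) == pytest.approx(mu.total_mass)
    assert mu.integrate(lambda x: x[0]) == pytest.approx(0.5 / 4)
    empty = EmpiricalMeasure.from_trajectory(two_jump, t=2.0, n=4.0,
                                             m_of_n=4.0)
    # beyond the horizon nothing was removed except site 1; origin remains
    assert empty.total_mass == pytest.approx(1 / 4)


def test_integrated_mass_fixtures():
    dead = OccupiedTrajectory(d=1, events=[(0.5, (0,), False)], t_max=4.0,
                              extinction_time=0.5)
    assert integrated_mass(dead, 1.0, 2.0, 1.0, lambda n: 1.0) == 0.0
    immortal = OccupiedTrajectory(d=1, events=[], t_max=10.0)
    assert integrated_mass(immortal, 0.5, 2.5, 2.0, lambda n: 4.0) == \
        pytest.approx((2.5 - 0.5) / 4.0)
    # hand value: |T| = 1 on [0, 1), 2 on [1, 3), 1 on [3, 4]
    two_jump = OccupiedTrajectory(
        d=1, events=[(1.0, (1,), True), (3.0, (1,), False)], t_max=4.0)
    val = integrated_mass(two_jump, 0.0, 4.0, 1.0, lambda n: 1.0)
    assert val == pytest.approx(1 * 1 + 2 * 2 + 1 * 1)


# ---------------------------------------------------------------------------
# spatial and ancestral moments, local jumps
# ---------------------------------------------------------------------------

def test_spatial_moment_voter_duality(k2d):
    # E sum_{x in T_t} |x|^2 = t * d * sigma2_D exactly, by duality
    est = spatial_moment(VoterSpec(k2d), 4.0, 2.0, 8000, seed=11)
    assert abs(est.value - 4.0 * 2 * 0.75) < 3 * est.se
    zero = spatial_moment(VoterSpec(k2d), 0.0, 2.0, 100, seed=11)
    assert zero.value == 0.0


def test_spatial_moment_single_line_brw(k2d):
    # delta_1 offspring: the occupied set is one walker, so the p-th moment
    # equals the single-walk moment n * d * sigma2_D at p = 2
    spec = BRWSpec(OffspringLaw.delta(1), k2d)
    est = spatial_moment(spec, 10.0, 2.0, 4000, seed=12)
    expect = 10 * 2 * 0.75
    assert abs(est.value - expect) < 3.5 * est.se


def test_ancestral_increment_moment_trivial_and_voter(k2d):
    zero = ancestral_increment_moment(VoterSpec(k2d), 2.0, 0.0, 2.0, 200, seed=13)
    assert zero.value == 0.0
    est = ancestral_increment_moment(VoterSpec(k2d), 4.0, 3.0, 2.0, 6000, seed=13)
    assert abs(est.value - 3.0 * 2 * 0.75) < 3 * est.se


def test_ancestral_increment_bounded_for_op(k2d):
    # Condition-4-type boundedness: estimate / (s v 1)^{p/2} stays bounded
    spec = OPSpec(k2d, 1.0)
    ratios = []
    for s in (1.0, 2.0, 4.0):
        est = ancestral_increment_moment(spec, 6.0, s, 2.0, 400, seed=14)
        ratios.append(est.meta["normalized"])
    assert max(ratios) < 10 * 2 * 0.75  # generous constant, boundedness only


def test_local_jump_probe_finite_range_bound(k2d):
    # OP: within a window of length 2 at most 2 kernel steps occur, so the
    # ancestral displacement never exceeds 2 sqrt(d) L
    spec = OPSpec(k2d, 1.0)
    bound = 2 * math.sqrt(2) * 1
    out = local_jump_probe(spec, [0.0, bound + 0.01], 300, seed=15)
    assert out[bound + 0.01].value == 0.0
    probe0 = out[0.0]
    assert probe0.value >= probe0.meta["alive_fraction"]


def test_local_jump_tail_decays_for_voter(k2d):
    out = local_jump_probe(VoterSpec(k2d), [0.0, 2.0, 4.0, 6.0], 400, seed=16)
    vals = [out[n].value for n in (0.0, 2.0, 4.0, 6.0)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < vals[1]  # genuine decay over the grid


# ---------------------------------------------------------------------------
# modulus statistic
# ---------------------------------------------------------------------------

def test_modulus_stat_zero_window_and_monotone(k2d):
    spec = BRWSpec(OffspringLaw.binary_critical(), k2d)
    rng = np.random.default_rng(17)
    real = spec.sample(6, rng)
    rsys = rescale_system(spec.system(real), 2.0)
    v0, _ = modulus_stat(rsys, 0.0, rng=rng)
    assert v0 == 0.0
    vals = [modulus_stat(rsys, rho, rng=np.random.default_rng(0))[0]
            for rho in (0.2, 0.6, 1.5, 4.0)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))


def test_modulus_stat_matches_exhaustive_genealogy_oracle(k2d):
    # independent oracle: enumerate every ancestrally related particle pair
    # through the parent arrays and apply the same window rule
    spec = BRWSpec(OffspringLaw.binary_critical(), k2d)
    rng = np.random.default_rng(18)
    n = 2.0
    for _ in range(15):
        real = spec.sample(6, rng)
        rsys = rescale_system(spec.system(real), n)
        got, info = modulus_stat(rsys, 0.8, pair_budget=10 ** 9, rng=rng)
        assert info["exhaustive"]
        best = 0.0
        for g2, pos2 in enumerate(real.positions):
            for i2 in range(len(pos2)):
                j = i2
                for g1 in range(g2, -1, -1):
                    gap = max(0.0, (g2 - g1 - 1) / n)
                    if gap < 0.8 and g1 < g2:
                        disp = np.linalg.norm(
                            (pos2[i2] - real.positions[g1][j]) / math.sqrt(n))
                        best = max(best, float(disp))
                    if g1 > 0:
                        j = int(real.parents[g1][j])
        assert got == pytest.approx(best, abs=1e-12)


def test_modulus_config_invariants():
    cfg = ModulusConfig(alpha=0.25, beta=1.0, p=20, kappa=20)
    assert cfg.q == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ModulusConfig(alpha=0.45, beta=1.0, p=20, kappa=20)  # alpha too big
    with pytest.raises(ValueError):
        ModulusConfig(alpha=0.25, beta=1.0, p=6, kappa=20)  # moment too low
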