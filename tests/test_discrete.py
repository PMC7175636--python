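"""Oriented percolation, branching random walk and Galton-Watson laws."""

import math
from itertools import product

import numpy as np
import pytest
from scipy import stats

from critrange.discrete import (BRWSpec, DiscreteCaps, OffspringLaw, OPSpec,
                                brw_ancestral_system, gw_exact_survival,
                                gw_laplace_experiment, gw_survival_experiment,
                                gw_yaglom_experiment, op_ancestral_system,
                                simulate_brw, simulate_op, estimate_p_c)
from critrange.experiments import make_fixture
from critrange.sbm import SBMParams, laplace_integrated_mass


# ---------------------------------------------------------------------------
# offspring laws
# ---------------------------------------------------------------------------

def test_offspring_law_moments_by_enumeration():
    binary = OffspringLaw.binary_critical()
    assert binary.mean == pytest.approx(1.0)
    assert binary.variance == pytest.approx(1.0)
    v2 = OffspringLaw.variance_two()
    assert v2.mean == pytest.approx(1.0)
    assert v2.variance == pytest.approx(2.0)
    with pytest.raises(ValueError):
        OffspringLaw(values=(0, 2), probs=(0.6, 0.6))


# ---------------------------------------------------------------------------
# oriented percolation
# ---------------------------------------------------------------------------

def test_op_zero_bond_probability_dies_immediately(k1d):
    real = simulate_op(k1d, 0.0, 5, seed=1)
    assert real.set_at(0) == frozenset({(0,)})
    for n in range(1, 6):
        assert real.set_at(n) == frozenset()
    assert real.extinction_time == 1.0


def test_op_one_generation_law(k1d):
    # d=1, L=1, p=1: two independent Bernoulli(1/2) bonds, so
    # P(T_1 = empty) = 1/4 and E|T_1| = p = 1.
    reps = 20_000
    rng = np.random.default_rng(12)
    empty = 0
    total = 0
    for _ in range(reps):
        real = simulate_op(k1d, 1.0, 1, rng=rng)
        size = real.size_at(1)
        empty += size == 0
        total += size
    p_empty = empty / reps
    se = math.sqrt(0.25 * 0.75 / reps)
    assert abs(p_empty - 0.25) < 3 * se
    mean = total / reps
    se_mean = math.sqrt(0.5 / reps)  # Var|T_1| = 2 * (1/2)(1/2)
    assert abs(mean - 1.0) < 3 * se_mean


def test_op_conditional_mean_regression_through_origin():
    # E[|T_{n+1}| | T_n] = p |T_n| up to the (rare, for spread-out kernels)
    # event that two parents reach the same child site, which only lowers
    # the set-valued count: regression without intercept recovers p.
    from critrange.kernels import uniform_box_kernel

    K = uniform_box_kernel(2, 3)  # 48 offsets: collisions are negligible
    p = 0.9
    rng = np.random.default_rng(31)
    xs, ys = [], []
    for _ in range(1500):
        real = simulate_op(K, p, 6, rng=rng)
        sizes = [len(g) for g in real.generations]
        for a, b in zip(sizes, sizes[1:]):
            if a:
                xs.append(a)
                ys.append(b)
    xs, ys = np.array(xs, float), np.array(ys, float)
    slope = (xs * ys).sum() / (xs * xs).sum()
    # residual-based slope standard error
    resid = ys - slope * xs
    se = math.sqrt((resid ** 2).sum() / (len(xs) - 1) / (xs * xs).sum())
    assert abs(slope - p) < 3.5 * se


def test_op_fixture_reachability_vs_path_enumeration():
    real = make_fixture("op_three_gen")
    sys = op_ancestral_system(real)

    def brute_paths(n, x, n2, x2):
        if n == n2:
            return 1 if (x == x2 and x in real.generations[n]) else 0
        total = 0
        for child in real.children[n].get(x, ()):
            total += brute_paths(n + 1, child, n2, x2)
        return total

    for n, n2 in product(range(4), range(4)):
        if n > n2:
            continue
        for x in real.generations[n]:
            for x2 in real.generations[n2]:
                assert sys.relates(n, x, n2, x2) == (brute_paths(n, x, n2, x2) > 0)
    # two distinct occupied paths reach (3, +1)
    assert brute_paths(0, (0,), 3, (1,)) == 2


def test_op_equal_time_convention():
    real = make_fixture("op_three_gen")
    sys = op_ancestral_system(real)
    assert sys.relates(1, (1,), 1, (1,))
    assert not sys.relates(1, (1,), 1, (-1,))
    # real-time queries floor to generations
    assert sys.relates(0.4, (0,), 2.9, (0,))


# ---------------------------------------------------------------------------
# branching random walk
# ---------------------------------------------------------------------------

def test_brw_deterministic_single_line_is_random_walk(k2d):
    real = simulate_brw(OffspringLaw.delta(1), k2d, 30, seed=4)
    assert all(len(pos) == 1 for pos in real.positions)
    # generation-n displacement variance per coordinate = n * sigma2_D
    rng = np.random.default_rng(9)
    finals = []
    for _ in range(3000):
        r = simulate_brw(OffspringLaw.delta(1), k2d, 10, rng=rng)
        finals.append(r.positions[10][0])
    finals = np.array(finals, float)
    var = finals[:, 0].var()
    expect = 10 * 0.75
    se = expect * math.sqrt(2.0 / len(finals))  # chi-square fluctuation scale
    assert abs(var - expect) < 3.5 * se


def test_brw_critical_mass_martingale(k2d):
    rng = np.random.default_rng(41)
    masses = np.array([simulate_brw(OffspringLaw.binary_critical(), k2d, 20,
                                    rng=rng).mass_at(20)
                       for _ in range(10_000)], dtype=float)
    se = masses.std(ddof=1) / math.sqrt(len(masses))
    assert abs(masses.mean() - 1.0) < 3 * se


def test_brw_supercritical_hits_caps(k2d):
    real = simulate_brw(OffspringLaw.delta(2), k2d, 40, seed=2,
                        caps=DiscreteCaps(max_particles=1000))
    assert real.censored


def test_brw_ancestor_chain_consistency(k2d):
    real = simulate_brw(OffspringLaw.binary_critical(), k2d, 8, seed=11)
    sys = brw_ancestral_system(real)
    for g, pos in enumerate(real.positions):
        for i in range(len(pos)):
            # every particle descends from the root
            assert sys.relates(0, (0, 0), g, (g, i))


# ---------------------------------------------------------------------------
# Galton-Watson experiments
# ---------------------------------------------------------------------------

def test_gw_survival_delta0_dies():
    est = gw_survival_experiment(OffspringLaw.delta(0), 3, 1000, seed=1)
    assert est.value == 0.0


def test_gw_exact_recursion_values():
    law = OffspringLaw.binary_critical()
    # p_{n+1} = p_n - p_n^2/2 from f(s) = (1 + s^2)/2
    p = 1.0
    for n in (1, 2, 3):
        p = p - p * p / 2
        assert gw_exact_survival(law, n) == pytest.approx(p)


@pytest.mark.parametrize("n", [25, 50, 100, 200])
def test_gw_survival_matches_recursion_oracle(n):
    law = OffspringLaw.binary_critical()
    est = gw_survival_experiment(law, n, 100_000, seed=n)
    exact = n * gw_exact_survival(law, n)
    assert abs(est.value - exact) < 3 * est.se


def test_gw_yaglom_variance_two_law():
    # Yaglom rate 2/gamma = 1 for the variance-2 critical law; a finite-n
    # bias of order 5-10 percent is expected at n = 100.
    est, _ = gw_yaglom_experiment(OffspringLaw.variance_two(), 100, 100_000,
                                  seed=6, min_survivors=3000)
    assert est.meta["survivors"] >= 3000
    assert abs(est.value - 1.0) < 0.12


def test_gw_yaglom_conditional_law_is_exponential():
    est, cond = gw_yaglom_experiment(OffspringLaw.binary_critical(), 100,
                                     250_000, seed=9, min_survivors=4000)
    # Z_n is even for the binary law, so Z_n/n sits on a lattice of spacing
    # 2/n with the atom at k*h carrying the continuous mass of the cell
    # below it; a uniform jitter over that cell is the standard continuity
    # correction before comparing with the (continuous) exponential limit
    jitter = np.random.default_rng(97).uniform(-2 / 100, 0, size=len(cond))
    stat = stats.kstest(cond + jitter, "expon",
                        args=(0, 1.0 / est.value)).statistic
    # 1% critical value of the Kolmogorov-Smirnov statistic
    assert stat < 1.628 / math.sqrt(len(cond))


def test_gw_laplace_identity_and_monotonicity():
    law = OffspringLaw.binary_critical()
    z = gw_laplace_experiment(law, 0.0, 50, 20_000, seed=3)
    assert z.value == pytest.approx(1.0)
    vals = [gw_laplace_experiment(law, lam, 50, 20_000, seed=3).value
            for lam in (0.25, 0.5, 1.0, 2.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_gw_laplace_against_closed_form():
    law = OffspringLaw.binary_critical()
    params = SBMParams(gamma=law.gamma, sigma0_sq=1.0)
    est = gw_laplace_experiment(law, 1.0, 100, 150_000, seed=13)
    closed = laplace_integrated_mass(params, 1.0)
    assert abs(est.value - closed) < 3 * est.se + 0.1 * closed


def test_p_c_bracket_sanity(k2d):
    est = estimate_p_c(k2d, bracket=(0.5, 2.0), n_probe=12, reps=250, seed=4,
                       iters=4)
    lo, hi = est["bracket"]
    assert 0.5 <= lo < hi <= 2.0
    assert est["approximate"]
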