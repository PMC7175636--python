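"""Super-Brownian-motion side: closed forms, blow-up ODE, escape probability."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from critrange.kernels import uniform_box_kernel
from critrange.sbm import (LimitConstants, SBMParams, abs_normal_moment,
                           canonical_survival, escape_probability,
                           laplace_integrated_mass, predicted_one_arm_constant,
                           predicted_spatial_moment, sbm_one_arm_tail,
                           small_mass_asymptotics, solve_vd0, v_lambda,
                           yaglom_density, yaglom_mean, constants_report)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_canonical_survival_values():
    assert canonical_survival(SBMParams(1.0, 1.0), 1.0) == pytest.approx(2.0)
    assert canonical_survival(SBMParams(2.0, 1.0), 1.0) == pytest.approx(1.0)
    ss = [canonical_survival(SBMParams(1.0, 1.0), s) for s in (1, 10, 100)]
    assert ss[0] > ss[1] > ss[2] > 0
    with pytest.raises(ValueError):
        canonical_survival(SBMParams(1.0, 1.0), 0.0)


def test_one_arm_tail_scaling_and_value():
    params = SBMParams(1.0, 1.0)
    tail1, exit1 = sbm_one_arm_tail(params, 12.5, 1.0)
    assert tail1 == pytest.approx(12.5)
    tail2, _ = sbm_one_arm_tail(params, 12.5, 2.0)
    assert tail2 == pytest.approx(tail1 / 4.0)
    tail_big, exit_big = sbm_one_arm_tail(params, 12.5, 1e4)
    assert exit_big == pytest.approx(tail_big, rel=1e-4)  # 1-e^-x ~ x


def test_yaglom_density_normalization_and_mean():
    for gamma in (0.5, 1.0, 2.0):
        params = SBMParams(gamma, 1.0)
        total, _ = quad(lambda x: yaglom_density(params, x), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-9)
        mean, _ = quad(lambda x: x * yaglom_density(params, x), 0, np.inf)
        assert mean == pytest.approx(yaglom_mean(params), abs=1e-9)
    assert yaglom_density(SBMParams(1.0, 1.0), 0.0) == pytest.approx(2.0)


def test_v_lambda_riccati_residual_and_laplace_limits():
    params = SBMParams(1.3, 1.0)
    lam = 0.7
    h = 1e-5
    for t in (0.2, 0.5, 1.0, 2.0):
        dv = (v_lambda(params, lam, t + h) - v_lambda(params, lam, t - h)) / (2 * h)
        v = v_lambda(params, lam, t)
        assert dv == pytest.approx(-params.gamma * v * v / 2.0 + lam, abs=1e-6)
    assert v_lambda(params, 0.0, 1.0) == 0.0
    # lambda -> 0: Laplace transform -> 1
    assert laplace_integrated_mass(params, 1e-12) == pytest.approx(1.0, abs=1e-5)
    # large lambda: value ~ sqrt(2/(gamma lambda))
    lam_big = 1e6
    val = laplace_integrated_mass(params, lam_big)
    assert val * math.sqrt(params.gamma * lam_big / 2.0) == pytest.approx(1.0, rel=1e-2)


def test_small_mass_asymptotics_ratio():
    # ratio = 2e sqrt(2/gamma) / (4 / sqrt(2 pi gamma)) = e sqrt(pi),
    # independent of a and gamma
    for gamma, a in ((1.0, 0.01), (2.0, 0.5), (0.3, 1e-6)):
        asym, bound = small_mass_asymptotics(SBMParams(gamma, 1.0), a)
        assert asym <= bound
        assert bound / asym == pytest.approx(math.e * math.sqrt(math.pi))
    tiny = small_mass_asymptotics(SBMParams(1.0, 1.0), 1e-12)
    assert tiny[0] < 1e-5 and tiny[1] < 1e-5


def test_abs_normal_moments():
    assert abs_normal_moment(3, 2.0) == pytest.approx(3.0)
    assert abs_normal_moment(2, 0.0) == pytest.approx(1.0)
    # d = 1: E|Z| = sqrt(2/pi)
    assert abs_normal_moment(1, 1.0) == pytest.approx(math.sqrt(2 / math.pi))


# ---------------------------------------------------------------------------
# v_d(0)
# ---------------------------------------------------------------------------

def test_vd0_scaling_invariance_and_error_bound():
    base = solve_vd0(3, tol=1e-6)
    for a in (0.5, 2.0):
        other = solve_vd0(3, tol=1e-6, a=a)
        assert other.vd0 == pytest.approx(base.vd0, abs=2e-6)
    assert base.vd0_err < 1e-6
    # honesty of the bound: a much tighter threshold moves the value by
    # less than the reported bound
    assert abs(base.vd0 - solve_vd0(3, tol=1e-7).vd0) <= base.vd0_err + 1e-7


def _fd_residual(d, r, v):
    """Fourth-order central-difference residual of v'' + (d-1)/r v' - v^2,
    scaled by 1 + v^2 (the blow-up growth)."""
    h = r[1] - r[0]
    vpp = (-v[4:] + 16 * v[3:-1] - 30 * v[2:-2] + 16 * v[1:-3] - v[:-4]) / (12 * h ** 2)
    vp = (-v[4:] + 8 * v[3:-1] - 8 * v[1:-3] + v[:-4]) / (12 * h)
    mid = slice(2, -2)
    resid = vpp + (d - 1) / r[mid] * vp - v[mid] ** 2
    return np.abs(resid) / (1.0 + v[mid] ** 2)


@pytest.mark.parametrize("d", [1, 2, 3, 4])
def test_vd0_residual_on_returned_grid(d):
    sol = solve_vd0(d, tol=1e-6)
    assert _fd_residual(d, sol.r_grid, sol.v_grid).max() < 1e-5


def test_vd0_d1_first_integral_oracle():
    # d = 1: v'' = v^2 integrates to v'^2 = (2/3)(v^3 - 1) from v(0) = 1,
    # v'(0) = 0, so the blow-up radius is an explicit quadrature:
    # R = int_1^inf dv / sqrt((2/3)(v^3 - 1)), and v_1(0) = R^2.
    def integrand_near(u):
        w = 1.0 + u * u
        return 2.0 * math.sqrt(1.5) / math.sqrt(w * w + w + 1.0)

    part1, _ = quad(integrand_near, 0.0, 1.0, epsabs=1e-13, epsrel=1e-13)
    part2, _ = quad(lambda w: math.sqrt(1.5 / (w ** 3 - 1.0)), 2.0, np.inf,
                    epsabs=1e-13, epsrel=1e-13)
    R = part1 + part2
    sol = solve_vd0(1, tol=1e-6)
    assert sol.vd0 == pytest.approx(R * R, abs=2e-6)


def test_vd0_monotone_in_dimension():
    vals = [solve_vd0(d).vd0 for d in (1, 2, 3, 4)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# escape probability
# ---------------------------------------------------------------------------

def test_escape_d2_exact_convention():
    K = uniform_box_kernel(2, 1)
    out = escape_probability(K)
    assert out["value"] == pytest.approx(2 * math.pi * 0.75)
    with pytest.raises(ValueError):
        escape_probability(uniform_box_kernel(1, 1))


def test_escape_fourier_vs_monte_carlo(k3d):
    four = escape_probability(k3d, "fourier")
    mc = escape_probability(k3d, "monte_carlo", seed=5, n_walks=30_000,
                            n_steps=1500)
    band = 3 * mc["se"] + mc["tail_bound"] + four["resolution_delta"]
    assert abs(four["value"] - mc["value"]) < band
    assert 0 < four["value"] < 1


def test_escape_increases_with_spread(k3d):
    b1 = escape_probability(k3d, "fourier")["value"]
    b2 = escape_probability(uniform_box_kernel(3, 2), "fourier")["value"]
    assert b1 < b2 < 1.0


# ---------------------------------------------------------------------------
# assembled predictions
# ---------------------------------------------------------------------------

def test_voter_one_arm_constant_consistency(k3d):
    consts = LimitConstants.for_voter(k3d)
    val = predicted_one_arm_constant("vm", k3d, consts)
    # model-specific formula equals the general sigma0^2 s_D v_d(0)/2 form
    assert val == pytest.approx(
        consts.sigma0_sq * consts.s_D * consts.v_d0 / 2.0)
    assert val == pytest.approx(
        k3d.sigma2_D * consts.v_d0 / (2 * consts.beta_D))


def test_voter_d2_one_arm_constant_kernel_free():
    K = uniform_box_kernel(2, 1)
    K2 = uniform_box_kernel(2, 3)
    c1 = predicted_one_arm_constant("vm", K, LimitConstants.for_voter(K))
    c2 = predicted_one_arm_constant("vm", K2, LimitConstants.for_voter(K2))
    assert c1 == pytest.approx(c2)  # v_2(0)/(2 pi), independent of the kernel
    assert c1 == pytest.approx(solve_vd0(2).vd0 / (2 * math.pi), abs=1e-6)


def test_spread_out_one_arm_constant(k3d):
    consts = LimitConstants.for_spread_out(k3d, A=1.1, V=1.2, v=1.05)
    val = predicted_one_arm_constant("op", k3d, consts)
    assert val == pytest.approx(
        k3d.sigma2_D * 1.05 * consts.v_d0 / (1.1 * 1.2))
    with pytest.raises(ValueError):
        predicted_one_arm_constant("percolation", k3d, consts)


def test_predicted_spatial_moments(k3d):
    consts = LimitConstants.for_voter(k3d)
    # p = 2: s_D gamma sigma0^2 d / 2 = sigma2_D d for the voter model
    assert predicted_spatial_moment("vm", consts, 2.0) == pytest.approx(
        k3d.sigma2_D * 3)
    assert predicted_spatial_moment("vm", consts, 0.0) == pytest.approx(
        consts.s_D * consts.gamma / 2.0)
    sp = LimitConstants.for_spread_out(k3d, A=1.3, V=1.0, v=1.0)
    assert predicted_spatial_moment("op", sp, 2.0) == pytest.approx(
        1.3 * k3d.sigma2_D * 3)


def test_limit_constants_validation_and_report(k3d):
    with pytest.raises(ValueError):
        LimitConstants(d=3, gamma=1.0, sigma0_sq=1.0, s_D=-1.0)
    with pytest.raises(ValueError):
        LimitConstants(d=3, gamma=1.0, sigma0_sq=1.0, s_D=1.0, beta_D=1.5)
    consts = LimitConstants.for_voter(k3d)
    report = constants_report(k3d, consts)
    assert '"kernel_hash"' in report and '"v_d0"' in report
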