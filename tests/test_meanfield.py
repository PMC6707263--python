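import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from nmsis import (AgeGrid, Exponential, Weibull, erdos_renyi, eta_renewal,
                   integrate_mean_field, transient_time, uniform_initial)
from nmsis.meanfield import (InitialCondition, _bin_hazard, _phi_type1_brute,
                             activation_kernel_type1, activation_kernel_type2)
from nmsis.networks import Network


def test_eta_constant_for_poisson_process():
    """Constant-hazard renewal intensity is the rate, exactly on the grid."""
    grid = AgeGrid(0.01, 500)
    eta = eta_renewal(Weibull(1.0, 0.5), grid)
    np.testing.assert_allclose(eta, 2.0, atol=1e-6)
    eta = eta_renewal(Exponential(2.0), grid)
    np.testing.assert_allclose(eta, 2.0, atol=1e-12)


def test_eta_starts_at_density_and_reaches_renewal_limit():
    grid = AgeGrid(0.01, 800)
    dist = Weibull(2.0, 1.0)
    eta = eta_renewal(dist, grid)
    assert eta[0] == pytest.approx(float(dist.pdf(np.array(0.0))), abs=1e-12)
    # renewal theorem: eta -> 1/mean
    assert eta[-1] == pytest.approx(1.0 / dist.mean(), abs=0.01)


def test_eta_matches_monte_carlo_renewal_counting():
    """Histogram of renewal events from 5e4 sampled sequences."""
    grid = AgeGrid(0.02, 300)
    dist = Weibull(2.0, 1.0)
    eta = eta_renewal(dist, grid)
    rng = np.random.default_rng(8)
    n = 50_000
    counts = np.zeros(grid.n_bins)
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    while alive.any():
        t[alive] += dist.sample(rng, alive.sum())
        idx = np.where(alive)[0]
        inside = t[idx] < grid.tau_max
        np.add.at(counts, (t[idx[inside]] / grid.delta).astype(int), 1)
        alive = np.zeros(n, dtype=bool)
        alive[idx[inside]] = True
    mc = counts / (n * grid.delta)
    se = np.sqrt(np.maximum(counts, 1.0)) / (n * grid.delta)
    frac = np.mean(np.abs(mc - eta) < 3 * se)
    assert frac > 0.95


def test_kernels_zero_field_and_constant_hazard_agreement():
    grid = AgeGrid(0.05, 60)
    omega = _bin_hazard(Exponential(0.7), grid)
    eta = eta_renewal(Exponential(0.7), grid)
    zero = np.zeros(grid.n_bins)
    assert np.all(activation_kernel_type1(omega, zero, grid.delta) == 0.0)
    assert activation_kernel_type2(eta, zero, grid.delta) == 0.0

    rng = np.random.default_rng(1)
    field = rng.random(grid.n_bins)
    mass = field.sum() * grid.delta
    phi1 = activation_kernel_type1(omega, field, grid.delta)
    phi2 = activation_kernel_type2(eta, field, grid.delta)
    np.testing.assert_allclose(phi1, 0.7 * mass, rtol=1e-10)
    assert phi2 == pytest.approx(0.7 * mass, rel=1e-10)


def test_type1_kernel_matches_double_loop_oracle():
    grid = AgeGrid(0.1, 30)
    omega = _bin_hazard(Weibull(2.0, 1.0), grid)
    field = np.zeros(grid.n_bins)
    field[:3] = [0.2, 0.1, 0.0]
    fast = activation_kernel_type1(omega, field, grid.delta)
    brute = _phi_type1_brute(omega, field, grid.delta)
    np.testing.assert_allclose(fast, brute, atol=1e-14)


def test_no_spontaneous_infection():
    net = erdos_renyi(50, 5.0, seed=0)
    grid = AgeGrid(0.05, 80)
    init = uniform_initial(net.n, 0.0, grid)
    res = integrate_mean_field(net, "type2", Weibull(2, 1), Weibull(2, 0.5),
                               init, grid, 5.0)
    assert np.all(res.infected == 0.0)


def test_probability_conservation_long_run():
    edges = np.array([(i, (i + 1) % 10) for i in range(10)])
    net = Network(10, edges)
    grid = AgeGrid(0.01, 250)
    init = uniform_initial(10, 0.3, grid)
    res = integrate_mean_field(net, "type1", Weibull(0.5, 1.0),
                               Weibull(2.0, 0.5), init, grid, 10.0)
    I, S = res.final_fields
    total = (I.sum(axis=1) + S.sum(axis=1)) * grid.delta
    assert np.abs(total - 1.0).max() < 1e-9


def _qmf_ode_solution(net, b, d, rho0, t_eval):
    adj = net.adjacency()

    def rhs(_, y):
        return -d * y + b * (1 - y) * (adj @ y)

    sol = solve_ivp(rhs, (0, t_eval[-1]), np.full(net.n, rho0),
                    t_eval=t_eval, rtol=1e-10, atol=1e-12)
    return sol.y.T


@pytest.mark.parametrize("mechanism", ["type1", "type2"])
def test_markovian_limit_matches_qmf_ode(mechanism):
    """With constant hazards the PDE collapses to the quenched MF ODE."""
    net = erdos_renyi(80, 6.0, seed=2)
    b, d = 0.3, 1.0
    grid = AgeGrid.for_recovery(Exponential(d), 0.01)
    init = uniform_initial(net.n, 0.05, grid)
    res = integrate_mean_field(net, mechanism, Exponential(b), Exponential(d),
                               init, grid, 5.0)
    ode = _qmf_ode_solution(net, b, d, 0.05, res.times)
    assert np.abs(res.infected_nodes - ode).max() < 0.01


def test_grid_refinement_first_order_convergence():
    net = erdos_renyi(60, 6.0, seed=4)
    b, d = 0.3, 1.0
    errs = []
    for delta in (0.04, 0.02):
        grid = AgeGrid.for_recovery(Exponential(d), delta)
        init = uniform_initial(net.n, 0.05, grid)
        res = integrate_mean_field(net, "type2", Exponential(b),
                                   Exponential(d), init, grid, 4.0,
                                   sample_times=np.array([0.0, 2.0, 4.0]))
        ode = _qmf_ode_solution(net, b, d, 0.05, res.times)
        errs.append(np.abs(res.infected_nodes - ode).max())
    assert errs[0] / errs[1] > 1.5  # empirical order >= 1


def test_steady_state_field_satisfies_stationary_equations(er200):
    """Late-time surfaces obey d/dtau ln I = -omega_rec and I(0) = S(0)."""
    rec = Weibull(2.0, 0.5)
    grid = AgeGrid.for_recovery(rec, 0.02)
    init = uniform_initial(er200.n, 0.1, grid)
    res = integrate_mean_field(er200, "type2", Weibull(1.0, 1.0), rec, init,
                               grid, 40.0)
    I, S = res.final_fields
    omega_bar = _bin_hazard(rec, grid)
    node = int(np.argmax(I.sum(axis=1)))
    prof = I[node]
    thr = prof.max() * 1e-6
    valid = (prof[:-1] > thr) & (prof[1:] > thr)
    valid[-1] = False  # the terminal bin pools overflow mass
    log_slope = np.diff(np.log(np.where(prof > 0, prof, 1.0)))[valid] / grid.delta
    target = -omega_bar[:-1][valid]
    np.testing.assert_allclose(log_slope, target, rtol=1e-6)
    assert I[node, 0] == pytest.approx(S[node, 0], rel=0.01)


def test_initial_condition_validation():
    grid = AgeGrid(0.1, 20)
    bad = InitialCondition(rho=np.full((3, 20), 0.1), chi=np.zeros((3, 20)))
    with pytest.raises(ValueError):
        bad.validate(grid)


def test_transient_time_closed_forms():
    t = np.linspace(0, 40, 2001)
    assert transient_time(t, np.full(t.size, 0.4), 1e-3, 5.0) == 0.0
    decay = np.exp(-t)
    est = transient_time(t, decay, 1e-3, 20.0)
    assert est == pytest.approx(math.log(1e3), abs=0.5)
    with pytest.raises(ValueError):
        transient_time(t[:100], decay[:100], 1e-3, 30.0)
    # a pure linear drift never stabilizes
    assert transient_time(t, 0.01 * t, 1e-3, 5.0) == math.inf


def test_transient_lengthens_with_infection_shape(er200):
    """Narrower infection-time laws (larger shape) prolong the transient."""
    rec = Weibull(2.0, 0.5)
    grid = AgeGrid.for_recovery(rec, 0.02)
    ts = []
    for a_I in (0.5, 1.0, 2.0):
        init = uniform_initial(er200.n, 0.01, grid)
        res = integrate_mean_field(er200, "type2", Weibull(a_I, 1.0), rec,
                                   init, grid, 40.0,
                                   sample_times=np.linspace(0, 40, 401))
        ts.append(transient_time(res.times, res.infected, 1e-3, 8.0))
    assert ts[0] < ts[1] < ts[2]
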