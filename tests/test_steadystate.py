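import math

import numpy as np
import pytest
from scipy.interpolate import interp1d
from scipy.optimize import fsolve

from nmsis import (AgeGrid, BetaSigma1, Exponential, Weibull,
                   beta_from_lambda_eff, delta_eff, effective_rates,
                   lambda_eff_type2, markovian_reference, omega_and_theta,
                   solve_qmf_fixed_point, solve_type1_fixed_point)
from nmsis.steadystate import EffectiveRates, _series_reversion


def test_delta_eff_values():
    assert delta_eff(Exponential(0.7)) == pytest.approx(0.7, rel=1e-12)
    assert delta_eff(Weibull(2.0, 0.5)) == pytest.approx(
        1.0 / (0.5 * math.gamma(1.5)), rel=1e-12)
    assert delta_eff(Weibull(2.0, 0.5)) == pytest.approx(2.25676, abs=1e-5)
    # near-deterministic recovery of duration T: rate -> 1/T
    assert delta_eff(Weibull(200.0, 3.0)) == pytest.approx(1 / 3.0, rel=0.01)


def test_lambda_eff_markovian_ratio():
    assert lambda_eff_type2(Exponential(0.4), Exponential(2.0)) == pytest.approx(
        0.2, abs=1e-6)


def test_lambda_eff_unit_exponential_infection_is_mean_recovery():
    """With eta = 1 the effective rate equals the mean infectious period."""
    val = lambda_eff_type2(Weibull(1.0, 1.0), Weibull(2.0, 0.5))
    assert val == pytest.approx(0.443113, abs=1e-5)


def test_lambda_eff_matches_renewal_counting_monte_carlo():
    inf, rec = Weibull(2.0, 1.0), Weibull(2.0, 0.5)
    val = lambda_eff_type2(inf, rec)
    rng = np.random.default_rng(7)
    n = 100_000
    T = rec.sample(rng, n)
    count = np.zeros(n)
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    while alive.any():
        t[alive] += inf.sample(rng, alive.sum())
        fired = alive & (t < T)
        count[fired] += 1
        alive = fired
    se = count.std(ddof=1) / math.sqrt(n)
    assert abs(val - count.mean()) < 3 * se


def test_lambda_eff_truncation_guard():
    with pytest.raises(ValueError):
        lambda_eff_type2(Weibull(2.0, 1.0), Weibull(2.0, 0.5),
                         grid=AgeGrid(0.01, 50))


def test_omega_theta_constant_hazard_structure():
    """Markovian infection: Omega linear, single theta term, Eq-style
    equality lambda_eff = lambda_eff*."""
    b = 0.7
    rec = Weibull(2.0, 0.5)
    taus, omega, theta, lam_star = omega_and_theta(Exponential(b), rec)
    d_eff = delta_eff(rec)
    np.testing.assert_allclose(omega, b * taus, rtol=1e-8, atol=1e-12)
    assert theta[0] == pytest.approx(1.0 / b, rel=1e-12)
    np.testing.assert_allclose(theta[1:], 0.0, atol=1e-10)
    assert lam_star == pytest.approx(b / d_eff, rel=1e-12)
    assert lambda_eff_type2(Exponential(b), rec) == pytest.approx(lam_star,
                                                                  rel=1e-6)


@pytest.mark.parametrize("inf", [Exponential(0.8), BetaSigma1(1.3),
                                 Weibull(1.0, 2.0)], ids=str)
def test_lambda_star_is_initial_hazard_over_delta_eff(inf):
    rec = Weibull(2.0, 0.5)
    *_, lam_star = omega_and_theta(inf, rec)
    haz0 = float(inf.hazard(np.array(0.0)))
    assert lam_star == pytest.approx(haz0 / delta_eff(rec), rel=1e-6)


def test_lambda_star_beta_closed_form():
    *_, lam_star = omega_and_theta(BetaSigma1(1.5), Weibull(2.0, 0.5))
    assert lam_star == pytest.approx(1.5 * 0.443113462726379, rel=1e-9)


def test_omega_theta_rejects_degenerate_slope():
    # Weibull shape 2 has zero hazard at age 0: the inverse series is singular
    with pytest.raises(ValueError):
        omega_and_theta(Weibull(2.0, 1.0), Weibull(2.0, 0.5))


def test_theta_derivatives_match_numerical_inversion():
    """FD derivatives of the numerically inverted Omega as oracle."""
    taus, omega, theta, _ = omega_and_theta(BetaSigma1(1.5), Weibull(2.0, 0.5))
    inv = interp1d(omega, taus, kind="cubic")
    h = 2e-3
    fd1 = (-3 * inv(0) + 4 * inv(h) - inv(2 * h)) / (2 * h)
    fd2 = (inv(0) - 2 * inv(h) + inv(2 * h)) / h ** 2
    assert theta[0] == pytest.approx(float(fd1), rel=1e-3)
    assert theta[1] == pytest.approx(float(fd2), rel=5e-3)


def test_omega_theta_scaling_law():
    """gamma -> theta*gamma scales Omega by theta and theta^(n)(0) by theta^-n."""
    _, om1, th1, ls1 = omega_and_theta(BetaSigma1(1.5), Weibull(2.0, 0.5))
    _, om2, th2, ls2 = omega_and_theta(BetaSigma1(3.0), Weibull(2.0, 0.5))
    np.testing.assert_allclose(om2, 2.0 * om1, rtol=1e-10)
    n = np.arange(1, th1.size + 1)
    np.testing.assert_allclose(th2, th1 / 2.0 ** n, rtol=1e-9)
    assert ls2 == pytest.approx(2 * ls1, rel=1e-12)


def test_series_reversion_linear_case():
    a = np.array([0.0, 0.7, 0.0, 0.0])
    b = _series_reversion(a)
    np.testing.assert_allclose(b, [0.0, 1 / 0.7, 0.0, 0.0], atol=1e-14)


def test_qmf_regular_graph_closed_form(ring_regular_200):
    res = solve_qmf_fixed_point(ring_regular_200, 0.2)
    np.testing.assert_allclose(res.infected_prob, 0.5, atol=1e-10)
    assert res.converged
    assert res.network_density == pytest.approx(0.5, abs=1e-10)


def test_qmf_star_matches_root_finder(star5):
    res = solve_qmf_fixed_point(star5, 0.6)

    def system(v):
        hub, leaf = v
        return [hub - 0.6 * (1 - hub) * 5 * leaf,
                leaf - 0.6 * (1 - leaf) * hub]

    hub, leaf = fsolve(system, [0.5, 0.5], xtol=1e-14)
    assert res.infected_prob[0] == pytest.approx(hub, abs=1e-10)
    np.testing.assert_allclose(res.infected_prob[1:], leaf, atol=1e-10)


def test_qmf_subcritical_is_zero(ring_regular_200):
    res = solve_qmf_fixed_point(ring_regular_200, 0.05)  # threshold is 0.1
    assert np.all(res.infected_prob == 0.0)
    with pytest.raises(ValueError):
        solve_qmf_fixed_point(ring_regular_200, -0.1)


def test_type1_constant_hazard_reduces_to_qmf(ring_regular_200):
    rates = effective_rates(Exponential(0.7), Weibull(2.0, 0.5))
    r1 = solve_type1_fixed_point(ring_regular_200, rates)
    r2 = solve_qmf_fixed_point(ring_regular_200, rates.lambda_eff_star)
    np.testing.assert_allclose(r1.infected_prob, r2.infected_prob, atol=1e-10)


def test_type1_series_truncation_converged(ring_regular_200):
    """The inverse-mass expansion is asymptotic: raising n_max beyond the
    optimal truncation point changes nothing, and the optimally truncated
    sum agrees with its exact Laplace-integral resummation."""
    rates = effective_rates(BetaSigma1(2.0), Weibull(2.0, 0.5), n_max=20)
    r10 = solve_type1_fixed_point(ring_regular_200, rates, n_max=10)
    r20 = solve_type1_fixed_point(ring_regular_200, rates, n_max=20)
    assert r10.flagged_nodes.size == 0
    assert abs(r10.network_density - r20.network_density) < 1e-6
    exact = solve_type1_fixed_point(ring_regular_200, rates, method="integral")
    assert abs(r20.network_density - exact.network_density) < 1e-4


def test_type1_series_breaks_at_low_density(ring_regular_200):
    """At small neighborhood infected mass every node's expansion fails."""
    rates = effective_rates(BetaSigma1(0.6), Weibull(2.0, 0.5), n_max=16)
    with pytest.raises(RuntimeError, match="series inapplicable"):
        solve_type1_fixed_point(ring_regular_200, rates, n_max=16)


def test_type1_gap_to_markovian_shrinks_with_density(ring_regular_200):
    """Raising gamma raises density and closes the type-I/Markovian gap."""
    rec = Weibull(2.0, 0.5)
    gaps = []
    for gamma in (0.6, 1.0, 1.6, 2.4):
        rates = effective_rates(BetaSigma1(gamma), rec, n_max=16)
        t1 = solve_type1_fixed_point(ring_regular_200, rates, method="integral")
        qmf = solve_qmf_fixed_point(ring_regular_200, rates.lambda_eff_star)
        gaps.append(abs(t1.network_density - qmf.network_density))
    assert all(gaps[i] > gaps[i + 1] for i in range(len(gaps) - 1))


def test_markovian_reference_round_trip():
    rates = EffectiveRates(delta_eff=1.0, lambda_eff=0.5,
                           lambda_eff_star=0.5, theta_derivs=np.array([2.0]))
    inf, rec = markovian_reference(rates)
    assert inf.rate == pytest.approx(0.5) and rec.rate == pytest.approx(1.0)
    assert lambda_eff_type2(inf, rec) == pytest.approx(0.5, abs=1e-8)


def test_beta_inversion_round_trip():
    rec = Weibull(2.0, 0.5)
    for target in (0.1, 0.3):
        beta = beta_from_lambda_eff(2.0, rec, target)
        assert lambda_eff_type2(Weibull(2.0, beta), rec) == pytest.approx(
            target, abs=1e-6)
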