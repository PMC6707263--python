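"""Steady-state theory: effective rates and Markovian-equivalence machinery.

A non-Markovian SIS process is summarized by two numbers wherever an exact
or approximate Markovian reduction exists:

* the effective recovery rate ``delta_eff = 1 / E[recovery time]``;
* the effective infection rate, the expected number of transmission events
  one active edge hosts during one infectious period.  Under type-II
  activation this is exact and equals ``lambda_eff = int eta(tau)
  Psi_rec(tau) dtau`` with ``eta`` the renewal intensity of the infection
  law; under type-I only the first-order coefficient survives,
  ``lambda_eff* = 1 / (delta_eff * theta'(0))`` where ``theta`` inverts the
  integrated cross-hazard ``Omega``.

The stationary per-node infected probabilities then solve the quenched
mean-field fixed point ``I_i = lambda_eff * (1 - I_i) * sum_j a_ij I_j``
(type-II / Markovian), or its series generalization in inverse neighborhood
mass for type-I; the outbreak threshold is ``lambda_eff = 1 / Lambda_max``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import (TimeDistribution, Weibull, BetaSigma1,
                            Exponential, from_spec)
from .meanfield import AgeGrid, eta_renewal
from .networks import Network, leading_eigenvalue

__all__ = ["EffectiveRates", "SteadyStateResult", "delta_eff",
           "lambda_eff_type2", "omega_and_theta", "effective_rates",
           "solve_qmf_fixed_point", "solve_type1_fixed_point",
           "markovian_reference", "beta_from_lambda_eff"]


def delta_eff(rec_dist: TimeDistribution) -> float:
    """Effective recovery rate: reciprocal mean infectious period."""
    return 1.0 / from_spec(rec_dist).mean()


def _default_grid(rec_dist: TimeDistribution, delta: float = 1e-3) -> AgeGrid:
    return AgeGrid.for_recovery(rec_dist, delta, tail=1e-10)


def lambda_eff_type2(inf_dist: TimeDistribution, rec_dist: TimeDistribution,
                     grid: AgeGrid | None = None) -> float:
    """Expected transmissions per infectious period (type-II, exact).

    ``int_0^inf eta(tau) Psi_rec(tau) dtau`` by trapezoid on the grid; for a
    constant infection hazard eta is the rate and the closed form
    ``rate * mean_recovery`` is returned.
    """
    inf_dist = from_spec(inf_dist)
    rec_dist = from_spec(rec_dist)
    if isinstance(inf_dist, Exponential):
        return inf_dist.rate * rec_dist.mean()
    if isinstance(inf_dist, Weibull) and inf_dist.shape == 1.0:
        return rec_dist.mean() / inf_dist.scale
    if grid is None:
        grid = _default_grid(rec_dist)
    if rec_dist.sf(grid.tau_max) > 1e-6:
        raise ValueError("age grid truncates too much recovery survival mass")
    eta = eta_renewal(inf_dist, grid)
    sf = rec_dist.sf(grid.taus)
    return float(np.trapezoid(eta * sf, dx=grid.delta))


# ---------------------------------------------------------------------------
# the Omega / theta series for type-I


def _series_exp(a: np.ndarray) -> np.ndarray:
    """Power-series exp for a series with zero constant term."""
    n = a.size
    out = np.zeros(n)
    out[0] = 1.0
    for k in range(1, n):
        out[k] = sum(j * a[j] * out[k - j] for j in range(1, k + 1)) / k
    return out


def _series_mul(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    return np.convolve(a, b)[:n]


def _series_int(a: np.ndarray) -> np.ndarray:
    """Antiderivative with zero constant term, same length (degree shifts)."""
    out = np.zeros(a.size)
    out[1:] = a[:-1] / np.arange(1, a.size)
    return out


def _hazard_series(dist: TimeDistribution, n: int) -> np.ndarray:
    """Taylor coefficients of the hazard at age 0 (requires analyticity)."""
    if isinstance(dist, Exponential):
        out = np.zeros(n)
        out[0] = dist.rate
        return out
    if isinstance(dist, BetaSigma1):
        # gamma / (1 - x) = gamma * sum x^k
        return np.full(n, dist.gamma)
    if isinstance(dist, Weibull):
        a = dist.shape
        if abs(a - round(a)) > 1e-12:
            raise ValueError("Weibull hazard is analytic at 0 only for "
                             "integer shape; the type-I series needs an "
                             "analytic hazard")
        a = int(round(a))
        out = np.zeros(n)
        if a - 1 < n:
            out[a - 1] = a / dist.scale ** a
        return out
    raise ValueError(f"no hazard series for {type(dist).__name__}")


def _survival_series(dist: TimeDistribution, n: int) -> np.ndarray:
    """Taylor coefficients of the survival function at age 0."""
    if isinstance(dist, Exponential):
        return np.array([(-dist.rate) ** k / math.factorial(k) for k in range(n)])
    if isinstance(dist, BetaSigma1):
        g = dist.gamma
        out = np.empty(n)
        out[0] = 1.0
        for k in range(1, n):
            out[k] = out[k - 1] * (-(g - k + 1)) / k  # binomial (1-x)^g
        return out
    if isinstance(dist, Weibull):
        a = dist.shape
        if abs(a - round(a)) > 1e-12:
            raise ValueError("Weibull survival is analytic at 0 only for "
                             "integer shape")
        a = int(round(a))
        mono = np.zeros(n)
        if a < n:
            mono[a] = -1.0 / dist.scale ** a
        return _series_exp(mono)
    raise ValueError(f"no survival series for {type(dist).__name__}")


def _series_reversion(a: np.ndarray) -> np.ndarray:
    """Coefficients b of the inverse series of sum_{k>=1} a_k x^k (a_0 = 0)."""
    n = a.size
    if abs(a[1]) < 1e-12:
        raise ValueError("series reversion ill-conditioned: vanishing slope")
    b = np.zeros(n)
    b[1] = 1.0 / a[1]
    for m in range(2, n):
        # coefficient of x^m in sum_{j=1}^{m-1} b_j * A(x)^j must cancel
        acc = 0.0
        power = np.zeros(n)
        power[0] = 1.0
        for j in range(1, m):
            power = _series_mul(power, a, n)
            acc += b[j] * power[m]
        b[m] = -acc / a[1] ** m
    return b


@dataclass(frozen=True)
class EffectiveRates:
    """Effective-rate summary of a (infection, recovery) pair."""

    delta_eff: float
    lambda_eff: float | None          # type-II exact rate (None if not computed)
    lambda_eff_star: float            # type-I first-order rate
    theta_derivs: np.ndarray          # theta^(n)(0), n = 1..n_max
    infection: TimeDistribution = None
    recovery: TimeDistribution = None


def omega_and_theta(inf_dist: TimeDistribution, rec_dist: TimeDistribution,
                    n_max: int = 10, grid: AgeGrid | None = None):
    """The integrated cross-hazard Omega, its inverse's derivatives, and
    the first-order effective infection rate for type-I activation.

    ``Omega(tau) = delta_eff * int_0^tau g``, with the inner integral
    ``g(u) = int_0^inf omega_inf(min(u, tau')) Psi_rec(tau') dtau'``
    decomposed as a prefix integral of ``omega_inf * Psi_rec`` plus
    ``omega_inf(u)`` times the survival tail mass.  ``theta = Omega^{-1}``;
    its derivatives at 0 come from power-series reversion of Omega's exact
    Taylor series (hazard and survival expanded analytically per family),
    and ``lambda_eff* = 1/(delta_eff * theta'(0))``.

    Returns ``(taus, Omega_on_grid, theta_derivs, lambda_eff_star)``.
    """
    inf_dist = from_spec(inf_dist)
    rec_dist = from_spec(rec_dist)
    if n_max < 1 or n_max > 24:
        raise ValueError("n_max must lie in 1..24")
    d_eff = delta_eff(rec_dist)

    # --- exact Taylor series of Omega at 0 -----------------------------
    n_coef = n_max + 1
    om = _hazard_series(inf_dist, n_coef)
    sf = _survival_series(rec_dist, n_coef)
    prefix = _series_int(_series_mul(om, sf, n_coef))      # int_0^u om*sf
    tail = np.zeros(n_coef)
    tail[0] = rec_dist.mean()
    tail -= _series_int(sf)                                # int_u^inf sf
    g = prefix + _series_mul(om, tail, n_coef)
    omega_series = d_eff * _series_int(g)                  # Omega coefficients
    if abs(omega_series[1]) < 1e-12:
        raise ValueError("Omega'(0) vanishes; reversion ill-conditioned")
    theta_series = _series_reversion(omega_series)
    theta_derivs = theta_series[1:] * np.array(
        [math.factorial(k) for k in range(1, n_coef)])
    lambda_eff_star = 1.0 / (d_eff * theta_derivs[0])

    if grid is None:
        grid = _default_grid(rec_dist, delta=1e-3)
    taus, omega_grid, _ = _omega_on_grid(inf_dist, rec_dist, grid)
    return taus, omega_grid, theta_derivs, lambda_eff_star


def _omega_on_grid(inf_dist, rec_dist, grid: AgeGrid):
    """Omega(tau) and the inner integral g(tau) by nested trapezoid."""
    d_eff = delta_eff(rec_dist)
    taus = grid.taus
    delta = grid.delta
    sf_grid = rec_dist.sf(taus)
    haz = np.asarray(inf_dist.hazard(taus), dtype=float)
    if np.isfinite(inf_dist.support_upper):
        cap = float(inf_dist.hazard(inf_dist.support_upper - delta))
        haz = np.minimum(haz, cap)
    if not math.isfinite(haz[0]):
        haz[0] = float(inf_dist.bin_average_hazard(np.array([0.0, delta]))[0])
    integrand = haz * sf_grid
    prefix_g = np.concatenate(([0.0], np.cumsum(
        (integrand[1:] + integrand[:-1]) / 2.0 * delta)))
    tail_g = rec_dist.mean() - np.concatenate(([0.0], np.cumsum(
        (sf_grid[1:] + sf_grid[:-1]) / 2.0 * delta)))
    g_grid = prefix_g + haz * tail_g
    omega_grid = d_eff * np.concatenate(([0.0], np.cumsum(
        (g_grid[1:] + g_grid[:-1]) / 2.0 * delta)))
    return taus, omega_grid, d_eff * g_grid


def effective_rates(inf_dist, rec_dist, n_max: int = 10,
                    grid: AgeGrid | None = None,
                    want_series: bool = True) -> EffectiveRates:
    """Bundle delta_eff, lambda_eff (type-II) and the type-I series."""
    inf_dist = from_spec(inf_dist)
    rec_dist = from_spec(rec_dist)
    d_eff = delta_eff(rec_dist)
    lam2 = lambda_eff_type2(inf_dist, rec_dist, grid)
    if want_series:
        _, _, theta, lam_star = omega_and_theta(inf_dist, rec_dist, n_max)
    else:
        haz0 = float(inf_dist.hazard(np.array(0.0)))
        if math.isfinite(haz0) and haz0 > 0:
            theta = np.array([1.0 / haz0])
            lam_star = haz0 / d_eff
        else:
            # zero or divergent initial hazard: the first-order type-I
            # coefficient is degenerate (see omega_and_theta)
            theta = np.array([math.nan])
            lam_star = haz0 / d_eff if math.isfinite(haz0) else math.nan
    return EffectiveRates(delta_eff=d_eff, lambda_eff=lam2,
                          lambda_eff_star=lam_star, theta_derivs=theta,
                          infection=inf_dist, recovery=rec_dist)


# ---------------------------------------------------------------------------
# stationary fixed points


@dataclass
class SteadyStateResult:
    infected_prob: np.ndarray
    network_density: float
    converged: bool
    iterations: int
    flagged_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def susceptible_prob(self) -> np.ndarray:
        return 1.0 - self.infected_prob


def solve_qmf_fixed_point(net: Network, lam: float,
                          tol: float = 1e-12, damping: float = 0.5,
                          max_iter: int = 100_000) -> SteadyStateResult:
    """Stationary quenched-mean-field probabilities at effective rate lam.

    Damped iteration of ``I_i <- x_i/(1+x_i)`` with ``x = lam * A I``,
    started from 1/2; below the spectral threshold the zero solution is
    returned directly.
    """
    if lam < 0:
        raise ValueError("effective infection rate must be non-negative")
    n = net.n
    if lam == 0.0 or lam * leading_eigenvalue(net) <= 1.0 + 1e-12:
        return SteadyStateResult(np.zeros(n), 0.0, True, 0)
    adj = net.adjacency()
    I = np.full(n, 0.5)
    for it in range(1, max_iter + 1):
        x = lam * (adj @ I)
        new = x / (1.0 + x)
        change = np.max(np.abs(new - I))
        I = (1.0 - damping) * I + damping * new
        if change < tol:
            break
    residual = np.max(np.abs(I - lam * (1.0 - I) * (adj @ I)))
    converged = residual < 1e-10
    return SteadyStateResult(I, float(I.mean()), bool(converged), it)


def _series_F(coefs: np.ndarray, x: np.ndarray,
              rel_tol: float = 1e-2) -> tuple[np.ndarray, np.ndarray]:
    """Optimally truncated asymptotic sum ``F(x) = sum_n coefs[n] x^-n``.

    The inverse-mass expansion has factorially growing coefficients
    (Watson's-lemma asymptotics of the underlying Laplace integral), so per
    node the sum stops at the smallest term.  Nodes whose smallest term
    exceeds ``rel_tol`` of the partial sum — small neighborhood infected
    mass, where the expansion breaks — are flagged.
    """
    n = x.size
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = 1.0 / np.maximum(x, 1e-300)
        F = np.zeros(n)
        term = np.ones(n)
        prev_mag = np.full(n, np.inf)
        min_mag = np.full(n, np.inf)
        active = np.ones(n, dtype=bool)
        for k in range(coefs.size):
            term = term * inv
            contrib = coefs[k] * term
            mag = np.abs(contrib)
            active &= mag <= prev_mag          # stop before a growing term
            F += np.where(active, contrib, 0.0)
            min_mag = np.where(active, mag, min_mag)
            active &= mag > 1e-14              # converged: nothing left to add
            prev_mag = mag
    flagged = ~np.isfinite(F) | (F <= 0) | (min_mag > rel_tol * np.abs(F))
    return F, flagged


def solve_type1_fixed_point(net: Network, rates: EffectiveRates,
                            n_max: int | None = None, method: str = "series",
                            tol: float = 1e-12, damping: float = 0.5,
                            max_iter: int = 100_000,
                            grid: AgeGrid | None = None) -> SteadyStateResult:
    """Stationary probabilities under type-I activation.

    Solves ``1/I_i = (1/S_i) * delta_eff * sum_n theta^(n)(0) x_i^{-n}``
    with ``x = A I``.  With ``method="series"`` the asymptotic sum is
    truncated optimally at ``n_max`` terms and nodes where the expansion
    cannot reach ~1% precision are flagged (pinned to the first-order
    value, the result marked partial).  With ``method="integral"`` the
    series is resummed exactly as the Laplace integral
    ``delta_eff * int_0^inf exp(-x Omega(tau)) dtau`` evaluated on a grid
    (requires ``rates.infection``/``rates.recovery``).
    """
    theta = rates.theta_derivs
    if n_max is None:
        n_max = theta.size
    n_max = min(n_max, theta.size)
    coefs = rates.delta_eff * theta[:n_max]

    if rates.lambda_eff_star * leading_eigenvalue(net) <= 1.0 + 1e-12:
        return SteadyStateResult(np.zeros(net.n), 0.0, True, 0)

    if method == "integral":
        if rates.infection is None or rates.recovery is None:
            raise ValueError("integral method needs the distributions on rates")
        if grid is None:
            grid = _default_grid(rates.recovery)
        _, omega_grid, g_grid = _omega_on_grid(rates.infection, rates.recovery,
                                               grid)

        def F_of(x):
            # L(x) = int exp(-x Omega); trapezoid plus an exponential tail
            expo = np.exp(-np.outer(x, omega_grid))
            L = np.trapezoid(expo, dx=grid.delta, axis=1)
            L += expo[:, -1] / (x * g_grid[-1])
            return rates.delta_eff * L, np.zeros(x.size, dtype=bool)
    elif method == "series":
        def F_of(x):
            return _series_F(coefs, x)
    else:
        raise ValueError("method must be 'series' or 'integral'")

    adj = net.adjacency()
    I = solve_qmf_fixed_point(net, rates.lambda_eff_star).infected_prob
    I = np.maximum(I, 1e-6)
    flagged = np.zeros(net.n, dtype=bool)
    for it in range(1, max_iter + 1):
        x = adj @ I
        F, flagged = F_of(x)
        F = np.where(flagged, coefs[0] / np.maximum(x, 1e-300), F)
        new = 1.0 / (1.0 + F)
        change = np.max(np.abs(new - I))
        I = (1.0 - damping) * I + damping * new
        if change < tol:
            break
    if np.all(flagged):
        raise RuntimeError("type-I series inapplicable at this density "
                           "(all nodes flagged)")
    good = ~flagged
    F, _ = F_of(adj @ I)
    residual = np.max(np.abs(I[good] - 1.0 / (1.0 + F[good])))
    return SteadyStateResult(I, float(I.mean()), bool(residual < 1e-10), it,
                             flagged_nodes=np.where(flagged)[0])


def markovian_reference(rates: EffectiveRates,
                        lam: float | None = None) -> tuple[Exponential, Exponential]:
    """The Markovian (infection, recovery) pair matching the effective rates.

    Recovery is exponential at ``delta_eff``; infection is exponential at
    ``lambda_eff * delta_eff`` so that the Markovian ratio ``b/d`` equals
    the effective infection rate.
    """
    if lam is None:
        lam = rates.lambda_eff if rates.lambda_eff is not None else rates.lambda_eff_star
    if not (rates.delta_eff > 0 and lam > 0):
        raise ValueError("effective rates must be positive")
    return Exponential(lam * rates.delta_eff), Exponential(rates.delta_eff)


def beta_from_lambda_eff(alpha_I: float, rec_dist: TimeDistribution,
                         target: float, grid: AgeGrid | None = None,
                         lo: float = 1e-3, hi: float = 1e3,
                         tol: float = 1e-8) -> float:
    """Invert beta_I from a target type-II effective rate by bisection.

    lambda_eff is monotone decreasing in the Weibull infection scale for a
    fixed shape (slower transmission clock, fewer events per period).
    """
    rec_dist = from_spec(rec_dist)
    if grid is None:
        grid = _default_grid(rec_dist)

    def f(beta):
        import warnings as _w
        with _w.catch_warnings():
            # bracket endpoints probe extreme scales where the renewal grid
            # is coarse; only the sign of f matters there
            _w.simplefilter("ignore")
            return lambda_eff_type2(Weibull(alpha_I, beta), rec_dist, grid) - target

    flo, fhi = f(lo), f(hi)
    if flo < 0 or fhi > 0:
        raise ValueError("target effective rate outside the bracket")
    a, b = lo, hi
    while b - a > tol * max(1.0, a):
        mid = math.sqrt(a * b)  # bisect in log space
        if f(mid) > 0:
            a = mid
        else:
            b = mid
    return math.sqrt(a * b)
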