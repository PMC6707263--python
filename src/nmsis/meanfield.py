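"""First-order age-structured mean-field theory for non-Markovian SIS.

Each node i carries two age-density surfaces on a common age grid:
``I_i(tau; t)`` (infected, infection age tau) and ``S_i(tau; t)``
(susceptible, susceptibility age tau), with total probability
``sum_tau (I + S) * dtau = 1`` per node at all times.  One step of size
``delta`` (the age step equals the time step by construction):

1. evaluate the per-node infection pressure ``Phi_i(tau)`` from the
   neighbors' infected surfaces — under type-I activation the integrand is
   the infection hazard at the *younger* of the two endpoint ages,
   ``omega_inf(min(tau, tau'))``; under type-II it is the renewal intensity
   ``eta(tau')`` of the infected source and is independent of tau;
2. transport both surfaces one bin to the right with exact survival factors
   (``Psi_rec(tau+d)/Psi_rec(tau)`` for infected mass, ``exp(-Phi_i d)`` for
   susceptible mass);
3. re-inject the recovered and newly-infected outflows into age bin zero.

Mass older than the grid cutoff pools in the terminal bin and keeps decaying
at the terminal-age hazard, so probability is conserved to round-off.

The ages of adjacent nodes are treated as independent (first-order closure);
pairwise age correlations are deliberately not modelled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .distributions import TimeDistribution, Exponential, Weibull
from .networks import Network

__all__ = ["AgeGrid", "InitialCondition", "MeanFieldResult", "eta_renewal",
           "activation_kernel_type1", "activation_kernel_type2",
           "integrate_mean_field", "uniform_initial", "transient_time"]


@dataclass(frozen=True)
class AgeGrid:
    """Uniform age grid: bins [k*delta, (k+1)*delta), k = 0..n_bins-1."""

    delta: float
    n_bins: int

    def __post_init__(self):
        if self.delta <= 0 or self.n_bins < 2:
            raise ValueError("need delta > 0 and at least two bins")

    @property
    def tau_max(self) -> float:
        return self.delta * self.n_bins

    @property
    def taus(self) -> np.ndarray:
        """Left bin edges."""
        return self.delta * np.arange(self.n_bins)

    @property
    def edges(self) -> np.ndarray:
        return self.delta * np.arange(self.n_bins + 1)

    @classmethod
    def for_recovery(cls, rec_dist: TimeDistribution, delta: float,
                     tail: float = 1e-8, tau_min: float = 0.0) -> "AgeGrid":
        """Grid whose cutoff leaves at most `tail` recovery survival mass."""
        tau = rec_dist.ppf_survival(min(tail, 1.0))
        tau = max(float(tau) * 1.05, tau_min, 4 * delta)
        return cls(delta=delta, n_bins=int(np.ceil(tau / delta)))


def _bin_hazard(dist: TimeDistribution, grid: AgeGrid) -> np.ndarray:
    """Exact bin-averaged hazard; finite even for singular endpoint hazards.

    Beyond a finite support the cumulative hazard is infinite; those bins get
    a large finite sentinel (mass there is annihilated within one step).
    """
    H = dist.cum_hazard(grid.edges)
    with np.errstate(invalid="ignore"):
        bar = np.diff(H) / grid.delta
    big = 745.0 / grid.delta  # exp(-745) underflows to zero
    return np.where(np.isfinite(bar), np.minimum(bar, big), big)


def eta_renewal(inf_dist: TimeDistribution, grid: AgeGrid) -> np.ndarray:
    """Renewal intensity eta(tau) of the infection law on the grid.

    Solves the Volterra renewal equation
    ``eta(tau) = psi(tau) + int_0^tau eta(tau') psi(tau - tau') dtau'``
    by forward substitution with product integration: eta is taken piecewise
    constant on bins and the kernel is integrated exactly through survival
    differences, which reproduces a constant-hazard law exactly and remains
    stable for densities that diverge at age zero (Weibull shape < 1).
    """
    if isinstance(inf_dist, Exponential):
        return np.full(grid.n_bins, inf_dist.rate)
    if isinstance(inf_dist, Weibull) and inf_dist.shape == 1.0:
        return np.full(grid.n_bins, 1.0 / inf_dist.scale)
    delta = grid.delta
    if hasattr(inf_dist, "scale") and delta > 0.1 * inf_dist.scale:
        warnings.warn("age grid coarser than a tenth of the infection scale; "
                      "renewal solution may be inaccurate", stacklevel=2)
    taus = grid.taus
    n = grid.n_bins
    sf = inf_dist.sf(grid.edges)
    w = sf[:-1] - sf[1:]  # mass of psi in bin m
    psi = np.asarray(inf_dist.pdf(taus), dtype=float)
    eta = np.empty(n)
    psi0 = float(psi[0])
    eta[0] = psi0 if math.isfinite(psi0) else w[0] / delta
    wrev = w[::-1]
    for b in range(1, n):
        p = psi[b] if math.isfinite(psi[b]) else w[b] / delta
        eta[b] = p + np.dot(eta[:b], wrev[n - b:])
    return eta


def activation_kernel_type2(eta: np.ndarray, infected_field: np.ndarray,
                            delta: float) -> float:
    """Age-independent infection pressure from one infected neighbor field."""
    return float(np.dot(eta, infected_field) * delta)


def activation_kernel_type1(omega_inf: np.ndarray, infected_field: np.ndarray,
                            delta: float) -> np.ndarray:
    """Age-resolved pressure ``Phi(tau) = int omega(min(tau, tau')) I_j dtau'``.

    Decomposes into a prefix integral of ``omega * I_j`` plus the hazard at
    tau times the suffix mass of ``I_j``; O(n_bins) per field.
    """
    mass = infected_field * delta
    prefix = np.concatenate(([0.0], np.cumsum(omega_inf * mass)[:-1]))
    suffix = mass[::-1].cumsum()[::-1]
    return prefix + omega_inf * suffix


def _phi_type1_brute(omega_inf: np.ndarray, infected_field: np.ndarray,
                     delta: float) -> np.ndarray:
    """Direct double loop over (tau, tau'); test oracle for the fast kernel."""
    n = omega_inf.size
    out = np.zeros(n)
    for b in range(n):
        for bp in range(n):
            out[b] += omega_inf[min(b, bp)] * infected_field[bp] * delta
    return out


@dataclass
class InitialCondition:
    """Per-node age densities at t = 0 (rows: nodes, cols: age bins)."""

    rho: np.ndarray  # infected density I_i(tau; 0)
    chi: np.ndarray  # susceptible density S_i(tau; 0)

    def validate(self, grid: AgeGrid):
        total = (self.rho.sum(axis=1) + self.chi.sum(axis=1)) * grid.delta
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("per-node age densities must integrate to 1")
        if np.any(self.rho < 0) or np.any(self.chi < 0):
            raise ValueError("age densities must be non-negative")


def uniform_initial(n: int, rho0: float, grid: AgeGrid) -> InitialCondition:
    """Every node infected with probability rho0, all ages concentrated at 0.

    Point masses are represented as a full first bin of density mass/delta.
    This mirrors the simulator's fresh start: seed infection ages are zero
    and initial susceptible nodes carry age zero as well.
    """
    rho = np.zeros((n, grid.n_bins))
    chi = np.zeros((n, grid.n_bins))
    rho[:, 0] = rho0 / grid.delta
    chi[:, 0] = (1.0 - rho0) / grid.delta
    return InitialCondition(rho=rho, chi=chi)


@dataclass
class MeanFieldResult:
    times: np.ndarray
    infected: np.ndarray        # network-averaged I(t)
    infected_nodes: np.ndarray  # per-node I_i(t), shape (n_times, N)
    final_fields: tuple         # (I surface, S surface) at t_max


def integrate_mean_field(net: Network, mechanism: str,
                         inf_dist: TimeDistribution,
                         rec_dist: TimeDistribution,
                         init: InitialCondition, grid: AgeGrid,
                         t_max: float,
                         sample_times: np.ndarray | None = None,
                         conservation_tol: float = 1e-6) -> MeanFieldResult:
    """Integrate the age-structured PDE system up to t_max.

    The time step equals the age step ``grid.delta``; sample times snap to
    the nearest step.
    """
    if mechanism not in ("type1", "type2"):
        raise ValueError("mechanism must be 'type1' or 'type2'")
    init.validate(grid)
    delta = grid.delta
    n_steps = int(round(t_max / delta))
    if sample_times is None:
        sample_times = np.linspace(0.0, n_steps * delta, min(n_steps, 200) + 1)
    sample_steps = np.unique(np.clip(np.round(np.asarray(sample_times) / delta
                                              ).astype(int), 0, n_steps))

    adj = net.adjacency()
    I = init.rho.copy()
    S = init.chi.copy()

    omega_rec_bar = _bin_hazard(rec_dist, grid)
    decay_I = np.exp(-omega_rec_bar * delta)        # survival ratio per bin
    if mechanism == "type2":
        eta = eta_renewal(inf_dist, grid)
    else:
        omega_inf_bar = _bin_hazard(inf_dist, grid)
        if np.isfinite(inf_dist.support_upper):
            # min(tau, tau') beyond the support end is an artefact of the
            # independent-age closure; cap the hazard at support_upper-delta
            cap = float(inf_dist.hazard(inf_dist.support_upper - delta))
            omega_inf_bar = np.minimum(omega_inf_bar, cap)

    out_times, out_net, out_nodes = [], [], []

    def record(step):
        mass = I.sum(axis=1) * delta
        out_times.append(step * delta)
        out_nodes.append(mass)
        out_net.append(mass.mean())

    next_sample = 0
    for step in range(n_steps + 1):
        if next_sample < sample_steps.size and step == sample_steps[next_sample]:
            record(step)
            next_sample += 1
        if step == n_steps:
            break

        # -- infection pressure Phi_i(tau) ------------------------------
        if mechanism == "type2":
            phi_node = adj @ (I @ eta * delta)          # (N,) age-independent
            decay_S = np.exp(-delta * phi_node)[:, None]
            phi_term = None
        else:
            mass_I = I * delta
            prefix = np.concatenate(
                [np.zeros((net.n, 1)), np.cumsum(mass_I * omega_inf_bar, axis=1)[:, :-1]],
                axis=1)
            suffix = np.flip(np.cumsum(np.flip(mass_I, axis=1), axis=1), axis=1)
            phi = (adj @ prefix) + omega_inf_bar[None, :] * (adj @ suffix)
            decay_S = np.exp(-delta * phi)

        # -- transport with exact survival factors ----------------------
        newI = np.empty_like(I)
        newS = np.empty_like(S)
        survI = I * decay_I[None, :]
        survS = S * decay_S
        recovered_mass = delta * (I - survI).sum(axis=1)
        infected_mass = delta * (S - survS).sum(axis=1)
        newI[:, 1:] = survI[:, :-1]
        newS[:, 1:] = survS[:, :-1]
        # terminal bin pools mass older than the cutoff
        newI[:, -1] += survI[:, -1]
        newS[:, -1] += survS[:, -1]
        newI[:, 0] = infected_mass / delta
        newS[:, 0] = recovered_mass / delta
        I, S = newI, newS

        if step % 200 == 0:
            total = (I.sum(axis=1) + S.sum(axis=1)) * delta
            err = np.abs(total - 1.0).max()
            if err > conservation_tol:
                raise RuntimeError(
                    f"probability conservation violated at t={step*delta:.3f}: "
                    f"max deviation {err:.3e}")

    return MeanFieldResult(times=np.array(out_times),
                           infected=np.array(out_net),
                           infected_nodes=np.array(out_nodes),
                           final_fields=(I, S))


def transient_time(times: np.ndarray, infected: np.ndarray,
                   epsilon: float, window: float) -> float:
    """Earliest t after which I stays within epsilon of I(t) for `window`.

    Returns ``inf`` if the trajectory never stabilizes within the covered
    span.  The trajectory must cover at least two windows.
    """
    times = np.asarray(times, dtype=float)
    infected = np.asarray(infected, dtype=float)
    span = times[-1] - times[0]
    if span < 2 * window:
        raise ValueError("trajectory must cover at least two windows")
    for k in range(times.size):
        if times[k] + window > times[-1]:
            break
        mask = (times >= times[k]) & (times <= times[k] + window)
        if np.max(np.abs(infected[mask] - infected[k])) < epsilon:
            return float(times[k])
    return math.inf
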