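"""Exact event-driven Monte Carlo simulation of non-Markovian SIS dynamics.

Every infected node carries an absolute recovery time drawn from the recovery
law at the moment of infection, and every active directed edge carries an
absolute transmission time drawn from the infection law at the moment the
edge (re)entered age zero.  A min-heap delivers events in order; see
:mod:`nmsis._core` for the mechanism rules (type-I vs type-II edge
activation) and the lazy-invalidation scheme.

Ensembles average unconditionally: realizations that go extinct contribute
zeros from their extinction time onward, matching the interpretation of
published transient curves that decay to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _core
from ._rng import generator, substream
from .distributions import TimeDistribution, from_spec
from .networks import Network

__all__ = ["SimulationConfig", "Trajectory", "run_sis", "run_ensemble",
           "stationary_density"]

_MECHS = {"type1": _core.MECH_TYPE1, "type2": _core.MECH_TYPE2}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation experiment."""

    mechanism: str
    infection: TimeDistribution
    recovery: TimeDistribution
    initial_infected_fraction: float = 0.01
    t_max: float = 30.0
    sample_times: np.ndarray | int = 200
    seed: int = 0
    #: run the state/heap consistency audit every this many events (0 = off)
    audit_every: int = 1024

    def __post_init__(self):
        if self.mechanism not in _MECHS:
            raise ValueError(f"mechanism must be one of {sorted(_MECHS)}")
        if not (0.0 < self.initial_infected_fraction <= 1.0):
            raise ValueError("initial_infected_fraction must lie in (0, 1]")
        object.__setattr__(self, "infection", from_spec(self.infection))
        object.__setattr__(self, "recovery", from_spec(self.recovery))
        st = self.sample_times
        if isinstance(st, (int, np.integer)):
            st = np.linspace(0.0, self.t_max, int(st) + 1)
        st = np.asarray(st, dtype=float)
        if st.size == 0 or np.any(np.diff(st) <= 0) or st[0] < 0 or st[-1] > self.t_max:
            raise ValueError("sample_times must be increasing within [0, t_max]")
        object.__setattr__(self, "sample_times", st)


@dataclass
class Trajectory:
    """Sampled infected density I(t), possibly an ensemble average."""

    times: np.ndarray
    infected_density: np.ndarray
    stderr: np.ndarray | None = None
    extinct_time: float | None = None
    n_realizations: int = 1
    #: per-realization density matrix (n_realizations x n_times), if kept
    realizations: np.ndarray | None = None
    n_transmissions: int = 0
    n_recoveries: int = 0
    extinct_times: list = field(default_factory=list)


def _draw_seeds(net: Network, fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_seeds = int(np.ceil(fraction * net.n))
    if n_seeds < 1:
        raise ValueError("initial condition draws zero seed nodes")
    return np.sort(rng.choice(net.n, size=n_seeds, replace=False)).astype(np.int64)


def _run_one(net: Network, config: SimulationConfig, realization_seed) -> Trajectory:
    indptr, dst, src, pair = net.directed_arrays()
    ss = substream(config.seed, "event-sim", realization_seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    seeds = _draw_seeds(net, config.initial_infected_fraction, rng)
    core_seed = int(ss.generate_state(2)[1] & 0x7FFFFFFF)
    inf_fam, ip1, ip2 = config.infection.family_code()
    rec_fam, rp1, rp2 = config.recovery.family_code()
    counts, extinct, n_trans, n_rec, ok = _core.run_realization(
        indptr, dst, src, pair, seeds, _MECHS[config.mechanism],
        inf_fam, ip1, ip2, rec_fam, rp1, rp2,
        float(config.t_max), config.sample_times, core_seed,
        int(config.audit_every))
    if not ok:
        raise RuntimeError("state/heap consistency audit failed (internal error)")
    return Trajectory(
        times=config.sample_times,
        infected_density=counts / net.n,
        extinct_time=None if np.isnan(extinct) else float(extinct),
        n_transmissions=int(n_trans),
        n_recoveries=int(n_rec),
    )


def run_sis(net: Network, config: SimulationConfig) -> Trajectory:
    """Run a single realization; deterministic given (config, seed)."""
    if net.n == 0:
        raise ValueError("empty network")
    return _run_one(net, config, 0)


def run_ensemble(net: Network, config: SimulationConfig,
                 n_realizations: int,
                 condition_on_survival: bool = False) -> Trajectory:
    """Average `n_realizations` independent realizations.

    The default average is unconditional (extinct runs contribute zeros);
    with ``condition_on_survival`` each sample time averages only the
    realizations not yet extinct at that time.  The returned trajectory
    carries the per-time ensemble mean, the standard error of that mean,
    and the full per-realization density matrix.
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    if net.n == 0:
        raise ValueError("empty network")
    mat = np.empty((n_realizations, config.sample_times.size))
    extincts = []
    n_trans = n_rec = 0
    for r in range(n_realizations):
        traj = _run_one(net, config, r)
        mat[r] = traj.infected_density
        if traj.extinct_time is not None:
            extincts.append(traj.extinct_time)
        n_trans += traj.n_transmissions
        n_rec += traj.n_recoveries
    if condition_on_survival:
        alive = mat > 0
        n_alive = np.maximum(alive.sum(axis=0), 1)
        masked = np.where(alive, mat, np.nan)
        with np.errstate(invalid="ignore"):
            mean = np.where(alive.any(axis=0), np.nanmean(masked, axis=0), 0.0)
            sd = np.where(n_alive > 1, np.nanstd(masked, axis=0, ddof=1), 0.0)
        stderr = sd / np.sqrt(n_alive)
    else:
        mean = mat.mean(axis=0)
        if n_realizations > 1:
            stderr = mat.std(axis=0, ddof=1) / np.sqrt(n_realizations)
        else:
            stderr = np.zeros_like(mean)
    return Trajectory(times=config.sample_times, infected_density=mean,
                      stderr=stderr, n_realizations=n_realizations,
                      realizations=mat, n_transmissions=n_trans,
                      n_recoveries=n_rec, extinct_times=extincts)


def stationary_density(traj: Trajectory, burn_in: float) -> tuple[float, float]:
    """Time-average of I(t) over (burn_in, t_max] with a standard error.

    For an ensemble trajectory the standard error is taken across the
    independent per-realization time averages; for a single realization a
    batch-means estimate over 10 batches is used (time samples are
    autocorrelated, so a naive iid error would be too small).
    """
    mask = traj.times > burn_in
    if not np.any(mask):
        raise ValueError("no sample times after burn_in")
    if traj.realizations is not None and traj.n_realizations > 1:
        per_real = traj.realizations[:, mask].mean(axis=1)
        return float(per_real.mean()), float(per_real.std(ddof=1) / np.sqrt(per_real.size))
    values = traj.infected_density[mask]
    n_batches = min(10, values.size)
    batches = np.array_split(values, n_batches)
    means = np.array([b.mean() for b in batches])
    if n_batches > 1 and means.std(ddof=1) > 0:
        se = float(means.std(ddof=1) / np.sqrt(n_batches))
    else:
        se = 0.0
    return float(values.mean()), se


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of the config with a different master seed."""
    return replace(config, seed=seed)
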