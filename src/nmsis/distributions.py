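"""Waiting-time laws for infection and recovery events.

The SIS dynamics implemented in this package are driven by two renewal-type
clocks: the time an infected node needs to recover, and the time an active
directed edge needs to transmit.  Each clock is described by a waiting-time
distribution through four interchangeable views,

* the density ``psi(x)``,
* the survival function ``Psi(x) = P(T > x)``,
* the hazard (instantaneous rate) ``omega(x) = psi(x) / Psi(x)``,
* the cumulative hazard ``H(x) = -log Psi(x)``,

related by ``psi = omega * Psi`` and ``Psi = exp(-H)``.  Three families cover
everything the dynamics need:

* :class:`Weibull` with shape ``alpha`` and scale ``beta`` — the workhorse for
  heavy- or light-tailed infection and recovery times,
* :class:`BetaSigma1` — the Beta(1, gamma) law on [0, 1) with density
  ``gamma * (1-x)**(gamma-1)`` and hazard ``gamma / (1-x)``, used to probe
  non-constant infection hazards with bounded support,
* :class:`Exponential` — the constant-hazard (Markovian) special case,
  identical to a Weibull with shape 1 and scale ``1/rate``.

Samples are drawn by inverting the survival function, ``Psi(x) = u`` with
``u`` uniform on (0, 1]; all three families invert in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "TimeDistribution",
    "Weibull",
    "BetaSigma1",
    "Exponential",
    "evaluate_distribution",
    "sample_waiting_time",
    "laplace_transform",
    "survival_integral",
    "from_spec",
]

#: absolute tolerance used for all quadrature on distribution functions
QUAD_ATOL = 1e-10

# family codes shared with the compiled simulator core
FAM_WEIBULL = 0
FAM_BETA_SIGMA1 = 1
FAM_EXPONENTIAL = 2


class TimeDistribution:
    """Abstract waiting-time law on [0, support_upper)."""

    #: upper end of the support (``inf`` unless the law is bounded)
    support_upper: float = math.inf

    # -- the four views ---------------------------------------------------
    def pdf(self, x):
        raise NotImplementedError

    def sf(self, x):
        """Survival function ``P(T > x)``."""
        raise NotImplementedError

    def hazard(self, x):
        """Instantaneous rate ``pdf/sf``; ``inf`` at/beyond the support end."""
        raise NotImplementedError

    def cum_hazard(self, x):
        """Cumulative hazard ``-log sf(x)``."""
        raise NotImplementedError

    # -- sampling ----------------------------------------------------------
    def ppf_survival(self, u):
        """The unique ``x`` with ``sf(x) = u``, for ``u`` in (0, 1]."""
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size=None):
        """Draw via survival inversion from a seeded generator stream."""
        u = 1.0 - rng.random(size)  # uniform on (0, 1]
        return self.ppf_survival(u)

    # -- integral summaries ------------------------------------------------
    def mean(self) -> float:
        """``int_0^sup Psi(x) dx``, the mean waiting time."""
        raise NotImplementedError

    def laplace(self, s: float) -> float:
        """``int psi(x) exp(-s x) dx`` for real ``s >= 0``."""
        if s < 0:
            raise ValueError("Laplace transform evaluated at s < 0 may diverge")
        upper = self.support_upper
        if math.isinf(upper):
            # split at the distribution scale to help the adaptive rule
            mid = self.mean()
            a, _ = integrate.quad(lambda x: self.pdf(x) * math.exp(-s * x),
                                  0.0, mid, epsabs=QUAD_ATOL, epsrel=1e-12)
            b, _ = integrate.quad(lambda x: self.pdf(x) * math.exp(-s * x),
                                  mid, math.inf, epsabs=QUAD_ATOL, epsrel=1e-12)
            return a + b
        val, _ = integrate.quad(lambda x: self.pdf(x) * math.exp(-s * x),
                                0.0, upper, epsabs=QUAD_ATOL, epsrel=1e-12)
        return val

    # -- helpers for grid-based solvers -------------------------------------
    def bin_average_hazard(self, edges: np.ndarray) -> np.ndarray:
        """Exact bin averages ``(H(edge[k+1]) - H(edge[k])) / width``.

        Finite even when the pointwise hazard diverges at an endpoint
        (e.g. Weibull with shape < 1 at zero), which makes it the right
        hazard discretization for age-grid solvers.
        """
        H = self.cum_hazard(np.asarray(edges, dtype=float))
        return np.diff(H) / np.diff(edges)

    # -- interop -----------------------------------------------------------
    def family_code(self) -> tuple[int, float, float]:
        """(family id, par1, par2) encoding for the compiled event loop."""
        raise NotImplementedError


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def _as_nonneg(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("waiting times are non-negative; got a negative argument")
    return x


@dataclass(frozen=True)
class Weibull(TimeDistribution):
    """Weibull law: ``Psi(x) = exp(-(x/scale)**shape)``.

    ``shape < 1`` gives a heavy-tailed law with decreasing hazard,
    ``shape = 1`` is exponential, ``shape > 1`` concentrates mass near the
    scale with increasing hazard.
    """

    shape: float
    scale: float
    support_upper: float = math.inf

    def __post_init__(self):
        _check_positive(shape=self.shape, scale=self.scale)

    def cum_hazard(self, x):
        x = _as_nonneg(x)
        return (x / self.scale) ** self.shape

    def sf(self, x):
        return np.exp(-self.cum_hazard(x))

    def hazard(self, x):
        x = _as_nonneg(x)
        a, b = self.shape, self.scale
        with np.errstate(divide="ignore"):
            return (a / b) * (x / b) ** (a - 1.0)

    def pdf(self, x):
        return self.hazard(x) * self.sf(x)

    def ppf_survival(self, u):
        u = np.asarray(u, dtype=float)
        if np.any(u <= 0) or np.any(u > 1):
            raise ValueError("survival level must lie in (0, 1]")
        return self.scale * np.log(1.0 / u) ** (1.0 / self.shape)

    def mean(self):
        return self.scale * math.gamma(1.0 + 1.0 / self.shape)

    def family_code(self):
        return FAM_WEIBULL, self.shape, self.scale


@dataclass(frozen=True)
class BetaSigma1(TimeDistribution):
    """Beta(1, gamma) law on [0, 1): density ``gamma*(1-x)**(gamma-1)``.

    The hazard ``gamma/(1-x)`` diverges at the upper support end; evaluation
    there reports an infinite-hazard sentinel rather than raising, because
    age-grid solvers may touch the endpoint even though the event-driven
    simulator never does.
    """

    gamma: float
    support_upper: float = 1.0

    def __post_init__(self):
        _check_positive(gamma=self.gamma)

    def sf(self, x):
        x = _as_nonneg(x)
        return np.where(x < 1.0, np.clip(1.0 - x, 0.0, 1.0) ** self.gamma, 0.0)

    def cum_hazard(self, x):
        x = _as_nonneg(x)
        with np.errstate(divide="ignore"):
            return np.where(x < 1.0, -self.gamma * np.log1p(-np.minimum(x, 1.0 - 1e-300)), np.inf)

    def hazard(self, x):
        x = _as_nonneg(x)
        with np.errstate(divide="ignore"):
            return np.where(x < 1.0, self.gamma / (1.0 - x), np.inf)

    def pdf(self, x):
        x = _as_nonneg(x)
        with np.errstate(divide="ignore"):
            return np.where(x < 1.0,
                            self.gamma * np.clip(1.0 - x, 0.0, 1.0) ** (self.gamma - 1.0),
                            0.0)

    def ppf_survival(self, u):
        u = np.asarray(u, dtype=float)
        if np.any(u <= 0) or np.any(u > 1):
            raise ValueError("survival level must lie in (0, 1]")
        return 1.0 - u ** (1.0 / self.gamma)

    def mean(self):
        return 1.0 / (self.gamma + 1.0)

    def family_code(self):
        return FAM_BETA_SIGMA1, self.gamma, 0.0


@dataclass(frozen=True)
class Exponential(TimeDistribution):
    """Constant-hazard (Markovian) law with the given rate."""

    rate: float
    support_upper: float = math.inf

    def __post_init__(self):
        _check_positive(rate=self.rate)

    def cum_hazard(self, x):
        return self.rate * _as_nonneg(x)

    def sf(self, x):
        return np.exp(-self.cum_hazard(x))

    def hazard(self, x):
        x = _as_nonneg(x)
        return np.full_like(x, self.rate)

    def pdf(self, x):
        return self.rate * self.sf(x)

    def ppf_survival(self, u):
        u = np.asarray(u, dtype=float)
        if np.any(u <= 0) or np.any(u > 1):
            raise ValueError("survival level must lie in (0, 1]")
        return np.log(1.0 / u) / self.rate

    def mean(self):
        return 1.0 / self.rate

    def laplace(self, s):
        if s < 0:
            raise ValueError("Laplace transform evaluated at s < 0 may diverge")
        return self.rate / (self.rate + s)

    def family_code(self):
        return FAM_EXPONENTIAL, self.rate, 0.0


# ---------------------------------------------------------------------------
# functional surface


def evaluate_distribution(dist: TimeDistribution, x):
    """Return ``(psi(x), Psi(x), omega(x))``.

    Beyond the support the density and survival are 0 and the hazard is the
    ``inf`` sentinel.
    """
    x = _as_nonneg(x)
    return dist.pdf(x), dist.sf(x), dist.hazard(x)


def sample_waiting_time(dist: TimeDistribution, u):
    """Solve ``Psi(x) = u`` for the waiting time; ``u`` in (0, 1]."""
    return dist.ppf_survival(u)


def laplace_transform(dist: TimeDistribution, s: float) -> float:
    return dist.laplace(s)


def survival_integral(dist: TimeDistribution) -> float:
    """``int_0^sup Psi(x) dx`` — the mean waiting time."""
    return dist.mean()


_FAMILIES = {
    "weibull": (Weibull, ("shape", "scale")),
    "beta_sigma1": (BetaSigma1, ("gamma",)),
    "exponential": (Exponential, ("rate",)),
}


def from_spec(spec) -> TimeDistribution:
    """Build a distribution from a config mapping or compact string.

    Accepts ``{"family": "weibull", "shape": 2, "scale": 0.5}`` or the CLI
    short form ``"weibull:2,0.5"`` (parameters in declaration order).
    """
    if isinstance(spec, TimeDistribution):
        return spec
    if isinstance(spec, str):
        family, _, rest = spec.partition(":")
        family = family.strip().lower()
        if family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {family!r}")
        cls, names = _FAMILIES[family]
        values = [float(tok) for tok in rest.split(",") if tok.strip()]
        if len(values) != len(names):
            raise ValueError(f"{family} expects parameters {names}, got {values}")
        return cls(*values)
    spec = dict(spec)
    family = str(spec.pop("family")).lower()
    if family not in _FAMILIES:
        raise ValueError(f"unknown distribution family {family!r}")
    cls, names = _FAMILIES[family]
    try:
        args = [float(spec.pop(name)) for name in names]
    except KeyError as exc:
        raise ValueError(f"{family} requires parameter {exc.args[0]!r}") from exc
    if spec:
        raise ValueError(f"unexpected parameters for {family}: {sorted(spec)}")
    return cls(*args)
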