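"""Shifted positive-support response-time distributions.

A raw response time ``y`` is decomposed as ``y = theta + x`` where ``theta``
is a deterministic, participant-specific shift (the nondecision time, in ms)
and ``x > 0`` is the stochastic component.  The stochastic component follows
one of three two-parameter families with positive skew that are standard in
RT modelling:

===========  ==================  =====================================
family       rho1                rho2
===========  ==================  =====================================
lognormal    mu (ln-ms scale)    sigma^2 (variance of ln x)
wald         mu (mean, ms)       lambda (shape, ms)
gamma        alpha (shape)       beta (rate, 1/ms)
===========  ==================  =====================================

All densities are zero (log-density ``-inf``) for ``y <= theta``, and all
parameters live in milliseconds so that typical ``x`` values exceed 1 and
the lognormal location ``mu = E[ln x]`` stays positive, which the positive
gamma priors of the hierarchical model require.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["Family", "ShiftedParams", "log_density", "sample", "cell_mean", "cdf"]

_LOG_2PI = math.log(2.0 * math.pi)


class Family(str, enum.Enum):
    """The stochastic-component family of a shifted RT distribution."""

    LOGNORMAL = "lognormal"
    WALD = "wald"
    GAMMA = "gamma"

    @classmethod
    def coerce(cls, value: "Family | str") -> "Family":
        if isinstance(value, cls):
            return value
        v = str(value).lower()
        aliases = {"lnorm": "lognormal", "invgauss": "wald", "inverse_gaussian": "wald"}
        return cls(aliases.get(v, v))


@dataclass(frozen=True)
class ShiftedParams:
    """Parameters of one shifted distribution (one cell of the model)."""

    family: Family
    theta: float  # shift, ms, >= 0
    rho1: float  # mu (lognormal, Wald) or alpha (gamma)
    rho2: float  # sigma^2 (lognormal), lambda (Wald) or beta rate (gamma)

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family.coerce(self.family))
        if not (self.theta >= 0.0):
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if not self.rho2 > 0.0:
            raise ValueError(f"rho2 must be positive, got {self.rho2}")
        # The lognormal location mu lives on the log-ms scale, where the
        # density is defined for any finite mu; the hierarchical gamma prior
        # is what keeps it positive in practice.  Wald mean and gamma shape
        # must be strictly positive.
        if self.family is Family.LOGNORMAL:
            if not np.isfinite(self.rho1):
                raise ValueError(f"rho1 must be finite, got {self.rho1}")
        elif not self.rho1 > 0.0:
            raise ValueError(f"rho1 must be positive, got {self.rho1}")


def log_density_arrays(y, theta, rho1, rho2, family: Family | str):
    """Elementwise shifted log-density; broadcasts all arguments.

    Returns ``-inf`` wherever ``y <= theta``.  This is the hot path used by
    the posterior sampler, so it is plain vectorized numpy.
    """
    family = Family.coerce(family)
    y, theta, rho1, rho2 = np.broadcast_arrays(
        np.asarray(y, dtype=float), theta, rho1, rho2
    )
    d = y - theta
    ok = d > 0.0
    ds = np.where(ok, d, 1.0)  # safe placeholder; masked out below
    logd = np.log(ds)
    if family is Family.LOGNORMAL:
        out = -0.5 * (_LOG_2PI + np.log(rho2)) - logd - (logd - rho1) ** 2 / (2.0 * rho2)
    elif family is Family.WALD:
        out = 0.5 * (np.log(rho2) - _LOG_2PI - 3.0 * logd) - rho2 * (ds - rho1) ** 2 / (
            2.0 * rho1**2 * ds
        )
    elif family is Family.GAMMA:
        out = (
            special.xlogy(rho1, rho2)
            - special.gammaln(rho1)
            + special.xlogy(rho1 - 1.0, ds)
            - rho2 * ds
        )
    else:  # pragma: no cover
        raise ValueError(family)
    return np.where(ok, out, -np.inf)


def _validate(p: ShiftedParams) -> ShiftedParams:
    if not isinstance(p, ShiftedParams):
        raise TypeError("expected ShiftedParams")
    return p


def log_density(y, p: ShiftedParams):
    """Log-density of the shifted family at ``y`` (ms); ``-inf`` off-support."""
    _validate(p)
    out = log_density_arrays(y, p.theta, p.rho1, p.rho2, p.family)
    return float(out) if np.isscalar(y) else out


def _frozen(p: ShiftedParams):
    """The scipy frozen distribution equivalent to ``p`` (used for CDF/PPF)."""
    if p.family is Family.LOGNORMAL:
        return stats.lognorm(s=math.sqrt(p.rho2), loc=p.theta, scale=math.exp(p.rho1))
    if p.family is Family.WALD:
        return stats.invgauss(mu=p.rho1 / p.rho2, loc=p.theta, scale=p.rho2)
    return stats.gamma(a=p.rho1, loc=p.theta, scale=1.0 / p.rho2)


def cdf(y, p: ShiftedParams):
    """CDF of the shifted family at ``y``."""
    _validate(p)
    return _frozen(p).cdf(y)


def sample(p: ShiftedParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` response times (ms) from the shifted family.

    ``seed`` may be an int or a ``numpy.random.Generator``; fixed seeds give
    reproducible draws.
    """
    _validate(p)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return sample_arrays(rng, p.theta, p.rho1, p.rho2, p.family, size=n)


def sample_arrays(rng: np.random.Generator, theta, rho1, rho2, family, size=None):
    """Vectorized sampler used by the generator and posterior predictive."""
    family = Family.coerce(family)
    if family is Family.LOGNORMAL:
        x = rng.lognormal(mean=rho1, sigma=np.sqrt(rho2), size=size)
    elif family is Family.WALD:
        x = rng.wald(mean=rho1, scale=rho2, size=size)
    else:
        x = rng.gamma(shape=rho1, scale=1.0 / np.asarray(rho2, dtype=float), size=size)
    return theta + x


def cell_mean(p: ShiftedParams) -> float:
    """Expected RT (ms) of the shifted family: theta + E[x]."""
    _validate(p)
    return float(cell_mean_arrays(p.theta, p.rho1, p.rho2, p.family))


def cell_mean_arrays(theta, rho1, rho2, family):
    family = Family.coerce(family)
    theta = np.asarray(theta, dtype=float)
    if family is Family.LOGNORMAL:
        return theta + np.exp(np.asarray(rho1) + np.asarray(rho2) / 2.0)
    if family is Family.WALD:
        return theta + np.asarray(rho1, dtype=float)
    return theta + np.asarray(rho1) / np.asarray(rho2)
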