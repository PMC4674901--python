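"""Overlap probabilities for deletion events during fractionation.

A new deletion event may fall entirely inside a run of double-copy genes
(creating a new single-copy run), or skip through q >= 1 pre-existing
single-copy runs (merging them).  These probabilities depend only on the
deletion-length law (geometric, mean ``mu``) and the current double-copy
run-length law (geometric, mean ``nu``; exponential in the continuous
analogue).

Discrete model
    ``p0_discrete_sum``     triple-sum definition of p_0, truncated tail
    ``p0_discrete_closed``  closed form (nu-1)^2 / ((mu+nu-1) nu)
    ``p0_discrete_approx``  large-nu approximation nu/(mu+nu) * (1-1/nu)
    ``zeta_mean``           mean of the combined geometric law arising in the
                            reduction of the triple sum

Continuous model (exponential deletion lengths and segment lengths)
    ``pq_continuous``         closed form: q is geometric with parameter
                              mu/(mu+nu)
    ``pq_continuous_oracle``  direct numerical quadrature of the defining
                              nested integrals for q in {0, 1}

The closed forms for discrete p_q with q >= 1 are not provided; empirical
q-counts come from the simulator's event log instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate

__all__ = [
    "OverlapParams",
    "ZetaReduction",
    "p0_discrete_sum",
    "p0_discrete_closed",
    "p0_discrete_approx",
    "zeta_mean",
    "pq_continuous",
    "pq_continuous_oracle",
]

_L_CAP = 10_000_000  # hard cap on the outer run-length sum


@dataclass(frozen=True)
class OverlapParams:
    """Parameter pair (mu, nu): mean deletion length and mean double-run length."""

    mu: float
    nu: float

    def validate_discrete(self) -> None:
        if self.mu < 1.0:
            raise ValueError(f"discrete model requires mu >= 1, got {self.mu}")
        if self.nu <= 1.0:
            raise ValueError(f"discrete model requires nu > 1, got {self.nu}")

    def validate_continuous(self) -> None:
        if self.mu <= 0.0 or self.nu <= 0.0:
            raise ValueError(
                f"continuous model requires mu > 0 and nu > 0, got mu={self.mu}, nu={self.nu}"
            )


@dataclass(frozen=True)
class ZetaReduction:
    """Mean zeta of the geometric law with 1 - 1/zeta = (1 - 1/mu)(1 - 1/nu)."""

    zeta: float


def zeta_mean(params: OverlapParams) -> ZetaReduction:
    """Combined geometric mean arising when the p_0 triple sum is reduced.

    Terms of the form ((1-1/mu)(1-1/nu))^l behave as tails of a geometric
    law with mean ``zeta = 1 / (1 - (1-1/mu)(1-1/nu))``; ``zeta <= min(mu, nu)``.
    """
    if params.mu < 1.0 or params.nu < 1.0:
        raise ValueError("zeta_mean requires mu >= 1 and nu >= 1")
    prod = (1.0 - 1.0 / params.mu) * (1.0 - 1.0 / params.nu)
    return ZetaReduction(zeta=1.0 / (1.0 - prod))


def _geom_pmf(l: int, mean: float) -> float:
    p = 1.0 / mean
    return p * (1.0 - p) ** (l - 1)


def p0_discrete_sum(params: OverlapParams, tail_tol: float = 1e-12) -> float:
    """p_0 by direct summation: the event starts uniformly inside a double run
    of length l (length-biased by l * rho(l) / nu) and must end strictly before
    the run's last gene.

    p0 = (1/nu) * sum_{l>2} rho(l) * sum_{a=1}^{l-2} (l - a - 1) gamma(a)

    The outer sum over l is truncated once the remaining mass of the
    length-biased law l * rho(l) / nu falls below ``tail_tol``.
    """
    params.validate_discrete()
    if not (0.0 < tail_tol <= 1e-6):
        raise ValueError(f"tail_tol must be in (0, 1e-6], got {tail_tol}")
    mu, nu = params.mu, params.nu
    r = 1.0 - 1.0 / nu  # rho ratio

    # inner(l) = sum_{a=1}^{l-2} (l - a - 1) * gamma(a); since every weight grows
    # by one as l -> l+1 and the entering a = l-1 term has weight 0,
    # inner(l+1) = inner(l) + GammaCDF(l-1).
    total = 0.0
    inner = _geom_pmf(1, mu)  # inner(3) = gamma(1)
    gamma_cdf = _geom_pmf(1, mu) + _geom_pmf(2, mu)  # GammaCDF(2)
    l = 3
    while l < _L_CAP:
        total += _geom_pmf(l, nu) * inner
        # remaining mass of the length-biased start law: sum_{k>l} k*rho(k)/nu
        tail = r**l * (1.0 + l * (1.0 - r))
        if tail < tail_tol:
            break
        inner += gamma_cdf
        l += 1
        gamma_cdf += _geom_pmf(l - 1, mu)
    else:
        raise RuntimeError(f"p0_discrete_sum did not converge within l <= {_L_CAP}")
    return total / nu


def p0_discrete_closed(params: OverlapParams) -> float:
    """Closed form of p_0: ``(nu - 1)^2 / ((mu + nu - 1) * nu)``."""
    params.validate_discrete()
    mu, nu = params.mu, params.nu
    return (nu - 1.0) ** 2 / ((mu + nu - 1.0) * nu)


def p0_discrete_approx(params: OverlapParams) -> float:
    """Large-nu approximation of p_0: ``nu/(mu+nu) * (1 - 1/nu)``.

    Accurate early in the process, when double-copy runs are still long.
    """
    if params.nu <= 1.0:
        raise ValueError(f"approximation requires nu > 1, got {params.nu}")
    mu, nu = params.mu, params.nu
    return nu / (mu + nu) * (1.0 - 1.0 / nu)


def pq_continuous(params: OverlapParams, q: int) -> float:
    """Probability a deletion event overlaps exactly q existing runs
    (continuous model): ``(nu/(mu+nu)) * (mu/(mu+nu))^q``.

    q is geometric on {0, 1, ...} with parameter mu/(mu+nu).
    """
    params.validate_continuous()
    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    mu, nu = params.mu, params.nu
    return (nu / (mu + nu)) * (mu / (mu + nu)) ** q


def pq_continuous_oracle(
    params: OverlapParams, q: int, quadrature_tol: float = 1e-8
) -> float:
    """p_q for q in {0, 1} by numerical quadrature of the defining integrals.

    The deletion length is exponential with mean mu (density f), the
    double-copy segment length exponential with mean nu (density sigma); the
    start point is chosen by segment-length bias then uniformly within the
    segment.  Serves as an independent check of ``pq_continuous``.
    """
    params.validate_continuous()
    if q not in (0, 1):
        raise ValueError("the quadrature oracle covers q in {0, 1} only")
    mu, nu = params.mu, params.nu

    def sigma(l: float) -> float:
        return math.exp(-l / nu) / nu

    def f_cdf(y: float) -> float:
        return -math.expm1(-y / mu) if y > 0.0 else 0.0

    if q == 0:
        # p0 = int_l sigma(l)/nu * int_{x=0}^{l} F(l - x) dx dl
        def inner(l: float) -> float:
            val, _ = integrate.quad(
                lambda x: f_cdf(l - x), 0.0, l, epsabs=quadrature_tol, epsrel=quadrature_tol
            )
            return sigma(l) / nu * val

        val, err = integrate.quad(
            inner, 0.0, math.inf, epsabs=quadrature_tol, epsrel=quadrature_tol, limit=200
        )
    else:
        # p1 = (1/nu) int_l int_z sigma(l) sigma(z)
        #          int_{x=0}^{l} [F(l-x+z) - F(l-x)] dx dz dl
        def inner_x(l: float, z: float) -> float:
            val, _ = integrate.quad(
                lambda x: f_cdf(l - x + z) - f_cdf(l - x),
                0.0,
                l,
                epsabs=quadrature_tol,
                epsrel=quadrature_tol,
            )
            return val

        def inner_z(l: float) -> float:
            val, _ = integrate.quad(
                lambda z: sigma(z) * inner_x(l, z),
                0.0,
                math.inf,
                epsabs=quadrature_tol,
                epsrel=quadrature_tol,
                limit=200,
            )
            return sigma(l) * val

        val, err = integrate.quad(
            inner_z, 0.0, math.inf, epsabs=quadrature_tol, epsrel=quadrature_tol, limit=200
        )
        val /= nu
    if err > max(quadrature_tol, 1e-6) * 10.0:
        raise RuntimeError(f"quadrature failed to reach tolerance (est. error {err:g})")
    return val
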