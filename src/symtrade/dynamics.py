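"""Symbiont biomass adjustment toward the trade equilibrium.

The exchange ratio r is fixed; supply–demand imbalance is cleared not by
price adjustment but by the Rhizobium population size sigma.  The
population's ATP budget is proportional to its size,
``b_R(sigma) = beta * sigma``, so the N it fixes is
``w(sigma) = beta * sigma / a_RN_hat``.  The excess supply of C,

    F(sigma) = h - c_L h/(c_L+r) - (c_R r/(c_R+r)) w(sigma),

drives the first-order adjustment ``dsigma/dt = rate * F(sigma)``: the
population grows while the legume's fixed C exceeds total C demand and
shrinks otherwise.  F is affine in sigma with negative slope, so the
process is globally asymptotically stable and the trajectory is the
exponential relaxation

    sigma(t) = sigma* + (sigma0 - sigma*) exp(-lambda t),

with decay rate ``lambda = rate * (c_R r/(c_R+r)) * beta / a_RN_hat``.
The fixed point satisfies ``w(sigma*) = w*``, the equilibrium box width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class AdjustmentParams:
    """Parameters of the biomass-adjustment ODE.

    ``beta`` is ATP budget per unit population size; with the default
    ``beta = a_RN_hat`` the fixed N equals sigma and population size is
    measured directly in mol N fixed per unit time.  ``rate_constant``
    scales d(sigma)/dt (time units are arbitrary).
    """

    h: float
    c_L: float
    c_R: float
    r: float
    a_RN_hat: float
    beta: Optional[float] = None
    rate_constant: float = 1.0

    def __post_init__(self) -> None:
        beta = self.a_RN_hat if self.beta is None else self.beta
        object.__setattr__(self, "beta", beta)
        for name in ("h", "c_L", "c_R", "r", "a_RN_hat", "beta", "rate_constant"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def fixed_n(self, sigma: float) -> float:
        """N fixed per unit time by a population of size sigma, w(sigma)."""
        return self.beta * sigma / self.a_RN_hat

    @property
    def decay_rate(self) -> float:
        """The exponential relaxation rate lambda of the linear ODE."""
        return (
            self.rate_constant
            * (self.c_R * self.r / (self.c_R + self.r))
            * self.beta
            / self.a_RN_hat
        )


@dataclass(frozen=True)
class AdjustmentTrajectory:
    """Sampled solution path: times, population sizes, excess C supply."""

    times: np.ndarray
    sigma: np.ndarray
    excess_C: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.sigma) == len(self.excess_C)):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def excess_carbon_supply(sigma: float, params: AdjustmentParams) -> float:
    """F(sigma): fixed C minus total C demand at population size sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x_LC = params.c_L * params.h / (params.c_L + params.r)
    x_RC = (params.c_R * params.r / (params.c_R + params.r)) * params.fixed_n(sigma)
    return params.h - x_LC - x_RC


def equilibrium_population(params: AdjustmentParams) -> float:
    """The globally stable fixed point sigma* with w(sigma*) = w*."""
    w_star = (params.c_R + params.r) * params.h / (params.c_R * (params.c_L + params.r))
    return params.a_RN_hat * w_star / params.beta


def analytic_solution(t: np.ndarray, sigma0: float, params: AdjustmentParams) -> np.ndarray:
    """Exact exponential relaxation of the affine ODE."""
    s_star = equilibrium_population(params)
    return s_star + (sigma0 - s_star) * np.exp(-params.decay_rate * np.asarray(t))


def simulate_adjustment(
    sigma0: float,
    params: AdjustmentParams,
    t_end: float,
    dt: Optional[float] = None,
) -> AdjustmentTrajectory:
    """Integrate d(sigma)/dt = rate * F(sigma) with classical RK4.

    The default step is 0.01 of the relaxation time 1/lambda.  The ODE
    is affine, so the numerical path is checked in the test-suite
    against :func:`analytic_solution`.  Sigma is clipped at 0 should a
    large user-supplied step undershoot (population size cannot be
    negative); at the default step this never triggers.
    """
    if not math.isfinite(sigma0) or sigma0 < 0:
        raise ValueError(f"sigma0 must be finite and >= 0, got {sigma0!r}")
    if not math.isfinite(t_end) or t_end <= 0:
        raise ValueError(f"t_end must be finite and > 0, got {t_end!r}")
    if dt is None:
        dt = 0.01 / params.decay_rate
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")

    def rhs(s: float) -> float:
        return params.rate_constant * excess_carbon_supply(max(s, 0.0), params)

    n_steps = max(1, int(math.ceil(t_end / dt)))
    times = np.linspace(0.0, t_end, n_steps + 1)
    sigma = np.empty(n_steps + 1)
    sigma[0] = sigma0
    s = sigma0
    for i in range(1, n_steps + 1):
        step = times[i] - times[i - 1]
        k1 = rhs(s)
        k2 = rhs(s + 0.5 * step * k1)
        k3 = rhs(s + 0.5 * step * k2)
        k4 = rhs(s + step * k3)
        s = max(s + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        sigma[i] = s

    excess = np.array([excess_carbon_supply(si, params) for si in sigma])
    return AdjustmentTrajectory(times=times, sigma=sigma, excess_C=excess)
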