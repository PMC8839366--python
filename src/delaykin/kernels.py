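"""Shifted-gamma delay distributions.

A distributed delay attributes product formation at time ``t`` to reactant
encounters at earlier times ``t + s`` (``s < 0``), weighted by a probability
density ``f`` of the delay.  The density used throughout this package is a
gamma distribution shifted by a minimal delay ``tau_min``::

    f(s) = 0                                               s <= tau_min
    f(s) = a^(m+1)/Gamma(m+1) * (s - tau_min)^m * exp(-a (s - tau_min)),
                                                           s >  tau_min

with rate ``a > 0`` (1/s), shape ``m >= 0`` (the classical gamma shape is
``m + 1``) and shift ``tau_min >= 0`` (s).  The distribution has mean
``tau_min + (m+1)/a`` and variance ``(m+1)/a**2``.

Distributed-delay integrals run over an infinite history.  They are reduced
to a finite window ``[-tau_M, 0]`` by a Chebyshev bound: for a confidence
level ``c`` in (0, 1),

    tau_M = E(tau) + sqrt(Var(tau) / (1 - c))

guarantees that at least a fraction ``c`` of the delay mass lies below
``tau_M`` (Chebyshev is conservative; the actual gamma CDF at ``tau_M`` is
well above ``c``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "DEFAULT_CONFIDENCE",
    "GammaDelayKernel",
    "TruncationRule",
    "Quadrature",
    "kernel_density",
    "kernel_moments",
    "truncation_bound",
    "kernel_weights",
]

#: Default confidence level for Chebyshev truncation of the delay density.
DEFAULT_CONFIDENCE = 0.95


class KernelParameterError(ValueError):
    """Raised for delay-kernel parameters outside their domain."""


@dataclass(frozen=True)
class GammaDelayKernel:
    """Shifted gamma delay density ``f(a, m, tau_min, s)``.

    Parameters
    ----------
    rate_a
        Rate parameter ``a`` (1/s); must be positive.
    shape_m
        Shape offset ``m`` (dimensionless); the gamma shape is ``m + 1``.
        Must be nonnegative.  ``m = 0`` reduces to a shifted exponential.
    tau_min
        Minimal possible delay (s); the density is zero at and below it.
    """

    rate_a: float
    shape_m: float = 0.0
    tau_min: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rate_a) and self.rate_a > 0):
            raise KernelParameterError(f"rate_a must be positive, got {self.rate_a}")
        if not (np.isfinite(self.shape_m) and self.shape_m >= 0):
            raise KernelParameterError(f"shape_m must be >= 0, got {self.shape_m}")
        if not (np.isfinite(self.tau_min) and self.tau_min >= 0):
            raise KernelParameterError(f"tau_min must be >= 0, got {self.tau_min}")

    # -- scipy frozen distribution of the unshifted part -------------------
    def _gamma(self):
        return stats.gamma(a=self.shape_m + 1.0, scale=1.0 / self.rate_a)

    @property
    def mean(self) -> float:
        """Mean delay ``tau_min + (m + 1)/a`` (s)."""
        return self.tau_min + (self.shape_m + 1.0) / self.rate_a

    @property
    def variance(self) -> float:
        """Delay variance ``(m + 1)/a**2`` (s^2)."""
        return (self.shape_m + 1.0) / self.rate_a**2

    def density(self, s):
        """Density evaluated at delay ``s`` (scalar or array); 0 for ``s <= tau_min``."""
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        pos = s > self.tau_min
        if np.any(pos):
            x = s[pos] - self.tau_min
            m, a = self.shape_m, self.rate_a
            log_f = (m + 1.0) * math.log(a) - gammaln(m + 1.0) + m * np.log(x) - a * x
            out[pos] = np.exp(log_f)
        return out if out.ndim else float(out)

    def cdf(self, s) -> float:
        """Cumulative delay mass on ``(tau_min, s]``."""
        s = np.asarray(s, dtype=float)
        out = self._gamma().cdf(np.maximum(s - self.tau_min, 0.0))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class TruncationRule:
    """Finite truncation ``tau_M`` of a delay density at confidence ``c``.

    ``tau_M`` is derived from the kernel via the Chebyshev bound; the mass of
    the kernel on ``(tau_min, tau_M]`` is guaranteed to be at least ``c``.
    """

    confidence_c: float
    tau_M: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence_c < 1.0):
            raise KernelParameterError(
                f"confidence must be in (0, 1), got {self.confidence_c}"
            )
        if self.tau_M is not None and self.tau_M <= 0:
            raise KernelParameterError(f"tau_M must be positive, got {self.tau_M}")


def kernel_density(kernel: GammaDelayKernel, s) -> float:
    """Evaluate the shifted-gamma delay density at delay ``s`` (1/s)."""
    return kernel.density(s)


def kernel_moments(kernel: GammaDelayKernel) -> tuple[float, float]:
    """Return ``(mean, variance)`` of the delay distribution in (s, s^2)."""
    return kernel.mean, kernel.variance


def truncation_bound(
    kernel: GammaDelayKernel, c: float = DEFAULT_CONFIDENCE
) -> TruncationRule:
    """Chebyshev upper delay bound at confidence ``c``.

    Returns a :class:`TruncationRule` with
    ``tau_M = mean + sqrt(variance / (1 - c))``; the gamma CDF at ``tau_M``
    is at least ``c`` (typically much larger, Chebyshev being conservative).
    """
    if not (0.0 < c < 1.0):
        raise KernelParameterError(f"confidence must be in (0, 1), got {c}")
    tau_M = kernel.mean + math.sqrt(kernel.variance / (1.0 - c))
    return TruncationRule(confidence_c=c, tau_M=tau_M)


class ResolutionError(ValueError):
    """Raised when the quadrature step cannot resolve the truncated window."""


@dataclass(frozen=True)
class Quadrature:
    """Uniform quadrature of a truncated delay density.

    ``nodes`` are nonpositive lag times ``s_k = -k * step`` spanning
    ``[-tau_M_snapped, 0]``; ``weights[k]`` approximates the density mass
    attached to lag ``-nodes[k]``.  ``weights`` follow the composite
    trapezoid rule on the uniform grid and are *unnormalized* by default:
    their sum approximates the kernel mass on ``(tau_min, tau_M]``, which is
    below 1 by the truncation deficit.
    """

    nodes: np.ndarray
    weights: np.ndarray
    step: float
    tau_M_snapped: float

    @property
    def lag_steps(self) -> int:
        return len(self.weights) - 1


def kernel_weights(
    kernel: GammaDelayKernel,
    rule: TruncationRule,
    step: float,
    renormalize: bool = False,
) -> Quadrature:
    """Discretize the truncated delay integral on a uniform lag grid.

    ``tau_M`` is rounded *up* to an integer multiple of ``step`` so that the
    quadrature nodes align with the integrator's stored trajectory nodes.
    With ``renormalize=True`` the weights are rescaled to sum exactly to 1
    (mass conservation); by default they are left unnormalized, matching the
    untruncated density integrated over a truncated range.
    """
    if step <= 0:
        raise ResolutionError(f"step must be positive, got {step}")
    tau_M = rule.tau_M
    if tau_M is None:
        raise KernelParameterError("TruncationRule carries no tau_M")
    if step >= tau_M:
        raise ResolutionError(f"step {step} does not resolve tau_M {tau_M}")
    n = math.ceil(tau_M / step - 1e-9)
    tau_M_snapped = n * step
    lags = np.arange(n + 1) * step
    f = kernel.density(lags)
    weights = f * step
    weights[0] *= 0.5
    weights[-1] *= 0.5
    if renormalize:
        total = weights.sum()
        if total <= 0:
            raise ResolutionError("kernel mass on the truncated window is zero")
        weights = weights / total
    return Quadrature(
        nodes=-lags, weights=weights, step=step, tau_M_snapped=tau_M_snapped
    )
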