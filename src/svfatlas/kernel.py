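"""Gaussian kernel regression weights on gestational age.

Subjects contribute to the template at age ``t`` with weights from a
normalized Gaussian centered at ``t``. Weights beyond a hard truncation
window (one week by default) are set exactly to zero before renormalization,
so distant ages never influence a timepoint. The bandwidth ``sigma_t`` adapts
to the local density of ages: it is the smallest value whose effective sample
size over the untruncated window reaches a configured minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelConfig", "KernelWeights", "compute_weights", "adapt_sigma"]


class NoSupportError(ValueError):
    """No subject lies within the truncation window of the requested age."""


@dataclass
class KernelConfig:
    """Bandwidth and truncation policy.

    truncation : half-width (weeks) of the hard support window.
    sigma_min / sigma_max : bandwidth bounds (weeks).
    n_eff_min : minimum effective sample size targeted by adapt_sigma.
    sigma : fixed bandwidth; when set, adaptation is skipped.
    """

    truncation: float = 1.0
    sigma_min: float = 0.25
    sigma_max: float = 1.0
    n_eff_min: float = 5.0
    sigma: float | None = None


@dataclass
class KernelWeights:
    """Normalized per-subject weights at a target age."""

    weights: np.ndarray
    t: float
    sigma_t: float
    support: np.ndarray = field(default=None)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.support is None:
            self.support = np.flatnonzero(self.weights > 0)


def _gaussian(ages: np.ndarray, t: float, sigma: float) -> np.ndarray:
    return np.exp(-((ages - t) ** 2) / (2.0 * sigma ** 2)) / (sigma * np.sqrt(2.0 * np.pi))


def adapt_sigma(ages, t: float, config: KernelConfig | None = None) -> float:
    """Smallest bandwidth in [sigma_min, sigma_max] whose effective sample
    size (Σg)²/Σg² over the untruncated window reaches ``n_eff_min``.

    The ESS is monotone non-decreasing in sigma, so a bisection suffices; if
    even sigma_max falls short, sigma_max is returned (the caps always apply).
    """
    config = config or KernelConfig()
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise NoSupportError("adapt_sigma requires at least one age")
    window = np.abs(ages - t) <= config.truncation
    if not np.any(window):
        return config.sigma_max

    def ess(sigma: float) -> float:
        g = _gaussian(ages[window], t, sigma)
        s = g.sum()
        if s == 0:
            return 0.0
        return s * s / (g * g).sum()

    if ess(config.sigma_min) >= config.n_eff_min:
        return config.sigma_min
    if ess(config.sigma_max) < config.n_eff_min:
        return config.sigma_max
    lo, hi = config.sigma_min, config.sigma_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ess(mid) >= config.n_eff_min:
            hi = mid
        else:
            lo = mid
    return hi


def compute_weights(ages, t: float, config: KernelConfig | None = None) -> KernelWeights:
    """Truncated, normalized Gaussian weights at target age ``t``.

    Truncation is applied first (weights at |t_i - t| > truncation are exactly
    zero), then the surviving weights are renormalized to sum to 1.
    """
    config = config or KernelConfig()
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise NoSupportError(f"no ages supplied for target age t={t}")
    inside = np.abs(ages - t) <= config.truncation
    if not np.any(inside):
        raise NoSupportError(
            f"no subject within {config.truncation} weeks of target age t={t}")
    sigma = config.sigma if config.sigma is not None else adapt_sigma(ages, t, config)
    g = _gaussian(ages, t, sigma)
    g[~inside] = 0.0
    weights = g / g.sum()
    return KernelWeights(weights=weights, t=float(t), sigma_t=float(sigma))
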