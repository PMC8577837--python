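"""Scalar count-distribution primitives.

Poisson and Conway-Maxwell-Poisson (CoM-Poisson) probability mass
functions, truncated log-partition functions, and moments.

The CoM-Poisson distribution ``p(n) ∝ (λ^n / n!)^ν`` decouples the
location ``λ`` from the shape ``ν``: ``ν = 1`` recovers a Poisson with
rate ``λ``, ``ν > 1`` concentrates the distribution (under-dispersion,
Fano factor < 1) and ``0 < ν < 1`` disperses it.  In exponential-family
coordinates the natural parameters are ``θ = ν·log λ`` (location) and
``θ* = −ν`` (shape), with sufficient statistic ``(n, log n!)``.  The
log-partition function has no closed form and is approximated by
truncating the series ``Σ_n exp(n·θ + log(n!)·θ*)``; the series
converges only for ``θ* < 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ComNatural",
    "Truncation",
    "log_factorial",
    "poisson_log_pmf",
    "com_log_partition",
    "com_log_pmf_table",
    "com_moments",
    "com_mode",
]

#: Hard ceiling on series truncation; exceeding it signals runaway parameters.
MAX_TRUNCATION = 20_000


@dataclass(frozen=True)
class ComNatural:
    """Natural parameters of one or more CoM-Poisson distributions.

    Parameters
    ----------
    theta_n : array_like
        Location natural parameters, ``ν·log λ`` (dimensionless).
    theta_star : array_like
        Shape natural parameters, ``−ν``; must be strictly negative for
        the log-partition series to converge.  ``theta_star = −1``
        recovers a Poisson with rate ``exp(theta_n)``.
    """

    theta_n: np.ndarray
    theta_star: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta_n", np.asarray(self.theta_n, dtype=float))
        object.__setattr__(self, "theta_star", np.asarray(self.theta_star, dtype=float))
        if np.any(self.theta_star >= 0):
            raise ValueError("theta_star must be strictly negative (ν > 0); "
                             "the CoM-Poisson series diverges otherwise")

    @property
    def mode_location(self) -> np.ndarray:
        """The location parameter ``λ = exp(θ/ν)`` whose floor is the mode."""
        return np.exp(self.theta_n / (-self.theta_star))


@dataclass(frozen=True)
class Truncation:
    """Series-truncation policy for CoM-Poisson summations.

    ``max_count=None`` selects the cutoff adaptively per call as
    ``max(128, ceil(10 · λ))`` over the parameters involved, which keeps
    the neglected tail mass below ~1e−12 in the regimes exercised here.
    """

    max_count: int | None = None

    def __post_init__(self):
        if self.max_count is not None and self.max_count < 1:
            raise ValueError("max_count must be >= 1")

    def resolve(self, params: ComNatural) -> int:
        if self.max_count is not None:
            return int(self.max_count)
        lam = np.max(params.mode_location) if params.theta_n.size else 1.0
        cutoff = int(max(128, np.ceil(10.0 * max(lam, 1.0))))
        if cutoff > MAX_TRUNCATION:
            raise ValueError(
                f"required truncation {cutoff} exceeds ceiling {MAX_TRUNCATION}; "
                "location parameters are implausibly large")
        return cutoff


DEFAULT_TRUNCATION = Truncation()


def log_factorial(n) -> np.ndarray:
    """``log n!`` through the log-gamma function (exact for large n)."""
    return gammaln(np.asarray(n, dtype=float) + 1.0)


def _validate_counts(n) -> np.ndarray:
    arr = np.asarray(n)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("counts must be integers")
        arr = arr.astype(np.int64)
    return arr


def poisson_log_pmf(n, log_rate) -> np.ndarray:
    """Log-pmf of a Poisson distribution, ``n·log λ − λ − log n!``.

    Broadcasts over arrays of counts and log-rates.
    """
    n = _validate_counts(n)
    log_rate = np.asarray(log_rate, dtype=float)
    return n * log_rate - np.exp(log_rate) - log_factorial(n)


def _series_logits(params: ComNatural, max_count: int) -> np.ndarray:
    """Unnormalized log-masses ``n·θ + log(n!)·θ*`` on ``n = 0..max_count``.

    Output shape is ``params.theta_n.shape + (max_count + 1,)``.
    """
    ns = np.arange(max_count + 1, dtype=float)
    lf = gammaln(ns + 1.0)
    theta_n = params.theta_n[..., None]
    theta_star = params.theta_star[..., None]
    return ns * theta_n + lf * theta_star


def com_log_partition(params: ComNatural, trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Truncated log-partition ``log Σ_{n≤M} exp(n·θ + log(n!)·θ*)``.

    Monotone non-decreasing in the cutoff M; converges to the exact
    log normalizer as M → ∞.  Elementwise over ``params``.
    """
    m = trunc.resolve(params)
    return logsumexp(_series_logits(params, m), axis=-1)


def com_log_pmf_table(params: ComNatural, trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Normalized log-pmf on the truncated support ``0..M`` (last axis)."""
    m = trunc.resolve(params)
    logits = _series_logits(params, m)
    return logits - logsumexp(logits, axis=-1, keepdims=True)


def com_moments(params: ComNatural, trunc: Truncation = DEFAULT_TRUNCATION):
    """Mean and variance of CoM-Poisson distributions by truncated summation.

    Returns ``(mean, variance)`` arrays with the shape of ``params.theta_n``.
    In the regime where neither λ nor ν is small these are approximately
    ``λ + 1/(2ν) − 1/2`` and ``λ/ν``.
    """
    table = np.exp(com_log_pmf_table(params, trunc))
    ns = np.arange(table.shape[-1], dtype=float)
    mean = table @ ns
    second = table @ (ns * ns)
    return mean, second - mean**2


def com_mean_log_factorial(params: ComNatural, trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """``E[log n!]`` by truncated summation (the CoM shape-statistic mean)."""
    table = np.exp(com_log_pmf_table(params, trunc))
    ns = np.arange(table.shape[-1], dtype=float)
    return table @ gammaln(ns + 1.0)


def com_mode(params: ComNatural) -> np.ndarray:
    """Mode of a CoM-Poisson distribution: ``floor(λ)`` with ``λ = exp(θ/ν)``.

    A relative epsilon guards against ``exp(θ/ν)`` landing a last-bit
    below an integral λ.
    """
    loc = params.mode_location
    return np.floor(loc * (1.0 + 1e-12) + 1e-12).astype(np.int64)
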