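"""Stimulus-independent multivariate spike-count mixtures.

A finite mixture of independent-Poisson (IP) populations is written as a
latent-variable exponential family over counts ``n`` and a component
index ``k``::

    p(n, k) ∝ exp(θN·n + θK·δ(k) + n·ΘNK·δ(k)) / Π_i n_i!

with ``δ(k)`` the (dK−1)-element one-hot vector of components 2..dK
(component 1 is the baseline, ``δ(1) = 0``).  The CoM-based (CB)
extension adds a shape term ``θN*·lf(n)`` with ``lf(n) = (log n_1!, …)``,
making each component a product of independent CoM-Poisson
distributions; ``θN* = −1`` recovers the IP mixture exactly.

Although every component is a product of independent count
distributions, randomly switching between components induces
correlations between neurons, and with enough components a mixture can
reproduce any covariance matrix.

Component-axis convention: ``ΘNK`` is dN × (dK−1); component ``k`` (for
k ≥ 1 zero-based, i.e. the non-baseline components) uses column ``k−1``.
Component indices are zero-based throughout the code; the baseline
component is ``k = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .countdist import (
    ComNatural,
    Truncation,
    DEFAULT_TRUNCATION,
    com_log_partition,
    com_log_pmf_table,
    com_moments,
    com_mean_log_factorial,
    log_factorial,
)

__all__ = [
    "WeightsRates",
    "MixtureNatural",
    "MixtureMoments",
    "natural_from_weights_rates",
    "weights_rates_from_natural",
    "log_partition",
    "joint_log_pmf",
    "index_log_probabilities",
    "component_params",
    "observable_log_pmf",
    "moments",
    "sample",
]


@dataclass(frozen=True)
class WeightsRates:
    """Mixture in its intuitive parameterization: weights and firing rates.

    Parameters
    ----------
    weights : (dK,) array
        Mixture weights, strictly positive, summing to 1.
    rates : (dK, dN) array
        Per-component firing-rate vectors (spikes/trial), strictly positive.
    """

    weights: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        r = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if np.any(w <= 0) or np.any(r <= 0):
            raise ValueError("weights and rates must be strictly positive for the "
                             "natural parameters to be well-defined")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if r.shape[0] != w.shape[0]:
            raise ValueError("rates must have one row per weight")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "rates", r)

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]


@dataclass(frozen=True)
class MixtureNatural:
    """Natural parameters (θN, θN*, θK, ΘNK) of an IP or CB mixture.

    ``theta_star=None`` denotes the IP family (implicitly θN* ≡ −1).
    """

    theta_n: np.ndarray
    theta_k: np.ndarray
    theta_nk: np.ndarray
    theta_star: np.ndarray | None = None

    def __post_init__(self):
        tn = np.asarray(self.theta_n, dtype=float)
        tk = np.asarray(self.theta_k, dtype=float)
        tnk = np.asarray(self.theta_nk, dtype=float).reshape(tn.shape[0], -1)
        if tk.shape[0] != tnk.shape[1]:
            raise ValueError("theta_k and theta_nk disagree on the number of components")
        for name, arr in (("theta_n", tn), ("theta_k", tk), ("theta_nk", tnk)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        object.__setattr__(self, "theta_n", tn)
        object.__setattr__(self, "theta_k", tk)
        object.__setattr__(self, "theta_nk", tnk)
        if self.theta_star is not None:
            ts = np.asarray(self.theta_star, dtype=float)
            if ts.shape != tn.shape:
                raise ValueError("theta_star must match theta_n in shape")
            if np.any(ts >= 0):
                raise ValueError("theta_star must be strictly negative")
            object.__setattr__(self, "theta_star", ts)

    @property
    def n_neurons(self) -> int:
        return self.theta_n.shape[0]

    @property
    def n_components(self) -> int:
        return self.theta_k.shape[0] + 1

    @property
    def is_cb(self) -> bool:
        return self.theta_star is not None

    def effective_theta_star(self) -> np.ndarray:
        """θN* as used in the density: the stored vector, or −1 for IP."""
        if self.theta_star is not None:
            return self.theta_star
        return np.full(self.n_neurons, -1.0)

    def component_matrix(self) -> np.ndarray:
        """(dN, dK) matrix of per-component location natural parameters."""
        cols = np.concatenate(
            [np.zeros((self.n_neurons, 1)), self.theta_nk], axis=1)
        return self.theta_n[:, None] + cols

    def theta_k_full(self) -> np.ndarray:
        """(dK,) categorical natural parameters with the baseline 0 prepended."""
        return np.concatenate([[0.0], self.theta_k])


@dataclass(frozen=True)
class MixtureMoments:
    """First and second moments of a mixture: mean, covariance, Fano factors."""

    mean: np.ndarray
    covariance: np.ndarray
    fano: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.fano is None:
            object.__setattr__(
                self, "fano", np.diag(self.covariance) / self.mean)


def _psi_n(theta: np.ndarray) -> np.ndarray:
    """IP log-partition ψN(θ) = Σ_i exp(θ_i), summed over the first axis."""
    return np.exp(theta).sum(axis=0)


def component_log_partitions(params: MixtureNatural,
                             trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """(dK,) vector of per-component log-partitions ψ(θN + ΘNK·δ(k))."""
    comp = params.component_matrix()
    if not params.is_cb:
        return _psi_n(comp)
    com = ComNatural(comp, np.broadcast_to(
        params.theta_star[:, None], comp.shape))
    return com_log_partition(com, trunc).sum(axis=0)


def natural_from_weights_rates(model: WeightsRates) -> MixtureNatural:
    """Reparameterize an IP mixture from (weights, rates) to natural form.

    θN = log λ_1; column k−1 of ΘNK = log λ_k − log λ_1; and
    θK,k = log(w_{k+1}/w_1) + ψN(θN) − ψN(θN + ΘNK·δ(k)).
    Exact inverse of :func:`weights_rates_from_natural`.
    """
    log_rates = np.log(model.rates)
    theta_n = log_rates[0]
    theta_nk = (log_rates[1:] - log_rates[0]).T
    psi_base = _psi_n(theta_n[:, None])[0]
    psi_comp = _psi_n(theta_n[:, None] + theta_nk)
    theta_k = (np.log(model.weights[1:] / model.weights[0])
               + psi_base - psi_comp)
    return MixtureNatural(theta_n, theta_k, theta_nk)


def weights_rates_from_natural(params: MixtureNatural,
                               trunc: Truncation = DEFAULT_TRUNCATION) -> WeightsRates:
    """Recover weights and component rates from natural parameters.

    For an IP mixture this is the exact inverse of
    :func:`natural_from_weights_rates`; for a CB mixture the "rates" are
    the per-component CoM-Poisson means (by truncated summation).
    """
    log_w = index_log_probabilities(params, trunc)
    comp = params.component_matrix()
    if params.is_cb:
        com = ComNatural(comp, np.broadcast_to(
            params.theta_star[:, None], comp.shape))
        means, _ = com_moments(com, trunc)
        rates = means.T
    else:
        rates = np.exp(comp).T
    w = np.exp(log_w)
    return WeightsRates(w / w.sum(), rates)


def log_partition(params: MixtureNatural,
                  trunc: Truncation = DEFAULT_TRUNCATION) -> float:
    """Mixture log-partition ψNK (IP) or ψCK (CB).

    ``log Σ_k exp(θK·δ(k) + ψ(θN + ΘNK·δ(k)))`` with ψ the IP or
    truncated CoM log-partition of the component.
    """
    return float(logsumexp(params.theta_k_full()
                           + component_log_partitions(params, trunc)))


def index_log_probabilities(params: MixtureNatural,
                            trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Log index-probabilities log p(k), a (dK,) log-simplex."""
    logits = params.theta_k_full() + component_log_partitions(params, trunc)
    return logits - logsumexp(logits)


def component_params(params: MixtureNatural, k: int) -> ComNatural:
    """Natural parameters of component ``k`` (zero-based; k=0 is baseline).

    The location parameters are θN (+ column k−1 of ΘNK for k ≥ 1); the
    shape parameters θN* are shared by every component.
    """
    if not 0 <= k < params.n_components:
        raise IndexError(f"component {k} out of range [0, {params.n_components})")
    theta = params.theta_n if k == 0 else params.theta_n + params.theta_nk[:, k - 1]
    return ComNatural(theta, params.effective_theta_star())


def _log_density_terms(params: MixtureNatural, counts: np.ndarray,
                       trunc: Truncation) -> np.ndarray:
    """(T, dK) unnormalized joint log-densities log p(n, k) + ψ."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    comp = params.component_matrix()
    base = log_factorial(counts) @ params.effective_theta_star()
    return counts @ comp + base[:, None] + params.theta_k_full()[None, :]


def joint_log_pmf(params: MixtureNatural, counts, k: int,
                  trunc: Truncation = DEFAULT_TRUNCATION) -> float:
    """Joint log-density log p(n, k) at one count vector and component."""
    if not 0 <= k < params.n_components:
        raise IndexError(f"component {k} out of range [0, {params.n_components})")
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    terms = _log_density_terms(params, counts, trunc)
    return float(terms[0, k] - log_partition(params, trunc))


def observable_log_pmf(params: MixtureNatural, counts,
                       trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Marginal log-density log p(n) = log Σ_k p(n, k).

    Accepts a single count vector or a (T, dN) array of trials; returns
    a scalar or a (T,) vector accordingly.
    """
    counts = np.asarray(counts)
    single = counts.ndim == 1
    terms = _log_density_terms(params, counts, trunc)
    out = logsumexp(terms, axis=1) - log_partition(params, trunc)
    return float(out[0]) if single else out


def moments(params: MixtureNatural,
            trunc: Truncation = DEFAULT_TRUNCATION) -> MixtureMoments:
    """Mean vector, covariance matrix, and Fano factors of the mixture.

    μ_i = Σ_k w_k μ_ik;  σ_ij = Σ_k w_k (μ_ik − μ_i)(μ_jk − μ_j) for
    i ≠ j, with the within-component variance Σ_k w_k σ²_ik added on the
    diagonal.  For IP components μ_ik = σ²_ik = λ_ik, so every Fano
    factor is ≥ 1; CB components can push variances below means.
    """
    w = np.exp(index_log_probabilities(params, trunc))
    comp = params.component_matrix()
    if params.is_cb:
        com = ComNatural(comp, np.broadcast_to(
            params.theta_star[:, None], comp.shape))
        mu_k, var_k = com_moments(com, trunc)
    else:
        mu_k = np.exp(comp)
        var_k = mu_k
    mean = mu_k @ w
    centred = mu_k - mean[:, None]
    cov = (centred * w) @ centred.T
    cov[np.diag_indices_from(cov)] += var_k @ w
    return MixtureMoments(mean, cov)


def sample(params: MixtureNatural, m: int, seed,
           trunc: Truncation = DEFAULT_TRUNCATION,
           return_indices: bool = False):
    """Draw ``m`` count vectors by ancestral sampling.

    A component index is drawn from p(k), then each neuron's count from
    that component by inverse-CDF on its truncated pmf.  The same
    inverse-CDF path is used for IP and CB components, so an IP mixture
    and the equivalent CB mixture (θN* = −1) yield identical samples at
    the same seed.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w = np.exp(index_log_probabilities(params, trunc))
    ks = rng.choice(params.n_components, size=m, p=w / w.sum())
    comp = params.component_matrix()
    com = ComNatural(comp, np.broadcast_to(
        params.effective_theta_star()[:, None], comp.shape))
    cdf = np.cumsum(np.exp(com_log_pmf_table(com, trunc)), axis=-1)  # (dN, dK, M+1)
    u = rng.random((m, params.n_neurons))
    counts = np.empty((m, params.n_neurons), dtype=np.int64)
    top = cdf.shape[-1] - 1
    for k in np.unique(ks):
        rows = ks == k
        for i in range(params.n_neurons):
            counts[rows, i] = np.minimum(
                np.searchsorted(cdf[i, k], u[rows, i], side="left"), top)
    if return_indices:
        return counts, ks
    return counts


def to_dict(params: MixtureNatural) -> dict:
    """JSON-serializable form of the natural parameters."""
    out = {
        "schema_version": 1,
        "component_axis": "columns",
        "family": "cb" if params.is_cb else "ip",
        "n_neurons": params.n_neurons,
        "n_components": params.n_components,
        "theta_n": params.theta_n.tolist(),
        "theta_k": params.theta_k.tolist(),
        "theta_nk": params.theta_nk.tolist(),
    }
    if params.is_cb:
        out["theta_star"] = params.theta_star.tolist()
    return out


def from_dict(doc: dict) -> MixtureNatural:
    """Inverse of :func:`to_dict`."""
    theta_star = doc.get("theta_star")
    return MixtureNatural(
        np.asarray(doc["theta_n"], dtype=float),
        np.asarray(doc["theta_k"], dtype=float),
        np.asarray(doc["theta_nk"], dtype=float).reshape(doc["n_neurons"], -1),
        None if theta_star is None else np.asarray(theta_star, dtype=float),
    )
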