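"""Synthetic populations: randomized ground-truth CMs and information-limited data.

Two generators are provided.

``random_ground_truth_cm`` draws a von Mises conditional mixture with
randomized tuning: preferred stimuli tiled over the (doubled-angle)
circle, log-normal concentrations and gains, normal gain modulations,
and uniform CoM shape parameters.  An optional second stage re-centres
the index-probability natural parameters so that no single component
dominates any orientation, and converts the smooth model to a discrete
lookup over a condition grid — the construction used for decoder
benchmarks on larger populations.

``info-limited`` generators emulate information-limiting correlations: a
source population of conditionally independent Poisson neurons with
homogeneous von Mises tuning responds to a *noisy* orientation
``s ~ p(s|x)`` (von Mises around the true stimulus x).  Marginally over
s the responses are correlated, and the Fisher information about x is
bounded by the precision of the sensory noise no matter how many
neurons are observed, while the information about s itself grows
linearly with population size.

All generators are pure functions of (recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ive

from .countdist import Truncation, DEFAULT_TRUNCATION
from .mixture import sample as mixture_sample
from .conditional import ConditionalMixture, VonMisesMap, DiscreteMap

__all__ = [
    "RandomCmRecipe",
    "InfoLimitedRecipe",
    "random_ground_truth_cm",
    "generate_dataset",
    "info_limited_sample",
    "generate_info_limited_dataset",
    "source_population",
    "source_fi_curve",
    "noise_channel_fi_bound",
]


@dataclass(frozen=True)
class RandomCmRecipe:
    """Randomization laws for a ground-truth von Mises CM.

    Concentrations and gains are log-normal (log κ_i ~ N(−0.1, 0.2),
    log γ_i ~ N(0.2, 0.1), parameters are mean and SD of the log), gain
    modulations [ΘNK]_{ik} ~ N(0.2, 0.1), CoM shape parameters
    θN*_i ~ U(−1.5, −0.8), and preferred stimuli are tiled,
    ρ_i = (i/dN)·360° on the doubled-angle circle (i.e. preferred
    orientations tile 0–180°).
    """

    n_neurons: int = 20
    n_components: int = 5
    family: str = "cb"
    kappa_log_mean: float = -0.1
    kappa_log_sd: float = 0.2
    gain_log_mean: float = 0.2
    gain_log_sd: float = 0.1
    modulation_mean: float = 0.2
    modulation_sd: float = 0.1
    theta_star_low: float = -1.5
    theta_star_high: float = -0.8
    #: second-stage options ("model 2"): re-centre θK so that several
    #: components stay active at every orientation, and/or convert the
    #: smooth model into a discrete lookup over these condition labels.
    recenter_index_params: bool = False
    discretize_levels: tuple | None = None
    recenter_grid_size: int = 360


def _log_bessel_i0(kappa):
    """log I0(κ), the von Mises log-partition, overflow-safe."""
    return np.log(ive(0, kappa)) + np.abs(kappa)


def random_ground_truth_cm(recipe: RandomCmRecipe, seed,
                           trunc: Truncation = DEFAULT_TRUNCATION) -> ConditionalMixture:
    """Draw a randomized ground-truth conditional mixture.

    The baseline component of neuron i has a von Mises tuning curve with
    gain γ_i at its preferred orientation: θNX,i = (κ_i cos ρ_i,
    κ_i sin ρ_i) and θN0,i = log γ_i − log I0(κ_i).
    """
    rng = np.random.default_rng(seed)
    dn, dk = recipe.n_neurons, recipe.n_components
    rho = np.deg2rad(np.arange(dn) / dn * 360.0)       # doubled-angle radians
    kappa = np.exp(rng.normal(recipe.kappa_log_mean, recipe.kappa_log_sd, dn))
    gain = np.exp(rng.normal(recipe.gain_log_mean, recipe.gain_log_sd, dn))
    theta_nx = np.column_stack([kappa * np.cos(rho), kappa * np.sin(rho)])
    theta_n0 = np.log(gain) - _log_bessel_i0(kappa)
    theta_k = np.zeros(dk - 1)
    theta_nk = rng.normal(recipe.modulation_mean, recipe.modulation_sd,
                          size=(dn, dk - 1))
    theta_star = (rng.uniform(recipe.theta_star_low, recipe.theta_star_high, dn)
                  if recipe.family == "cb" else None)
    cm = ConditionalMixture("von_mises", recipe.family,
                            stimulus_map=VonMisesMap(theta_n0, theta_nx),
                            theta_k=theta_k, theta_nk=theta_nk,
                            theta_star=theta_star)
    if recipe.recenter_index_params:
        cm = _recenter_index_params(cm, recipe.recenter_grid_size, trunc)
    if recipe.discretize_levels is not None:
        cm = _discretize(cm, recipe.discretize_levels)
    return cm


def index_natural_param_curves(cm: ConditionalMixture, xs,
                               trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """θK⁰(x): categorical natural parameters of p(k|x) relative to component 1.

    Shape (dK−1, X): entry k is θK,k + ψ(θ_k(x)) − ψ(θ_1(x)).
    """
    from .em import _component_stats
    out = np.empty((cm.n_components - 1, len(xs)))
    for j, x in enumerate(xs):
        mix = cm.mixture_at(x)
        psi_k, _, _ = _component_stats(mix, trunc, need_lf=False)
        out[:, j] = cm.theta_k + psi_k[1:] - psi_k[0]
    return out


def _recenter_index_params(cm: ConditionalMixture, grid_size: int,
                           trunc: Truncation) -> ConditionalMixture:
    """Re-centre θK so the maxima of θK⁰(x) share a common ceiling.

    θK,k ← θ̄K⁺ − θK,k⁺ with θK,k⁺ = max_x θK,k⁰(x) over a dense grid;
    afterwards several components have non-negligible probability at
    every orientation, which suppresses single-component dominance in
    large populations.
    """
    grid = np.linspace(0.0, 180.0, grid_size, endpoint=False)
    curves = index_natural_param_curves(cm, grid, trunc)
    peak = curves.max(axis=1)                  # θK,k⁺, given current θK
    # peak = theta_k + max_x(ψ_k − ψ_1); choose new θK with common ceiling
    new_theta_k = cm.theta_k + (peak.mean() - peak)
    return ConditionalMixture(cm.variant, cm.family, stimulus_map=cm.stimulus_map,
                              theta_k=new_theta_k, theta_nk=cm.theta_nk,
                              theta_star=cm.theta_star)


def _discretize(cm: ConditionalMixture, levels) -> ConditionalMixture:
    """Convert a von Mises CM into a discrete lookup over the given levels."""
    levels = [float(l) for l in levels]
    thetas = np.stack([cm.baseline_params(l) for l in sorted(levels)], axis=1)
    smap = DiscreteMap(thetas[:, 0], thetas[:, 1:] - thetas[:, :1], sorted(levels))
    return ConditionalMixture("discrete", cm.family, stimulus_map=smap,
                              theta_k=cm.theta_k, theta_nk=cm.theta_nk,
                              theta_star=cm.theta_star)


def generate_dataset(cm: ConditionalMixture, stimuli, reps: int, seed,
                     trunc: Truncation = DEFAULT_TRUNCATION):
    """Ancestral samples from a CM: ``reps`` trials at each stimulus.

    Returns ``(counts, stimulus)`` with trials blocked in stimulus order;
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for x in stimuli:
        xval = x.item() if hasattr(x, "item") else x
        blocks.append(mixture_sample(cm.mixture_at(xval), reps, rng, trunc))
        labels.extend([xval] * reps)
    return np.concatenate(blocks, axis=0), np.asarray(labels)


# ---------------------------------------------------------------------------
# information-limited populations


@dataclass(frozen=True)
class InfoLimitedRecipe:
    """A homogeneous Poisson source population behind von Mises sensory noise.

    ``gain`` (spikes/trial) and ``concentration`` define identical von
    Mises tuning curves with preferred orientations tiled uniformly —
    the homogeneity that makes the source Fisher information exactly
    additive across neurons.  ``noise_circ_sd_deg`` is the circular
    standard deviation of p(s|x) in degrees of orientation; the noise
    concentration κ is solved from it.
    """

    n_neurons: int = 200
    gain: float = 5.0
    concentration: float = 1.0
    noise_circ_sd_deg: float = 10.0
    fit_components: int = 20

    @property
    def noise_kappa(self) -> float:
        """Von Mises concentration (doubled-angle) matching the circular SD."""
        sigma = 2.0 * np.deg2rad(self.noise_circ_sd_deg)   # doubled angle
        target = np.exp(-0.5 * sigma**2)                   # mean resultant length
        return float(brentq(lambda k: ive(1, k) / ive(0, k) - target, 1e-6, 1e6))


def source_population(recipe: InfoLimitedRecipe) -> ConditionalMixture:
    """The dK=1 independent-Poisson source model p(n | s)."""
    dn = recipe.n_neurons
    rho = np.deg2rad(np.arange(dn) / dn * 360.0)
    kappa = np.full(dn, recipe.concentration)
    theta_nx = np.column_stack([kappa * np.cos(rho), kappa * np.sin(rho)])
    theta_n0 = np.log(recipe.gain) - _log_bessel_i0(kappa)
    return ConditionalMixture("von_mises", "ip",
                              stimulus_map=VonMisesMap(theta_n0, theta_nx))


def _sample_noisy_orientation(recipe: InfoLimitedRecipe, x, m: int, rng) -> np.ndarray:
    phi = rng.vonmises(0.0, recipe.noise_kappa, size=m)    # doubled-angle radians
    return (np.asarray(x, dtype=float) + np.rad2deg(phi) / 2.0) % 180.0


def info_limited_sample(recipe: InfoLimitedRecipe, x, m: int, seed):
    """``m`` responses to true orientation x (degrees) through sensory noise.

    Draws s ~ p(s|x), then independent Poisson counts at rates μ(s).
    Returns ``(counts, s)``.  Marginally over s the counts are
    correlated across neurons even though the source is independent.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    source = source_population(recipe)
    s = _sample_noisy_orientation(recipe, x, m, rng)
    rates = np.exp(source.stimulus_map(s)).T               # (m, dN)
    return rng.poisson(rates), s


def generate_info_limited_dataset(recipe: InfoLimitedRecipe, stimuli, reps: int,
                                  seed):
    """Information-limited dataset: ``reps`` noisy-stimulus trials per orientation."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for x in stimuli:
        counts, _ = info_limited_sample(recipe, x, reps, rng)
        blocks.append(counts)
        labels.extend([float(x)] * reps)
    return np.concatenate(blocks, axis=0), np.asarray(labels)


def noise_channel_fi_bound(recipe: InfoLimitedRecipe) -> float:
    """Fisher information about x carried by the noisy orientation s.

    For s − x von Mises with concentration κ on the doubled angle,
    I = 2κ²(1 − I₂(κ)/I₀(κ)) per radian² of orientation — the precision
    of the sensory noise, and a data-processing bound on the FI of any
    downstream population.
    """
    k = recipe.noise_kappa
    return float(2.0 * k**2 * (1.0 - ive(2, k) / ive(0, k)))


def source_fi_curve(recipe: InfoLimitedRecipe, sizes, seed,
                    n_orientations: int = 50) -> "pd.DataFrame":
    """Average source FI about s for nested random subpopulations.

    Neurons are reintroduced in one random order; for each requested
    size the FI of the leading subset, Σ_i μ'_i(s)²/μ_i(s), is averaged
    over an orientation grid.  Returns a table with columns ``size`` and
    ``fi`` plus the noise-channel bound as ``df.attrs["bound"]``.
    """
    import pandas as pd
    rng = np.random.default_rng(seed)
    order = rng.permutation(recipe.n_neurons)
    source = source_population(recipe)
    grid = np.linspace(0.0, 180.0, n_orientations, endpoint=False)
    mu = np.exp(source.stimulus_map(grid))                 # (dN, X)
    dmu = mu * source.stimulus_map.derivative(grid)
    per_neuron = (dmu**2 / mu).mean(axis=1)                # orientation-avg FI
    rows = [{"size": int(s), "fi": float(per_neuron[order[:int(s)]].sum())}
            for s in sizes]
    df = pd.DataFrame(rows)
    df.attrs["bound"] = noise_channel_fi_bound(recipe)
    return df
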