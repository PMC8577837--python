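"""Shared fixtures: small mixtures, ground-truth CMs, and enumeration helpers."""

import itertools

import numpy as np
import pytest

from condmix.mixture import (
    WeightsRates,
    MixtureNatural,
    natural_from_weights_rates,
    joint_log_pmf,
)
from condmix.synthetic import RandomCmRecipe, random_ground_truth_cm, generate_dataset


def enumerate_counts(n_neurons: int, max_count: int) -> np.ndarray:
    """All count vectors with entries 0..max_count (enumeration oracle support)."""
    return np.array(list(itertools.product(range(max_count + 1), repeat=n_neurons)))


_JOINT_CACHE: dict = {}


def enumerated_joint(params: MixtureNatural, max_count: int):
    """Exhaustive joint pmf table p(n, k) on the truncated support.

    Returns (grid, probs) with probs of shape (len(grid), dK); the
    brute-force table behind normalization, moment, and marginal checks.
    Spot-agreement with ``joint_log_pmf`` is asserted on a few entries so
    the batched table and the scalar operation cannot drift apart.
    """
    key = (id(params), max_count)
    if key in _JOINT_CACHE:
        return _JOINT_CACHE[key]
    from scipy.special import gammaln
    from condmix.mixture import log_partition
    grid = enumerate_counts(params.n_neurons, max_count)
    comp = params.component_matrix()
    logs = (grid @ comp
            + (gammaln(grid + 1.0) @ params.effective_theta_star())[:, None]
            + params.theta_k_full()[None, :]
            - log_partition(params))
    probs = np.exp(logs)
    rng = np.random.default_rng(0)
    for j in rng.integers(0, len(grid), size=5):
        k = int(rng.integers(0, params.n_components))
        assert np.isclose(logs[j, k], joint_log_pmf(params, grid[j], k), atol=1e-10)
    _JOINT_CACHE[key] = (grid, probs)
    return grid, probs


@pytest.fixture(scope="session")
def small_ip():
    """Random 3-neuron, 4-component IP mixture with modest rates."""
    rng = np.random.default_rng(101)
    w = rng.dirichlet(np.ones(4))
    rates = rng.uniform(0.5, 4.0, size=(4, 3))
    return natural_from_weights_rates(WeightsRates(w, rates))


@pytest.fixture(scope="session")
def small_cb(small_ip):
    """CB mixture sharing the IP mixture's location parameters."""
    return MixtureNatural(small_ip.theta_n, small_ip.theta_k, small_ip.theta_nk,
                          theta_star=np.array([-1.3, -0.9, -1.1]))


@pytest.fixture(scope="session")
def tiny_truth_cm():
    """Small randomized ground-truth CB-CM (3 neurons, 2 components)."""
    return random_ground_truth_cm(RandomCmRecipe(n_neurons=3, n_components=2), seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_truth_cm):
    """Modest dataset from the tiny ground truth: 4 orientations x 25 trials."""
    grid = np.linspace(0.0, 180.0, 4, endpoint=False)
    counts, stim = generate_dataset(tiny_truth_cm, grid, 25, seed=8)
    return counts, stim
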