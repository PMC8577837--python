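"""Stimulus-dependent conditional mixtures (CMs).

A conditional mixture makes the parameters of a spike-count mixture
depend on a stimulus ``x``.  Three variants are supported:

* **minimal von Mises** — only the baseline parameters depend on the
  stimulus, through ``θN(x) = θN0 + ΘNX·vm(x)`` with
  ``vm(x) = (cos 2x, sin 2x)``, giving von Mises-shaped component tuning
  curves with period 180° of orientation;
* **minimal discrete** — ``θN(x) = θN0 + ΘNX·δ(x)`` with ``δ(x)`` the
  one-hot vector over the non-baseline stimulus conditions;
* **maximal** — an independent full mixture per stimulus condition
  (a lookup table).

Minimal CMs share θN*, θK and ΘNK across stimuli, which makes them
members of the exponential family with linear sufficient statistics
(their marginal likelihood factorizes as ``exp(θN(x)·n)·φ(n)``) and
yields a closed-form Fisher information.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .countdist import Truncation, DEFAULT_TRUNCATION, ComNatural, com_moments
from .mixture import (
    MixtureNatural,
    index_log_probabilities,
    to_dict as mixture_to_dict,
    from_dict as mixture_from_dict,
)

__all__ = [
    "VonMisesMap",
    "DiscreteMap",
    "ConditionalMixture",
    "vm",
    "param_count",
    "tuning_curves",
    "grand_tuning_curves",
    "index_probability_curves",
]


def vm(x_degrees) -> np.ndarray:
    """Doubled-angle sufficient statistic (cos 2x, sin 2x) of an orientation.

    Accepts degrees; broadcast over arrays.  Output shape ``(2,) + x.shape``.
    """
    rad = np.deg2rad(np.asarray(x_degrees, dtype=float))
    return np.stack([np.cos(2.0 * rad), np.sin(2.0 * rad)])


def vm_derivative(x_degrees) -> np.ndarray:
    """d vm / dx in radians of orientation: 2·(−sin 2x, cos 2x)."""
    rad = np.deg2rad(np.asarray(x_degrees, dtype=float))
    return np.stack([-2.0 * np.sin(2.0 * rad), 2.0 * np.cos(2.0 * rad)])


@dataclass(frozen=True)
class VonMisesMap:
    """Smooth stimulus map θN(x) = θN0 + ΘNX·vm(x); 180°-periodic."""

    theta_n0: np.ndarray
    theta_nx: np.ndarray  # (dN, 2)

    def __post_init__(self):
        object.__setattr__(self, "theta_n0", np.asarray(self.theta_n0, dtype=float))
        tnx = np.asarray(self.theta_nx, dtype=float)
        if tnx.shape != (self.theta_n0.shape[0], 2):
            raise ValueError("theta_nx must be dN x 2")
        object.__setattr__(self, "theta_nx", tnx)

    @property
    def n_neurons(self) -> int:
        return self.theta_n0.shape[0]

    def __call__(self, x) -> np.ndarray:
        """θN at stimulus x (degrees); (dN,) for a scalar, (dN, X) for arrays."""
        out = self.theta_n0[:, None] + self.theta_nx @ vm(x).reshape(2, -1)
        return out[:, 0] if np.isscalar(x) or np.ndim(x) == 0 else out

    def derivative(self, x) -> np.ndarray:
        """dθN/dx in radians of orientation, same shape contract as call."""
        out = self.theta_nx @ vm_derivative(x).reshape(2, -1)
        return out[:, 0] if np.isscalar(x) or np.ndim(x) == 0 else out

    def preferred_stimuli(self) -> np.ndarray:
        """Preferred orientation of each neuron in degrees: ½·atan2(b, a)."""
        rho = 0.5 * np.arctan2(self.theta_nx[:, 1], self.theta_nx[:, 0])
        return np.rad2deg(rho) % 180.0


@dataclass(frozen=True)
class DiscreteMap:
    """Lookup stimulus map θN(x) = θN0 + ΘNX·δ(x) over ordered condition labels.

    ``stimulus_levels`` are stored in sorted order; the first level is the
    baseline with δ = 0.
    """

    theta_n0: np.ndarray
    theta_nx: np.ndarray  # (dN, dX - 1)
    stimulus_levels: tuple

    def __post_init__(self):
        object.__setattr__(self, "theta_n0", np.asarray(self.theta_n0, dtype=float))
        tnx = np.asarray(self.theta_nx, dtype=float).reshape(self.theta_n0.shape[0], -1)
        levels = tuple(np.sort(np.asarray(self.stimulus_levels)).tolist())
        if len(levels) != tnx.shape[1] + 1:
            raise ValueError("need one stimulus level per delta column plus a baseline")
        object.__setattr__(self, "theta_nx", tnx)
        object.__setattr__(self, "stimulus_levels", levels)

    @property
    def n_neurons(self) -> int:
        return self.theta_n0.shape[0]

    def level_index(self, x) -> int:
        try:
            return self.stimulus_levels.index(x)
        except ValueError:
            raise KeyError(f"unknown stimulus level {x!r}; known: {self.stimulus_levels}")

    def __call__(self, x) -> np.ndarray:
        l = self.level_index(x)
        if l == 0:
            return self.theta_n0.copy()
        return self.theta_n0 + self.theta_nx[:, l - 1]


class ConditionalMixture:
    """A stimulus-conditioned IP or CB mixture.

    Parameters
    ----------
    variant : {"von_mises", "discrete", "maximal"}
    family : {"ip", "cb"}
    stimulus_map : VonMisesMap or DiscreteMap
        Required for the minimal variants.
    theta_k, theta_nk, theta_star
        Shared mixing parameters (minimal variants only); ``theta_star``
        only for family "cb".
    table, stimulus_levels
        For the maximal variant: one :class:`MixtureNatural` per level.
    """

    def __init__(self, variant: str, family: str, *, stimulus_map=None,
                 theta_k=None, theta_nk=None, theta_star=None,
                 table=None, stimulus_levels=None):
        if variant not in ("von_mises", "discrete", "maximal"):
            raise ValueError(f"unknown variant {variant!r}")
        if family not in ("ip", "cb"):
            raise ValueError(f"unknown family {family!r}")
        self.variant = variant
        self.family = family
        if variant == "maximal":
            if table is None or stimulus_levels is None:
                raise ValueError("maximal CMs need a per-condition table and levels")
            order = np.argsort(np.asarray(stimulus_levels))
            self.stimulus_levels = tuple(np.asarray(stimulus_levels)[order].tolist())
            self.table = [table[i] for i in order]
            dks = {m.n_components for m in self.table}
            if len(dks) != 1:
                raise ValueError("all conditions of a maximal CM must share dK")
            self.stimulus_map = None
            self.theta_k = self.theta_nk = self.theta_star = None
        else:
            if stimulus_map is None:
                raise ValueError("minimal CMs need a stimulus map")
            self.stimulus_map = stimulus_map
            dn = stimulus_map.n_neurons
            self.theta_k = np.zeros(0) if theta_k is None else np.asarray(theta_k, dtype=float)
            self.theta_nk = (np.zeros((dn, 0)) if theta_nk is None
                             else np.asarray(theta_nk, dtype=float).reshape(dn, -1))
            if family == "cb":
                if theta_star is None:
                    raise ValueError("CB family requires theta_star")
                self.theta_star = np.asarray(theta_star, dtype=float)
            else:
                self.theta_star = None
            self.table = None
            self.stimulus_levels = (tuple(stimulus_map.stimulus_levels)
                                    if isinstance(stimulus_map, DiscreteMap) else None)

    # -- structure ----------------------------------------------------

    @property
    def n_neurons(self) -> int:
        if self.variant == "maximal":
            return self.table[0].n_neurons
        return self.stimulus_map.n_neurons

    @property
    def n_components(self) -> int:
        if self.variant == "maximal":
            return self.table[0].n_components
        return self.theta_k.shape[0] + 1

    @property
    def is_minimal(self) -> bool:
        return self.variant != "maximal"

    # -- evaluation ---------------------------------------------------

    def baseline_params(self, x) -> np.ndarray:
        """θN(x): the stimulus-dependent baseline natural parameters."""
        if self.variant == "maximal":
            return self._lookup(x).theta_n.copy()
        return self.stimulus_map(x)

    def mixture_at(self, x) -> MixtureNatural:
        """The full mixture p(n, k | x) at one stimulus."""
        if self.variant == "maximal":
            return self._lookup(x)
        return MixtureNatural(self.stimulus_map(x), self.theta_k,
                              self.theta_nk, self.theta_star)

    def _lookup(self, x) -> MixtureNatural:
        levels = list(self.stimulus_levels)
        try:
            return self.table[levels.index(x)]
        except ValueError:
            raise KeyError(f"unknown stimulus level {x!r}; known: {tuple(levels)}")

    def param_count(self) -> int:
        dx = len(self.stimulus_levels) if self.stimulus_levels is not None else None
        return param_count(self.variant, self.family, self.n_neurons,
                           self.n_components, dx)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        out = {"schema_version": 1, "variant": self.variant, "family": self.family,
               "component_axis": "columns"}
        if self.variant == "maximal":
            out["stimulus_levels"] = list(self.stimulus_levels)
            out["table"] = [mixture_to_dict(m) for m in self.table]
            return out
        out["theta_k"] = self.theta_k.tolist()
        out["theta_nk"] = self.theta_nk.tolist()
        if self.theta_star is not None:
            out["theta_star"] = self.theta_star.tolist()
        m = self.stimulus_map
        out["theta_n0"] = m.theta_n0.tolist()
        out["theta_nx"] = m.theta_nx.tolist()
        if self.variant == "discrete":
            out["stimulus_levels"] = list(m.stimulus_levels)
        return out

    @classmethod
    def from_dict(cls, doc: dict) -> "ConditionalMixture":
        variant, family = doc["variant"], doc["family"]
        if variant == "maximal":
            return cls(variant, family,
                       table=[mixture_from_dict(d) for d in doc["table"]],
                       stimulus_levels=doc["stimulus_levels"])
        theta_n0 = np.asarray(doc["theta_n0"], dtype=float)
        theta_nx = np.asarray(doc["theta_nx"], dtype=float)
        if variant == "von_mises":
            smap = VonMisesMap(theta_n0, theta_nx)
        else:
            smap = DiscreteMap(theta_n0, theta_nx, doc["stimulus_levels"])
        ts = doc.get("theta_star")
        return cls(variant, family, stimulus_map=smap,
                   theta_k=np.asarray(doc["theta_k"], dtype=float),
                   theta_nk=np.asarray(doc["theta_nk"], dtype=float),
                   theta_star=None if ts is None else np.asarray(ts, dtype=float))


def param_count(variant: str, family: str, n_neurons: int, n_components: int,
                n_stimuli: int | None = None) -> int:
    """Number of free parameters of a CM variant.

    IP counts: maximal dS(dN·dK + dK − 1); von Mises
    (dN+1)(dK−1) + 3dN; discrete (dN+1)(dK−1) + dS·dN.  The CB family
    adds dS·dN (maximal) or dN (minimal) shape parameters.
    """
    dn, dk, ds = int(n_neurons), int(n_components), n_stimuli
    if min(dn, dk) < 1:
        raise ValueError("dimensions must be positive")
    if variant == "maximal":
        if ds is None:
            raise ValueError("maximal CMs need the number of stimulus conditions")
        count = ds * (dn * dk + dk - 1)
        extra = ds * dn
    elif variant == "von_mises":
        count = (dn + 1) * (dk - 1) + 3 * dn
        extra = dn
    elif variant == "discrete":
        if ds is None:
            raise ValueError("discrete CMs need the number of stimulus conditions")
        count = (dn + 1) * (dk - 1) + ds * dn
        extra = dn
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return count + (extra if family == "cb" else 0)


def _stimulus_grid(cm: ConditionalMixture, xs):
    if xs is not None:
        return list(np.atleast_1d(xs)) if not isinstance(xs, (list, tuple)) else list(xs)
    if cm.stimulus_levels is None:
        raise ValueError("a stimulus grid is required for von Mises CMs")
    return list(cm.stimulus_levels)


def tuning_curves(cm: ConditionalMixture, xs=None,
                  trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Component tuning curves μ_ik(x): a (dN, dK, X) array.

    For IP components μ_ik(x) = exp(θN,i(x) + [ΘNK]_{i,k−1}), i.e. each
    non-baseline component is a gain-modulated copy of the baseline
    tuning curve; CB component means come from truncated summation.
    """
    grid = _stimulus_grid(cm, xs)
    out = np.empty((cm.n_neurons, cm.n_components, len(grid)))
    for j, x in enumerate(grid):
        mix = cm.mixture_at(x)
        comp = mix.component_matrix()
        if mix.is_cb:
            com = ComNatural(comp, np.broadcast_to(
                mix.theta_star[:, None], comp.shape))
            out[:, :, j] = com_moments(com, trunc)[0]
        else:
            out[:, :, j] = np.exp(comp)
    return out


def index_probability_curves(cm: ConditionalMixture, xs=None,
                             trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Index probabilities p(k | x) over a stimulus grid: (dK, X), columns sum to 1."""
    grid = _stimulus_grid(cm, xs)
    out = np.empty((cm.n_components, len(grid)))
    for j, x in enumerate(grid):
        out[:, j] = np.exp(index_log_probabilities(cm.mixture_at(x), trunc))
    return out


def grand_tuning_curves(cm: ConditionalMixture, xs=None,
                        trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Population tuning curves μ_i(x) = Σ_k p(k|x)·μ_ik(x): (dN, X)."""
    curves = tuning_curves(cm, xs, trunc)
    probs = index_probability_curves(cm, xs, trunc)
    return np.einsum("ikx,kx->ix", curves, probs)
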