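"""Model/Results interface for conditional mixtures.

``ConditionalMixtureModel`` holds a spike-count dataset and a model
specification; ``fit`` runs the EM algorithm and returns a
``ConditionalMixtureResults`` carrying the fitted parameters, the
log-likelihood trace, and methods for decoding, Fisher information,
simulation, and plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .countdist import Truncation, DEFAULT_TRUNCATION
from .conditional import (
    ConditionalMixture,
    param_count,
    tuning_curves,
    grand_tuning_curves,
    index_probability_curves,
)
from .mixture import moments as mixture_moments
from .em import (
    TrainingSchedule,
    fit_em,
    fit_independent_baseline,
    log_likelihood,
    _as_dataset,
)
from . import decode as _decode
from .synthetic import generate_dataset

__all__ = ["ConditionalMixtureModel", "ConditionalMixtureResults"]


class ConditionalMixtureModel:
    """A conditional mixture specification bound to a spike-count dataset.

    Parameters
    ----------
    counts : (n_trials, n_neurons) int array
        Spike counts, one row per trial.
    stimulus : (n_trials,) array
        Stimulus label per trial: an orientation in degrees for the
        von Mises variant, any hashable condition label otherwise.
    variant : {"von_mises", "discrete", "maximal"}
        How the baseline parameters depend on the stimulus.
    family : {"ip", "cb"}
        Independent-Poisson components, or the CoM-Poisson extension
        that decouples spike-count means from variances.
    n_components : int
        Number of mixture components dK; dK=1 is the non-mixed
        independent model.
    """

    def __init__(self, counts, stimulus, variant: str = "von_mises",
                 family: str = "ip", n_components: int = 5,
                 truncation: Truncation = DEFAULT_TRUNCATION):
        self.counts, self.stimulus = _as_dataset(counts, stimulus)
        self.variant = variant
        self.family = family
        self.n_components = int(n_components)
        self.truncation = truncation

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, stimulus_col: str = "stimulus",
                       **kwargs) -> "ConditionalMixtureModel":
        """Build from a tidy table: one stimulus column, one column per neuron."""
        neuron_cols = [c for c in df.columns if c != stimulus_col]
        return cls(df[neuron_cols].to_numpy(), df[stimulus_col].to_numpy(), **kwargs)

    @classmethod
    def from_trials(cls, table, **kwargs) -> "ConditionalMixtureModel":
        """Build from an :class:`condmix.io.TrialTable`."""
        return cls(table.counts, table.stimulus, **kwargs)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    def fit(self, schedule: TrainingSchedule | None = None, seed=0,
            init: ConditionalMixture | None = None) -> "ConditionalMixtureResults":
        """Fit by approximate EM; see :func:`condmix.em.fit_em`."""
        cm, trace = fit_em(self.counts, self.stimulus, self.variant, self.family,
                           self.n_components, schedule, seed, self.truncation,
                           init=init)
        return ConditionalMixtureResults(self, cm, trace)

    def fit_baseline(self) -> "ConditionalMixtureResults":
        """ML fit of the non-mixed (dK=1) independent-Poisson model."""
        variant = "von_mises" if self.variant == "von_mises" else "discrete"
        cm = fit_independent_baseline(self.counts, self.stimulus, variant,
                                      self.truncation)
        trace = np.array([log_likelihood(cm, self.counts, self.stimulus,
                                         self.truncation)])
        return ConditionalMixtureResults(self, cm, trace)


class ConditionalMixtureResults:
    """A fitted conditional mixture with its diagnostics."""

    def __init__(self, model: ConditionalMixtureModel, cm: ConditionalMixture,
                 trace: np.ndarray):
        self.model = model
        self.cm = cm
        self.llf_trace = np.asarray(trace, dtype=float)
        self.llf = float(self.llf_trace[-1]) if self.llf_trace.size else float(
            log_likelihood(cm, model.counts, model.stimulus, model.truncation))

    # -- basic quantities ----------------------------------------------

    @property
    def n_params(self) -> int:
        levels = self.cm.stimulus_levels
        dx = len(levels) if levels is not None else len(np.unique(self.model.stimulus))
        return param_count(self.cm.variant, self.cm.family, self.cm.n_neurons,
                           self.cm.n_components, dx)

    @property
    def llf_per_trial(self) -> float:
        return self.llf / max(self.model.n_trials, 1)

    def loglike(self, counts=None, stimulus=None, per_trial: bool = False):
        """Data log-likelihood on (counts, stimulus), default the training data."""
        if counts is None:
            counts, stimulus = self.model.counts, self.model.stimulus
        return log_likelihood(self.cm, counts, stimulus, self.model.truncation,
                              per_trial=per_trial)

    # -- response statistics -------------------------------------------

    def moments(self, x):
        """Mean, covariance, and Fano factors of p(n | x)."""
        return mixture_moments(self.cm.mixture_at(x), self.model.truncation)

    def tuning_curves(self, xs=None) -> np.ndarray:
        return tuning_curves(self.cm, xs, self.model.truncation)

    def grand_tuning_curves(self, xs=None) -> np.ndarray:
        return grand_tuning_curves(self.cm, xs, self.model.truncation)

    def index_probability_curves(self, xs=None) -> np.ndarray:
        return index_probability_curves(self.cm, xs, self.model.truncation)

    def fisher_information(self, x) -> float:
        return _decode.fisher_information(self.cm, x, self.model.truncation)

    # -- decoding and simulation ---------------------------------------

    def decoder(self, prior=None) -> "_decode.BayesDecoder":
        """Bayesian decoder over the dataset's stimulus conditions."""
        levels, emp_prior = _decode.estimate_prior(self.model.stimulus)
        return _decode.BayesDecoder(self.cm, levels,
                                    emp_prior if prior is None else np.asarray(prior),
                                    self.model.truncation)

    def predict_posterior(self, counts) -> np.ndarray:
        """Log-posteriors log p(x | n) for each row of ``counts``."""
        return self.decoder().log_posteriors(counts)

    def simulate(self, stimuli=None, reps: int = 100, seed=0):
        """Draw a synthetic dataset from the fitted model."""
        if stimuli is None:
            stimuli = (self.cm.stimulus_levels if self.cm.stimulus_levels is not None
                       else np.unique(self.model.stimulus))
        return generate_dataset(self.cm, stimuli, reps, seed, self.model.truncation)

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Conditional Mixture Results",
            "=" * 46,
            f"{'Variant:':<24}{self.cm.variant}",
            f"{'Family:':<24}{self.cm.family.upper()}",
            f"{'Neurons (dN):':<24}{self.cm.n_neurons}",
            f"{'Components (dK):':<24}{self.cm.n_components}",
            f"{'Trials:':<24}{self.model.n_trials}",
            f"{'Parameters:':<24}{self.n_params}",
            f"{'EM iterations:':<24}{len(self.llf_trace)}",
            f"{'Log-likelihood:':<24}{self.llf:.3f}",
            f"{'Log-lik. per trial:':<24}{self.llf_per_trial:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_tuning_curves(self, xs=None, ax=None, **kwargs):
        """Plot population (grand) tuning curves; requires matplotlib."""
        import matplotlib.pyplot as plt
        if xs is None:
            xs = np.linspace(0.0, 180.0, 90, endpoint=False)
        curves = self.grand_tuning_curves(xs)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.asarray(xs, dtype=float), curves.T, lw=1, **kwargs)
        ax.set_xlabel("orientation (deg)")
        ax.set_ylabel("mean spike count")
        return ax

    def save(self, path, seed=None) -> None:
        """Serialize the fitted parameters to JSON."""
        from .io import save_model_json
        save_model_json(self.cm.to_dict(), path, seed=seed)
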