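"""Bayesian decoding, Fisher information, and decoder baselines.

A fitted encoding model p(n | x) is inverted with Bayes' rule,
p(x | n) ∝ p(n | x)·p(x), by brute-force normalization over the discrete
stimulus conditions.  Decoding quality is summarized by the
cross-validated mean log-posterior of the true condition (nats), and
encoding quality by the "information gain": the held-out log-likelihood
of a model minus that of a von Mises-tuned independent-Poisson baseline,
per trial.

For minimal conditional mixtures the Fisher information about the
stimulus has the closed form  I(x) = ∂xθN(x)·Σ(x)·∂xθN(x)  and equals
the linear Fisher information ∂xμ(x)·Σ⁻¹(x)·∂xμ(x).  Both forms are
implemented; FI is reported per radian² of orientation.

Two direct decoders are provided for comparison: a multiclass linear
decoder and a multilayer perceptron with sigmoid hidden units, both
emitting the dX−1 natural parameters of a categorical distribution over
conditions and trained by minibatch Adam with early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .countdist import Truncation, DEFAULT_TRUNCATION, ComNatural, com_moments
from .mixture import moments as mixture_moments, observable_log_pmf
from .conditional import ConditionalMixture
from .em import fit_independent_baseline, log_likelihood, TrainingSchedule, _as_dataset

__all__ = [
    "estimate_prior",
    "bayes_posterior",
    "BayesDecoder",
    "mean_log_posterior",
    "fisher_information",
    "linear_fisher_information",
    "mean_derivative",
    "subpopulation_lfi",
    "CategoricalDecoder",
    "fit_categorical_decoder",
    "decoder_param_count",
    "crossval",
    "fold_summary",
    "crossval_information_gain",
    "crossval_log_posterior",
]

#: Held-out log-posteriors are floored here so fold averages stay finite.
LOG_POSTERIOR_FLOOR = np.log(1e-12)


def estimate_prior(stimulus, levels=None):
    """Empirical stimulus prior: relative presentation frequencies.

    Returns ``(levels, prior)`` with the levels sorted.  A level supplied
    via ``levels`` but absent from the data receives prior 0.
    """
    stimulus = np.asarray(stimulus)
    if levels is None:
        levels, counts = np.unique(stimulus, return_counts=True)
    else:
        levels = np.sort(np.asarray(levels))
        counts = np.array([(stimulus == l).sum() for l in levels], dtype=float)
    prior = counts / counts.sum()
    return levels, prior


def _log_posterior_matrix(cm: ConditionalMixture, counts, levels, log_prior,
                          trunc: Truncation) -> np.ndarray:
    counts = np.atleast_2d(np.asarray(counts))
    loglik = np.empty((counts.shape[0], len(levels)))
    for j, x in enumerate(levels):
        xval = x.item() if hasattr(x, "item") else x
        loglik[:, j] = np.atleast_1d(
            observable_log_pmf(cm.mixture_at(xval), counts, trunc))
    unnorm = loglik + log_prior[None, :]
    return unnorm - logsumexp(unnorm, axis=1, keepdims=True)


def bayes_posterior(cm: ConditionalMixture, n, prior, levels=None,
                    trunc: Truncation = DEFAULT_TRUNCATION) -> np.ndarray:
    """Normalized log-posterior log p(x | n) over the stimulus conditions."""
    prior = np.asarray(prior, dtype=float)
    if not np.isclose(prior.sum(), 1.0) or np.any(prior < 0):
        raise ValueError("prior must be a simplex vector")
    if levels is None:
        if cm.stimulus_levels is None:
            raise ValueError("levels are required for von Mises CMs")
        levels = np.asarray(cm.stimulus_levels)
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior)
    return _log_posterior_matrix(cm, n, levels, log_prior, trunc)[0]


@dataclass
class BayesDecoder:
    """A conditional mixture inverted into a decoder over discrete conditions."""

    cm: ConditionalMixture
    levels: np.ndarray
    prior: np.ndarray
    trunc: Truncation = DEFAULT_TRUNCATION

    def log_posteriors(self, counts) -> np.ndarray:
        with np.errstate(divide="ignore"):
            log_prior = np.log(self.prior)
        return _log_posterior_matrix(self.cm, counts, self.levels, log_prior,
                                     self.trunc)


def mean_log_posterior(decoder, counts, stimulus,
                       floor: float = LOG_POSTERIOR_FLOOR):
    """Average log-posterior of the true condition over trials (nats).

    ``decoder`` is anything exposing ``log_posteriors(counts)`` and
    ``levels``.  Values below the floor are clipped before averaging (a
    model that assigns numerically zero probability stays visible but
    finite); the raw per-trial values are returned alongside.
    """
    counts, stimulus = _as_dataset(counts, stimulus)
    logpost = decoder.log_posteriors(counts)
    levels = list(np.asarray(decoder.levels))
    idx = np.array([levels.index(s) for s in stimulus])
    raw = logpost[np.arange(len(idx)), idx]
    return float(np.maximum(raw, floor).mean()), raw


# ---------------------------------------------------------------------------
# Fisher information


def _theta_derivative(cm: ConditionalMixture, x, dx: float) -> np.ndarray:
    smap = cm.stimulus_map
    if hasattr(smap, "derivative"):
        return smap.derivative(x)
    if getattr(smap, "stimulus_levels", None) is not None:
        raise ValueError("Fisher information needs a smooth stimulus map")
    return (smap(x + dx) - smap(x - dx)) / np.deg2rad(2.0 * dx)


def fisher_information(cm: ConditionalMixture, x,
                       trunc: Truncation = DEFAULT_TRUNCATION,
                       dx: float = 0.5) -> float:
    """Closed-form FI of a minimal CM: ∂xθN(x)·Σ(x)·∂xθN(x) (radians⁻²).

    ``dx`` (degrees) is the central-difference step used only when the
    stimulus map lacks an analytic derivative.
    """
    if not cm.is_minimal:
        raise ValueError("the closed-form FI applies to minimal CMs only")
    dtheta = _theta_derivative(cm, x, dx)
    cov = mixture_moments(cm.mixture_at(x), trunc).covariance
    return float(dtheta @ cov @ dtheta)


def mean_derivative(cm: ConditionalMixture, x,
                    trunc: Truncation = DEFAULT_TRUNCATION,
                    dx: float = 0.5) -> np.ndarray:
    """Analytic ∂x of the population mean μ(x) of a minimal CM (per radian).

    μ(x) = Σ_k w_k(x)·μ_k(x) with w_k(x) ∝ exp(θK,k + ψ_k(x)); both
    factors are differentiated through θN(x): ∂x μ_k = σ²_k ⊙ ∂xθN and
    ∂x log w_k = μ_k·∂xθN − Σ_l w_l μ_l·∂xθN.
    """
    if not cm.is_minimal:
        raise ValueError("mean_derivative applies to minimal CMs only")
    dtheta = _theta_derivative(cm, x, dx)
    mix = cm.mixture_at(x)
    comp = mix.component_matrix()
    if mix.is_cb:
        com = ComNatural(comp, np.broadcast_to(mix.theta_star[:, None], comp.shape))
        mu_k, var_k = com_moments(com, trunc)
    else:
        mu_k = np.exp(comp)
        var_k = mu_k
    from .mixture import index_log_probabilities
    w = np.exp(index_log_probabilities(mix, trunc))
    dpsi = dtheta @ mu_k                      # (dK,)
    dlogw = dpsi - w @ dpsi
    dw = w * dlogw
    return mu_k @ dw + (var_k @ w) * dtheta


def linear_fisher_information(cm: ConditionalMixture, x,
                              trunc: Truncation = DEFAULT_TRUNCATION,
                              dx: float = 0.5) -> float:
    """Linear FI ∂xμ(x)·Σ⁻¹(x)·∂xμ(x); equals the FI for minimal CMs."""
    dmu = mean_derivative(cm, x, trunc, dx)
    cov = mixture_moments(cm.mixture_at(x), trunc).covariance
    return float(dmu @ np.linalg.solve(cov, dmu))


def subpopulation_lfi(cm: ConditionalMixture, x, idx,
                      trunc: Truncation = DEFAULT_TRUNCATION) -> float:
    """Linear FI carried by a neuron subset, from the full model's moments.

    Uses the exact marginal mean derivative and covariance of the
    subpopulation (rows/columns ``idx``), which is well defined even
    though the marginal of a minimal CM is not itself a minimal CM.
    """
    idx = np.asarray(idx)
    dmu = mean_derivative(cm, x, trunc)[idx]
    cov = mixture_moments(cm.mixture_at(x), trunc).covariance[np.ix_(idx, idx)]
    return float(dmu @ np.linalg.solve(cov, dmu))


# ---------------------------------------------------------------------------
# direct decoders: linear and MLP natural-parameter networks


def decoder_param_count(n_neurons: int, n_conditions: int, hidden=()) -> int:
    """Parameter count of a categorical-natural-parameter decoder.

    The network maps dN counts to the dX−1 natural parameters of a
    categorical distribution; a linear decoder has (dN+1)(dX−1)
    parameters, and each hidden layer of width h adds (fan_in+1)·h.
    """
    dims = [n_neurons, *hidden, n_conditions - 1]
    return int(sum((dims[i] + 1) * dims[i + 1] for i in range(len(dims) - 1)))


@dataclass
class CategoricalDecoder:
    """Feedforward decoder emitting categorical natural parameters θX(n).

    Hidden layers (if any) use sigmoid activations; the output layer is
    linear with dX−1 units, and the implied class-0 natural parameter is
    pinned at 0.
    """

    levels: np.ndarray
    weights: list          # [(W, b), ...] with W of shape (out, in)

    @property
    def param_count(self) -> int:
        return int(sum(w.size + b.size for w, b in self.weights))

    def natural_params(self, counts) -> np.ndarray:
        a = np.atleast_2d(np.asarray(counts, dtype=float))
        for w, b in self.weights[:-1]:
            a = 1.0 / (1.0 + np.exp(-(a @ w.T + b)))
        w, b = self.weights[-1]
        return a @ w.T + b

    def log_posteriors(self, counts) -> np.ndarray:
        theta = self.natural_params(counts)
        logits = np.concatenate([np.zeros((theta.shape[0], 1)), theta], axis=1)
        return logits - logsumexp(logits, axis=1, keepdims=True)


def _decoder_grads(weights, counts, labels):
    """Mean log-likelihood and its gradients for one minibatch."""
    acts = [np.asarray(counts, dtype=float)]
    for w, b in weights[:-1]:
        acts.append(1.0 / (1.0 + np.exp(-(acts[-1] @ w.T + b))))
    w, b = weights[-1]
    theta = acts[-1] @ w.T + b
    logits = np.concatenate([np.zeros((theta.shape[0], 1)), theta], axis=1)
    logp = logits - logsumexp(logits, axis=1, keepdims=True)
    m = counts.shape[0]
    value = float(logp[np.arange(m), labels].mean())
    onehot = np.zeros_like(logp)
    onehot[np.arange(m), labels] = 1.0
    delta = (onehot - np.exp(logp))[:, 1:] / m      # ascent direction at output
    grads = []
    for layer in range(len(weights) - 1, -1, -1):
        w, _ = weights[layer]
        gw = delta.T @ acts[layer]
        gb = delta.sum(axis=0)
        grads.append((gw, gb))
        if layer > 0:
            a = acts[layer]
            delta = (delta @ w) * a * (1.0 - a)
    return value, grads[::-1]


def fit_categorical_decoder(counts, stimulus, hidden=(), seed=0,
                            learning_rate: float = 3e-4, batch_size: int = 500,
                            max_epochs: int = 300) -> CategoricalDecoder:
    """Train a linear (``hidden=()``) or MLP decoder by minibatch Adam.

    The trials are split 80/10/10 into training, test and validation
    partitions; training stops when the test-partition mean
    log-posterior declines from one epoch to the next (early stopping),
    returning the parameters of the best test epoch.  Deterministic
    given the seed.
    """
    counts, stimulus = _as_dataset(counts, stimulus)
    rng = np.random.default_rng(seed)
    levels = np.unique(stimulus)
    lookup = {l.item() if hasattr(l, "item") else l: j for j, l in enumerate(levels)}
    labels = np.array([lookup[s.item() if hasattr(s, "item") else s]
                       for s in stimulus])
    order = rng.permutation(len(labels))
    n_train = int(0.8 * len(order))
    n_test = int(0.1 * len(order))
    tr, te = order[:n_train], order[n_train:n_train + n_test]

    dims = [counts.shape[1], *hidden, len(levels) - 1]
    weights = [(rng.normal(0.0, 1.0 / np.sqrt(dims[i]), size=(dims[i + 1], dims[i])),
                np.zeros(dims[i + 1])) for i in range(len(dims) - 1)]
    flat_dim = sum(w.size + b.size for w, b in weights)
    schedule = TrainingSchedule()
    adam_m, adam_v, t_adam = np.zeros(flat_dim), np.zeros(flat_dim), 0

    def flatten(ws):
        return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in ws])

    def unflatten(vec):
        out, pos = [], 0
        for i in range(len(dims) - 1):
            wsize = dims[i + 1] * dims[i]
            w = vec[pos:pos + wsize].reshape(dims[i + 1], dims[i]); pos += wsize
            b = vec[pos:pos + dims[i + 1]]; pos += dims[i + 1]
            out.append((w, b))
        return out

    params = flatten(weights)
    best_params, best_score, prev_score = params.copy(), -np.inf, -np.inf
    for epoch in range(max_epochs):
        perm = rng.permutation(tr)
        for start in range(0, len(perm), batch_size):
            mb = perm[start:start + batch_size]
            ws = unflatten(params)
            _, grads = _decoder_grads(ws, counts[mb], labels[mb])
            gvec = flatten(grads)
            t_adam += 1
            adam_m = schedule.beta1 * adam_m + (1 - schedule.beta1) * gvec
            adam_v = schedule.beta2 * adam_v + (1 - schedule.beta2) * gvec**2
            mhat = adam_m / (1 - schedule.beta1 ** t_adam)
            vhat = adam_v / (1 - schedule.beta2 ** t_adam)
            params = params + learning_rate * mhat / (np.sqrt(vhat) + schedule.adam_eps)
        if len(te):
            score, _ = _decoder_grads(unflatten(params), counts[te], labels[te])
        else:
            score, _ = _decoder_grads(unflatten(params), counts[tr], labels[tr])
        if score > best_score:
            best_score, best_params = score, params.copy()
        if score < prev_score:
            break
        prev_score = score
    if not np.isfinite(best_score):
        raise RuntimeError("decoder training produced a non-finite loss")
    return CategoricalDecoder(levels=levels, weights=unflatten(best_params))


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(stimulus, folds: int, seed) -> list[np.ndarray]:
    """Disjoint, exhaustive fold assignment stratified by condition."""
    from sklearn.model_selection import StratifiedKFold
    stimulus = np.asarray(stimulus)
    if len(stimulus) < folds:
        raise ValueError("need at least one trial per fold")
    state = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**32 - 1))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=state)
    return [test for _, test in skf.split(np.zeros(len(stimulus)), stimulus.astype(str))]


def crossval(counts, stimulus, fit_fn, eval_fn, folds: int = 10, seed=0) -> pd.DataFrame:
    """Generic stratified k-fold loop.

    ``fit_fn(train_counts, train_stimulus, fold_seed) -> model`` and
    ``eval_fn(model, test_counts, test_stimulus) -> dict`` of metrics.
    Returns one row per fold.
    """
    counts, stimulus = _as_dataset(counts, stimulus)
    rows = []
    test_sets = _stratified_folds(stimulus, folds, seed)
    for f, test_idx in enumerate(test_sets):
        mask = np.ones(len(stimulus), dtype=bool)
        mask[test_idx] = False
        model = fit_fn(counts[mask], stimulus[mask], seed * 1000 + f)
        metrics = eval_fn(model, counts[test_idx], stimulus[test_idx])
        rows.append({"fold": f, "n_test": len(test_idx), **metrics})
    return pd.DataFrame(rows)


def fold_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error across folds for every metric column."""
    metrics = [c for c in table.columns if c not in ("fold", "n_test")]
    out = {}
    for c in metrics:
        vals = table[c].to_numpy(dtype=float)
        out[c] = {"mean": vals.mean(),
                  "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0}
    return pd.DataFrame(out).T


def crossval_information_gain(counts, stimulus, fit_model, folds: int = 10,
                              seed=0, trunc: Truncation = DEFAULT_TRUNCATION) -> pd.DataFrame:
    """Cross-validated information gain of a model over the IP baseline.

    ``fit_model(train_counts, train_stimulus, fold_seed)`` returns a
    ConditionalMixture; the baseline is a von Mises-tuned independent
    Poisson model fit on the same training fold.  The metric is the mean
    held-out log-likelihood difference per trial (nats/trial).
    """
    def fit_fn(tc, ts, fold_seed):
        model = fit_model(tc, ts, fold_seed)
        baseline = fit_independent_baseline(tc, ts, "von_mises", trunc)
        return model, baseline

    def eval_fn(pair, ec, es):
        model, baseline = pair
        _, lm = log_likelihood(model, ec, es, trunc, per_trial=True)
        _, lb = log_likelihood(baseline, ec, es, trunc, per_trial=True)
        return {"information_gain": float((lm - lb).mean())}

    return crossval(counts, stimulus, fit_fn, eval_fn, folds, seed)


def crossval_log_posterior(counts, stimulus, fit_decoder, folds: int = 10,
                           seed=0) -> pd.DataFrame:
    """Cross-validated mean log-posterior of the true condition.

    ``fit_decoder(train_counts, train_stimulus, fold_seed)`` returns any
    object with ``levels`` and ``log_posteriors``.
    """
    def eval_fn(dec, ec, es):
        mlp, _ = mean_log_posterior(dec, ec, es)
        return {"mean_log_posterior": mlp}

    return crossval(counts, stimulus, fit_decoder, eval_fn, folds, seed)
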