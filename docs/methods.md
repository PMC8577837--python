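# Methods

This note documents the models implemented in `condmix`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the package's known limitations.  Notation follows the README: counts
**n**, component index k, stimulus x (degrees of orientation, period 180°,
radians internally).

## Count distributions

The scalar layer (`condmix.countdist`) implements the Poisson log-pmf and
the Conway–Maxwell–Poisson (CoM-Poisson) family in natural coordinates
θ = ν·log λ (location) and θ* = −ν (shape), with sufficient statistic
(n, log n!).  The CoM-Poisson log-partition has no closed form; it is
computed by truncating the series Σₙ exp(n·θ + log(n!)·θ*), which converges
iff θ* < 0.  Moments (mean, variance, E[log n!]) come from the truncated,
renormalized pmf table.  The mode is ⌊λ⌋ with λ = exp(θ/ν); a relative
epsilon (1e−12) guards against λ landing one floating-point bit below an
integer.

**Truncation policy.**  No cutoff is inherent to the model, so accuracy
targets are self-imposed: the default cutoff is max(128, ⌈10·λ⌉) over the
parameters involved in a call, which bounds the neglected tail mass below
~1e−12 for the count regimes exercised here (rates up to a few hundred
spikes/trial).  The cutoff is configurable (`Truncation(max_count=...)`)
and monotone: increasing it never decreases a log-partition value.  A hard
ceiling of 20,000 terms converts runaway parameters into an explicit error
rather than an out-of-memory failure.  All series are accumulated in
log-space (log-sum-exp), and log n! uses the log-gamma function.

## Mixtures and conditional mixtures

`condmix.mixture` carries both parameterizations of a finite mixture of
independent count populations — intuitive (weights w, component rates λₖ)
and exponential-family (θN, θK, ΘNK, optionally θN*) — together with the
exact maps between them.  Conventions that matter:

* ΘNK is dN × (dK−1); component k ≥ 1 (zero-based) adds column k−1.
  Component 0 is the baseline with δ(k) = 0.  Component indices are
  zero-based in code.
* CoM shape parameters θN* are shared by all components: switching
  components shifts locations (gains), never shapes.
* Densities are evaluated and returned in log space; probabilities are
  normalized with log-sum-exp throughout.
* Moments use the mixture decomposition: mean μ = Σₖ wₖ μₖ, covariance
  Σ = Σₖ wₖ(μₖ−μ)(μₖ−μ)ᵀ + diag(Σₖ wₖ σ²ₖ).  For IP components this
  forces Fano factors ≥ 1; CB components can push them below 1.
* Sampling is ancestral (draw k, then each count by inverse CDF on the
  truncated component pmf).  The same inverse-CDF path is used for IP and
  CB components, so θN* = −1 reproduces the IP samples bit-for-bit at the
  same seed.

`condmix.conditional` adds the stimulus maps.  Minimal variants share
θN*, θK, ΘNK across stimuli and route all stimulus dependence through
θN(x) (von Mises: θN0 + ΘNX·vm(x) with vm(x) = (cos 2x, sin 2x);
discrete: θN0 + ΘNX·δ(x) with the lexically first condition as baseline).
The maximal variant is a lookup table of full mixtures, fit independently
per condition.  Parameter counts: maximal dS(dN·dK + dK−1), von Mises
(dN+1)(dK−1) + 3dN, discrete (dN+1)(dK−1) + dS·dN; the CB family adds
dS·dN / dN / dN respectively.  These formulas are authoritative for the
package even where a published table cell disagrees with its own formula
(the CB additions are always counted).

## Expectation–maximization

The E-step is exact: p(k|n, x) is a softmax over (0, θK + n·ΘNK); the
stimulus-dependent and shape terms are shared by all components and cancel.
The M-step maximizes the complete log-likelihood
Σᵢ [θN(xᵢ)·nᵢ + θN*·lf(nᵢ) + θK·ηᵢ + nᵢ·ΘNK·ηᵢ − ψ(xᵢ)], a convex
exponential-family problem whose gradients are "data statistic minus model
expectation":

    ∂θN = n − ηN,  ∂θN* = lf(n) − ηN*,  ∂θK = ηK(i) − ηK,
    ∂ΘNK = n ⊗ ηK(i) − H_NK,

chained into (θN0, ΘNX) through vm(x) or δ(x).  Because the
responsibilities are fixed within an M-step, the data-side statistics are
precomputed once per EM iteration and grouped by unique stimulus; each
Adam step then recomputes only the model expectations, in one batched
array operation over (stimulus, component, neuron[, count]) axes.  All
gradients are verified against central finite differences (1e−5 relative)
for every variant × family combination.

**Schedule.**  Defaults: dI = 500 EM iterations, 100 Adam ascent steps per
M-step (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, state reset each EM iteration),
learning rate decaying log-linearly from 2e−3 to 5e−4 across EM
iterations.  Gradients are full-batch: nothing in the M-step objective
requires minibatching at these scales, and full-batch ascent keeps the
monotonicity guarantee testable.  The data log-likelihood is evaluated
after every EM iteration for the returned trace; EM never decreases it
beyond the tolerance attributable to the approximate (truncated-ascent)
M-step, and the test suite enforces a 1e−6-per-trial slack over 20 seeds.
A non-finite log-likelihood aborts training with a diagnostic.

**Initialization.**  The baseline θN(x) comes from the non-mixed (dK=1)
maximum-likelihood fit: a Poisson GLM per neuron with regressors
(1, cos 2x, sin 2x) solved by IRLS (statsmodels) for von Mises maps, or the
closed-form per-condition log mean rates for discrete maps.  Empirical
rates are floored at 0.1/dT so silent neurons keep finite natural
parameters.  Mixing weights are drawn from Dirichlet(2) and converted to
θK; ΘNK entries are uniform on ±1e−4 (discrete/maximal) or sinusoidal in
the neuron's preferred orientation, 0.2·sin(2ρᵢ + k·360°/dK), giving each
modulation a distinct peak (von Mises).  Preferred orientation is
ρᵢ = ½·atan2(bᵢ, aᵢ) from the row (aᵢ, bᵢ) of ΘNX; θN0 scales the gain and
does not move the peak.

**CB warm start.**  CoM series make CB gradients one to two orders of
magnitude more expensive than IP gradients, so CB models train as an IP
model for the first 80% of iterations, then attach θN* = −1 — which leaves
the density unchanged — and continue in the CB family.  During CB ascent
θN* is clamped to ≤ −1e−3: the series diverges at θN* = 0, and a transient
Adam overshoot must not cross it.

## Decoding and Fisher information

Bayesian decoding evaluates log p(n|x) at each condition, adds the log
empirical prior, and normalizes (log-sum-exp).  Held-out log-posteriors
are floored at log(1e−12) before averaging so a model that assigns
numerically zero probability to the truth remains visible but finite; raw
values are returned alongside.  Cross-validation is stratified by
condition (guaranteeing every condition in every training fold) with
seeded fold assignment; information gain is the held-out per-trial
log-likelihood difference against a von Mises-tuned independent-Poisson
baseline refit on each training fold.

For minimal CMs the Fisher information is I(x) = ∂ₓθN(x)·Σ(x)·∂ₓθN(x),
reported per radian² of orientation.  ∂ₓθN is analytic for von Mises maps
(∂ₓvm = 2(−sin 2x, cos 2x)); central differences (default step 0.5°) serve
any other smooth map.  The equal-by-theory linear form ∂ₓμ·Σ⁻¹·∂ₓμ is
implemented with an analytic mean derivative (∂ₓμₖ = σ²ₖ ⊙ ∂ₓθN and the
index-probability chain rule), and the two agree to 1e−6 relative on
well-conditioned models; both match the definitional FI by enumeration on
two-neuron models.  Subpopulation information is computed as the linear FI
of the marginal — the exact mean derivative and covariance restricted to
the subset — because the marginal of a minimal CM over a neuron subset is
not itself a minimal CM, so the closed form does not apply to a truncated
parameter set.

The direct decoders map counts to the dX−1 natural parameters of a
categorical distribution (class 0 pinned at 0): linear, or an MLP with
sigmoid hidden layers.  Training is minibatch (500) Adam at a fixed 3e−4
learning rate with an 80/10/10 train/test/validation split and early
stopping on the test partition, returning the best-test-epoch parameters;
a `max_epochs` cap (default 300) bounds runtime, and both the learning
rate and cap are arguments.

## Synthetic generators

`random_ground_truth_cm` draws a von Mises CM with preferred stimuli tiled
over the doubled-angle circle (ρᵢ = i/dN·360°, i.e. preferred orientations
tiling 0–180°), log κᵢ ~ N(−0.1, 0.2), log γᵢ ~ N(0.2, 0.1) (mean and SD
of the log — the generator treats the second parameter of every normal law
as an SD), ΘNK entries ~ N(0.2, 0.1), θN*ᵢ ~ U(−1.5, −0.8), θN0ᵢ =
log γᵢ − log I₀(κᵢ), θK = 0.  The optional second stage re-centres θK so
the per-component index-probability natural parameters θK⁰(x) — measured
relative to component 1 on a 360-point grid over 180°, dense enough for
the sharpest lobes at dK ≤ 64 — share a common ceiling (no component
dominates any orientation), and can convert the smooth model to a discrete
lookup over a condition grid.

The information-limited generator draws a noisy orientation
s ~ vonMises(x, κ_noise) on the doubled angle, then independent Poisson
counts from a homogeneous von Mises-tuned source population (identical
gain 5 spikes/trial and concentration κ = 1, preferred orientations tiled
— homogeneity is what makes the source FI exactly additive; the resulting
peak ≈ 10.7 and trough ≈ 1.5 spikes/trial are typical of cortical counts
in 70–150 ms windows).  κ_noise is solved from a target circular SD of
p(s|x), default 10° of orientation.  Marginally over s the counts are
correlated, and no population, however large, can carry more information
about x than the noise channel itself: I_bound = 2κ²(1 − I₂(κ)/I₀(κ)) per
radian², ≈ 4κ for concentrated noise.  The bound is computed for whatever
noise level is configured, so the saturation checks are self-consistent.
A 20-component mixture fitted to 10,000 such responses exhibits the
signature pattern: source FI about s grows linearly in population size
while the fitted model's FI plateaus near the bound.

**What the generators do not emulate.**  Components are exactly von Mises
gain-modulated and noise is exactly CoM-Poisson conditional on the
component; real recordings have slow drifts, history dependence, and
higher-order structure none of which is generated here.  Passing the
recovery and information-limiting tests therefore demonstrates that the
estimator recovers models inside the model class at realistic trial
counts — not that cortical data satisfy the class.

## Problem sizes used in the checks

The packaged verification runs were sized for a single CPU: the recovery
experiment in the test suite uses the documented data scale (20 neurons,
5 components, 2000 trials) with a 100-iteration EM schedule, and
`scripts/acceptance.py` repeats it at the full 500-iteration reference
schedule; the information-limiting test fits 20 components to 10,000
responses of the 200-neuron source with 60 EM iterations.  Tuning-curve
recovery reaches r² ≈ 0.996–0.998 across seeds at either schedule.

## Known limitations

* CoM-Poisson work is truncation-bound: locations beyond a few thousand
  spikes/trial hit the series ceiling.
* Maximal CMs interpolate nothing between conditions and need every
  condition represented in training data.
* The EM objective is non-convex in the mixture as a whole; different
  seeds can find different component labelings (densities and moments are
  unaffected, and comparisons in the tests are permutation-safe).
* CB covariance matrices can be near-singular for strongly concentrated
  populations; the LFI cross-check reports the covariance-form FI and
  warns rather than failing when inversion is ill-conditioned.
* Continuous-stimulus posteriors are out of scope: decoding is over the
  discrete condition set, as is the cross-validation protocol.
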