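# Methods

## The discretized diffusion approximation

A continuous trait evolving by Brownian motion (rate σ², root state x₀) on a
phylogeny has a multivariate-normal tip density that is easy to evaluate — but
many biologically interesting variants (reflecting bounds, threshold
liability, censored observation, state-dependent rates and trends) do not.
The package replaces the continuous diffusion with a nearest-neighbor
continuous-time Markov chain on a lattice of n bins of width δ covering an
interval of trait space.  The chain's neighbor rate is

    q_c = σ² / (2 δ²)

and the approximation converges to the diffusion as δ → 0.  The probability
of the binned tip data is computed by Felsenstein's pruning algorithm, and for
m point-valued tips is converted to a density by

    log f = log p − m log δ.

Censored and discrete tips enter as probabilities (interval indicators over
bins), so they are not divided by δ.

Model variants differ only in the generator matrix:

* **Reflecting bounds** — outward transitions at the two edge rows are
  removed.  With the default `reassign` convention the lost rate is added to
  the inward transition (boundary rate 2·q_c); with `omit` it is dropped.
  The reassign chain is *not* symmetric: it satisfies detailed balance with
  stationary weights (1, 2, …, 2, 1), i.e. the edge bins carry half the mass
  of interior bins at stationarity.  The omit chain is symmetric with a
  uniform stationary law.  Both converge to the same reflected diffusion.
* **Linear trend μ** — asymmetric neighbor rates
  q± = σ²/(2δ²) ± μ/(2δ), valid only while |μ| ≤ σ²/δ (both rates must stay
  nonnegative).  During optimization each trend is kept strictly inside this
  box by the smooth map μ = 0.99·(σ²/δ)·tanh(u).
* **Joint discrete+continuous models** — k diffusion blocks of size n stacked
  into a k·n × k·n generator; off-diagonal blocks are q·I (the discrete
  character switches level without moving the trait).  The
  trait-dependent-rate model replaces the constant q with a four-parameter
  logistic of the bin center, separately per direction.

## Numerical engine

One generator decomposition serves every edge of a likelihood evaluation:

* Symmetric or reversible generators (diffusion with either boundary mode,
  state-dependent diffusion with equal switch rates) are symmetrized by the
  diagonal similarity given by their stationary weights and decomposed with a
  real `eigh`; each edge then costs two matrix products, batched across all
  edges whose subtrees complete at the same pruning wave.
* Trended and direction-asymmetric generators cannot be handled spectrally:
  the eigenvector basis of a drifted chain is ill-conditioned like
  exp(2|μ|·span/σ²), which overflows any realistic tolerance.  These use
  *uniformization*: exp(Qt)v = Σₖ Pois(k; Ωt) Rᵏ v with R = I + Q/Ω.  Every
  term is nonnegative, so the series is unconditionally stable; R is applied
  as a sparse matrix and all edges of a wave advance through the series
  together.  Intervals with Ωt > 500 are split so the Poisson weights stay in
  range.
* Small discrete-character generators (k ≤ 12 states) use a complex `eig`
  with an LU-solved change of basis — uniformization series become very long
  at the high rates the Mk optimizer explores.

Partial likelihoods are rescaled per node (log factors accumulated) so
200-taxon trees do not underflow.

Point tips are assigned to the bin containing their value, and the root state
to the bin containing x₀; the O(δ) quantization this induces is part of the
approximation and vanishes under grid refinement.  A consequence worth
knowing: the likelihood is *piecewise constant* in any parameter that moves
only through bin assignments (root state, thresholds), with plateaus about
one bin wide.  The Nelder–Mead optimizer therefore uses an absolute initial
simplex step (0.3–0.5 on the transformed scale) large enough to straddle
plateaus; rates and variances are optimized on log scale, bounded quantities
through tanh maps, and ordered thresholds as log-increments above the fixed
first threshold.

Grids are fixed once per fit from the data: the observed range padded by half
the range on each side for unbounded-type models (edges far enough away not
to act as spurious bounds), exactly the bounds for the bounded model, and a
±5·σ·√T liability span for the threshold model.  Default bin counts are 150–
200 for one-block models and ~100 per block for joint models; the multi-trend
fitter sizes its grid so δ ≈ 0.3 trait units, keeping the trend box roomy for
the regimes studied here.

## Model-specific conventions

* **Root priors.**  Continuous and trend models: point mass at the bin of x₀
  (x₀ is an ML parameter).  Threshold model: point mass at the estimated root
  liability bin.  Joint models: flat over levels × point mass at x₀'s bin
  (the data rarely inform the root level).
* **Threshold model.**  Liability is unitless, so σ² ≡ 1 and the first
  threshold is fixed at 0; free parameters are the remaining threshold
  positions and the root liability.  AIC counts (k−2) thresholds + 1.
* **Bounded model.**  Bounds default to the observed trait range, their MLE;
  when estimated that way they are counted as 2 extra AIC parameters.
* **Mk competitors.**  `ER` (one rate), `ordered-symmetric` (one rate per
  adjacent level pair, k−1 parameters), `ordered-asymmetric` (separate up and
  down rates per pair, 2(k−1)).  Rates are capped at 100× the tree depth —
  phylogenetically saturated data have likelihoods monotone in the rate, and
  an uncapped search walks to arbitrary magnitudes.
* **Two-step comparator.**  Stochastic character maps are sampled by
  forward-filtering/backward-sampling for node states and endpoint-
  conditioned uniformization for edge paths (robust at high rates, where
  rejection sampling stalls).  Per-map Gaussian state-dependent fits use the
  exact MVN likelihood with covariance Σᵢ σᵢ²·Cᵢ (Cᵢ = shared branch duration
  in level i); per-level rates are averaged across maps and ratios taken of
  the averages.

## Simulators

Every generating process has a forward simulator that is seeded and returns
its latent state (liabilities, discrete histories) so tests can condition on
the truth.  Brownian and state-dependent traits use exact Gaussian edge
increments; the discrete character uses exact Gillespie waiting times.
Bounded Brownian motion folds each Gaussian increment back into [a, b] —
folding is the method of images, so the simulated transition law is exact for
any step size (steps default to depth/1000).  The trait-dependent-switch
simulator is an Euler scheme (switch probability rate·dt per step) and is the
one simulator with genuine time-discretization error; it warns when
rate·dt > 0.1.

Pure-birth trees grow at unit speciation rate to the target tip count, add a
final waiting time, and are rescaled multiplicatively to the stated depth.
Non-ultrametric trees are made by shortening each terminal branch by
U(0, 0.5)·length and rescaling so the maximum tip height equals the original
depth — a stand-in for an unspecified empirical sampling process, exposed via
`max_fraction`.

## Replication studies and their scale

`ddpcm.studies.run_study` re-runs five simulation experiments
(bounded, threshold, semi-threshold, state-dependent, multi-trend).  The
generating conditions are: threshold — 200-taxon pure-birth trees of depth
3.0, liability BM with σ²=1, x₀ ~ U[−1,3], thresholds (0, 0.8, 1);
state-dependent — depth 1.0, q ~ U[1,10], σ²ₐ ~ U[0.5,2], σ²ᵦ ~ U[5,20];
multi-trend — non-ultrametric depth 10.0, q=0.5, μₐ ~ U[0.2,1],
μᵦ ~ U[−1,−0.2], σ² ~ U[0.3,1]; bounded and semi-threshold — log σ² ~ N(0,1)
with bounds/clamp at ±1 (tree depth 1.0, a package choice where unstated, so
that the censoring/bounding regime is informative rather than saturated).

The `desk` scale reduces *replicate counts* (25/20/10 for the three studies
above) but keeps the 200-taxon trees of the original experiments.  Tree size
is treated as a study condition, not a nuisance scale: profiling showed that
on 100-taxon depth-1.0 trees the Mk rate likelihood for the state-dependent
design loses its interior maximum entirely (the MLE diverges), and multi-
trend rate estimates inflate — the measured quantities change, not merely
their precision.  Replicate counts only widen sampling error, which the
reported tolerances absorb.  Monomorphic replicates (all tips in one state,
which the generating design permits) are recorded but excluded from
model-selection tallies, since no competitor model is fittable.

What the synthetic data do *not* emulate: measurement error, within-species
variation, tree misspecification, or extinction — passing tests demonstrate
internal consistency of estimator and generator, not robustness of the models
on empirical data.

## Known limitations

* Density evaluation at arbitrary points carries O(δ) bin-snapping error; the
  convergence tests therefore evaluate the discretized density surface (or
  its bilinear interpolation), which converges at O(δ²).
* x₀ is resolved only to bin width, and is weakly identified whenever the
  process forgets its root (beyond the relaxation time, or under strong
  trends on nearly ultrametric trees).
* The trait-dependent-switch model (8 sigmoid parameters) is expensive and
  its asymptotes are unidentified when the trait range is narrow; the fitter
  flags but does not prevent this.
* Threshold positions beyond the data's resolution drift to the grid edge;
  such replicates show up as large threshold estimates, not errors.
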