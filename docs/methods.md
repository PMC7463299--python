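# Methods

## Model

The skygrid coalescent treats the effective population size N_e(t) as a
piecewise-constant function of backwards time t (0 = the most recent sampled
tip across all loci, increasing into the past). M user-chosen grid points
0 < x_1 ≤ … ≤ x_M partition the past into M + 1 intervals; N_e(t) = θ_k on
[x_{k−1}, x_k) and θ_{M+1} beyond x_M. Inference is on γ_k = log θ_k.

For m genealogies assumed independent given N_e(t) (unlinked loci), each
inter-event span with v extant lineages contributes an exponential waiting
term with rate v(v−1)/(2θ_k), and each coalescence a factor 1/θ_k. Summing
spans interval by interval gives sufficient statistics per interval: the
coalescent count c_k and the pair-weighted waiting time
S_k = Σ v(v−1)Δt/2, aggregated across loci, so that

    log P(g | γ) = Σ_k [ −γ_k c_k − S_k e^{−γ_k} ]  + const.

All γ-independent constants (the per-event binomial factors) are dropped
throughout; only posterior ratios and gradients are ever needed.

Smoothness is imposed by a first-difference GMRF prior
P(γ | τ) ∝ τ^{M/2} exp[−(τ/2) γ'Qγ] with γ'Qγ = Σ (γ_{i+1} − γ_i)², and
τ ~ Gamma(a, b), a = b = 0.001 by default (weakly informative; both
overridable). The prior informs only the roughness of the trajectory, not
its level; intervals with no events are identified by the prior alone.

Conventions chosen where several readings are possible:

- An event exactly at a grid point belongs to the older interval
  (half-open intervals [x_{k−1}, x_k)).
- At exact time ties, sampling events sort before coalescent events;
  zero-length spans contribute nothing.
- With several loci whose most recent tips differ, every locus is anchored
  to the single global most-recent tip; the per-locus gap is the event
  sequence's `offset`.
- M is exposed directly and documented as yielding M + 1 population-size
  parameters (field descriptions sometimes conflate grid points and
  intervals; we avoid the ambiguity by naming both).

## Block-updating MCMC

One transition: draw f from the density ∝ f + 1/f on [1/F, F] (composition
sampling from its two mixture components; F defaults to 2.0, a moderate
conventional choice, fixed rather than auto-tuned) and set τ* = τ·f. Then
build a Gaussian approximation to P(γ | g, τ*): Newton–Raphson (damped, with
banded Cholesky solves; tolerance 1e-6 max-norm, cap 50 iterations) locates
the conditional mode γ̂, and a second-order Taylor expansion of the
likelihood terms about γ̂ gives precision τ*Q + Diag(S_k e^{−γ̂_k}) with
canonical linear term −c_k + S_k e^{−γ̂_k}(1 + γ̂_k) — with this sign the
approximation mean equals the mode whenever γ̂ is the mode, which is both an
algebraic identity and a regression test. A whole new γ* is sampled from the
approximation, and (τ*, γ*) accepted by Metropolis–Hastings.

Two subtleties:

- The reverse-move proposal density uses the approximation at the current τ.
  Because Newton–Raphson converges to the τ-conditional mode from any start,
  that approximation depends on τ only, making the Hastings ratio well
  defined without re-centring on γ*; the sampler caches it across iterations.
- The multiplicative τ proposal is *not* Hastings-neutral for this f
  density: the change-of-variables factor is g(1/f)/(f·g(f)) with
  g(f) = f + 1/f, which simplifies to 1/f since g(1/f) = g(f). The −log f
  correction is applied explicitly; the cross-kernel agreement test
  validates the resulting invariant distribution.

Newton–Raphson failure (possible when almost all S_k vanish) rejects the
proposal and is counted in diagnostics rather than aborting the chain.
The tridiagonal-plus-diagonal precision is handled with banded Cholesky
routines throughout (O(M) per solve); tests cross-check densities and
moments against dense linear algebra.

## Hamiltonian Monte Carlo

Momenta p ~ N(0, M) with identity mass matrix (diagonal override allowed;
no adaptive mass). Hamilton's equations are integrated with the leapfrog
scheme — half-step momentum, full-step position scaled by M⁻¹, half-step
momentum, n times with step size ε — and the proposal is accepted with
probability min(1, e^{−ΔH}). Momentum is fully refreshed every iteration.

τ is handled in one of two modes, which must agree (tested):

- `gibbs` (default): HMC on γ alone, then an exact conjugate draw
  τ | γ ~ Gamma(a + M/2, b + γ'Qγ/2).
- `joint`: position (γ, log τ), with the +log τ Jacobian of the transform
  added to the log target.

Defaults: n = 20 leapfrog steps, initial ε = 0.1/√d, target acceptance 0.8,
warmup fraction 0.1. During warmup ε adapts by Nesterov dual averaging
(μ = log 10ε₀, γ = 0.05, t₀ = 10, κ = 0.75) and is frozen at the smoothed
warmup-end value.

Step-size jitter: each iteration the frozen ε is multiplied by an
independent uniform draw on [0.1, 1]. The posterior's local curvature
varies strongly with τ — large τ stiffens the γ directions roughly like
√τ — and a single global step size stalls in the high-τ tail (in joint mode
this visibly under-dispersed the log τ marginal). The multiplier is
independent of the state, so detailed balance is untouched; disabling it
(`step_jitter = 1`) recovers the plain kernel.

## Reference random-walk kernel

A componentwise Gaussian random-walk Metropolis sampler (each γ_k in turn,
then log τ with its Jacobian) sharing no machinery with the other kernels.
Its only role is triangulation: all kernels must produce the same posterior
moments within Monte-Carlo error.

## Coalescent simulator

The simulator draws from the exact data-generating process of the
likelihood: going backwards in time, v lineages coalesce at rate
v(v−1)/(2 e^{γ_k}), with lineages inserted at their sampling times. Waiting
times are generated by time rescaling — the cumulative intensity is
integrated analytically across grid and sampling breakpoints (the rate is
constant within pieces), so draws are exact, with no thinning. The merging
pair is uniform over current pairs; topology does not enter the likelihood
but yields valid Newick output. Simulated trees anchor the most recent
sample at calendar 2000.0 by default (arbitrary, configurable).

What the simulator does *not* emulate about real data: genealogies are
given, not estimated — there is no sequence data, no phylogenetic
uncertainty, no substitution-model or clock misspecification, and no
recombination or population structure. Passing tests therefore demonstrate
correctness of the model, samplers and diagnostics on the model's own data,
not robustness to the upstream inference that produces genealogies in real
analyses.

## Diagnostics

ESS uses Geyer's initial-monotone-positive-sequence estimator
(FFT autocovariance; pair sums truncated at the first non-positive value and
forced non-increasing), clamped to at most 1.05× the series length; it is
validated against the AR(1) closed form n(1−ρ)/(1+ρ) and cross-checked
against an independent implementation. HPD intervals are the shortest
contiguous window containing ⌈level·n⌉ sorted samples. Trajectory summaries
are reported on the θ = e^γ scale (conventional for demographic
reconstructions), with γ-scale means alongside. Kernel comparisons use ESS
per wall-clock second: min and median across the γ components, plus the
precision separately, averaged over replicates with distinct derived seeds —
mirroring standard fixed-genealogy comparison protocols. Absolute
ESS-per-second values are hardware-bound; only within-run ratios are
meaningful.

## Problem sizes used in validation

The cross-kernel agreement runs use one fixed dataset of 3 loci × 20
heterochronous tips (sampling window 4, cutoff 10, M = 9, constant true
θ = 5 chosen so the expected TMRCA ≈ 9.5 matches the cutoff). Parameter
recovery uses replicated datasets of 100 loci × 10 isochronous tips under
constant θ = 10 with M = 4 and cutoff 20 ≈ the expected TMRCA of 18.
Simulator closed forms use 2×10⁴ replicates. These sizes give Monte-Carlo
standard errors comfortably below the tested tolerances.

## Numerical notes and limitations

- Tip-date/branch-length consistency tolerance is 1e-6 absolute (float
  round-trips through text formats); the worst root-to-tip discrepancy is
  reported on failure.
- τ ≤ 0 is rejected at the API boundary; the gamma prior with a < 1
  diverges as τ → 0 but the samplers never evaluate it at 0 (multiplicative
  and log-scale proposals keep τ > 0).
- Non-finite gradients or Hamiltonians during leapfrog reject the proposal
  silently (overflow of e^{−γ} on wild excursions is expected and benign).
- Grid choice is the user's: evenly spaced via `build_grid` or fully custom;
  no data-driven grid selection is provided.
- The covariate extension of the demographic model (regression of log N_e
  on external time series) is out of scope, as are sequence likelihoods,
  tree inference, and adaptive mass matrices for HMC.
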