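# skygrid

Bayesian nonparametric inference of past population dynamics from fixed,
dated genealogies, with two interchangeable posterior samplers — a
block-updating MCMC scheme and a Hamiltonian Monte Carlo kernel — built to
assess their statistical correctness and relative sampling efficiency.

The package is aimed at phylodynamics researchers and methods developers who
want a self-contained, testable implementation of the skygrid coalescent
model: the demographic function, the samplers, an exact coalescent simulator
of the model's own data-generating process, and the effective-sample-size
diagnostics used to compare transition kernels.

## Model

The effective population size N<sub>e</sub>(t) is piecewise constant on
intervals defined by M grid points 0 < x<sub>1</sub> ≤ … ≤ x<sub>M</sub>
(backwards time, 0 = most recent tip), giving parameters
θ = (θ<sub>1</sub>, …, θ<sub>M+1</sub>), estimated as γ<sub>k</sub> = log θ<sub>k</sub>.
Given m unlinked genealogies, the coalescent likelihood reduces to
per-interval sufficient statistics — coalescent counts c<sub>k</sub> and
weighted waiting times S<sub>k</sub> = Σ v(v−1)Δt/2:

    log P(g | γ) = Σ_k [ −γ_k c_k − S_k e^{−γ_k} ]   (+ const)

A Gaussian Markov random field prior smooths the trajectory,
P(γ | τ) ∝ τ^{M/2} exp[−(τ/2) Σ (γ<sub>i+1</sub> − γ<sub>i</sub>)²], and the
precision carries a Gamma(a, b) prior with a = b = 0.001 by default.

Samplers:

- **bumcmc** — proposes τ\* = τ·f (f ∝ f + 1/f on [1/F, F]) and a whole new
  γ vector from a mode-centred Gaussian approximation to P(γ | g, τ\*)
  (Newton–Raphson mode, tridiagonal precision τQ + Diag(S_k e^{−γ̂_k})),
  accepted jointly by Metropolis–Hastings.
- **hmc** — leapfrog-integrated Hamiltonian proposals for γ (with a
  conjugate Gibbs draw for τ) or for (γ, log τ) jointly; identity mass
  matrix, dual-averaging step-size adaptation during warmup.
- **rwmh** — a deliberately simple componentwise random-walk reference
  kernel used for cross-validation of the other two.

## Worked example

```python
import numpy as np
import skygrid as sg

# simulate 3 loci of 20 tips under constant theta = 5, grid of 9 points
rng = np.random.default_rng(1)
grid = sg.build_grid(cutoff=10.0, M=9)
truth = np.full(10, np.log(5.0))
gens = sg.simulate_dataset(3, [0.0] * 20, grid, truth, rng)

# convert to event sequences and sufficient statistics
ref = max(g.most_recent_tip_date for g in gens)
seqs = [sg.extract_event_sequence(g, ref) for g in gens]
stats = sg.sufficient_statistics(seqs, grid)

# sample the posterior with the block-updating kernel
spec = sg.GMRFSpec(grid.n_intervals)
init = sg.SkygridState(np.zeros(10), 1.0)
trace = sg.run_bumcmc(init, stats, spec, sg.BUMCMCSettings(),
                      iterations=20000, thin=10, rng=rng).burned()

table = sg.trajectory_summary(trace, grid)
print(table[["interval", "t_start", "median", "hpd_low", "hpd_high"]].head(3))
print(f"acceptance {trace.acceptance_rate:.2f}")
```

Output:

```
   interval   t_start    median   hpd_low  hpd_high
0         1  0.000000  4.605273  3.394086  5.884288
1         2  1.111111  4.843356  3.350610  7.246352
2         3  2.222222  4.835351  2.927176  8.179882
acceptance 0.63
```

The `median` column is the posterior median of θ<sub>k</sub> = e^{γ_k} for
each demographic interval (truth: 5 everywhere); `hpd_low`/`hpd_high` bound
the 95% highest-posterior-density interval, which widens for older intervals
where fewer coalescent events fall.

The same analysis runs from the shell:

```
skygrid simulate --loci 3 --tips 20 --cutoff 10 --grid-points 9 \
    --log-pop-sizes 1.61,1.61,1.61,1.61,1.61,1.61,1.61,1.61,1.61,1.61 --seed 1
skygrid analyze --trees simulated.trees.nwk --dates simulated.dates.tsv \
    --cutoff 10 --grid-points 9 --sampler hmc --iterations 20000 --seed 1
skygrid benchmark --samplers bumcmc,hmc --replicates 5 --seed 1
```

`analyze` writes a Tracer-loadable tab-separated parameter log, a trajectory
CSV and a diagnostics JSON; `benchmark` reports min/median ESS per second of
the log population sizes and ESS per second of the precision, per kernel.

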