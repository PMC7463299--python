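"""Reference univariate random-walk Metropolis-Hastings sampler.

A deliberately simple kernel used as an independent check on the block
updating and Hamiltonian kernels: each iteration sweeps over the gamma
components with univariate Gaussian random-walk proposals (accepted on the
local change in log posterior) and then updates log tau the same way, with
the +log tau Jacobian of the log transform included in the target.  It
shares no proposal machinery with the other kernels.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .core import GMRFSpec, SkygridState, SuffStats, log_posterior
from .diagnostics import Trace

__all__ = ["RWMHSettings", "run_rwmh"]


@dataclass(frozen=True)
class RWMHSettings:
    step_gamma: float = 0.5
    step_logtau: float = 0.8

    def __post_init__(self):
        if self.step_gamma <= 0 or self.step_logtau <= 0:
            raise ValueError("proposal step sizes must be positive")


def _delta_gamma_k(gamma, k, new_gk, tau, stats):
    """Change in log posterior when gamma_k alone moves to new_gk."""
    old = gamma[k]
    d_lik = -(new_gk - old) * stats.c[k] - stats.S[k] * (
        np.exp(-new_gk) - np.exp(-old)
    )
    d_quad = 0.0
    if k > 0:
        d_quad += (new_gk - gamma[k - 1]) ** 2 - (old - gamma[k - 1]) ** 2
    if k < gamma.size - 1:
        d_quad += (gamma[k + 1] - new_gk) ** 2 - (gamma[k + 1] - old) ** 2
    return d_lik - 0.5 * tau * d_quad


def run_rwmh(
    init: SkygridState,
    stats: SuffStats,
    spec: GMRFSpec,
    settings: RWMHSettings,
    iterations: int,
    thin: int,
    rng: np.random.Generator,
) -> Trace:
    """Run the componentwise random-walk chain; returns a thinned trace.

    The acceptance rate reported is averaged over all univariate updates.
    """
    if iterations < 0 or thin < 1:
        raise ValueError("iterations must be >= 0 and thin >= 1")
    gamma = init.gamma.copy()
    tau = init.tau
    n = gamma.size
    gammas = [gamma.copy()]
    taus = [tau]
    lps = [log_posterior(SkygridState(gamma, tau), stats, spec)]
    accepted = 0
    total = 0
    t0 = time.perf_counter()
    for it in range(1, iterations + 1):
        for k in range(n):
            cand = gamma[k] + settings.step_gamma * rng.standard_normal()
            delta = _delta_gamma_k(gamma, k, cand, tau, stats)
            total += 1
            if np.log(rng.uniform()) < delta:
                gamma[k] = cand
                accepted += 1
        # log tau random walk; target includes the log-transform Jacobian
        w = np.log(tau)
        w_new = w + settings.step_logtau * rng.standard_normal()
        tau_new = np.exp(w_new)
        q = spec.quad_form(gamma)
        delta = (
            (0.5 * spec.M + spec.a) * (w_new - w)
            - (0.5 * q + spec.b) * (tau_new - tau)
        )
        total += 1
        if np.log(rng.uniform()) < delta:
            tau = tau_new
            accepted += 1
        if it % thin == 0:
            gammas.append(gamma.copy())
            taus.append(tau)
            lps.append(log_posterior(SkygridState(gamma, tau), stats, spec))
    wall = time.perf_counter() - t0
    return Trace(
        gamma=np.array(gammas),
        tau=np.array(taus),
        log_posteriors=np.array(lps),
        acceptance_rate=accepted / total if total else 0.0,
        iteration_stride=thin,
        wall_time=wall,
        meta={"kernel": "rwmh"},
    )
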