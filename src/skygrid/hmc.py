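"""Hamiltonian Monte Carlo for the skygrid parameters.

The sampler introduces auxiliary momenta p ~ N(0, M) with identity (or
user-supplied diagonal) mass matrix, and proposes distant states by
integrating Hamilton's equations with the leapfrog scheme: a half step of
momentum, a full step of position scaled by the inverse mass, and a second
half step of momentum, repeated n times with step size epsilon.  Proposals
are accepted with probability min(1, exp(-dH)).

Two treatments of the GMRF precision tau are available:

``gibbs`` (default)
    HMC moves gamma only; tau is refreshed by an exact draw from its
    conjugate gamma full conditional each iteration.
``joint``
    The position vector is (gamma, log tau); the log transform contributes
    a +log tau Jacobian term to the log target.  The marginal posterior of
    tau must agree with gibbs mode — that agreement is a test.

The step size adapts during a warmup phase by dual averaging toward a target
acceptance probability and is frozen thereafter; the number of leapfrog
steps is fixed by the user.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    GMRFSpec,
    SkygridState,
    SuffStats,
    coalescent_loglik,
    gmrf_logprior,
    grad_gamma,
    log_posterior,
    tau_full_conditional,
    tau_logprior,
)
from .diagnostics import Trace

__all__ = [
    "HMCSettings",
    "PhaseState",
    "leapfrog",
    "hmc_step",
    "gibbs_tau",
    "adapt_step_size",
    "run_hmc",
    "DualAveraging",
]


@dataclass(frozen=True)
class HMCSettings:
    """Leapfrog and adaptation settings.

    ``epsilon=None`` selects the dimension-scaled default ``0.1 / sqrt(d)``
    at run time.  ``warmup_fraction`` is the fraction of iterations during
    which epsilon adapts by dual averaging; afterwards it is frozen.

    ``step_jitter`` multiplies the step size by an independent uniform draw
    on ``[step_jitter, 1]`` each iteration (1 disables jittering).  The
    local curvature of the posterior varies strongly with the precision tau
    — large tau makes the gamma directions stiff — and occasional small
    steps let trajectories be accepted there, where a single frozen step
    size would stall; the draw is independent of the state, so detailed
    balance is untouched.
    """

    epsilon: float | None = None
    n_leapfrog: int = 20
    mass_diagonal: np.ndarray | None = None
    target_accept: float = 0.8
    warmup_fraction: float = 0.1
    tau_update: str = "gibbs"
    step_jitter: float = 0.1

    def __post_init__(self):
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_leapfrog < 1:
            raise ValueError("n_leapfrog must be >= 1")
        if self.mass_diagonal is not None:
            m = np.asarray(self.mass_diagonal, dtype=float)
            if np.any(m <= 0):
                raise ValueError("mass_diagonal must be strictly positive")
            object.__setattr__(self, "mass_diagonal", m)
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")
        if self.tau_update not in ("gibbs", "joint"):
            raise ValueError(
                f"tau_update must be 'gibbs' or 'joint', got {self.tau_update!r}"
            )
        if not (0.0 < self.step_jitter <= 1.0):
            raise ValueError("step_jitter must lie in (0, 1]")

    def initial_epsilon(self, d: int) -> float:
        return self.epsilon if self.epsilon is not None else 0.1 / np.sqrt(d)


@dataclass
class PhaseState:
    """A point in phase space: position and conjugate momentum."""

    position: np.ndarray
    momentum: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.momentum = np.asarray(self.momentum, dtype=float)
        if self.position.shape != self.momentum.shape:
            raise ValueError("position and momentum must have equal shapes")
        if not np.all(np.isfinite(self.momentum)):
            raise ValueError("momentum must be finite")


class GradientError(FloatingPointError):
    """Non-finite gradient encountered during leapfrog integration."""

    def __init__(self, position):
        super().__init__(f"non-finite gradient at position {position}")
        self.position = position


def leapfrog(
    phase: PhaseState,
    epsilon: float,
    n: int,
    grad_logpdf,
    mass: np.ndarray | None = None,
) -> PhaseState:
    """Integrate Hamiltonian dynamics for n leapfrog steps of size epsilon.

    ``grad_logpdf`` returns the gradient of the log target density at a
    position (so dp/dt = grad log pi).  Deterministic; raises
    :class:`GradientError` when the gradient is non-finite.
    """
    if epsilon <= 0 or n < 1:
        raise ValueError("epsilon must be > 0 and n >= 1")
    q = phase.position.copy()
    p = phase.momentum.copy()
    inv_mass = 1.0 if mass is None else 1.0 / np.asarray(mass, dtype=float)
    g = grad_logpdf(q)
    if not np.all(np.isfinite(g)):
        raise GradientError(q)
    for _ in range(n):
        p = p + 0.5 * epsilon * g
        q = q + epsilon * inv_mass * p
        g = grad_logpdf(q)
        if not np.all(np.isfinite(g)):
            raise GradientError(q)
        p = p + 0.5 * epsilon * g
    return PhaseState(position=q, momentum=p)


def _log_target_gibbs(gamma, tau, stats, spec):
    return coalescent_loglik(stats, gamma) + gmrf_logprior(gamma, tau, spec)


def _joint_position(state: SkygridState) -> np.ndarray:
    return np.concatenate((state.gamma, [np.log(state.tau)]))


def _joint_log_target(pos, stats, spec):
    gamma, w = pos[:-1], pos[-1]
    tau = np.exp(w)
    st = SkygridState(gamma, tau)
    # +w: Jacobian of the log transform of tau
    return log_posterior(st, stats, spec) + w


def _joint_grad(pos, stats, spec):
    gamma, w = pos[:-1], pos[-1]
    tau = np.exp(w)
    st = SkygridState(gamma, tau)
    g_gamma = grad_gamma(st, stats, spec)
    q = spec.quad_form(gamma)
    g_w = 0.5 * spec.M + spec.a - tau * (0.5 * q + spec.b)
    return np.concatenate((g_gamma, [g_w]))


def hmc_step(
    state: SkygridState,
    stats: SuffStats,
    spec: GMRFSpec,
    settings: HMCSettings,
    rng: np.random.Generator,
    epsilon: float | None = None,
):
    """One HMC transition; returns ``(new_state, accepted, diagnostics)``.

    In gibbs mode the position block is gamma alone (tau held fixed); in
    joint mode it is (gamma, log tau).  Momentum is refreshed from N(0, M)
    and discarded after the step.  A non-finite Hamiltonian rejects.
    """
    joint = settings.tau_update == "joint"
    if joint:
        q0 = _joint_position(state)
        logpdf = lambda q: _joint_log_target(q, stats, spec)
        grad = lambda q: _joint_grad(q, stats, spec)
    else:
        tau = state.tau
        q0 = state.gamma.copy()
        logpdf = lambda q: _log_target_gibbs(q, tau, stats, spec)
        grad = lambda q: (
            -stats.c + stats.S * np.exp(-q) - tau * spec.Q_dot(q)
        )
    d = q0.size
    mass = settings.mass_diagonal
    if mass is not None and mass.size != d:
        raise ValueError("mass_diagonal length must match position dimension")
    eps = epsilon if epsilon is not None else settings.initial_epsilon(d)
    sd = np.ones(d) if mass is None else np.sqrt(mass)
    p0 = sd * rng.standard_normal(d)
    inv_mass = np.ones(d) if mass is None else 1.0 / mass
    h0 = -logpdf(q0) + 0.5 * float(np.sum(inv_mass * p0 * p0))
    try:
        # overflow in exp(-gamma) on wild excursions yields an infinite
        # gradient or Hamiltonian, which rejects below; keep it silent
        with np.errstate(over="ignore", invalid="ignore"):
            out = leapfrog(PhaseState(q0, p0), eps, settings.n_leapfrog, grad, mass)
            h1 = -logpdf(out.position) + 0.5 * float(
                np.sum(inv_mass * out.momentum**2)
            )
    except (GradientError, FloatingPointError, ValueError):
        return state, False, {"accept_prob": 0.0, "delta_h": np.inf}
    delta_h = h1 - h0
    if not np.isfinite(delta_h):
        return state, False, {"accept_prob": 0.0, "delta_h": delta_h}
    accept_prob = min(1.0, float(np.exp(-delta_h)))
    diag = {"accept_prob": accept_prob, "delta_h": float(delta_h)}
    if rng.uniform() < accept_prob:
        if joint:
            new = SkygridState(out.position[:-1], float(np.exp(out.position[-1])))
        else:
            new = SkygridState(out.position, state.tau)
        return new, True, diag
    return state, False, diag


def gibbs_tau(gamma, spec: GMRFSpec, rng: np.random.Generator) -> float:
    """Exact draw from the conjugate full conditional of tau."""
    shape, rate = tau_full_conditional(gamma, spec)
    return float(rng.gamma(shape, 1.0 / rate))


@dataclass
class DualAveraging:
    """Nesterov dual-averaging step-size adaptation (Hoffman & Gelman).

    Tracks a running discrepancy between the realized and target acceptance
    probabilities and moves log epsilon against it; ``finalize`` returns the
    smoothed value used after warmup.
    """

    mu: float
    target: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _t: int = 0
    _h_bar: float = 0.0
    _log_eps: float = 0.0
    _log_eps_bar: float = 0.0

    @classmethod
    def start(cls, eps0: float, target: float) -> "DualAveraging":
        obj = cls(mu=float(np.log(10.0 * eps0)), target=target)
        obj._log_eps = float(np.log(eps0))
        obj._log_eps_bar = float(np.log(eps0))
        return obj

    def update(self, accept_prob: float) -> float:
        self._t += 1
        t = self._t
        eta = 1.0 / (t + self.t0)
        self._h_bar = (1 - eta) * self._h_bar + eta * (self.target - accept_prob)
        self._log_eps = self.mu - np.sqrt(t) / self.gamma * self._h_bar
        w = t ** (-self.kappa)
        self._log_eps_bar = w * self._log_eps + (1 - w) * self._log_eps_bar
        return float(np.exp(self._log_eps))

    def finalize(self) -> float:
        return float(np.exp(self._log_eps_bar))


def adapt_step_size(history, settings: HMCSettings, iteration: int,
                    eps0: float | None = None, n_warmup: int | None = None) -> float:
    """Step size after replaying dual averaging over an acceptance record.

    ``history`` is the sequence of realized acceptance probabilities so far.
    During warmup (the first ``n_warmup`` iterations, default derived from
    ``settings.warmup_fraction`` when the total is known) the adapting value
    is returned; past warmup the frozen, smoothed warmup-end value is
    returned regardless of later history entries.
    """
    if eps0 is None:
        eps0 = settings.initial_epsilon(1)
    da = DualAveraging.start(eps0, settings.target_accept)
    if n_warmup is None:
        n_warmup = len(history)
    eps = eps0
    for ap in list(history)[:n_warmup]:
        eps = da.update(ap)
    if iteration >= n_warmup:
        return da.finalize()
    return eps


def run_hmc(
    init: SkygridState,
    stats: SuffStats,
    spec: GMRFSpec,
    settings: HMCSettings,
    iterations: int,
    thin: int,
    rng: np.random.Generator,
) -> Trace:
    """Run the HMC chain; returns a thinned :class:`Trace`.

    Each iteration performs one HMC transition and, in gibbs mode, one
    conjugate tau draw.  The step size adapts for the first
    ``warmup_fraction`` of iterations, then stays fixed.
    """
    if iterations < 0 or thin < 1:
        raise ValueError("iterations must be >= 0 and thin >= 1")
    state = init.copy()
    d = spec.n + (1 if settings.tau_update == "joint" else 0)
    eps = settings.initial_epsilon(d)
    n_warmup = int(np.floor(settings.warmup_fraction * iterations))
    da = DualAveraging.start(eps, settings.target_accept)
    gammas = [state.gamma.copy()]
    taus = [state.tau]
    lps = [log_posterior(state, stats, spec)]
    accepted = 0
    t0 = time.perf_counter()
    for it in range(1, iterations + 1):
        eps_it = eps * rng.uniform(settings.step_jitter, 1.0)
        state, acc, diag = hmc_step(state, stats, spec, settings, rng, eps_it)
        accepted += acc
        if settings.tau_update == "gibbs":
            state = SkygridState(state.gamma, gibbs_tau(state.gamma, spec, rng))
        if it <= n_warmup:
            eps = da.update(diag["accept_prob"])
            if it == n_warmup:
                eps = da.finalize()
        if it % thin == 0:
            gammas.append(state.gamma.copy())
            taus.append(state.tau)
            lps.append(log_posterior(state, stats, spec))
    wall = time.perf_counter() - t0
    return Trace(
        gamma=np.array(gammas),
        tau=np.array(taus),
        log_posteriors=np.array(lps),
        acceptance_rate=accepted / iterations if iterations else 0.0,
        iteration_stride=thin,
        wall_time=wall,
        meta={"kernel": f"hmc-{settings.tau_update}", "epsilon": eps},
    )
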