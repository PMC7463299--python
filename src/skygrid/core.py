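"""Skygrid model core: grid, sufficient statistics, likelihood, priors, gradient.

The skygrid models the effective population size :math:`N_e(t)` as a
piecewise-constant function of time before the present, changing value only at
pre-specified grid points ``x_1 <= ... <= x_M`` (with ``x_0 = 0``).  The M grid
points define M+1 demographic intervals with values
``theta = (theta_1, ..., theta_{M+1})``; inference is carried out on
``gamma_k = log(theta_k)``.

Given one or more genealogies, the coalescent likelihood depends on the data
only through per-interval sufficient statistics: the number of coalescent
events ``c_k`` in interval k and the lineage-pair-weighted waiting time
``S_k = sum v(v-1) dt / 2``.  Up to a gamma-independent constant,

    log P(g | gamma) = sum_k [ -gamma_k c_k - S_k exp(-gamma_k) ].

Smoothness of the trajectory is encouraged by a Gaussian Markov random field
prior on first differences of gamma with precision tau, and tau itself
carries a Gamma(a, b) prior (a = b = 0.001 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "SkygridState",
    "SuffStats",
    "GMRFSpec",
    "build_grid",
    "sufficient_statistics",
    "coalescent_loglik",
    "interval_loglik_direct",
    "gmrf_logprior",
    "tau_logprior",
    "log_posterior",
    "grad_gamma",
    "tau_full_conditional",
]


@dataclass(frozen=True)
class GridSpec:
    """Temporal grid ``x_1..x_M`` partitioning the past into M+1 intervals.

    Interval k is ``[x_{k-1}, x_k)`` with ``x_0 = 0``; interval M+1 is
    ``[x_M, inf)``.  An event exactly at a grid point belongs to the older
    interval.
    """

    grid_points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.grid_points, dtype=float)
        if pts.ndim != 1 or pts.size < 1:
            raise ValueError("grid_points must be a non-empty 1-d array")
        if pts[0] <= 0 or np.any(np.diff(pts) < 0):
            raise ValueError("grid points must satisfy 0 < x_1 <= ... <= x_M")
        object.__setattr__(self, "grid_points", pts)

    @property
    def M(self) -> int:
        return self.grid_points.size

    @property
    def cutoff(self) -> float:
        return float(self.grid_points[-1])

    @property
    def n_intervals(self) -> int:
        return self.M + 1

    def interval_of(self, t):
        """0-based interval index of backwards time(s) t (boundary -> older)."""
        return np.searchsorted(self.grid_points, t, side="right")


def build_grid(cutoff: float, M: int) -> GridSpec:
    """Evenly spaced grid: ``x_k = k * cutoff / M``, ``x_M = cutoff`` exactly."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    pts = np.arange(1, M + 1) * (cutoff / M)
    pts[-1] = cutoff
    return GridSpec(pts)


@dataclass
class SkygridState:
    """Current model parameters: log population sizes and GMRF precision."""

    gamma: np.ndarray
    tau: float

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float)).copy()
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("gamma must be finite")
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")

    def copy(self) -> "SkygridState":
        return SkygridState(self.gamma.copy(), self.tau)


@dataclass(frozen=True)
class SuffStats:
    """Per-interval coalescent counts c and weighted waiting times S."""

    c: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        S = np.asarray(self.S, dtype=float)
        if c.shape != S.shape or c.ndim != 1:
            raise ValueError("c and S must be 1-d arrays of equal length")
        if np.any(c < 0) or np.any(S < 0):
            raise ValueError("c and S must be nonnegative")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "S", S)

    @property
    def n_intervals(self) -> int:
        return self.c.size

    def __add__(self, other: "SuffStats") -> "SuffStats":
        return SuffStats(self.c + other.c, self.S + other.S)


@dataclass(frozen=True)
class GMRFSpec:
    """GMRF smoothing prior specification for a grid with ``n = M+1`` intervals.

    The structure matrix Q is the tridiagonal first-difference penalty with
    diagonal (1, 2, ..., 2, 1) and off-diagonals -1, so that
    ``gamma' Q gamma = sum_i (gamma_{i+1} - gamma_i)^2``.  a and b are the
    shape and rate of the gamma hyperprior on the precision tau.
    """

    n: int
    a: float = 0.001
    b: float = 0.001

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least two intervals (M >= 1)")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("gamma hyperprior parameters must be positive")

    @property
    def M(self) -> int:
        return self.n - 1

    @property
    def Q(self) -> np.ndarray:
        n = self.n
        Q = np.zeros((n, n))
        idx = np.arange(n)
        Q[idx, idx] = 2.0
        Q[0, 0] = Q[-1, -1] = 1.0
        Q[idx[:-1], idx[:-1] + 1] = -1.0
        Q[idx[:-1] + 1, idx[:-1]] = -1.0
        return Q

    def quad_form(self, gamma: np.ndarray) -> float:
        """gamma' Q gamma, evaluated as the sum of squared first differences."""
        return float(np.sum(np.diff(gamma) ** 2))

    def Q_dot(self, gamma: np.ndarray) -> np.ndarray:
        """Q @ gamma in O(n) without forming Q."""
        g = np.asarray(gamma, dtype=float)
        out = 2.0 * g
        out[0] -= g[0]
        out[-1] -= g[-1]
        out[:-1] -= g[1:]
        out[1:] -= g[:-1]
        return out


def sufficient_statistics(seqs, grid: GridSpec) -> SuffStats:
    """Aggregate (c_k, S_k) over loci.

    Each inter-event span of a locus's event sequence is split at the grid
    points it straddles; the piece falling in interval k contributes
    ``v (v-1) dt / 2`` to S_k, where v is the lineage count on the span.
    A coalescent event exactly at a grid point counts toward the older
    interval.
    """
    n = grid.n_intervals
    c = np.zeros(n)
    S = np.zeros(n)
    pts = grid.grid_points
    for seq in seqs:
        times = seq.times
        v = np.cumsum(seq.kinds)  # lineage count after each event
        coal = times[seq.kinds < 0]
        np.add.at(c, np.searchsorted(pts, coal, side="right"), 1.0)
        for j in range(times.size - 1):
            t0, t1 = times[j], times[j + 1]
            if t1 <= t0:
                continue
            w = v[j] * (v[j] - 1) / 2.0
            if w == 0:
                continue
            # split [t0, t1] at interior grid points
            lo = np.searchsorted(pts, t0, side="right")
            hi = np.searchsorted(pts, t1, side="left")
            cuts = np.concatenate(([t0], pts[lo:hi], [t1]))
            ks = np.searchsorted(pts, cuts[:-1], side="right")
            np.add.at(S, ks, w * np.diff(cuts))
    return SuffStats(c, S)


def coalescent_loglik(stats: SuffStats, gamma: np.ndarray) -> float:
    """Coalescent log likelihood from sufficient statistics.

    Returns ``sum_k (-gamma_k c_k - S_k exp(-gamma_k))``; exact up to a
    gamma-independent constant (the per-event binomial factors are dropped).
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != stats.c.shape:
        raise ValueError(
            f"gamma has length {gamma.size}, expected {stats.c.size}"
        )
    return float(np.sum(-gamma * stats.c - stats.S * np.exp(-gamma)))


def interval_loglik_direct(seq, grid: GridSpec, gamma: np.ndarray) -> float:
    """Direct per-span evaluation of the coalescent log likelihood.

    Walks the event sequence span by span, accumulating the exponential
    waiting-time terms ``-v(v-1) dt / (2 theta)`` piecewise across grid points
    and a ``-gamma_k`` term per coalescent event, without precomputing (c, S).
    Serves as an independent route to :func:`coalescent_loglik`.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size != grid.n_intervals:
        raise ValueError("gamma length must equal number of intervals")
    theta_inv = np.exp(-gamma)
    pts = grid.grid_points
    total = 0.0
    times = seq.times
    v = np.cumsum(seq.kinds)
    for j in range(times.size):
        if seq.kinds[j] < 0:  # coalescent event: 1/theta factor
            k = int(np.searchsorted(pts, times[j], side="right"))
            total -= gamma[k]
        if j + 1 < times.size:
            t0, t1 = times[j], times[j + 1]
            if t1 <= t0 or v[j] < 2:
                continue
            w = v[j] * (v[j] - 1) / 2.0
            lo = np.searchsorted(pts, t0, side="right")
            hi = np.searchsorted(pts, t1, side="left")
            cuts = np.concatenate(([t0], pts[lo:hi], [t1]))
            for piece_start, piece_end in zip(cuts[:-1], cuts[1:]):
                k = int(np.searchsorted(pts, piece_start, side="right"))
                total -= w * (piece_end - piece_start) * theta_inv[k]
    return total


def gmrf_logprior(gamma: np.ndarray, tau: float, spec: GMRFSpec) -> float:
    """Log GMRF prior density ``(M/2) log tau - (tau/2) gamma' Q gamma``."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return 0.5 * spec.M * np.log(tau) - 0.5 * tau * spec.quad_form(gamma)


def tau_logprior(tau: float, spec: GMRFSpec) -> float:
    """Log gamma-prior density ``(a-1) log tau - b tau`` (unnormalized)."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return (spec.a - 1.0) * np.log(tau) - spec.b * tau


def log_posterior(state: SkygridState, stats: SuffStats, spec: GMRFSpec) -> float:
    """Unnormalized log posterior of (gamma, tau) given the genealogies."""
    return (
        coalescent_loglik(stats, state.gamma)
        + gmrf_logprior(state.gamma, state.tau, spec)
        + tau_logprior(state.tau, spec)
    )


def grad_gamma(state: SkygridState, stats: SuffStats, spec: GMRFSpec) -> np.ndarray:
    """Gradient of the log posterior with respect to gamma.

    Component k: ``-c_k + S_k exp(-gamma_k) - tau (Q gamma)_k``.
    """
    g = state.gamma
    return -stats.c + stats.S * np.exp(-g) - state.tau * spec.Q_dot(g)


def tau_full_conditional(gamma: np.ndarray, spec: GMRFSpec):
    """Gamma full conditional of tau: shape ``a + M/2``, rate ``b + q/2``.

    Follows from conjugacy of the gamma hyperprior with the GMRF density,
    where ``q = gamma' Q gamma`` is the sum of squared first differences.
    """
    shape = spec.a + 0.5 * spec.M
    rate = spec.b + 0.5 * spec.quad_form(gamma)
    return shape, rate
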