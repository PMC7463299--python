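"""MCMC output container and diagnostics: ESS, HPD intervals, trajectories.

The effective sample size uses Geyer's initial-monotone-positive-sequence
estimator: autocorrelations are summed in adjacent pairs, truncated at the
first non-positive pair sum, and the pair sums are forced non-increasing
before summation.  ESS per unit of wall-clock time is the currency for
comparing transition kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GridSpec, SkygridState

__all__ = [
    "Trace",
    "EssSummary",
    "ess",
    "ess_per_time",
    "hpd_interval",
    "trajectory_summary",
]


@dataclass
class Trace:
    """Thinned posterior samples of (gamma, tau) with bookkeeping.

    ``gamma`` has one row per stored sample (the initial state is row 0) and
    one column per demographic interval.
    """

    gamma: np.ndarray
    tau: np.ndarray
    log_posteriors: np.ndarray
    acceptance_rate: float
    iteration_stride: int = 1
    wall_time: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.tau = np.asarray(self.tau, dtype=float)
        self.log_posteriors = np.asarray(self.log_posteriors, dtype=float)
        n = self.gamma.shape[0]
        if self.tau.size != n or self.log_posteriors.size != n:
            raise ValueError("gamma, tau and log_posteriors lengths differ")
        if not (0.0 <= self.acceptance_rate <= 1.0):
            raise ValueError("acceptance_rate must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.gamma.shape[1]

    def state(self, i: int) -> SkygridState:
        return SkygridState(self.gamma[i], float(self.tau[i]))

    @property
    def states(self) -> list:
        return [self.state(i) for i in range(self.n_samples)]

    def burned(self, fraction: float = 0.1) -> "Trace":
        """Copy of the trace with the first ``fraction`` of samples removed."""
        k = int(self.n_samples * fraction)
        return Trace(
            self.gamma[k:], self.tau[k:], self.log_posteriors[k:],
            self.acceptance_rate, self.iteration_stride, self.wall_time,
            dict(self.meta),
        )


def ess(series) -> float:
    """Effective sample size of a scalar MCMC series.

    Geyer initial-monotone-positive-sequence estimator of the integrated
    autocorrelation time; raises on constant (zero-variance) input.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"series too short for ESS ({n} < 10)")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0 or not np.isfinite(var):
        raise ValueError("zero-variance (degenerate) series has no ESS")
    # autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    rho = acov / acov[0]
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}
    n_pairs = n // 2
    pair = rho[: 2 * n_pairs].reshape(n_pairs, 2).sum(axis=1)
    # initial positive sequence: truncate before the first non-positive pair
    nonpos = np.nonzero(pair <= 0)[0]
    stop = nonpos[0] if nonpos.size else n_pairs
    pair = pair[:stop]
    if pair.size == 0:
        return float(n)
    # monotone: running minimum
    pair = np.minimum.accumulate(pair)
    tau_int = max(2.0 * pair.sum() - 1.0, 1e-12)
    return float(min(n / tau_int, n * 1.05))


@dataclass(frozen=True)
class EssSummary:
    """Per-second sampling efficiency for one trace."""

    min: float
    median: float
    per_parameter: np.ndarray
    tau: float


def ess_per_time(trace: Trace) -> EssSummary:
    """ESS divided by wall time, per log-population-size parameter.

    Returns the minimum and median across the gamma components plus the
    value for the precision tau separately.
    """
    if trace.wall_time is None:
        raise ValueError("trace has no wall_time recorded")
    per = np.array(
        [ess(trace.gamma[:, k]) for k in range(trace.n_intervals)]
    ) / trace.wall_time
    tau_rate = ess(np.log(trace.tau)) / trace.wall_time
    return EssSummary(
        min=float(per.min()),
        median=float(np.median(per)),
        per_parameter=per,
        tau=float(tau_rate),
    )


def hpd_interval(series, level: float):
    """Shortest contiguous interval containing ``ceil(level * n)`` points."""
    x = np.sort(np.asarray(series, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty series")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    k = int(np.ceil(level * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def trajectory_summary(trace: Trace, grid: GridSpec, level: float = 0.95) -> pd.DataFrame:
    """Posterior summary of the demographic trajectory, one row per interval.

    Summaries are on the effective-population-size scale theta = exp(gamma);
    gamma-scale means are included as well.
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if grid.n_intervals != trace.n_intervals:
        raise ValueError("grid and trace interval counts differ")
    starts = np.concatenate(([0.0], grid.grid_points))
    ends = np.concatenate((grid.grid_points, [np.inf]))
    rows = []
    for k in range(trace.n_intervals):
        theta = np.exp(trace.gamma[:, k])
        lo, hi = hpd_interval(theta, level)
        rows.append(
            dict(
                interval=k + 1,
                t_start=starts[k],
                t_end=ends[k],
                mean=float(theta.mean()),
                median=float(np.median(theta)),
                hpd_low=lo,
                hpd_high=hi,
                gamma_mean=float(trace.gamma[:, k].mean()),
            )
        )
    return pd.DataFrame(rows)
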