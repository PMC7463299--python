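"""Shared fixtures: hand-worked small examples and simulated datasets."""

import numpy as np
import pytest

from skygrid import (
    GMRFSpec,
    GridSpec,
    SuffStats,
    build_grid,
    extract_event_sequence,
    simulate_dataset,
    simulate_genealogy,
    sufficient_statistics,
)
from skygrid.simulate import DEFAULT_ANCHOR_DATE


@pytest.fixture
def worked_stats():
    """Sufficient statistics of the hand-worked 3-tip example.

    Three isochronous tips, coalescences at t = 1 and t = 2, grid x_1 = 1.5:
    c = (1, 1), S = (3.5, 0.5).
    """
    return SuffStats(c=np.array([1.0, 1.0]), S=np.array([3.5, 0.5]))


@pytest.fixture
def worked_spec():
    return GMRFSpec(2)


def random_genealogy(rng, n_tips=None, heterochronous=True):
    """A random simulated genealogy under a random demographic history."""
    if n_tips is None:
        n_tips = int(rng.integers(2, 51))
    if heterochronous and n_tips > 2 and rng.uniform() < 0.7:
        times = np.concatenate(([0.0], rng.uniform(0, 3.0, n_tips - 1)))
    else:
        times = np.zeros(n_tips)
    M = int(rng.integers(1, 8))
    grid = build_grid(float(rng.uniform(0.5, 20.0)), M)
    gamma = rng.normal(1.0, 1.0, M + 1)
    return simulate_genealogy(times, grid, gamma, rng), grid


def random_grid(rng, max_m=8):
    return build_grid(float(rng.uniform(0.5, 20.0)), int(rng.integers(1, max_m)))


@pytest.fixture(scope="session")
def benchmark_dataset():
    """Fixed simulated dataset: 3 loci x 20 heterochronous tips, M = 9.

    Simulated under a constant effective population size theta = 5 with tips
    sampled over a 4-time-unit window and a grid cutoff of 10, matching the
    expected TMRCA scale 2 theta (1 - 1/n) ~ 9.5.
    """
    rng = np.random.default_rng(20260920)
    grid = build_grid(10.0, 9)
    gamma_true = np.full(10, np.log(5.0))
    schemes = [
        np.concatenate(([0.0], rng.uniform(0.0, 4.0, 19))) for _ in range(3)
    ]
    gens = simulate_dataset(3, schemes, grid, gamma_true, rng, per_locus=True)
    reference = max(g.most_recent_tip_date for g in gens)
    seqs = [extract_event_sequence(g, reference) for g in gens]
    stats = sufficient_statistics(seqs, grid)
    spec = GMRFSpec(10)
    return {
        "grid": grid,
        "stats": stats,
        "spec": spec,
        "gamma_true": gamma_true,
        "seqs": seqs,
    }
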