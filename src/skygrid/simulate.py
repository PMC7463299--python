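"""Heterochronous coalescent simulation under a piecewise-constant N_e(t).

This is the exact data-generating process of the skygrid likelihood: going
backwards in time, v active lineages coalesce at rate
``v (v-1) / (2 theta_k)`` while time t lies in demographic interval k, and
new lineages enter at their (backwards) sampling times.  Waiting times are
drawn by time rescaling — the cumulative coalescent intensity is integrated
analytically across grid and sampling breakpoints, since the rate is constant
within each piece — so no thinning is involved.

Simulated trees are returned as :class:`~skygrid.genealogy.DatedGenealogy`
with the most recent sample anchored at a configurable calendar date
(2000.0 by default) and can be written in the Newick + dates-TSV formats the
input module reads.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .core import GridSpec
from .genealogy import DatedGenealogy

__all__ = ["simulate_genealogy", "simulate_dataset", "expand_sample_times"]

DEFAULT_ANCHOR_DATE = 2000.0


def expand_sample_times(sample_times) -> np.ndarray:
    """Normalize a sampling scheme to one backwards time per tip.

    Accepts either a flat sequence of backwards times (one per tip) or a
    sequence of ``(time, count)`` pairs.
    """
    times = []
    for entry in sample_times:
        if np.isscalar(entry):
            times.append(float(entry))
        else:
            t, count = entry
            times.extend([float(t)] * int(count))
    arr = np.sort(np.asarray(times, dtype=float))
    if arr.size < 2:
        raise ValueError(f"need at least 2 samples, got {arr.size}")
    if arr[0] < 0:
        raise ValueError("sample times must be nonnegative backwards times")
    return arr


def _intensity_crossing(t, target, rate_per_pair, v, grid_pts):
    """Advance from backwards time t until the integrated coalescent
    intensity reaches ``target``; returns the crossing time (or inf past the
    last grid point only conceptually — the final interval is unbounded so a
    crossing always exists while v >= 2)."""
    pair = v * (v - 1) / 2.0
    k = int(np.searchsorted(grid_pts, t, side="right"))
    remaining = target
    while True:
        rate = pair * rate_per_pair[k]
        seg_end = grid_pts[k] if k < grid_pts.size else np.inf
        seg_len = seg_end - t
        if rate * seg_len >= remaining:
            return t + remaining / rate
        remaining -= rate * seg_len
        t = seg_end
        k += 1


def simulate_genealogy(
    sample_times,
    grid: GridSpec,
    gamma,
    rng: np.random.Generator,
    anchor_date: float = DEFAULT_ANCHOR_DATE,
    label_prefix: str = "t",
) -> DatedGenealogy:
    """Simulate one dated genealogy under the skygrid coalescent.

    Parameters
    ----------
    sample_times
        Backwards sampling times of the tips (flat list or (time, count)
        pairs); 0 is the most recent possible sample.
    grid
        Temporal grid defining the demographic intervals.
    gamma
        Log effective population size per interval, length ``grid.M + 1``.
    rng
        NumPy random generator.
    anchor_date
        Calendar date assigned to backwards time 0.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size != grid.n_intervals:
        raise ValueError(
            f"gamma has length {gamma.size}, expected {grid.n_intervals}"
        )
    tip_times = expand_sample_times(sample_times)
    rate_per_pair = np.exp(-gamma)  # 1 / theta_k
    grid_pts = grid.grid_points

    taxon_namespace = dendropy.TaxonNamespace()
    tip_dates = {}
    pending = []  # (backwards time, node), most recent first
    for i, bt in enumerate(tip_times):
        label = f"{label_prefix}{i + 1}"
        taxon = taxon_namespace.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        node._height = bt
        tip_dates[label] = anchor_date - bt
        pending.append(node)
    pending.reverse()  # pop() yields most recent remaining sample

    t = tip_times[0]
    active = []
    while pending and pending[-1]._height <= t:
        active.append(pending.pop())

    while len(active) + len(pending) > 1:
        v = len(active)
        if v >= 2:
            target = rng.exponential()
            t_coal = _intensity_crossing(t, target, rate_per_pair, v, grid_pts)
        else:
            t_coal = np.inf
        t_next_sample = pending[-1]._height if pending else np.inf
        if t_next_sample <= t_coal:
            t = t_next_sample
            while pending and pending[-1]._height <= t:
                active.append(pending.pop())
        else:
            t = t_coal
            i, j = rng.choice(v, size=2, replace=False)
            a, b = active[i], active[j]
            parent = dendropy.Node()
            parent._height = t
            for child in (a, b):
                parent.add_child(child)
                child.edge.length = t - child._height
            active = [nd for idx, nd in enumerate(active) if idx not in (i, j)]
            active.append(parent)

    root = active[0]
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    tree.is_rooted = True
    return DatedGenealogy(
        tree=tree,
        tip_dates=tip_dates,
        most_recent_tip_date=float(max(tip_dates.values())),
    )


def simulate_dataset(
    m: int,
    sample_times,
    grid: GridSpec,
    gamma,
    rng: np.random.Generator,
    anchor_date: float = DEFAULT_ANCHOR_DATE,
    per_locus: bool = False,
) -> list:
    """Simulate ``m`` independent genealogies sharing one demographic history.

    ``sample_times`` is a single sampling scheme applied to every locus, or,
    with ``per_locus=True``, a list of m schemes.
    """
    if m < 1:
        raise ValueError(f"locus count must be >= 1, got {m}")
    if per_locus:
        if len(sample_times) != m:
            raise ValueError("per-locus sample_times must have length m")
        schemes = sample_times
    else:
        schemes = [sample_times] * m
    return [
        simulate_genealogy(
            schemes[i], grid, gamma, rng,
            anchor_date=anchor_date, label_prefix=f"l{i + 1}t",
        )
        for i in range(m)
    ]
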