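"""Dated genealogy input and conversion to backwards-time event sequences.

Trees are read from Newick or NEXUS via dendropy.  Tip sampling dates come
either from a two-column tab-separated file (``taxon<TAB>date``) or from a
trailing ``_<decimal>`` suffix in tip labels; an explicit file wins on
conflict.  All times use a single backwards-time convention: 0 is the global
reference (the most recent tip across all loci) and time increases into the
past, matching the grid anchored at ``x_0 = 0``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DatedGenealogy",
    "EventSequence",
    "parse_newick",
    "assign_tip_dates",
    "extract_event_sequence",
    "read_dates_tsv",
    "dates_from_labels",
    "read_trees",
]

#: absolute tolerance (time units) for root-to-tip path consistency
PATH_TOLERANCE = 1e-6

SAMPLING = 1
COALESCENT = -1

_LABEL_DATE_RE = re.compile(r"_(\d+(?:\.\d+)?)$")


@dataclass
class DatedGenealogy:
    """A rooted binary tree with branch lengths in time units, optionally dated.

    ``tip_dates`` maps tip label -> calendar time (same units as branch
    lengths, larger = more recent).  Until dates are assigned the genealogy
    is "undated" and cannot be placed on the shared timeline.
    """

    tree: dendropy.Tree
    tip_dates: dict | None = None
    most_recent_tip_date: float | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_nodes()]

    @property
    def is_dated(self) -> bool:
        return self.tip_dates is not None

    def node_depths(self) -> dict:
        """Distance from the root to every node."""
        depths = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def root_date(self) -> float:
        """Calendar time of the root, averaged over root-to-tip paths."""
        if not self.is_dated:
            raise ValueError("genealogy has no tip dates assigned")
        depths = self.node_depths()
        estimates = [
            self.tip_dates[leaf.taxon.label] - depths[leaf]
            for leaf in self.tree.leaf_nodes()
        ]
        return float(np.mean(estimates))

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class EventSequence:
    """Ordered sampling/coalescent events of one locus on the shared timeline.

    ``times`` are backwards times from the global reference; ``kinds`` is +1
    for a sampling event and -1 for a coalescence.  ``offset`` is the gap
    between the global reference and this locus's most recent tip, so the
    first event is a sampling event at ``times[0] == offset``.
    """

    times: np.ndarray
    kinds: np.ndarray
    offset: float
    n_tips: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=int)
        if self.times.shape != self.kinds.shape:
            raise ValueError("times and kinds must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be nondecreasing")
        counts = np.cumsum(self.kinds)
        if np.any(counts[:-1] < 1) or counts[-1] != 1:
            raise ValueError("lineage count must stay >= 1 and end at 1")
        if int(np.sum(self.kinds < 0)) != self.n_tips - 1:
            raise ValueError("expected n_tips - 1 coalescent events")

    @property
    def events(self) -> list:
        kind_name = {SAMPLING: "sampling", COALESCENT: "coalescent"}
        return [(float(t), kind_name[int(k)]) for t, k in zip(self.times, self.kinds)]

    def lineage_counts(self) -> np.ndarray:
        return np.cumsum(self.kinds)

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])


class GenealogyParseError(ValueError):
    """Malformed tree input."""


def parse_newick(text: str) -> DatedGenealogy:
    """Parse a single rooted Newick tree with branch lengths (undated).

    Raises :class:`GenealogyParseError` on unbalanced parentheses, missing
    branch lengths or fewer than two tips, naming the offending token.
    """
    text = text.strip()
    if text.count("(") != text.count(")"):
        raise GenealogyParseError(
            f"unbalanced parentheses in tree: {text.count('(')} '(' vs "
            f"{text.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise GenealogyParseError(f"could not parse Newick tree: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: dendropy.Tree) -> DatedGenealogy:
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise GenealogyParseError(
            f"tree must have at least 2 tips, found {len(leaves)}"
        )
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal node>"
            raise GenealogyParseError(f"missing branch length above {label!r}")
        if node.parent_node is not None and node.edge.length < 0:
            label = node.taxon.label if node.taxon else "<internal node>"
            raise GenealogyParseError(f"negative branch length above {label!r}")
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            raise GenealogyParseError(
                "tree must be strictly bifurcating; node with "
                f"{len(node.child_nodes())} children found"
            )
    return DatedGenealogy(tree=tree)


def assign_tip_dates(gen: DatedGenealogy, dates: dict) -> DatedGenealogy:
    """Attach calendar dates to tips and check path consistency.

    Every tip label must appear in ``dates``.  The calendar time of each
    internal node implied by (tip date - path length) must agree across all
    root-to-tip paths within ``PATH_TOLERANCE``; otherwise an error reports
    the worst discrepancy.
    """
    labels = gen.tip_labels
    missing = [lab for lab in labels if lab not in dates]
    if missing:
        raise ValueError(f"missing dates for tips: {missing}")
    tip_dates = {lab: float(dates[lab]) for lab in labels}
    depths = gen.node_depths()
    root_estimates = np.array(
        [tip_dates[leaf.taxon.label] - depths[leaf] for leaf in gen.tree.leaf_nodes()]
    )
    spread = float(root_estimates.max() - root_estimates.min())
    if spread > PATH_TOLERANCE:
        raise ValueError(
            "tip dates inconsistent with branch lengths: root-date estimates "
            f"from different root-to-tip paths differ by {spread:.6g} "
            f"(tolerance {PATH_TOLERANCE:g})"
        )
    return DatedGenealogy(
        tree=gen.tree,
        tip_dates=tip_dates,
        most_recent_tip_date=float(max(tip_dates.values())),
    )


def extract_event_sequence(
    gen: DatedGenealogy, global_reference: float
) -> EventSequence:
    """Convert a dated genealogy to backwards-time events.

    ``global_reference`` is a calendar time at or after this genealogy's most
    recent tip; event backwards times are measured from it.  At exact time
    ties sampling events sort before coalescent events.
    """
    if not gen.is_dated:
        raise ValueError("assign tip dates before extracting events")
    if global_reference < gen.most_recent_tip_date - PATH_TOLERANCE:
        raise ValueError(
            f"global reference {global_reference} predates the most recent "
            f"tip ({gen.most_recent_tip_date})"
        )
    depths = gen.node_depths()
    root_date = gen.root_date()
    events = []
    for node in gen.tree.preorder_node_iter():
        calendar = root_date + depths[node]
        t = global_reference - calendar
        if node.is_leaf():
            events.append((max(t, 0.0), SAMPLING))
        else:
            events.append((t, COALESCENT))
    # sampling (+1) before coalescent (-1) at equal times
    events.sort(key=lambda e: (e[0], -e[1]))
    times = np.array([e[0] for e in events])
    kinds = np.array([e[1] for e in events])
    return EventSequence(
        times=times,
        kinds=kinds,
        offset=float(times[0]),
        n_tips=gen.n_tips,
    )


def read_dates_tsv(path_or_buffer) -> dict:
    """Read a ``taxon<TAB>date`` file (header row required) into a dict."""
    if isinstance(path_or_buffer, (str, bytes)) or hasattr(path_or_buffer, "__fspath__"):
        with open(path_or_buffer) as fh:
            return _parse_dates_stream(fh)
    return _parse_dates_stream(path_or_buffer)


def _parse_dates_stream(fh) -> dict:
    header = fh.readline()
    if "\t" not in header:
        raise ValueError("dates file must be tab-separated with a header row")
    dates = {}
    for lineno, line in enumerate(fh, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 2 tab-separated fields")
        taxon, value = parts
        try:
            dates[taxon] = float(value)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad date {value!r}") from exc
    return dates


def dates_from_labels(labels) -> dict:
    """Parse dates from trailing ``_<decimal>`` suffixes of tip labels."""
    dates = {}
    for lab in labels:
        m = _LABEL_DATE_RE.search(lab)
        if m is None:
            raise ValueError(f"tip label {lab!r} has no trailing _<decimal> date")
        dates[lab] = float(m.group(1))
    return dates


def read_trees(path_or_text, schema: str | None = None) -> list:
    """Read one or more trees from a Newick (one per line) or NEXUS file."""
    if hasattr(path_or_text, "__fspath__") or (
        isinstance(path_or_text, str) and "\n" not in path_or_text and "(" not in path_or_text
    ):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = path_or_text
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    if schema == "newick":
        gens = []
        for line in text.strip().splitlines():
            line = line.strip()
            if line:
                gens.append(parse_newick(line))
        if not gens:
            raise GenealogyParseError("no trees found in input")
        return gens
    try:
        trees = dendropy.TreeList.get(
            file=io.StringIO(text),
            schema="nexus",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise GenealogyParseError(f"could not parse NEXUS trees: {exc}") from exc
    if len(trees) == 0:
        raise GenealogyParseError("no trees found in NEXUS input")
    return [_validate_tree(t) for t in trees]
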