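"""Nonparametric bootstrap over tumors: topology tallying, frequent-tree
ranking and strict >threshold split consensus.

Replicates draw n rows with replacement and refit deterministically; a
master seed spawns per-replicate seeds by a counter scheme so replicate r is
the same regardless of execution order.  Events absent from a resample are
retained (probability clamping keeps all weights finite) so topologies stay
comparable across replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .branching import fit_branching_tree
from .data import BinaryAlterationMatrix
from .distance import fit_distance_tree
from .exceptions import ValidationError

METHODS = ("branching", "distance")


def _fit_canonical(matrix: BinaryAlterationMatrix, method: str, floor=None):
    """Fit one matrix; return (canonical topology string, tuple of splits)."""
    if method == "branching":
        tree = fit_branching_tree(matrix, floor=floor)
        edges = tuple(sorted(f"{c}<{p}" for c, p in tree.parent.items()))
        return ",".join(edges), edges
    if method == "distance":
        tree = fit_distance_tree(matrix, floor=floor)
        splits = tree.splits()
        return ";".join(splits), splits
    raise ValidationError(f"method must be one of {METHODS}, got {method!r}")


def splits_of_topology(topology: str, method: str) -> tuple[str, ...]:
    """Invert the canonical string back into its split/edge identifiers."""
    sep = "," if method == "branching" else ";"
    return tuple(topology.split(sep)) if topology else ()


@dataclass(frozen=True)
class BootstrapResult:
    """Topology counts and split support over B bootstrap replicates."""

    B: int
    seed: int
    method: str
    topology_counts: dict[str, int]
    split_support: dict[str, float]
    original_topology: str
    replicate_topologies: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if sum(self.topology_counts.values()) != self.B:
            raise ValidationError("topology counts do not sum to B")
        if any(not (0.0 <= s <= 1.0) for s in self.split_support.values()):
            raise ValidationError("split support outside [0, 1]")

    def original_splits(self) -> tuple[str, ...]:
        return splits_of_topology(self.original_topology, self.method)

    def to_json_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "method": self.method,
            "original_topology": self.original_topology,
            "topology_counts": dict(self.topology_counts),
            "split_support": dict(self.split_support),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)


def bootstrap(
    matrix: BinaryAlterationMatrix,
    method: str,
    B: int,
    seed: int,
    floor: float | None = None,
) -> BootstrapResult:
    """B row-resamples with replacement, each refit with the chosen method."""
    if B < 1:
        raise ValidationError("B must be >= 1")
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    original, _ = _fit_canonical(matrix, method, floor)
    topo_counts: dict[str, int] = {}
    split_counts: dict[str, int] = {}
    replicate_topologies: list[str] = []
    n = matrix.n
    for rep in range(B):
        rng = np.random.default_rng([seed, rep])
        idx = rng.integers(0, n, size=n)
        topo, splits = _fit_canonical(matrix.resample(idx), method, floor)
        replicate_topologies.append(topo)
        topo_counts[topo] = topo_counts.get(topo, 0) + 1
        for s in set(splits):
            split_counts[s] = split_counts.get(s, 0) + 1
    support = {s: c / B for s, c in split_counts.items()}
    # the original tree's splits are always reported, even at support 0
    for s in splits_of_topology(original, method):
        support.setdefault(s, 0.0)
    return BootstrapResult(
        B=B,
        seed=seed,
        method=method,
        topology_counts=topo_counts,
        split_support=support,
        original_topology=original,
        replicate_topologies=tuple(replicate_topologies),
    )


@dataclass(frozen=True)
class ConsensusReport:
    """Splits exceeding the support threshold, plus the original tree's own."""

    threshold: float
    splits: tuple[tuple[str, float], ...]
    original_splits: dict[str, float]

    def to_text(self) -> str:
        lines = [f"# splits with support > {self.threshold:g}"]
        for s, sup in self.splits:
            lines.append(f"{sup:.4f}\t{s}")
        lines.append("# original tree splits")
        for s in sorted(self.original_splits):
            lines.append(f"{self.original_splits[s]:.4f}\t{s}")
        return "\n".join(lines) + "\n"


def consensus_report(
    result: BootstrapResult, threshold: float = 0.10
) -> ConsensusReport:
    """Splits with support strictly greater than the threshold, sorted by
    decreasing support (ties lexicographic)."""
    if not (0.0 <= threshold < 1.0):
        raise ValidationError("threshold must be in [0, 1)")
    kept = sorted(
        ((s, sup) for s, sup in result.split_support.items() if sup > threshold),
        key=lambda t: (-t[1], t[0]),
    )
    orig = {
        s: result.split_support.get(s, 0.0) for s in result.original_splits()
    }
    return ConsensusReport(
        threshold=threshold, splits=tuple(kept), original_splits=orig
    )


def frequent_trees(
    result: BootstrapResult, top_m: int | None = None
) -> list[tuple[str, int]]:
    """Topologies ranked by replicate count, descending; ties lexicographic."""
    ranked = sorted(result.topology_counts.items(), key=lambda t: (-t[1], t[0]))
    return ranked if top_m is None else ranked[:top_m]


def frequent_trees_text(result: BootstrapResult, top_m: int | None = None) -> str:
    lines = ["count\ttopology"]
    for topo, cnt in frequent_trees(result, top_m):
        lines.append(f"{cnt}\t{topo}")
    return "\n".join(lines) + "\n"


def modal_parent_tree(
    result: BootstrapResult,
) -> tuple[dict[str, str], list[str]]:
    """Majority-parent consensus for branching bootstraps.

    For each event, picks the parent occurring most often across replicates
    (ties lexicographic).  The result need not be a valid arborescence:
    events involved in cycles are returned in the second element, never
    silently repaired.
    """
    if result.method != "branching":
        raise ValidationError("modal-parent consensus requires branching method")
    counts: dict[str, dict[str, int]] = {}
    for topo in result.replicate_topologies:
        for edge in splits_of_topology(topo, "branching"):
            child, parent = edge.split("<", 1)
            counts.setdefault(child, {}).setdefault(parent, 0)
            counts[child][parent] += 1
    modal = {
        child: min(pc, key=lambda p: (-pc[p], p)) for child, pc in counts.items()
    }
    cyclic: set[str] = set()
    for start in modal:
        node, seen = start, []
        while node in modal and node not in seen:
            seen.append(node)
            node = modal[node]
        if node in seen:  # walked into a cycle
            cyclic.update(seen[seen.index(node):])
    return modal, sorted(cyclic)
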