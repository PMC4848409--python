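"""Cohort simulation from a progression tree and deterministic fixtures
reproducing printed marginal counts.

The generator draws, per tumor, an independent firing of every edge
top-down (a child edge can fire only if its parent edge fired); an event is
present iff its whole root path fired; observed bits are then flipped with
the false-positive / false-negative probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .branching import OncoTree
from .data import ROOT_LABEL, BinaryAlterationMatrix
from .distance import WeightedRootedTree
from .exceptions import ConstraintError, ValidationError

# Printed per-gene altered-sample counts of the 963-tumor cohort
COHORT_N = 963
COHORT_COUNTS = {
    "PIK3CA": 51,
    "AKT2": 22,
    "KRAS": 25,
    "PTEN": 55,
    "ErbB2": 121,
    "CCND1": 153,
}
COHORT_ANY_ALTERED = 342


@dataclass(frozen=True)
class GenerativeSpec:
    """Everything needed to simulate a cohort reproducibly."""

    tree: OncoTree | WeightedRootedTree
    n: int
    eps_plus: float = 0.0
    eps_minus: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name, v in (("eps_plus", self.eps_plus), ("eps_minus", self.eps_minus)):
            if not (0.0 <= v < 0.5):
                raise ValidationError(f"{name}={v} outside [0, 0.5)")

    # -- JSON round trip ----------------------------------------------
    def to_json_dict(self) -> dict:
        if isinstance(self.tree, OncoTree):
            tree_d = {
                "kind": "branching",
                "parent": dict(self.tree.parent),
                "fire_prob": dict(self.tree.fire_prob or {}),
                "events": list(self.tree.events),
            }
        else:
            tree_d = {
                "kind": "distance",
                "parent": dict(self.tree.parent),
                "length": dict(self.tree.length),
                "leaves": list(self.tree.leaves),
            }
        return {
            "tree": tree_d,
            "n": self.n,
            "eps_plus": self.eps_plus,
            "eps_minus": self.eps_minus,
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GenerativeSpec":
        td = d["tree"]
        tree: OncoTree | WeightedRootedTree
        if td["kind"] == "branching":
            fp = td.get("fire_prob") or None
            tree = OncoTree(
                events=tuple(td["events"]),
                parent=dict(td["parent"]),
                fire_prob=dict(fp) if fp else None,
                cond_prob=dict(fp) if fp else None,
            )
        else:
            tree = WeightedRootedTree(
                leaves=tuple(td["leaves"]),
                parent=dict(td["parent"]),
                length={k: float(v) for k, v in td["length"].items()},
            )
        return cls(
            tree=tree,
            n=int(d["n"]),
            eps_plus=float(d["eps_plus"]),
            eps_minus=float(d["eps_minus"]),
            seed=int(d["seed"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GenerativeSpec":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _tree_mechanism(tree: OncoTree | WeightedRootedTree):
    """(node order, parent index array, firing probs, event column indices)."""
    if isinstance(tree, OncoTree):
        if tree.fire_prob is None:
            raise ValidationError("OncoTree must carry fire_prob to simulate")
        order = list(tree.events)
        idx = {e: i for i, e in enumerate(order)}
        parents = np.array(
            [-1 if tree.parent[e] == ROOT_LABEL else idx[tree.parent[e]]
             for e in order],
            dtype=int,
        )
        probs = np.array([tree.fire_prob[e] for e in order])
        event_names = tuple(order)
        event_cols = list(range(len(order)))
    else:
        order, parents = tree.parent_indices()
        probs = np.array([tree.edge_prob(v) for v in order])
        event_names = tree.leaves
        event_cols = [order.index(leaf) for leaf in tree.leaves]
    return order, parents, probs, event_names, event_cols


def simulate_cohort(spec: GenerativeSpec) -> BinaryAlterationMatrix:
    """Simulate a cohort of n tumors from the generative tree."""
    order, parents, probs, event_names, event_cols = _tree_mechanism(spec.tree)
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, len(order)
    fired = np.zeros((n, m), dtype=bool)
    topo = sorted(range(m), key=lambda j: _depth(parents, j))
    draws = rng.random((n, m))
    for j in topo:
        ok = draws[:, j] < probs[j]
        if parents[j] < 0:
            fired[:, j] = ok
        else:
            fired[:, j] = fired[:, parents[j]] & ok
    true = fired[:, event_cols]
    if spec.eps_plus > 0 or spec.eps_minus > 0:
        flips = rng.random(true.shape)
        observed = np.where(true, flips >= spec.eps_minus, flips < spec.eps_plus)
    else:
        observed = true
    width = len(str(n - 1))
    ids = tuple(f"s{i:0{width}d}" for i in range(n))
    return BinaryAlterationMatrix(ids, event_names, observed.astype(np.int8))


def _depth(parents: np.ndarray, j: int) -> int:
    d = 0
    while parents[j] >= 0:
        j = parents[j]
        d += 1
    return d


def fixture_from_counts(
    n: int, counts: dict[str, int], any_altered: int | None = None
) -> BinaryAlterationMatrix:
    """Deterministic matrix with exact column sums and, when requested, an
    exact number of rows carrying at least one event.

    Greedy layout: the first ``any_altered`` rows each receive one event
    (largest-count events first, consuming rows in blocks); leftover 1s of
    each event are then stacked into already-altered rows from the top.
    """
    events = tuple(counts)
    for e, c in counts.items():
        if not (0 <= c <= n):
            raise ConstraintError(f"count for {e!r} is {c}, outside 0..n={n}")
    total = sum(counts.values())
    if any_altered is None:
        values = np.zeros((n, len(events)), dtype=np.int8)
        for j, e in enumerate(events):
            values[: counts[e], j] = 1
    else:
        mx = max(counts.values(), default=0)
        if any_altered < mx:
            raise ConstraintError(
                f"any_altered={any_altered} < max event count {mx}"
            )
        if any_altered > min(n, total):
            raise ConstraintError(
                f"any_altered={any_altered} > min(n={n}, sum of counts={total})"
            )
        values = np.zeros((n, len(events)), dtype=np.int8)
        fill_order = sorted(events, key=lambda e: (-counts[e], e))
        remaining = dict(counts)
        row = 0
        for e in fill_order:
            if row >= any_altered:
                break
            take = min(remaining[e], any_altered - row)
            j = events.index(e)
            values[row : row + take, j] = 1
            remaining[e] -= take
            row += take
        for e in fill_order:
            j = events.index(e)
            left = remaining[e]
            r = 0
            while left > 0:
                if values[r, j] == 0:
                    values[r, j] = 1
                    left -= 1
                r += 1
    width = len(str(max(n - 1, 1)))
    ids = tuple(f"s{i:0{width}d}" for i in range(n))
    return BinaryAlterationMatrix(ids, events, values)


def paper_tree_fixture(
    variant: str = "sibling", n: int = COHORT_N, seed: int = 0
) -> GenerativeSpec:
    """Generative spec shaped like the published 6-gene breast-cancer tree.

    Four branches leave the root (CCND1, PTEN, AKT2, ErbB2); KRAS and PIK3CA
    hang below ErbB2.  Edge probabilities are chosen so model marginals equal
    the printed frequencies (e.g. ErbB2 edge 121/963, KRAS edge 25/121).

    ``variant='sibling'`` (default) places KRAS and PIK3CA as siblings under
    ErbB2.  ``variant='chain'`` places PIK3CA below KRAS; its marginal cannot
    then match the printed count (51 > 25 would need an edge probability > 1)
    so the PIK3CA edge is saturated at 1.
    """
    cnt = COHORT_COUNTS
    if variant == "sibling":
        parent = {
            "CCND1": ROOT_LABEL, "PTEN": ROOT_LABEL, "AKT2": ROOT_LABEL,
            "ErbB2": ROOT_LABEL, "KRAS": "ErbB2", "PIK3CA": "ErbB2",
        }
        fire = {
            "CCND1": cnt["CCND1"] / COHORT_N,
            "PTEN": cnt["PTEN"] / COHORT_N,
            "AKT2": cnt["AKT2"] / COHORT_N,
            "ErbB2": cnt["ErbB2"] / COHORT_N,
            "KRAS": cnt["KRAS"] / cnt["ErbB2"],
            "PIK3CA": cnt["PIK3CA"] / cnt["ErbB2"],
        }
    elif variant == "chain":
        parent = {
            "CCND1": ROOT_LABEL, "PTEN": ROOT_LABEL, "AKT2": ROOT_LABEL,
            "ErbB2": ROOT_LABEL, "KRAS": "ErbB2", "PIK3CA": "KRAS",
        }
        fire = {
            "CCND1": cnt["CCND1"] / COHORT_N,
            "PTEN": cnt["PTEN"] / COHORT_N,
            "AKT2": cnt["AKT2"] / COHORT_N,
            "ErbB2": cnt["ErbB2"] / COHORT_N,
            "KRAS": cnt["KRAS"] / cnt["ErbB2"],
            "PIK3CA": min(1.0, cnt["PIK3CA"] / cnt["KRAS"]),
        }
    else:
        raise ValueError(f"unknown variant {variant!r}")
    events = ("CCND1", "PTEN", "AKT2", "ErbB2", "KRAS", "PIK3CA")
    tree = OncoTree(
        events=events, parent=parent, fire_prob=fire, cond_prob=dict(fire)
    )
    return GenerativeSpec(tree=tree, n=n, seed=seed)
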