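"""Branching oncogenetic tree: maximum-weight arborescence over pairwise
co-occurrence weights, conditional edge probabilities, and an
observation-error likelihood model.

The pairwise weight combines a nesting term and a correlation term,

    w(i -> j) = 2 log p_ij - log(p_i + p_j) - log p_i - log p_j
              = log[p_ij / (p_i + p_j)] + log[p_ij / (p_i p_j)],

with the root treated as an always-present event (p_root = 1,
p_root,j = p_j), so w(root -> j) = log[p_j / (1 + p_j)].  The fitted tree is
the maximum-weight arborescence rooted at the normal node; each event then
fires conditionally on its parent, and observed indicators may be corrupted
by shared false-positive / false-negative rates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from ._latent import (
    MAX_ENUM_EDGES,
    downward_closed_sets,
    latent_set_probabilities,
)
from .data import ROOT_LABEL, BinaryAlterationMatrix, FrequencyEstimates
from .exceptions import CapabilityError, ValidationError

# relative tolerance under which two arborescence totals count as tied;
# ties are then resolved to the lexicographically smallest (child, parent)
# assignment, child by child
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class EdgeWeightMatrix:
    """Complete weights over ordered pairs (i in {root} u events, j in events)."""

    events: tuple[str, ...]
    weights: dict[tuple[str, str], float]

    def w(self, parent: str, child: str) -> float:
        return self.weights[(parent, child)]


@dataclass(frozen=True)
class ErrorModel:
    """Shared false-positive / false-negative observation probabilities."""

    eps_plus: float = 0.0
    eps_minus: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("eps_plus", self.eps_plus), ("eps_minus", self.eps_minus)):
            if not (0.0 <= v < 0.5):
                raise ValidationError(f"{name}={v} outside [0, 0.5)")


@dataclass(frozen=True)
class OncoTree:
    """Rooted arborescence over {root} u events.

    ``parent`` maps each event to its parent node; ``edge_weight``,
    ``fire_prob`` and ``cond_prob`` each map an event to a property of its
    incoming edge (``fire_prob``/``cond_prob`` may be absent until fitted).
    """

    events: tuple[str, ...]
    parent: dict[str, str]
    edge_weight: dict[str, float] | None = None
    fire_prob: dict[str, float] | None = None
    cond_prob: dict[str, float] | None = None

    def __post_init__(self) -> None:
        events = set(self.events)
        if set(self.parent) != events:
            raise ValidationError("parent map must cover exactly the events")
        for child, par in self.parent.items():
            if par != ROOT_LABEL and par not in events:
                raise ValidationError(f"unknown parent {par!r} of {child!r}")
        # every event must reach the root without cycles
        for event in self.events:
            seen = set()
            node = event
            while node != ROOT_LABEL:
                if node in seen:
                    raise ValidationError(f"cycle through {node!r}")
                seen.add(node)
                node = self.parent[node]
        if self.fire_prob is not None:
            for e, p in self.fire_prob.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(f"fire_prob[{e!r}]={p} outside [0,1]")

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def path_from_root(self, event: str) -> list[str]:
        path = []
        node = event
        while node != ROOT_LABEL:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def total_weight(self) -> float:
        if self.edge_weight is None:
            raise ValidationError("edge weights not set")
        return sum(self.edge_weight.values())

    def canonical(self) -> str:
        """Canonical topology string: sorted 'child<parent' pairs."""
        return ",".join(sorted(f"{c}<{p}" for c, p in self.parent.items()))

    def parent_indices(self) -> np.ndarray:
        """Parent array over event indices (-1 for root children)."""
        idx = {e: i for i, e in enumerate(self.events)}
        return np.array(
            [-1 if self.parent[e] == ROOT_LABEL else idx[self.parent[e]]
             for e in self.events],
            dtype=int,
        )

    def to_json_dict(self) -> dict:
        out = {}
        for e in self.events:
            entry: dict = {"parent": self.parent[e]}
            if self.edge_weight is not None:
                entry["weight"] = self.edge_weight[e]
            if self.fire_prob is not None:
                entry["fire_prob"] = self.fire_prob[e]
            if self.cond_prob is not None:
                entry["cond_prob"] = self.cond_prob[e]
            out[e] = entry
        return out

    def to_dot(self) -> str:
        lines = ["digraph oncotree {"]
        for e in sorted(self.events):
            label = ""
            if self.cond_prob is not None:
                label = f' [label="{self.cond_prob[e]:.4f}"]'
            lines.append(f'  "{self.parent[e]}" -> "{e}"{label};')
        lines.append("}")
        return "\n".join(lines) + "\n"


def pair_weights(freq: FrequencyEstimates) -> EdgeWeightMatrix:
    """Complete edge-weight matrix from clamped frequency estimates."""
    weights: dict[tuple[str, str], float] = {}
    for j in freq.events:
        pj = freq.p(j)
        weights[(ROOT_LABEL, j)] = math.log(pj / (1.0 + pj))
        for i in freq.events:
            if i == j:
                continue
            pi, pij = freq.p(i), freq.p2(i, j)
            weights[(i, j)] = (
                2.0 * math.log(pij) - math.log(pi + pj) - math.log(pi) - math.log(pj)
            )
    return EdgeWeightMatrix(events=freq.events, weights=weights)


def _solve_arborescence(
    weights: EdgeWeightMatrix, forced: dict[str, str]
) -> tuple[dict[str, str], float]:
    """Maximum-weight arborescence honouring forced child->parent choices.

    The root has no in-edges, so every spanning arborescence of the digraph
    is rooted at it.  Raises ``nx.NetworkXException`` when the forced
    assignments admit no arborescence.
    """
    g = nx.DiGraph()
    g.add_nodes_from((ROOT_LABEL, *weights.events))
    for (par, child), w in weights.weights.items():
        if child in forced and forced[child] != par:
            continue
        g.add_edge(par, child, weight=w)
    arb = nx.maximum_spanning_arborescence(g, attr="weight")
    parent = {child: par for par, child in arb.edges}
    total = sum(weights.w(p, c) for c, p in parent.items())
    return parent, total


def optimal_branching(weights: EdgeWeightMatrix) -> OncoTree:
    """Maximum-weight arborescence rooted at the normal node.

    Among (numerically) tied optima the lexicographically smallest sorted
    (child, parent) assignment is returned: children are fixed in name order,
    each to the smallest-named parent that still attains the optimum.
    """
    events = weights.events
    if len(events) == 1:
        (e,) = events
        return OncoTree(
            events=events,
            parent={e: ROOT_LABEL},
            edge_weight={e: weights.w(ROOT_LABEL, e)},
        )
    best, w_opt = _solve_arborescence(weights, {})
    tol = _TIE_RTOL * (1.0 + abs(w_opt))
    forced: dict[str, str] = {}
    for child in sorted(events):
        for par in sorted((ROOT_LABEL, *(e for e in events if e != child))):
            if par == best[child]:
                forced[child] = par
                break
            trial = dict(forced, **{child: par})
            try:
                cand, cand_total = _solve_arborescence(weights, trial)
            except nx.NetworkXException:
                continue
            if cand_total >= w_opt - tol:
                forced[child] = par
                best = cand
                break
    return OncoTree(
        events=events,
        parent=best,
        edge_weight={c: weights.w(p, c) for c, p in best.items()},
    )


def exhaustive_branching(weights: EdgeWeightMatrix) -> OncoTree:
    """Brute-force oracle: enumerate all parent maps, keep arborescences,
    maximize total weight; ties to the lexicographically smallest pair set.

    Exponential — intended for cross-checking ``optimal_branching`` at small k.
    """
    events = weights.events
    k = len(events)
    if k > 6:
        raise CapabilityError("exhaustive search limited to k <= 6")
    arbs: list[tuple[float, list[tuple[str, str]], dict[str, str]]] = []
    candidates = [ROOT_LABEL, *events]
    for combo in itertools.product(candidates, repeat=k):
        parent = dict(zip(events, combo))
        if any(p == c for c, p in parent.items()):
            continue
        # arborescence check: all events reach root, no cycles
        ok = True
        for e in events:
            node, seen = e, set()
            while node != ROOT_LABEL:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parent[node]
            if not ok:
                break
        if not ok:
            continue
        total = sum(weights.w(p, c) for c, p in parent.items())
        arbs.append((total, sorted(parent.items()), parent))
    w_opt = max(t for t, _, _ in arbs)
    tol = _TIE_RTOL * (1.0 + abs(w_opt))
    best = min(
        (entry for entry in arbs if entry[0] >= w_opt - tol),
        key=lambda entry: entry[1],
    )
    return OncoTree(
        events=events,
        parent=best[2],
        edge_weight={c: weights.w(p, c) for c, p in best[2].items()},
    )


def edge_probabilities(tree: OncoTree, freq: FrequencyEstimates) -> OncoTree:
    """Fill conditional and firing probabilities on a fixed topology.

    cond_prob(j) = p_{parent(j), j} / p_parent(j); for root children it is the
    marginal p_j.  fire_prob mirrors cond_prob, capped into [0, 1].
    """
    cond: dict[str, float] = {}
    for child, par in tree.parent.items():
        if par == ROOT_LABEL:
            cond[child] = freq.p(child)
        else:
            cond[child] = freq.p2(par, child) / freq.p(par)
    fire = {c: min(max(v, 0.0), 1.0) for c, v in cond.items()}
    return replace(tree, cond_prob=cond, fire_prob=fire)


def _pattern_arrays(matrix: BinaryAlterationMatrix, events: tuple[str, ...]):
    """Unique observed patterns (U, k) aligned to ``events`` plus counts."""
    idx = [matrix.event_names.index(e) for e in events]
    vals = matrix.values[:, idx]
    patterns, counts = np.unique(vals, axis=0, return_counts=True)
    return patterns.astype(bool), counts


def _pattern_probs(
    member: np.ndarray,
    active: np.ndarray,
    patterns: np.ndarray,
    pi: np.ndarray,
    eps_plus: float,
    eps_minus: float,
) -> np.ndarray:
    """P(observed pattern) for each row of ``patterns`` under the model."""
    pT = latent_set_probabilities(member, active, pi)
    m = member.astype(float)
    y = patterns.astype(float)
    a = m @ y.T  # true and observed
    b = m.sum(axis=1)[:, None] - a  # true, observed 0
    c = y.sum(axis=1)[None, :] - a  # false, observed 1
    d = member.shape[1] - a - b - c
    err = (
        (1.0 - eps_minus) ** a
        * eps_minus**b
        * eps_plus**c
        * (1.0 - eps_plus) ** d
    )
    return pT @ err


def pattern_likelihood(
    tree: OncoTree, err: ErrorModel, pattern
) -> float:
    """Exact probability of one observed 0/1 pattern (aligned to tree.events).

    Sums over all downward-closed true-event sets; the observed indicator of
    a true event flips to 0 with eps_minus, of an absent event to 1 with
    eps_plus.
    """
    if tree.fire_prob is None:
        raise ValidationError("fire_prob not set on tree")
    if tree.events and len(tree.events) > MAX_ENUM_EDGES:
        raise CapabilityError(
            f"k={len(tree.events)} exceeds enumeration bound {MAX_ENUM_EDGES}"
        )
    pattern = np.asarray(pattern, dtype=bool).reshape(1, -1)
    if pattern.shape[1] != len(tree.events):
        raise ValidationError("pattern length does not match event count")
    member, active = downward_closed_sets(tree.parent_indices())
    pi = np.array([tree.fire_prob[e] for e in tree.events])
    return float(
        _pattern_probs(member, active, pattern, pi, err.eps_plus, err.eps_minus)[0]
    )


@dataclass(frozen=True)
class ErrorFit:
    """Result of joint edge-probability / error-rate estimation."""

    fire_prob: dict[str, float]
    error: ErrorModel
    loglik: float


def fit_error_model(
    matrix: BinaryAlterationMatrix,
    topology: OncoTree,
    n_starts: int = 5,
    seed: int = 0,
    fix_error: ErrorModel | None = None,
) -> ErrorFit:
    """Maximum-likelihood firing probabilities and shared error rates.

    Bounded multistart L-BFGS-B over pi_e in [1e-6, 1-1e-6] and
    eps_+/- in [0, 0.3].  The first start is the moment-based point
    (conditional frequencies, eps = 0.01); the returned objective is
    guaranteed >= the objective at that start.  ``fix_error`` pins the
    error rates instead of estimating them.
    """
    from .data import estimate_probabilities

    events = topology.events
    k = len(events)
    if k > MAX_ENUM_EDGES:
        raise CapabilityError(f"k={k} exceeds enumeration bound {MAX_ENUM_EDGES}")
    patterns, counts = _pattern_arrays(matrix, events)
    member, active = downward_closed_sets(topology.parent_indices())

    eps_lo, eps_hi = 0.0, 0.3
    pi_lo, pi_hi = 1e-6, 1.0 - 1e-6
    if fix_error is not None:
        eps_bounds = [
            (fix_error.eps_plus, fix_error.eps_plus),
            (fix_error.eps_minus, fix_error.eps_minus),
        ]
    else:
        eps_bounds = [(eps_lo, eps_hi)] * 2
    bounds = [(pi_lo, pi_hi)] * k + eps_bounds

    def negloglik(x: np.ndarray) -> float:
        pi, ep, em = x[:k], x[k], x[k + 1]
        probs = _pattern_probs(member, active, patterns, pi, ep, em)
        if not np.all(np.isfinite(probs)):
            bad = patterns[np.argmax(~np.isfinite(probs))].astype(int)
            raise FloatingPointError(
                f"non-finite likelihood for pattern {bad.tolist()}"
            )
        return -float(counts @ np.log(np.maximum(probs, 1e-300)))

    moment = edge_probabilities(topology, estimate_probabilities(matrix))
    eps0 = (
        [fix_error.eps_plus, fix_error.eps_minus]
        if fix_error is not None
        else [0.01, 0.01]
    )
    x0 = np.concatenate(
        [np.clip([moment.fire_prob[e] for e in events], pi_lo, pi_hi), eps0]
    )
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        eps_pert = (
            eps0 if fix_error is not None else rng.uniform(0.0, 0.2, size=2)
        )
        pert = np.concatenate([rng.uniform(0.05, 0.95, size=k), eps_pert])
        starts.append(pert)

    best_x, best_obj = x0, negloglik(x0)
    for s in starts:
        res = minimize(
            negloglik,
            s,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if np.isfinite(res.fun) and res.fun < best_obj:
            best_x, best_obj = res.x, float(res.fun)
    pi = dict(zip(events, map(float, best_x[:k])))
    return ErrorFit(
        fire_prob=pi,
        error=ErrorModel(
            eps_plus=float(best_x[k]), eps_minus=float(best_x[k + 1])
        ),
        loglik=-best_obj,
    )


def fit_branching_tree(
    matrix: BinaryAlterationMatrix, floor: float | None = None
) -> OncoTree:
    """End-to-end branching fit: frequencies -> weights -> arborescence ->
    conditional probabilities."""
    from .data import estimate_probabilities

    freq = estimate_probabilities(matrix, floor=floor)
    tree = optimal_branching(pair_weights(freq))
    return edge_probabilities(tree, freq)
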