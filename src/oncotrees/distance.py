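"""Distance-based oncogenetic tree: additive event metric from co-occurrence,
neighbor-joining topology with the normal state as root, and exact
maximum-likelihood edge probabilities.

Under the latent firing model (edge e fires with probability p_e, a leaf
event is present iff every edge on its root path fired) the path length
between two leaves under weights -log p_e is

    D_ij = log p_i + log p_j - 2 log p_ij,

and the root-to-leaf distance is r_i = -log p_i.  The metric is additive
whenever the joint probabilities are generated by such a tree, so
neighbor-joining (with the root added as a pseudo-leaf at distance r_i from
every event) recovers the generating topology exactly; see the derivation in
the README.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from ._latent import (
    MAX_ENUM_EDGES,
    downward_closed_sets,
    latent_set_probabilities,
)
from .data import ROOT_LABEL, BinaryAlterationMatrix, FrequencyEstimates
from .exceptions import CapabilityError, ValidationError


@dataclass(frozen=True)
class EventDistanceMatrix:
    """Symmetric pairwise event distances plus per-event root distances."""

    events: tuple[str, ...]
    D: np.ndarray
    root_dist: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        r = np.asarray(self.root_dist, dtype=float)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "root_dist", r)
        k = len(self.events)
        if D.shape != (k, k):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(D, D.T):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(D) != 0):
            raise ValidationError("nonzero diagonal")
        if np.any(D < -1e-12) or np.any(r < -1e-12):
            raise ValidationError("negative distance")


@dataclass(frozen=True)
class WeightedRootedTree:
    """Rooted tree with events at the leaves and anonymous hidden internal
    nodes; the length of the edge above node v is -log of its firing
    probability.

    ``parent`` maps every non-root node (internal or leaf) to its parent;
    ``length`` holds the branch length above each non-root node.
    """

    leaves: tuple[str, ...]
    parent: dict[str, str]
    length: dict[str, float]
    root: str = ROOT_LABEL
    _children: dict[str, list[str]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        nodes = set(self.parent)
        if self.root in nodes:
            raise ValidationError("root must not have a parent")
        for leaf in self.leaves:
            if leaf not in nodes:
                raise ValidationError(f"leaf {leaf!r} missing from tree")
        for v, p in self.parent.items():
            if p != self.root and p not in nodes:
                raise ValidationError(f"unknown parent {p!r}")
        for v, ln in self.length.items():
            if ln < 0:
                raise ValidationError(f"negative branch length above {v!r}")
        children: dict[str, list[str]] = {self.root: []}
        for v in self.parent:
            children.setdefault(v, [])
        for v, p in self.parent.items():
            children[p].append(v)
        for v in children:
            children[v].sort()
        object.__setattr__(self, "_children", children)
        interior_leaves = [
            v for v in self.leaves if children[v]
        ]
        if interior_leaves:
            raise ValidationError(f"event node(s) {interior_leaves} are not leaves")

    # -- structure -----------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return [self.root, *sorted(self.parent)]

    def children(self, node: str) -> list[str]:
        return list(self._children.get(node, []))

    def edge_count(self) -> int:
        return len(self.parent)

    def edge_prob(self, node: str) -> float:
        return math.exp(-self.length[node])

    def path_length(self, a: str, b: str) -> float:
        """Path length between two nodes (root allowed)."""

        def anc(v: str) -> list[str]:
            path = [v]
            while path[-1] != self.root:
                path.append(self.parent[path[-1]])
            return path

        pa, pb = anc(a), anc(b)
        sa, sb = set(pa), set(pb)
        mrca = next(v for v in pa if v in sb)
        dist = 0.0
        for v in pa:
            if v == mrca:
                break
            dist += self.length[v]
        for v in pb:
            if v == mrca:
                break
            dist += self.length[v]
        return dist

    def parent_indices(self) -> tuple[list[str], np.ndarray]:
        """Non-root nodes in a fixed order with parent index array."""
        order: list[str] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            for c in sorted(self.children(v), reverse=True):
                order.append(c)
                stack.append(c)
        idx = {v: i for i, v in enumerate(order)}
        parents = np.array(
            [-1 if self.parent[v] == self.root else idx[self.parent[v]]
             for v in order],
            dtype=int,
        )
        return order, parents

    # -- canonical form ------------------------------------------------
    def splits(self) -> tuple[str, ...]:
        """Leaf bipartitions, one per edge, with the root as a pseudo-leaf.

        Each split is the sorted '|'-joined set of leaves below the edge
        (the side away from the root pseudo-leaf).
        """
        below: dict[str, set[str]] = {}

        def collect(v: str) -> set[str]:
            s = {v} if v in self.leaves else set()
            for c in self.children(v):
                s |= collect(c)
            below[v] = s
            return s

        collect(self.root)
        return tuple(
            sorted("|".join(sorted(below[v])) for v in self.parent if below[v])
        )

    def canonical(self) -> str:
        return ";".join(self.splits())

    # -- serialization -------------------------------------------------
    def to_newick(self) -> str:
        def fmt(v: str) -> str:
            kids = self.children(v)
            label = v if v in self.leaves or v == self.root else ""
            inner = (
                "(" + ",".join(fmt(c) for c in kids) + ")" if kids else ""
            )
            ln = f":{self.length[v]:.10g}" if v != self.root else ""
            return f"{inner}{label}{ln}"

        return fmt(self.root) + ";"

    def to_json_dict(self) -> dict:
        return {
            "root": self.root,
            "leaves": list(self.leaves),
            "edges": {
                v: {"parent": p, "length": self.length[v],
                    "prob": self.edge_prob(v)}
                for v, p in sorted(self.parent.items())
            },
        }


def additive_distance(freq: FrequencyEstimates) -> EventDistanceMatrix:
    """Additive event distances implied by the latent firing model."""
    events = freq.events
    k = len(events)
    D = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pa, pb = freq.p(events[a]), freq.p(events[b])
            pab = freq.p2(events[a], events[b])
            D[a, b] = D[b, a] = math.log(pa) + math.log(pb) - 2.0 * math.log(pab)
    r = np.array([-math.log(freq.p(e)) for e in events])
    return EventDistanceMatrix(events=events, D=D, root_dist=r)


def _unique_root_label(events: tuple[str, ...]) -> str:
    label = ROOT_LABEL
    while label in events:  # events cannot normally be named 'root'
        label += "_"
    return label


def build_topology(dist: EventDistanceMatrix) -> WeightedRootedTree:
    """Neighbor-joining over the events plus a root pseudo-leaf, re-rooted at
    the pseudo-leaf.  Negative inferred branch lengths are clamped to 0 with
    a warning.  Exact on additive inputs."""
    events = dist.events
    k = len(events)
    if k == 1:
        e = events[0]
        return WeightedRootedTree(
            leaves=events, parent={e: ROOT_LABEL},
            length={e: float(dist.root_dist[0])},
        )
    pseudo = _unique_root_label(events)
    ids = [*events, pseudo]
    full = np.zeros((k + 1, k + 1))
    full[:k, :k] = dist.D
    full[:k, k] = full[k, :k] = dist.root_dist
    if k == 2:
        # NJ needs >= 3 taxa only formally; 3-leaf star is exact
        a, b = events
        da = 0.5 * (dist.D[0, 1] + dist.root_dist[0] - dist.root_dist[1])
        db = dist.D[0, 1] - da
        dr = dist.root_dist[0] - da
        lengths = {"h1": dr, a: da, b: db}
        clamped = {v: max(0.0, ln) for v, ln in lengths.items()}
        if any(ln < 0 for ln in lengths.values()):
            warnings.warn("negative branch length clamped to 0")
        return WeightedRootedTree(
            leaves=events,
            parent={"h1": ROOT_LABEL, a: "h1", b: "h1"},
            length=clamped,
        )
    skt = _skbio_nj(DistanceMatrix(full, ids=ids), neg_as_zero=False)
    # convert to an undirected adjacency, suppressing the arbitrary skbio root
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    counter = [0]

    def nid(node) -> int:
        if not hasattr(node, "_oid"):
            node._oid = counter[0]
            counter[0] += 1
            names[node._oid] = node.name if node.name else None
            adj[node._oid] = []
        return node._oid

    for node in skt.traverse():
        nid(node)
    for node in skt.traverse():
        if node.parent is not None:
            a, b = nid(node), nid(node.parent)
            ln = float(node.length or 0.0)
            adj[a].append((b, ln))
            adj[b].append((a, ln))
    # suppress degree-2 vertices (skbio may root with two children)
    changed = True
    while changed:
        changed = False
        for v, nbrs in list(adj.items()):
            if len(nbrs) == 2 and names[v] is None:
                (u, lu), (w, lw) = nbrs
                adj[u] = [(x, l) for x, l in adj[u] if x != v] + [(w, lu + lw)]
                adj[w] = [(x, l) for x, l in adj[w] if x != v] + [(u, lu + lw)]
                del adj[v]
                changed = True
                break
    # re-root at the pseudo-leaf: it becomes the root node itself
    root_id = next(v for v, nm in names.items() if nm == pseudo and v in adj)
    parent: dict[str, str] = {}
    length: dict[str, float] = {}
    hidden = [0]
    node_name: dict[int, str] = {root_id: ROOT_LABEL}
    clamped_any = False
    stack = [root_id]
    seen = {root_id}
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        for u, ln in sorted(adj[v], key=lambda t: (names[t[0]] or "", t[0])):
            if u in seen:
                continue
            seen.add(u)
            if names[u]:
                node_name[u] = names[u]
            else:
                hidden[0] += 1
                node_name[u] = f"h{hidden[0]}"
            if ln < 0:
                clamped_any = True
                ln = 0.0
            parent[node_name[u]] = node_name[v]
            length[node_name[u]] = ln
            stack.append(u)
    if clamped_any:
        warnings.warn("negative branch length(s) clamped to 0")
    return WeightedRootedTree(leaves=events, parent=parent, length=length)


def pattern_distribution(tree: WeightedRootedTree) -> dict[tuple[int, ...], float]:
    """Exact probability of every observable leaf pattern.

    Enumerates all downward-closed edge-firing states; a leaf is present iff
    its node belongs to the fired set.
    """
    if tree.edge_count() > 16:
        raise CapabilityError(
            f"{tree.edge_count()} edges exceed the exact enumeration bound of 16"
        )
    order, parents = tree.parent_indices()
    member, active = downward_closed_sets(parents)
    probs = np.array([tree.edge_prob(v) for v in order])
    pT = latent_set_probabilities(member, active, probs)
    leaf_idx = [order.index(leaf) for leaf in tree.leaves]
    out: dict[tuple[int, ...], float] = {}
    for s in range(member.shape[0]):
        pat = tuple(int(member[s, j]) for j in leaf_idx)
        out[pat] = out.get(pat, 0.0) + float(pT[s])
    return out


def tree_loglik(tree: WeightedRootedTree, matrix: BinaryAlterationMatrix) -> float:
    """Exact log-likelihood of the cohort under the tree.

    A pattern that is impossible under the tree yields -inf (flagged via a
    warning, not an exception).
    """
    missing = [e for e in matrix.event_names if e not in tree.leaves]
    if missing:
        raise ValidationError(f"matrix event(s) {missing} are not tree leaves")
    dist = pattern_distribution(tree)
    idx = [matrix.event_names.index(leaf) for leaf in tree.leaves]
    vals = matrix.values[:, idx]
    patterns, counts = np.unique(vals, axis=0, return_counts=True)
    total = 0.0
    for pat, cnt in zip(patterns, counts):
        p = dist.get(tuple(int(x) for x in pat), 0.0)
        if p <= 0.0:
            warnings.warn(
                f"pattern {pat.tolist()} has probability 0 under the tree"
            )
            return float("-inf")
        total += cnt * math.log(p)
    return float(total)


def ml_edge_probabilities(
    topology: WeightedRootedTree,
    matrix: BinaryAlterationMatrix,
    n_starts: int = 5,
    seed: int = 0,
) -> WeightedRootedTree:
    """Re-estimate branch lengths by bounded multistart maximum likelihood.

    Edge probabilities are optimized in [1e-6, 1]; the returned tree's
    log-likelihood is >= that of the input lengths.
    """
    if topology.edge_count() > 16:
        raise CapabilityError("edge count exceeds enumeration bound of 16")
    order, parents = topology.parent_indices()
    member, active = downward_closed_sets(parents)
    leaf_pos = [order.index(leaf) for leaf in topology.leaves]
    col = [matrix.event_names.index(leaf) for leaf in topology.leaves]
    vals = matrix.values[:, col]
    patterns, counts = np.unique(vals, axis=0, return_counts=True)
    # indicator[s, u]: latent state s induces observed pattern u
    leaf_member = member[:, leaf_pos].astype(np.int8)
    indicator = (leaf_member[:, None, :] == patterns[None, :, :]).all(axis=2)

    def negloglik(p: np.ndarray) -> float:
        pT = latent_set_probabilities(member, active, p)
        pp = pT @ indicator
        return -float(counts @ np.log(np.maximum(pp, 1e-300)))

    lo, hi = 1e-6, 1.0
    bounds = [(lo, hi)] * len(order)
    x0 = np.clip([topology.edge_prob(v) for v in order], lo, hi)
    rng = np.random.default_rng(seed)
    starts = [x0] + [
        rng.uniform(0.05, 0.99, size=len(order)) for _ in range(n_starts - 1)
    ]
    best_x, best_obj = x0, negloglik(x0)
    for s in starts:
        res = minimize(
            negloglik, s, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if np.isfinite(res.fun) and res.fun < best_obj:
            best_x, best_obj = res.x, float(res.fun)
    new_lengths = {
        v: float(-math.log(max(p, 1e-300))) for v, p in zip(order, best_x)
    }
    return replace(topology, length=new_lengths)


def fit_distance_tree(
    matrix: BinaryAlterationMatrix, floor: float | None = None
) -> WeightedRootedTree:
    """End-to-end distance fit: frequencies -> additive metric -> NJ topology."""
    from .data import estimate_probabilities

    freq = estimate_probabilities(matrix, floor=floor)
    return build_topology(additive_distance(freq))
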