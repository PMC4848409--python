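"""Exact enumeration of downward-closed firing sets on a rooted tree.

Both tree models share the same latent mechanism: every non-root node has an
incoming edge that can fire only if the parent's edge fired, and it fires
independently with its own probability.  The reachable latent states are
exactly the downward-closed node sets, enumerated here once per topology and
scored vectorially for any probability assignment.
"""

from __future__ import annotations

import numpy as np

from .exceptions import CapabilityError

#: Hard bound on the number of latent edges for exact enumeration.
MAX_ENUM_EDGES = 20


def topological_order(parents: np.ndarray) -> list[int]:
    """Return node indices ordered so every parent precedes its children.

    ``parents[j]`` is the index of j's parent, or -1 for children of the root.
    """
    k = len(parents)
    children: list[list[int]] = [[] for _ in range(k)]
    roots = []
    for j, p in enumerate(parents):
        if p < 0:
            roots.append(j)
        else:
            children[p].append(j)
    order: list[int] = []
    stack = sorted(roots, reverse=True)
    while stack:
        j = stack.pop()
        order.append(j)
        stack.extend(sorted(children[j], reverse=True))
    if len(order) != k:
        raise ValueError("parent array does not describe a rooted forest")
    return order


def downward_closed_sets(parents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all downward-closed node sets of a rooted tree.

    Parameters
    ----------
    parents
        Integer array of length k; ``parents[j]`` is j's parent index or -1
        when j hangs directly off the root.

    Returns
    -------
    member, active : boolean arrays of shape (S, k)
        ``member[s, j]`` — node j belongs to set s.  ``active[s, j]`` — j's
        parent belongs to set s (or j is a root child), i.e. j's edge had the
        chance to fire in state s.
    """
    k = len(parents)
    if k > MAX_ENUM_EDGES:
        raise CapabilityError(
            f"{k} edges exceed the exact enumeration bound of {MAX_ENUM_EDGES}"
        )
    order = topological_order(np.asarray(parents))
    masks = [0]
    for j in order:
        p = parents[j]
        bit = 1 << j
        pbit = 0 if p < 0 else (1 << p)
        nxt = []
        for m in masks:
            nxt.append(m)
            if p < 0 or (m & pbit):
                nxt.append(m | bit)
        masks = nxt
    member = np.zeros((len(masks), k), dtype=bool)
    active = np.zeros((len(masks), k), dtype=bool)
    for s, m in enumerate(masks):
        for j in range(k):
            member[s, j] = bool(m & (1 << j))
            p = parents[j]
            active[s, j] = p < 0 or bool(m & (1 << p))
    return member, active


def latent_set_probabilities(
    member: np.ndarray, active: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Probability of each enumerated latent set under per-edge firing probs.

    Edges below a non-fired edge contribute no factor (they never had the
    chance to fire).
    """
    probs = np.asarray(probs, dtype=float)
    factors = np.where(member, probs, np.where(active, 1.0 - probs, 1.0))
    return factors.prod(axis=1)
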