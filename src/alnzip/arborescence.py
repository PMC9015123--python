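"""Minimum spanning arborescence of the encodability graph.

The children of the dummy root in the optimal arborescence are the
reference sequences; every other row is stored as a delta against its
parent.  Because edge weights are exact record sizes in bits, the
arborescence's total weight is the exact pre-backend archive payload.

The solver delegates to networkx's Edmonds/Chu-Liu implementation.
Determinism across runs is guaranteed by a lexicographic weight
perturbation: the primary objective is total bits, the secondary objective
is the sum of parent vertex ids (root counted lowest), folded into a
single integer weight so ties never reach the solver's internal arbitrary
choices at the level that matters for archive bytes.

An exhaustive oracle (:func:`brute_force_arborescence`) enumerates every
parent map on small graphs; it exists to certify the solver's optimality
and shares the tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import ROOT, EncodabilityGraph


@dataclass(frozen=True)
class Arborescence:
    """Parent map rooted at the dummy vertex.

    ``parent[i]`` is ROOT for reference rows, otherwise the row whose
    record reconstructs row i.  ``total_weight`` is the summed edge
    weights in bits.
    """

    parent: dict[int, int]
    total_weight: int

    @property
    def references(self) -> list[int]:
        """Rows stored verbatim (children of the dummy root), ascending."""
        return sorted(i for i, p in self.parent.items() if p == ROOT)

    def children(self) -> dict[int, list[int]]:
        """Parent -> sorted child list (ROOT included)."""
        out: dict[int, list[int]] = {ROOT: []}
        for i in self.parent:
            out.setdefault(i, [])
        for i, p in sorted(self.parent.items()):
            out.setdefault(p, []).append(i)
        return out


def _check_root_connected(eg: EncodabilityGraph) -> None:
    reachable = nx.descendants(eg.graph, ROOT)
    missing = set(range(eg.n)) - reachable
    if missing:
        raise ValueError(
            f"graph not root-connected: vertices {sorted(missing)} unreachable"
        )


def minimum_spanning_arborescence(eg: EncodabilityGraph) -> Arborescence:
    """Optimal reference set and referencing order (Edmonds/Chu-Liu).

    Returns the spanning arborescence rooted at the dummy vertex with
    minimum total bit cost; among weight ties, the solution minimizing the
    sum of parent ids is chosen, making output deterministic.
    """
    _check_root_connected(eg)
    n = eg.n
    # Fold (weight, sum of parent ids) into one integer objective.
    # Parent-id key per edge is src+2 in [1, n+1]; any arborescence has
    # exactly n edges, so the secondary term is < n*(n+2) and cannot
    # override a one-bit difference in primary weight.
    scale = n * (n + 2) + 1
    g2 = nx.DiGraph()
    for u, v, w in eg.graph.edges.data("weight"):
        g2.add_edge(u, v, wp=w * scale + (u + 2))
    opt = nx.minimum_spanning_arborescence(g2, attr="wp", preserve_attrs=False)
    parent: dict[int, int] = {}
    for u, v in opt.edges:
        parent[v] = u
    total = sum(eg.weight(parent[i], i) for i in range(n))
    return Arborescence(parent=parent, total_weight=total)


def brute_force_arborescence(eg: EncodabilityGraph, max_n: int = 8) -> Arborescence:
    """Exhaustive minimum arborescence by enumerating all parent maps.

    Every row independently picks an in-neighbour; maps that are acyclic
    and root-connected are spanning arborescences.  Feasible only for
    small graphs (the parent-map space is ~n^n); refuses above ``max_n``
    rows.  Vectorised with numpy so 500-instance certification runs stay
    cheap.
    """
    n = eg.n
    if n > max_n:
        raise ValueError(f"brute force limited to n <= {max_n}, got {n}")
    _check_root_connected(eg)

    candidates = [
        sorted(u for u in eg.graph.predecessors(v)) for v in range(n)
    ]
    counts = [len(c) for c in candidates]
    # all combinations of per-vertex parent choices
    idx = np.indices(counts).reshape(n, -1).T  # (M, n)
    parents = np.empty_like(idx, dtype=np.int16)
    for v in range(n):
        parents[:, v] = np.asarray(candidates[v], dtype=np.int16)[idx[:, v]]

    # validity: following parent pointers n times must reach ROOT everywhere
    cur = parents.copy()
    row_ix = np.arange(parents.shape[0])[:, None]
    for _ in range(n):
        nonroot = cur != ROOT
        cur = np.where(nonroot, parents[row_ix, np.where(nonroot, cur, 0)], ROOT)
    valid = (cur == ROOT).all(axis=1)
    if not valid.any():
        raise ValueError("graph not root-connected: no spanning arborescence")

    wmat = np.full((n + 1, n), np.iinfo(np.int64).max // (n + 1), dtype=np.int64)
    for u, v, w in eg.graph.edges.data("weight"):
        wmat[u + 1, v] = w
    totals = wmat[parents + 1, np.arange(n)].sum(axis=1)

    vtot = totals[valid]
    vpar = parents[valid]
    best_w = vtot.min()
    ties = vpar[vtot == best_w]
    sec = ties.sum(axis=1)
    ties = ties[sec == sec.min()]
    best = ties[np.lexsort(ties.T[::-1])][0]
    parent = {v: int(best[v]) for v in range(n)}
    return Arborescence(parent=parent, total_weight=int(best_w))
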