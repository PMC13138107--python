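"""Markov Cluster (MCL) algorithm on a weighted adjacency matrix.

MCL simulates random walks on the graph: the column-stochastic transition
matrix is alternately *expanded* (matrix squaring, spreading flow) and
*inflated* (entry-wise power followed by column renormalization, boosting
strong flows), until the matrix converges to a union of attractor systems
that define the clusters.  The inflation exponent ("granularity") controls
cluster size: higher values give more, smaller clusters.
"""

from __future__ import annotations

import numpy as np


def _add_self_loops(adjacency: np.ndarray) -> np.ndarray:
    a = adjacency.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    incident_max = a.max(axis=1)
    # isolated nodes get unit self-loops so columns stay stochastic
    np.fill_diagonal(a, np.where(incident_max > 0, incident_max, 1.0))
    return a


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_matrix(
    adjacency: np.ndarray,
    granularity: float = 1.75,
    max_iterations: int = 200,
    prune_threshold: float = 1e-5,
    convergence_tol: float = 1e-6,
) -> np.ndarray:
    """Run MCL iterations to convergence; returns the limit matrix."""
    if granularity <= 1:
        raise ValueError("granularity must be > 1")
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] == 0:
        raise ValueError("adjacency must be a non-empty square matrix")
    if np.any(a < 0):
        raise ValueError("adjacency weights must be non-negative")
    m = _normalize_columns(_add_self_loops(a))
    for _ in range(max_iterations):
        nxt = m @ m                                   # expansion
        nxt = np.power(nxt, granularity)              # inflation
        keep = nxt >= prune_threshold
        keep[nxt.argmax(axis=0), np.arange(nxt.shape[1])] = True
        nxt = np.where(keep, nxt, 0.0)
        nxt = _normalize_columns(nxt)
        residual = np.abs(nxt - m).max()
        m = nxt
        if residual < convergence_tol:
            return m
    raise RuntimeError(
        f"MCL did not converge in {max_iterations} iterations (residual {residual:.3g})"
    )


def clusters_from_matrix(m: np.ndarray, tol: float = 1e-5) -> list[list[int]]:
    """Read clusters off a converged MCL matrix.

    Attractors are nodes with positive diagonal mass; each attractor system
    (attractors connected through their row supports) spans one cluster.
    A node reachable from several systems is assigned to the largest cluster,
    ties broken by lowest cluster index.
    """
    n = m.shape[0]
    attractors = np.flatnonzero(np.diag(m) > tol)
    if attractors.size == 0:                          # numerically degenerate
        attractors = np.array([int(np.argmax(np.diag(m)))])
    # union-find over attractors sharing support
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    support = {int(a): set(np.flatnonzero(m[a] > tol)) | {int(a)} for a in attractors}
    att_set = set(int(a) for a in attractors)
    for a in attractors:
        for b in support[int(a)] & att_set:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    systems: dict[int, set[int]] = {}
    for a in attractors:
        systems.setdefault(find(int(a)), set()).update(support[int(a)])
    clusters = [sorted(v) for _, v in sorted(systems.items())]
    # resolve overlaps: largest cluster wins, then lowest index
    assignment: dict[int, int] = {}
    order = sorted(range(len(clusters)), key=lambda c: (-len(clusters[c]), c))
    for c in order:
        for node in clusters[c]:
            assignment.setdefault(node, c)
    for node in range(n):                             # stragglers become singletons
        if node not in assignment:
            clusters.append([node])
            assignment[node] = len(clusters) - 1
    final: dict[int, list[int]] = {}
    for node, c in assignment.items():
        final.setdefault(c, []).append(node)
    return [sorted(v) for v in final.values()]


def run_mcl(
    adjacency: np.ndarray,
    granularity: float = 1.75,
    max_iterations: int = 200,
    prune_threshold: float = 1e-5,
    convergence_tol: float = 1e-6,
) -> list[list[int]]:
    """MCL end to end: returns clusters as sorted index lists, ordered by
    decreasing size (ties by smallest member index)."""
    m = mcl_matrix(adjacency, granularity, max_iterations, prune_threshold, convergence_tol)
    clusters = clusters_from_matrix(m, tol=prune_threshold)
    return sorted(clusters, key=lambda c: (-len(c), c[0]))
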