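"""Interscan connectivity: scan similarity networks, Markov clustering, and
cluster x group enrichment.

Each scan is represented by its organ SUV_90-120 profile; pairwise Pearson
correlation of profiles gives a scan x scan similarity matrix.  A thresholded
graph over it is clustered with MCL, and the resulting clusters are tested
for enrichment of experimental groups with a one-sided Fisher exact
(hypergeometric upper-tail) test, Bonferroni-adjusted over the group family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .mcl import run_mcl
from .suv import SUVTable

log = logging.getLogger(__name__)

EDGE_THRESHOLD_DEFAULT = 0.85
GRANULARITY_DEFAULT = 1.75


@dataclass
class InterscanGraph:
    """Scan x scan correlation matrix plus its thresholded graph."""

    scan_ids: list[str]
    corr: np.ndarray
    edge_threshold: float | None = None
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.corr, index=self.scan_ids, columns=self.scan_ids)

    def adjacency(self) -> np.ndarray:
        """Thresholded non-negative adjacency (zero diagonal)."""
        a = np.zeros_like(self.corr)
        for i, j, w in self.edges:
            a[i, j] = a[j, i] = w
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.scan_ids)
        for i, j, w in self.edges:
            g.add_edge(self.scan_ids[i], self.scan_ids[j], weight=w)
        return g


@dataclass
class ClusterAssignment:
    """Scan -> cluster index (1-based, ordered by decreasing cluster size)."""

    assignment: pd.Series
    granularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max())

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])


def interscan_correlation(table: SUVTable) -> InterscanGraph:
    """Pearson correlation between every pair of scans' organ profiles."""
    if len(table.scan_ids) < 2:
        raise ValueError("need >= 2 scans")
    if len(table.organs) < 3:
        raise ValueError("need >= 3 organs")
    values = table.values
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [table.scan_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant organ profile for scan(s): {bad}")
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    return InterscanGraph(list(table.scan_ids), corr)


def most_similar(graph: InterscanGraph) -> pd.Series:
    """For each scan, the other scan with the highest correlation (ties break
    to the earliest scan in table order)."""
    n = len(graph.scan_ids)
    if n < 2:
        raise ValueError("need >= 2 scans")
    c = graph.corr.copy()
    np.fill_diagonal(c, -np.inf)
    best = c.argmax(axis=1)
    return pd.Series(
        [graph.scan_ids[j] for j in best], index=graph.scan_ids, name="most_similar"
    )


def build_graph(graph: InterscanGraph, edge_threshold: float = EDGE_THRESHOLD_DEFAULT) -> InterscanGraph:
    """Keep scan pairs with correlation >= threshold as weighted undirected
    edges; isolated scans are retained as nodes."""
    if not -1.0 <= edge_threshold < 1.0:
        raise ValueError("edge_threshold must be in [-1, 1)")
    iu, ju = np.triu_indices(len(graph.scan_ids), k=1)
    keep = graph.corr[iu, ju] >= edge_threshold
    edges = [
        (int(i), int(j), float(graph.corr[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    ]
    log.info(
        "interscan graph: %d nodes, %d edges at threshold %.2f",
        len(graph.scan_ids), len(edges), edge_threshold,
    )
    return InterscanGraph(graph.scan_ids, graph.corr, edge_threshold, edges)


def markov_cluster(
    graph: InterscanGraph,
    granularity: float = GRANULARITY_DEFAULT,
    **mcl_kwargs,
) -> ClusterAssignment:
    """Cluster the thresholded interscan graph with MCL; deterministic for a
    given graph and granularity."""
    if graph.edge_threshold is None:
        graph = build_graph(graph)
    clusters = run_mcl(graph.adjacency(), granularity=granularity, **mcl_kwargs)
    labels = pd.Series(0, index=graph.scan_ids, dtype=int)
    for idx, members in enumerate(clusters, start=1):
        for node in members:
            labels.iloc[node] = idx
    return ClusterAssignment(labels, granularity)


def granularity_sweep(
    graph: InterscanGraph,
    granularities: list[float],
    **mcl_kwargs,
) -> tuple[list[ClusterAssignment], pd.DataFrame]:
    """Cluster at each granularity and summarize stability as the pairwise
    adjusted Rand index between assignments."""
    assignments = [markov_cluster(graph, g, **mcl_kwargs) for g in granularities]
    k = len(assignments)
    ari = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ari[i, j] = ari[j, i] = adjusted_rand_score(
                assignments[i].assignment.to_numpy(), assignments[j].assignment.to_numpy()
            )
    ari_frame = pd.DataFrame(ari, index=granularities, columns=granularities)
    return assignments, ari_frame


def enrichment(
    assignment: ClusterAssignment,
    group_labels: pd.Series,
    n_permutations: int = 10_000,
    seed: int = 0,
    bonferroni_family: str = "groups",
) -> pd.DataFrame:
    """Cluster x group enrichment table.

    For each (cluster, group) pair: the observed member count, the expected
    count under random assignment (``cluster_size * group_size / N``) with a
    permutation-estimated SD, the representation factor observed/expected, a
    one-sided Fisher exact p (hypergeometric upper tail), and a Bonferroni
    adjustment over the number of groups per cluster (``bonferroni_family =
    'groups'``, default) or over all cluster x group tests
    (``'clusters_x_groups'``).  Rows are sorted by adjusted p.
    """
    labels = group_labels.reindex(assignment.assignment.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()][:5])
        raise ValueError(f"unlabeled scan(s): {missing}")
    n_total = len(labels)
    clusters = np.sort(assignment.assignment.unique())
    groups = list(pd.unique(labels))
    if bonferroni_family == "groups":
        n_tests = len(groups)
    elif bonferroni_family == "clusters_x_groups":
        n_tests = len(groups) * len(clusters)
    else:
        raise ValueError(f"unknown bonferroni_family {bonferroni_family!r}")

    cluster_codes = assignment.assignment.to_numpy()
    label_codes = pd.Categorical(labels, categories=groups).codes
    n_clusters, n_groups = len(clusters), len(groups)
    observed = np.zeros((n_clusters, n_groups), dtype=int)
    np.add.at(observed, (cluster_codes - 1, label_codes), 1)

    rng = np.random.default_rng(seed)
    sums = np.zeros((n_clusters, n_groups))
    sq_sums = np.zeros((n_clusters, n_groups))
    for _ in range(n_permutations):
        perm = rng.permutation(label_codes)
        counts = np.zeros((n_clusters, n_groups))
        np.add.at(counts, (cluster_codes - 1, perm), 1)
        sums += counts
        sq_sums += counts**2
    mean_perm = sums / n_permutations
    sd_perm = np.sqrt(np.maximum(sq_sums / n_permutations - mean_perm**2, 0.0))

    cluster_sizes = np.bincount(cluster_codes - 1, minlength=n_clusters)
    group_sizes = np.bincount(label_codes, minlength=n_groups)
    rows = []
    for ci in range(n_clusters):
        for gi in range(n_groups):
            obs = int(observed[ci, gi])
            expected = cluster_sizes[ci] * group_sizes[gi] / n_total
            fisher_p = float(
                stats.hypergeom.sf(obs - 1, n_total, group_sizes[gi], cluster_sizes[ci])
            )
            rows.append(
                {
                    "cluster": int(clusters[ci]),
                    "group": groups[gi],
                    "cluster_size": int(cluster_sizes[ci]),
                    "observed": obs,
                    "expected_mean": expected,
                    "expected_sd": float(sd_perm[ci, gi]),
                    "representation": obs / expected if expected > 0 else np.nan,
                    "fisher_p": fisher_p,
                    "adjusted_p": min(1.0, fisher_p * n_tests),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["adjusted_p", "cluster", "group"], kind="stable")
        .reset_index(drop=True)
    )
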