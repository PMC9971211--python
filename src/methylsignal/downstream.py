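"""Downstream interpretation of DMG lists: term enrichment and network hubs.

Fold enrichment of annotation terms (hypergeometric upper-tail p) turns
a DMG list into biological-process signal; centrality-based k-means
clustering of a protein–protein-interaction-style network identifies the
"core hub" — the cluster of nodes with the highest centrality, read as
the functional center of the differentially methylated gene network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dmg import adjust_pvalues

CENTRALITY_METRICS = ["betweenness", "closeness", "avg_shortest_path_length",
                      "clustering_coefficient", "degree", "eccentricity"]


def enrich_terms(study_genes: Iterable[str], annotation: Mapping[str, Iterable[str]],
                 population: Iterable[str], min_fold: float = 4.0,
                 alpha: float = 0.05, filtered: bool = True) -> pd.DataFrame:
    """Fold enrichment of terms in a study gene set vs a population.

    ``annotation`` maps gene_id -> iterable of term ids; genes without
    annotation count toward the population size N only.  Per term with k
    study hits out of n study genes and K population hits out of N:
    fold = (k/n)/(K/N) and p = hypergeometric P(X >= k).  When
    ``filtered``, results are restricted to fold > min_fold and
    BH-adjusted p < alpha, sorted by fold descending.
    """
    study = set(study_genes)
    pop = set(population)
    if not study:
        raise ValueError("study gene set is empty")
    if not study <= pop:
        raise ValueError("study genes must be a subset of the population")
    n, N = len(study), len(pop)
    term_pop: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in pop:
            continue
        for term in terms:
            term_pop.setdefault(term, set()).add(gene)
    rows = []
    for term, members in sorted(term_pop.items()):
        K = len(members)
        if K == 0:
            continue
        k = len(members & study)
        fold = (k / n) / (K / N)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "n": n, "K": K, "N": N,
                     "fold": fold, "p_value": p})
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "fold", "p_value"])
    if df.empty:
        df["p_adjusted"] = []
        return df
    df["p_adjusted"] = adjust_pvalues(df["p_value"].to_numpy())
    if filtered:
        df = df[(df["fold"] > min_fold) & (df["p_adjusted"] < alpha)]
    return df.sort_values("fold", ascending=False).reset_index(drop=True)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Load an undirected simple graph from a TSV edge list.

    Columns: node_a, node_b, and optionally a confidence score (stored
    as edge attribute ``score``).  Self-loops are dropped on load.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            continue
        attrs = {"score": float(row[2])} if len(cols) > 2 else {}
        g.add_edge(a, b, **attrs)
    return g


def prune_low_degree(graph: nx.Graph, min_edges: int = 2,
                     cascade: bool = False) -> nx.Graph:
    """Remove nodes with fewer than ``min_edges`` edges.

    Degrees are evaluated on the INPUT graph in a single pass; nodes that
    drop below the threshold only after their neighbors are removed are
    kept (set ``cascade=True`` for iterated removal).
    """
    g = graph.copy()
    while True:
        drop = [n for n, d in g.degree() if d < min_edges]
        g.remove_nodes_from(drop)
        if not cascade or not drop:
            break
    # non-cascading keeps survivors even if their degree fell below the bar
    return g


def centrality_profile(graph: nx.Graph) -> pd.DataFrame:
    """Six per-node centrality metrics, connectivity handled per component.

    - betweenness: unnormalized count of shortest paths through the node
      (each unordered pair counted once, endpoints excluded);
    - closeness: (n_comp - 1) / sum of distances within the component;
    - avg_shortest_path_length: sum of distances / (n_comp - 1);
    - clustering_coefficient: triangles / possible wedges, 0 for degree < 2;
    - degree; eccentricity: max distance within the component.
    Isolated nodes get closeness, average path length and eccentricity 0.
    """
    nodes = list(graph.nodes)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    clustering = nx.clustering(graph)
    rows = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        m = len(comp)
        for node in comp:
            dists = nx.single_source_shortest_path_length(sub, node)
            total = sum(dists.values())
            rows[node] = {
                "betweenness": betweenness[node],
                "closeness": (m - 1) / total if total > 0 else 0.0,
                "avg_shortest_path_length": total / (m - 1) if m > 1 else 0.0,
                "clustering_coefficient": clustering[node],
                "degree": graph.degree(node),
                "eccentricity": max(dists.values()) if m > 1 else 0,
            }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[nodes]
    df.index.name = "node_id"
    return df[CENTRALITY_METRICS].astype(float)


@dataclass
class HubClustering:
    """k-means partition of centrality profiles plus the core-hub cluster."""

    labels: pd.Series = field(repr=False)
    core_cluster_id: int
    k: int
    iterations: int
    seed: int

    @property
    def core_nodes(self) -> list[str]:
        return list(self.labels.index[self.labels == self.core_cluster_id])


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def kmeans_hub_cluster(profiles: pd.DataFrame, k: int = 3, iterations: int = 500,
                       seed: int = 0) -> HubClustering:
    """Cluster standardized centrality profiles with Lloyd's k-means.

    Profiles are z-scored per metric (raw centralities live on wildly
    different scales, and unstandardized Euclidean distance would be
    degree-dominated).  Initialization draws k distinct nodes; iteration
    is capped at ``iterations``; everything is deterministic given the
    seed.  The core hub is the cluster with the highest mean standardized
    degree + betweenness.
    """
    n = len(profiles)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    X = _zscore(profiles.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    # kmeans++-style seeded start: k distinct random nodes, successive
    # picks weighted by squared distance to the chosen set (avoids the
    # bad local optima of uniformly random starts)
    first = int(rng.integers(n))
    chosen = [first]
    for _ in range(1, k):
        d2 = np.min(((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(axis=2),
                    axis=1)
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            remaining = [i for i in range(n) if i not in chosen]
            chosen.append(int(rng.choice(remaining)))
        else:
            chosen.append(int(rng.choice(n, p=d2 / total)))
    centers = X[chosen].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(iterations):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
    n_nonempty = len(np.unique(labels))
    if n_nonempty < k:
        warnings.warn(f"k-means produced only {n_nonempty} non-empty clusters "
                      f"(k={k}); geometry may be degenerate", stacklevel=2)
    idx_deg = profiles.columns.get_loc("degree")
    idx_btw = profiles.columns.get_loc("betweenness")
    centrality_score = np.full(k, -np.inf)
    for j in np.unique(labels):
        members = X[labels == j]
        centrality_score[j] = members[:, idx_deg].mean() + members[:, idx_btw].mean()
    core = int(np.argmax(centrality_score))
    return HubClustering(
        labels=pd.Series(labels, index=profiles.index, name="cluster"),
        core_cluster_id=core, k=k, iterations=iterations, seed=seed,
    )


def core_hub_genes(graph: nx.Graph, k: int = 3, iterations: int = 500,
                   seed: int = 0, min_edges: int = 2) -> tuple[list[str], HubClustering, pd.DataFrame]:
    """Prune, profile and cluster a network; return the core-hub gene list."""
    pruned = prune_low_degree(graph, min_edges=min_edges)
    if pruned.number_of_nodes() < k:
        raise ValueError(
            f"pruned network has {pruned.number_of_nodes()} nodes, fewer than k={k}")
    profiles = centrality_profile(pruned)
    clustering = kmeans_hub_cluster(profiles, k=k, iterations=iterations, seed=seed)
    return clustering.core_nodes, clustering, profiles
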