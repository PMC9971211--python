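import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from methylsignal.downstream import (centrality_profile, core_hub_genes,
                                     enrich_terms, kmeans_hub_cluster,
                                     prune_low_degree)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct summation of hypergeometric masses."""
    total = 0.0
    denom = comb(N, n, exact=True)
    for x in range(k, min(K, n) + 1):
        total += comb(K, x, exact=True) * comb(N - K, n - x, exact=True) / denom
    return total


def brute_force_centralities(g):
    """All six metrics from explicit all-pairs shortest paths."""
    out = {}
    sp = dict(nx.all_pairs_shortest_path_length(g))
    # betweenness from explicit path enumeration
    btw = {v: 0.0 for v in g}
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            btw[v] += frac
    for v in g:
        comp = [u for u in g if u in sp[v]]
        dists = [sp[v][u] for u in comp if u != v]
        deg = g.degree(v)
        neigh = list(g.neighbors(v))
        links = sum(1 for x, y in itertools.combinations(neigh, 2)
                    if g.has_edge(x, y))
        out[v] = {
            "betweenness": btw[v],
            "closeness": (len(dists) / sum(dists)) if dists else 0.0,
            "avg_shortest_path_length": (sum(dists) / len(dists)) if dists else 0.0,
            "clustering_coefficient": links / (deg * (deg - 1) / 2) if deg > 1 else 0.0,
            "degree": deg,
            "eccentricity": max(dists) if dists else 0,
        }
    return pd.DataFrame.from_dict(out, orient="index")


class TestEnrichTerms:
    def _setup(self):
        population = [f"g{i}" for i in range(1000)]
        annotation = {f"g{i}": {"T1"} for i in range(10)}     # K=10
        study = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(100, 145)]
        return study, annotation, population

    def test_fold_enrichment_arithmetic(self):
        study, ann, pop = self._setup()
        res = enrich_terms(study, ann, pop, min_fold=0, alpha=1.1, filtered=False)
        row = res[res["term_id"] == "T1"].iloc[0]
        # k=5/n=50 over K=10/N=1000 -> fold 10
        assert row.fold == pytest.approx(10.0)

    def test_min_fold_threshold_is_strict(self):
        study, ann, pop = self._setup()
        ann = dict(ann)
        ann.update({f"g{i}": {"T2"} for i in range(200, 800)})  # fold < 4 term
        res = enrich_terms(study, ann, pop, min_fold=4.0, alpha=1.0)
        assert set(res["term_id"]) <= {"T1"}

    def test_study_equal_to_population_has_unit_folds(self):
        pop = [f"g{i}" for i in range(40)]
        ann = {g: {"T"} for g in pop[:12]}
        res = enrich_terms(pop, ann, pop, filtered=False)
        assert res["fold"].to_numpy() == pytest.approx(1.0)

    def test_pvalues_match_hypergeometric_summation(self):
        rng = np.random.default_rng(19)
        for _ in range(40):
            N = int(rng.integers(5, 30))
            pop = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            ann = {g: {"T"} for g in pop[:K]}
            study = list(rng.choice(pop, size=n, replace=False))
            res = enrich_terms(study, ann, pop, filtered=False)
            k = len(set(study) & set(pop[:K]))
            assert res.iloc[0]["p_value"] == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), abs=1e-10)

    def test_empty_study_is_an_error(self):
        with pytest.raises(ValueError):
            enrich_terms([], {}, ["g1"])


class TestPruneLowDegree:
    def test_pendant_removed_triangle_kept(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        pruned = prune_low_degree(g, min_edges=2)
        assert set(pruned.nodes) == {"a", "b", "c"}

    def test_single_pass_keeps_survivors_with_fallen_degree(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        pruned = prune_low_degree(g, min_edges=2)
        assert set(pruned.nodes) == {"B"}
        assert pruned.degree("B") == 0

    def test_cascade_removes_everything_on_a_path(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        assert len(prune_low_degree(g, min_edges=2, cascade=True)) == 0

    def test_empty_graph(self):
        assert len(prune_low_degree(nx.Graph(), min_edges=2)) == 0


class TestCentralityProfile:
    def test_star_graph_enumerated_paths(self):
        g = nx.star_graph(3)  # hub 0, leaves 1..3
        prof = centrality_profile(g)
        assert prof.loc[0, "betweenness"] == pytest.approx(3.0)
        assert prof.loc[0, "eccentricity"] == 1
        assert prof.loc[1, "eccentricity"] == 2

    def test_triangle_is_fully_clustered_with_no_betweenness(self):
        g = nx.complete_graph(3)
        prof = centrality_profile(g)
        assert prof["clustering_coefficient"].to_numpy() == pytest.approx(1.0)
        assert prof["betweenness"].to_numpy() == pytest.approx(0.0)

    def test_path_graph_distance_sums(self):
        g = nx.path_graph(["A", "B", "C"])
        prof = centrality_profile(g)
        assert prof.loc["B", "closeness"] == pytest.approx(1.0)
        assert prof.loc["A", "closeness"] == pytest.approx(2 / 3)
        assert prof.loc["A", "avg_shortest_path_length"] == pytest.approx(1.5)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(20)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)),
                                    seed=int(rng.integers(1 << 30)))
            prof = centrality_profile(g)
            oracle = brute_force_centralities(g).loc[prof.index]
            pd.testing.assert_frame_equal(prof, oracle.astype(float),
                                          check_exact=False, atol=1e-9)

    def test_isolated_node_conventions(self):
        g = nx.Graph()
        g.add_node("x")
        prof = centrality_profile(g)
        assert prof.loc["x"].to_numpy() == pytest.approx(0.0)


class TestKmeansHubCluster:
    def _clouds(self):
        rng = np.random.default_rng(21)
        centers = np.array([[0.0] * 6, [30.0] * 6, [-30.0] * 6])
        rows, labels = [], []
        for i, c in enumerate(centers):
            for _ in range(15):
                rows.append(c + rng.normal(0, 0.5, 6))
                labels.append(i)
        prof = pd.DataFrame(rows, columns=["betweenness", "closeness",
                                           "avg_shortest_path_length",
                                           "clustering_coefficient", "degree",
                                           "eccentricity"])
        prof.index = [f"n{i}" for i in range(len(prof))]
        return prof, np.array(labels)

    def test_recovers_three_separated_clouds(self):
        prof, truth = self._clouds()
        clustering = kmeans_hub_cluster(prof, k=3, seed=4)
        got = clustering.labels.to_numpy()
        # partition identity up to label permutation
        for lab in range(3):
            members = got[truth == lab]
            assert len(np.unique(members)) == 1
        assert len(np.unique(got)) == 3

    def test_core_cluster_has_highest_degree_and_betweenness(self):
        prof, truth = self._clouds()
        clustering = kmeans_hub_cluster(prof, k=3, seed=4)
        core = clustering.core_cluster_id
        # the +30 cloud dominates degree+betweenness
        assert set(np.flatnonzero(clustering.labels.to_numpy() == core)) == \
            set(np.flatnonzero(truth == 1))

    def test_k_one_puts_everything_in_the_core(self):
        prof, _ = self._clouds()
        clustering = kmeans_hub_cluster(prof, k=1, seed=0)
        assert clustering.core_cluster_id == 0
        assert len(clustering.core_nodes) == len(prof)

    def test_identical_profiles_warn_about_degeneracy(self):
        prof = pd.DataFrame(np.ones((6, 6)),
                            columns=["betweenness", "closeness",
                                     "avg_shortest_path_length",
                                     "clustering_coefficient", "degree",
                                     "eccentricity"])
        with pytest.warns(UserWarning):
            kmeans_hub_cluster(prof, k=3, seed=0)

    def test_k_larger_than_node_count_is_an_error(self):
        prof, _ = self._clouds()
        with pytest.raises(ValueError):
            kmeans_hub_cluster(prof.head(2), k=3)

    def test_deterministic_given_seed(self):
        prof, _ = self._clouds()
        a = kmeans_hub_cluster(prof, k=3, seed=9)
        b = kmeans_hub_cluster(prof, k=3, seed=9)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestCoreHubGenes:
    def test_prunes_then_clusters(self):
        g = nx.barbell_graph(6, 2)
        core, clustering, profiles = core_hub_genes(g, k=2, seed=0, min_edges=2)
        assert set(profiles.index) <= set(g.nodes)
        assert set(core) <= set(profiles.index)
        assert len(core) > 0
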