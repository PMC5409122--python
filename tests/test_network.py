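"""Network convergence statistic, matched sampling and the two nulls."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from danseq.containers import empirical_p_value
from danseq.network import (
    build_integrated_network,
    cluster_test,
    clustering_statistic,
    permuted_direction_test,
    sample_matched,
    simulation_null_test,
    top_k_genes,
)
from danseq.synthetic import SimulationConfig, simulate_counts


def brute_force_statistic(genes, G):
    """Independent oracle: explicit double loop over all unordered pairs."""
    genes = list(dict.fromkeys(genes))
    w, c = 0.0, 0
    for u, v in itertools.combinations(genes, 2):
        if G.has_edge(u, v):
            w += G.edges[u, v].get("weight", 1.0)
            c += 1
    return w, c


class TestClusteringStatistic:
    def test_simple_path_and_triangle(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=2.0)
        G.add_edge("b", "c", weight=3.0)
        assert clustering_statistic(["a", "b", "c"], G) == (5.0, 2)
        T = nx.Graph()
        for u, v in (("x", "y"), ("y", "z"), ("x", "z")):
            T.add_edge(u, v, weight=1.0)
        assert clustering_statistic(["x", "y", "z"], T) == (3.0, 3)

    def test_single_gene_and_empty_set(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=1.0)
        assert clustering_statistic(["a"], G) == (0.0, 0)
        with pytest.warns(UserWarning):
            assert clustering_statistic([], G) == (0.0, 0)

    def test_absent_genes_contribute_nothing(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=4.0)
        assert clustering_statistic(["a", "b", "ghost"], G) == (4.0, 1)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            G = nx.gnp_random_graph(n, 0.1, seed=int(rng.integers(1 << 30)))
            for u, v in G.edges:
                G.edges[u, v]["weight"] = float(rng.random())
            genes = list(rng.choice(n, size=min(n, 30), replace=False))
            assert clustering_statistic(genes, G) == brute_force_statistic(genes, G)

    def test_adding_internal_edge_never_decreases(self):
        rng = np.random.default_rng(1)
        G = nx.gnp_random_graph(50, 0.05, seed=2)
        for u, v in G.edges:
            G.edges[u, v]["weight"] = 1.0
        genes = list(range(10))
        before, _ = clustering_statistic(genes, G)
        pairs = [p for p in itertools.combinations(genes, 2) if not G.has_edge(*p)]
        G.add_edge(*pairs[0], weight=0.5)
        after, _ = clustering_statistic(genes, G)
        assert after >= before


class TestEmpiricalP:
    def test_add_one_formula_vs_direct_count(self):
        rng = np.random.default_rng(3)
        null = rng.normal(size=999)
        for obs in (-3.0, 0.0, 2.5):
            direct = (np.sum(null >= obs) + 1) / (len(null) + 1)
            assert empirical_p_value(null, obs) == direct

    def test_extremes(self):
        null = np.arange(99, dtype=float)
        assert empirical_p_value(null, 1000.0) == 1 / 100  # beats every null
        assert empirical_p_value(null, -5.0) == 1.0  # below every null


class TestMatchedSampling:
    def test_single_cell_universe_constraint(self):
        # two attribute cells; targets in cell A must be replaced within A
        attrs = pd.DataFrame(
            {
                "degree": [1] * 40 + [100] * 40,
                "cds_length": [500] * 40 + [5000] * 40,
                "fpkm": [1] * 40 + [90] * 40,
            },
            index=[f"g{i}" for i in range(80)],
        )
        target = [f"g{i}" for i in range(5)]
        sets = sample_matched(target, attrs, 20, seed=4, min_donors=10)
        for s in sets:
            assert all(int(g[1:]) < 40 for g in s)
            assert len(set(s)) == len(target)  # no within-set replacement

    def test_matched_sets_preserve_median_degree(self, null_network):
        G, attrs = null_network
        rng = np.random.default_rng(5)
        target = list(rng.choice(list(G.nodes), 60, replace=False))
        sets = sample_matched(target, attrs, 100, seed=6)
        target_med = np.median(attrs.loc[target, "degree"])
        matched_med = np.median([np.median(attrs.loc[s, "degree"]) for s in sets])
        assert abs(matched_med - target_med) <= 2

    def test_same_seed_identical_sets(self, null_network):
        _, attrs = null_network
        target = list(attrs.index[:30])
        a = sample_matched(target, attrs, 5, seed=7)
        b = sample_matched(target, attrs, 5, seed=7)
        assert a == b

    def test_universe_smaller_than_set_rejected(self):
        attrs = pd.DataFrame(
            {"degree": [1, 2], "cds_length": [10, 20], "fpkm": [1, 2]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError):
            sample_matched(["a", "b", "missing"], attrs, 1)


class TestClusterTest:
    def test_planted_module_maximally_significant(self, planted_network):
        G, attrs, _ = planted_network
        res = cluster_test(G.graph["modules"][0], G, attrs, n_null=999, seed=8)
        assert res.empirical_p == 1 / 1000
        assert res.observed_stat > res.null_stats.max()
        # nearly all module genes carry at least one within-set edge
        assert len(res.clustered_genes) >= 45

    def test_null_set_not_significant(self, null_network):
        G, attrs = null_network
        rng = np.random.default_rng(9)
        target = list(rng.choice(list(G.nodes), 40, replace=False))
        res = cluster_test(target, G, attrs, n_null=199, seed=10)
        assert res.empirical_p > 0.05

    def test_requires_minimum_nulls(self, null_network):
        G, attrs = null_network
        with pytest.raises(ValueError):
            cluster_test(list(attrs.index[:10]), G, attrs, n_null=50)


class TestPermutedDirectionTest:
    def test_shuffling_dilutes_module_structure(self, planted_network):
        G, attrs, _ = planted_network
        up, down = G.graph["modules"]
        intact_up = cluster_test(up, G, attrs, n_null=199, seed=11)
        res_up, res_down = permuted_direction_test(
            up, down, attrs, G, n_null=199, seed=12
        )
        # shuffled sets mix the two modules: fewer within-set links than intact
        assert res_up.observed_stat < intact_up.observed_stat

    def test_empty_up_degenerates_with_warning(self, null_network):
        G, attrs = null_network
        with pytest.warns(UserWarning):
            res_up, res_down = permuted_direction_test(
                [], list(attrs.index[:10]), attrs, G, n_null=199, seed=13
            )
        assert res_up is None and res_down is not None

    def test_seed_reproducible(self, planted_network):
        G, attrs, _ = planted_network
        up, down = G.graph["modules"]
        a = permuted_direction_test(up, down, attrs, G, n_null=199, seed=14)
        b = permuted_direction_test(up, down, attrs, G, n_null=199, seed=14)
        assert np.array_equal(a[0].null_stats, b[0].null_stats)
        assert a[0].observed_stat == b[0].observed_stat


class TestTopK:
    def test_deterministic_tie_break(self):
        t = pd.DataFrame(
            {
                "p_value": [0.5, 0.01, 0.01, np.nan],
                "wald_stat": [1.0, 2.0, -3.0, np.nan],
            },
            index=["d", "b", "a", "z"],
        )
        assert top_k_genes(t, 2) == ["a", "b"]  # |stat| desc breaks the tie


class TestSimulationNull:
    def test_saturating_k_gives_p_one(self, nb_template):
        cm, _ = simulate_counts(
            SimulationConfig(n_genes=60, p_diff=0.0, p_outlier=0.0, seed=15), nb_template
        )
        G = nx.Graph()
        genes = list(cm.counts.index)
        for i in range(len(genes) - 1):
            G.add_edge(genes[i], genes[i + 1], weight=1.0)
        obs, _ = clustering_statistic(genes, G)
        res = simulation_null_test(cm, k=60, n_sim=5, network=G, observed_stat=obs, seed=16)
        assert res["empirical_p"] == 1.0
        assert np.allclose(res["null_stats"], obs)

    def test_seed_reproducible(self, nb_template):
        cm, _ = simulate_counts(
            SimulationConfig(n_genes=60, p_diff=0.0, seed=17), nb_template
        )
        G = nx.path_graph([f"G{i:04d}" for i in range(60)])
        nx.set_edge_attributes(G, 1.0, "weight")
        a = simulation_null_test(cm, k=10, n_sim=4, network=G, observed_stat=3.0, seed=18)
        b = simulation_null_test(cm, k=10, n_sim=4, network=G, observed_stat=3.0, seed=18)
        assert np.array_equal(a["null_stats"], b["null_stats"])


class TestIntegratedNetwork:
    @staticmethod
    def make_benchmark(rng, genes, n_terms=6, term_size=30):
        return {
            f"t{k}": set(rng.choice(genes, term_size, replace=False))
            for k in range(n_terms)
        }

    def test_self_calibrating_dataset_recovers_sharing_pairs(self):
        # score == sharing indicator, with sharing pairs exactly 2/5 of the
        # input so the five quantile bins align with the class boundary:
        # non-sharing bins get likelihood ratio 0 and drop out entirely
        rng = np.random.default_rng(19)
        genes = [f"g{i}" for i in range(120)]
        benchmark = self.make_benchmark(rng, genes)
        gene_terms = {}
        for t, members in benchmark.items():
            for g in members:
                gene_terms.setdefault(g, set()).add(t)
        all_pairs = list(itertools.combinations(genes, 2))
        rng.shuffle(all_pairs)
        share_of = {
            p: bool(gene_terms.get(p[0], set()) & gene_terms.get(p[1], set()))
            for p in all_pairs
        }
        sharing = [p for p in all_pairs if share_of[p]][:800]
        nonsharing = [p for p in all_pairs if not share_of[p]][:1200]
        pairs = sharing + nonsharing
        df = pd.DataFrame(
            {
                "gene_a": [p[0] for p in pairs],
                "gene_b": [p[1] for p in pairs],
                "score": [1.0 + rng.normal(0, 1e-6) if share_of[p] else rng.normal(0, 1e-6)
                          for p in pairs],
            }
        )
        G = build_integrated_network({"d": df}, benchmark, top_m=10_000, bins=5)
        retained = {tuple(sorted(e)) for e in G.edges}
        assert retained == {tuple(sorted(p)) for p in sharing}

    def test_duplicated_dataset_doubles_weights(self):
        rng = np.random.default_rng(20)
        genes = [f"g{i}" for i in range(120)]
        benchmark = self.make_benchmark(rng, genes)
        pairs = rng.integers(0, 120, size=(2000, 2))
        df = pd.DataFrame(
            {
                "gene_a": [genes[a] for a, b in pairs if a != b],
                "gene_b": [genes[b] for a, b in pairs if a != b],
                "score": rng.random(sum(1 for a, b in pairs if a != b)),
            }
        )
        g1 = build_integrated_network({"d": df}, benchmark, top_m=10**6, bins=4)
        g2 = build_integrated_network({"d1": df, "d2": df}, benchmark, top_m=10**6, bins=4)
        for u, v, w in g1.edges(data="weight"):
            assert g2.edges[u, v]["weight"] == pytest.approx(2 * w)

    def test_uninformative_dataset_contributes_nothing(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(200)]
        benchmark = self.make_benchmark(rng, genes, n_terms=8, term_size=60)
        idx = rng.integers(0, 200, size=(20_000, 2))
        mask = idx[:, 0] != idx[:, 1]
        df = pd.DataFrame(
            {
                "gene_a": [genes[a] for a in idx[mask, 0]],
                "gene_b": [genes[b] for b in idx[mask, 1]],
                "score": rng.random(int(mask.sum())),  # independent of sharing
            }
        )
        G = build_integrated_network({"d": df}, benchmark, top_m=10**6, bins=5)
        if G.number_of_edges():
            weights = [w for _, _, w in G.edges(data="weight")]
            assert max(weights) < 0.1

    def test_empty_benchmark_rejected(self):
        df = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "score": [1.0]})
        with pytest.raises(ValueError):
            build_integrated_network({"d": df}, {}, top_m=10)
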