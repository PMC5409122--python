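"""Generators: NB parameter fitting, count simulation, networks, ranks."""

import numpy as np
import pandas as pd
import pytest

from danseq.containers import SignedGeneSet
from danseq.synthetic import (
    SimulationConfig,
    SyntheticNetworkConfig,
    _drop_extreme_phi,
    default_nb_params,
    fit_nb_params,
    generate_annotations,
    generate_rank_matrix,
    generate_synthetic_network,
    gene_names,
    resample_joint_params,
    simulate_counts,
    simulate_matched_null,
)


class TestFitNBParams:
    def test_moments_formula(self):
        # constant counts: Poisson; all-zero: degenerate and flagged;
        # mean 20 with sample variance 96 gives phi = (96-20)/400 = 0.19
        df = pd.DataFrame(
            [[10, 10, 10, 10], [0, 0, 0, 0], [8, 32, 20, 20]],
            index=["const", "zero", "disp"],
        )
        par = fit_nb_params(df)
        assert par.loc["const", "mu"] == 10 and par.loc["const", "phi"] == 0
        assert par.loc["zero", "mu"] == 0 and par.loc["zero", "phi"] == 0
        assert bool(par.loc["zero", "flagged"]) and not bool(par.loc["const", "flagged"])
        assert par.loc["disp", "mu"] == 20
        assert par.loc["disp", "phi"] == pytest.approx((96 - 20) / 400)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            fit_nb_params(pd.DataFrame([[5]]))


class TestResampling:
    def test_drop_extreme_dispersion_exact_top_decile(self):
        phis = np.arange(10, dtype=float)
        par = pd.DataFrame({"mu": np.full(10, 5.0), "phi": phis})
        kept = _drop_extreme_phi(par, 0.1)
        assert len(kept) == 9 and kept["phi"].max() == 8.0

    def test_joint_copula_preserved(self):
        par = default_nb_params(2000, seed=5)
        rng = np.random.default_rng(0)
        mu, phi = resample_joint_params(par, 10_000, 0.0, rng)
        orig = np.corrcoef(np.log(par["mu"]), np.log(par["phi"]))[0, 1]
        boot = np.corrcoef(np.log(mu), np.log(phi))[0, 1]
        assert abs(orig - boot) < 0.05


class TestSimulateCounts:
    def test_fold_change_three(self, nb_template):
        cfg = SimulationConfig(n_genes=3000, n_cases=30, n_controls=30,
                               p_diff=0.2, p_outlier=0.0, seed=7)
        cm, truth = simulate_counts(cfg, nb_template)
        case = cm.counts[cm.samples_in("case")].mean(axis=1)
        ctrl = cm.counts[cm.samples_in("control")].mean(axis=1)
        up = truth == "up_in_case"
        ratios = (case[up] + 0.5) / (ctrl[up] + 0.5)
        assert np.median(ratios) == pytest.approx(3.0, rel=0.15)
        down = truth == "down_in_case"
        assert np.median((ctrl[down] + 0.5) / (case[down] + 0.5)) == pytest.approx(3.0, rel=0.15)

    def test_null_config_all_labels_null(self, nb_template):
        _, truth = simulate_counts(SimulationConfig(n_genes=200, p_diff=0.0, seed=1), nb_template)
        assert (truth == "null").all()

    def test_truth_label_count_invariant(self, nb_template):
        cfg = SimulationConfig(n_genes=1000, p_diff=0.13, seed=2)
        _, truth = simulate_counts(cfg, nb_template)
        assert (truth != "null").sum() == round(0.13 * 1000)

    def test_poisson_limit_variance_equals_mean(self):
        par = pd.DataFrame({"mu": [50.0], "phi": [0.0]})
        cfg = SimulationConfig(n_genes=1, n_cases=5000, n_controls=5000,
                               p_diff=0.0, p_outlier=0.0, drop_extreme_dispersion=0.0, seed=3)
        cm, _ = simulate_counts(cfg, par)
        x = cm.counts.iloc[0].to_numpy()
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.06)

    def test_outliers_single_count_and_rate(self, nb_template):
        cfg = SimulationConfig(n_genes=4000, p_outlier=0.05, p_diff=0.0, seed=4)
        base, _ = simulate_counts(
            SimulationConfig(n_genes=4000, p_outlier=0.0, p_diff=0.0, seed=4), nb_template
        )
        out, _ = simulate_counts(cfg, nb_template)
        diff = (base.counts.to_numpy() != out.counts.to_numpy())
        per_gene = diff.sum(axis=1)
        assert per_gene.max() <= 1  # at most one altered count per gene
        frac = (per_gene == 1).mean()
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(frac - 0.05) < 4 * se

    def test_seed_reproducible(self, nb_template):
        a, ta = simulate_counts(SimulationConfig(n_genes=100, seed=9), nb_template)
        b, tb = simulate_counts(SimulationConfig(n_genes=100, seed=9), nb_template)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(ta, tb)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_diff=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(fold_diff=0.5)


class TestMatchedNull:
    def test_means_match_template(self, nb_template):
        cm, _ = simulate_counts(SimulationConfig(n_genes=300, p_diff=0.0, seed=5), nb_template)
        sets = list(simulate_matched_null(cm, 200, seed=6))
        template_mean = cm.counts.mean(axis=1).to_numpy()
        sim_mean = np.mean([s.counts.mean(axis=1).to_numpy() for s in sets], axis=0)
        big = template_mean >= 10
        assert np.allclose(sim_mean[big] / template_mean[big], 1.0, atol=0.15)

    def test_first_matrix_deterministic(self, nb_template):
        cm, _ = simulate_counts(SimulationConfig(n_genes=100, seed=5), nb_template)
        a = next(simulate_matched_null(cm, 3, seed=8))
        b = next(simulate_matched_null(cm, 3, seed=8))
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_rejects_nonpositive_n_sets(self, nb_template):
        cm, _ = simulate_counts(SimulationConfig(n_genes=50, seed=5), nb_template)
        with pytest.raises(ValueError):
            list(simulate_matched_null(cm, 0))


class TestSyntheticNetwork:
    def test_planted_module_beats_random_sets(self):
        from danseq.network import clustering_statistic

        G = generate_synthetic_network(
            SyntheticNetworkConfig(n_genes=600, module_sizes=(50,), seed=1)
        )
        module = G.graph["modules"][0]
        obs, _ = clustering_statistic(module, G)
        rng = np.random.default_rng(2)
        nodes = list(G.nodes)
        null = [
            clustering_statistic(list(rng.choice(nodes, 50, replace=False)), G)[0]
            for _ in range(200)
        ]
        assert obs > np.quantile(null, 0.99)

    def test_zero_background_confines_edges_to_module(self):
        G = generate_synthetic_network(
            SyntheticNetworkConfig(
                n_genes=100, module_sizes=(20,), background_density=0.0, seed=2
            )
        )
        module = set(G.graph["modules"][0])
        assert G.number_of_edges() > 0
        assert all(u in module and v in module for u, v in G.edges)

    def test_seed_reproducible_edge_list(self):
        cfg = SyntheticNetworkConfig(n_genes=200, module_sizes=(20,), seed=3)
        e1 = sorted(generate_synthetic_network(cfg).edges(data="weight"))
        e2 = sorted(generate_synthetic_network(cfg).edges(data="weight"))
        assert e1 == e2

    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError):
            SyntheticNetworkConfig(n_genes=10, module_sizes=(8, 8))


class TestAnnotations:
    def test_full_overlap_term_equals_module(self):
        genes = gene_names(200)
        module = genes[:30]
        terms, _ = generate_annotations(
            genes, [module], n_terms=3, overlap_fraction=1.0, seed=1,
            term_size_range=(30, 30),
        )
        assert terms["TERM:0000"] == set(module)

    def test_zero_overlap_matches_hypergeometric(self):
        genes = gene_names(400)
        module = genes[:40]
        overlaps = []
        for seed in range(60):
            terms, _ = generate_annotations(
                genes, [module], n_terms=1, overlap_fraction=0.0, seed=seed,
                term_size_range=(50, 50),
            )
            overlaps.append(len(terms["TERM:0000"] & set(module)))
        expect = 50 * 40 / 400  # hypergeometric mean
        se = np.sqrt(expect * (1 - 40 / 400)) / np.sqrt(60)
        assert abs(np.mean(overlaps) - expect) < 4 * se

    def test_attributes_positive(self):
        _, attrs = generate_annotations(gene_names(50), [], n_terms=2, seed=3)
        assert (attrs["cds_length"] > 0).all() and (attrs["fpkm"] > 0).all()


class TestRankMatrix:
    @pytest.fixture()
    def setup(self):
        genes = gene_names(100)
        probe_map = {f"P{i:05d}": genes[i % 100] for i in range(400)}
        sig = SignedGeneSet(up=genes[:10], down=genes[10:18])
        return genes, probe_map, sig

    def test_columns_are_permutations(self, setup):
        _, probe_map, sig = setup
        ranks, _ = generate_rank_matrix(400, {"a": 3}, sig, {"a": 0.5}, probe_map, seed=1)
        for col in ranks.columns:
            assert sorted(ranks[col]) == list(range(1, 401))

    def test_maximal_concordance_blocks(self, setup):
        _, probe_map, sig = setup
        ranks, meta = generate_rank_matrix(400, {"a": 2}, sig, {"a": 1.0}, probe_map, seed=2)
        up_probes = [p for p, g in probe_map.items() if g in set(sig.up)]
        down_probes = [p for p, g in probe_map.items() if g in set(sig.down)]
        for col in ranks.columns:
            assert set(ranks.loc[up_probes, col]) == set(range(1, len(up_probes) + 1))
            assert ranks.loc[down_probes, col].min() == 401 - len(down_probes)

    def test_zero_concordance_mean_rank(self, setup):
        _, probe_map, sig = setup
        cols = []
        for seed in range(30):
            ranks, _ = generate_rank_matrix(400, {"a": 1}, sig, {}, probe_map, seed=seed)
            sig_probes = [p for p, g in probe_map.items() if g in set(sig.genes)]
            cols.append(ranks.loc[sig_probes].to_numpy().mean())
        assert np.mean(cols) == pytest.approx((400 + 1) / 2, rel=0.05)

    def test_deterministic(self, setup):
        _, probe_map, sig = setup
        r1, _ = generate_rank_matrix(400, {"a": 2}, sig, {"a": 0.3}, probe_map, seed=9)
        r2, _ = generate_rank_matrix(400, {"a": 2}, sig, {"a": 0.3}, probe_map, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_unmapped_signature_gene_rejected(self, setup):
        genes, probe_map, _ = setup
        bad = SignedGeneSet(up=["NOT_A_GENE"], down=genes[:2])
        with pytest.raises(ValueError):
            generate_rank_matrix(400, {"a": 1}, bad, {}, probe_map, seed=1)
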