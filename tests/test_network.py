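"""Network construction, metrics, subsample equalization and comparison."""

import numpy as np
import pandas as pd
import pytest

from micronet.network import (
    SubsampleComparison,
    TimepointComparisonConfig,
    build_network,
    compare_timepoints,
    compute_metrics,
    percent_change,
    representative_network,
    subsample_networks,
)
from micronet.sparcc import CorrelationResult, SparccParams


def result_from_p(p, taxa=None):
    p = np.asarray(p, dtype=float)
    taxa = taxa or [f"t{j}" for j in range(p.shape[0])]
    return CorrelationResult(r=np.eye(len(taxa)), p=p, taxa=taxa)


def network_from_edges(n, edges, alpha=0.05):
    p = np.ones((n, n))
    for i, j in edges:
        p[i, j] = p[j, i] = 0.01
    return build_network(result_from_p(p), alpha)


class TestBuildNetwork:
    def test_all_ones_pvalues_give_empty_network(self):
        net = build_network(result_from_p(np.ones((4, 4))))
        assert len(net.edges) == 0
        assert compute_metrics(net).edge_density == 0.0

    def test_threshold_is_strict(self):
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = 0.05  # exactly alpha: excluded
        p[0, 2] = p[2, 0] = 0.049999
        net = build_network(result_from_p(p), alpha=0.05)
        assert ("t0", "t2") in net.edges or ("t2", "t0") in net.edges
        assert len(net.edges) == 1

    def test_isolated_taxa_remain_nodes(self):
        net = network_from_edges(5, [(0, 1)])
        assert len(net.nodes) == 5

    def test_density_at_printed_scale(self):
        # 382 edges over 70 nodes: 382 / C(70,2) = 382/2415 ~ 15.8%
        rng = np.random.default_rng(0)
        pairs = [(i, j) for i in range(70) for j in range(i + 1, 70)]
        chosen = [pairs[k] for k in rng.choice(len(pairs), 382, replace=False)]
        m = compute_metrics(network_from_edges(70, chosen))
        assert m.n_edges == 382
        assert m.edge_density == pytest.approx(382 / 2415)
        assert round(100 * m.edge_density) == 16


class TestComputeMetrics:
    def test_triangle(self):
        m = compute_metrics(network_from_edges(3, [(0, 1), (1, 2), (0, 2)]))
        assert (m.n_edges, m.edge_density, m.avg_clustering) == (3, 1.0, 1.0)

    def test_star_has_zero_clustering(self):
        m = compute_metrics(network_from_edges(4, [(0, 1), (0, 2), (0, 3)]))
        assert m.avg_clustering == 0.0

    def test_clustering_matches_bruteforce_triangles(self):
        rng = np.random.default_rng(1)
        n = 14
        p = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    p[i, j] = p[j, i] = 0.01
        net = build_network(result_from_p(p))
        adj = (p < 0.05).astype(int)
        np.fill_diagonal(adj, 0)
        local = []
        for v in range(n):
            nb = np.flatnonzero(adj[v])
            k = len(nb)
            if k < 2:
                local.append(0.0)
                continue
            links = sum(
                adj[a, b] for ai, a in enumerate(nb) for b in nb[ai + 1:]
            )
            local.append(2 * links / (k * (k - 1)))
        assert compute_metrics(net).avg_clustering == pytest.approx(np.mean(local))

    def test_single_node_rejected(self):
        net = network_from_edges(1, [])
        with pytest.raises(ValueError, match="2 nodes"):
            compute_metrics(net)

    def test_relabeling_invariance(self):
        edges = [(0, 1), (1, 2), (0, 2), (2, 3)]
        a = compute_metrics(network_from_edges(5, edges))
        relabeled = [(4 - i, 4 - j) for i, j in edges]
        b = compute_metrics(network_from_edges(5, relabeled))
        assert a.avg_clustering == pytest.approx(b.avg_clustering)

    def test_alpha_extremes(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 0.999, (6, 6))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 1.0)
        assert len(build_network(result_from_p(p), alpha=0.0).edges) == 0
        full = build_network(result_from_p(p), alpha=1.0)
        assert len(full.edges) == 6 * 5 // 2


# few-taxon fixtures: keep exclusion rounds low, otherwise noisy small-D
# estimates exclude every pair of some taxon and the system turns singular
FAST = SparccParams(
    n_estimation_iterations=4, n_bootstraps=8, max_exclusion_rounds=3, seed=0
)


class TestSubsampleNetworks:
    def test_fixed_seed_reproduces_all_replicates(self, cluster_counts):
        rng = np.random.default_rng(5)
        counts = rng.poisson(200, size=(30, 8)) + 1
        kw = dict(n_subsample=15, n_replicates=12, sparcc_params=FAST, seed=42)
        a = subsample_networks(counts, **kw)
        b = subsample_networks(counts, **kw)
        assert [m.as_tuple() for m in a.metrics] == [m.as_tuple() for m in b.metrics]
        assert a.replicate_seeds == b.replicate_seeds

    def test_full_size_subsample_with_fixed_estimator_seed_degenerates(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(150, size=(16, 6)) + 1
        comp = subsample_networks(
            counts, n_subsample=16, n_replicates=8,
            sparcc_params=FAST, seed=1, reseed_per_replicate=False,
        )
        tuples = {m.as_tuple() for m in comp.metrics}
        assert len(tuples) == 1

    def test_singular_replicates_are_redrawn_to_full_count(self, cluster_counts):
        comp = subsample_networks(
            cluster_counts, n_subsample=8, n_replicates=20,
            sparcc_params=SparccParams(
                n_estimation_iterations=4, n_bootstraps=5,
                max_exclusion_rounds=10, seed=0,
            ),
            seed=3,
        )
        assert len(comp.metrics) == 20
        assert comp.n_discarded > 0

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError, match="cannot subsample"):
            subsample_networks(np.ones((5, 6), dtype=int), n_subsample=10)

    def test_mean_metrics_are_arithmetic_means(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, size=(20, 6)) + 1
        comp = subsample_networks(
            counts, n_subsample=10, n_replicates=6, sparcc_params=FAST, seed=2
        )
        assert comp.mean_n_edges == pytest.approx(
            np.mean([m.n_edges for m in comp.metrics])
        )


class TestRepresentativeNetwork:
    def _comparison(self, tuples):
        from micronet.network import CooccurrenceNetwork, NetworkMetrics
        import networkx as nx

        metrics = [
            NetworkMetrics(n_nodes=10, n_edges=int(e), edge_density=d, avg_clustering=c)
            for e, d, c in tuples
        ]
        nets = [
            CooccurrenceNetwork(graph=nx.empty_graph(i + 2), alpha=0.05)
            for i in range(len(tuples))
        ]
        return SubsampleComparison(
            metrics=metrics, networks=nets, replicate_seeds=list(range(len(tuples))),
            n_discarded=0,
        )

    def test_all_identical_ties_break_to_first(self):
        comp = self._comparison([(5, 0.1, 0.2)] * 4)
        assert representative_network(comp) is comp.networks[0]

    def test_exact_mean_replicate_wins(self):
        tuples = [(4, 0.10, 0.1), (8, 0.20, 0.3), (6, 0.15, 0.2)]
        comp = self._comparison(tuples)  # third tuple is the mean vector
        assert representative_network(comp) is comp.networks[2]

    def test_argmin_matches_bruteforce_distance(self):
        tuples = [(3, 0.1, 0.05), (9, 0.31, 0.4), (5, 0.18, 0.22),
                  (6, 0.22, 0.18), (7, 0.2, 0.33)]
        comp = self._comparison(tuples)
        X = np.array(tuples, dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        dist = np.sqrt((((X - mu) / sd) ** 2).sum(axis=1))
        assert representative_network(comp) is comp.networks[int(np.argmin(dist))]


class TestCompareTimepoints:
    def test_percent_change_printed_examples(self):
        assert percent_change(382, 328) == -14.14
        assert percent_change(0.29, 0.41) == 41.38
        assert percent_change(7.5, 7.5) == 0.0

    def test_zero_baseline_is_undefined_not_infinite(self):
        assert percent_change(0, 5) is None

    def test_direct_mode_for_small_groups_and_planted_separation(self):
        # planted correlated block vs null group at matched n: the planted
        # group must yield strictly more edges
        from micronet.synthetic_data import (
            SyntheticConfig, block_correlation, generate_basis, sample_counts,
        )

        cells = [(g, t) for g in ("gain", "loss") for t in ("1m", "6m")]
        n_taxa, n = 12, 60
        C = block_correlation(n_taxa, list(range(6)), 0.8)
        cfg_planted = SyntheticConfig(
            n_taxa=n_taxa, basis_correlations={c: C.copy() for c in cells},
            fold_changes=np.ones(n_taxa), dominance_factor=1.0, seed=0,
        )
        cfg_null = SyntheticConfig(
            n_taxa=n_taxa, basis_correlations={c: np.eye(n_taxa) for c in cells},
            fold_changes=np.ones(n_taxa), dominance_factor=1.0, seed=0,
        )
        counts = {}
        for name, cfg in (("planted", cfg_planted), ("null", cfg_null)):
            rng = np.random.default_rng(1)
            basis = generate_basis(cfg, "gain", "1m", n, rng=rng)
            libs = cfg.library_size_law.draw(rng, n)
            counts[name] = pd.DataFrame(
                sample_counts(basis, libs, seed=rng),
                columns=[f"t{j}" for j in range(n_taxa)],
            )
        cfg = TimepointComparisonConfig(
            n_subsample=None, sparcc_params=SparccParams(
                n_estimation_iterations=5, n_bootstraps=30, seed=0
            ), seed=0,
        )
        out = compare_timepoints(counts["planted"], counts["null"], cfg)
        assert out["metrics"]["1m"]["mode"] == "direct"
        assert out["metrics"]["1m"]["n_edges"] > out["metrics"]["6m"]["n_edges"]

    def test_mismatched_taxa_rejected(self):
        a = pd.DataFrame(np.ones((4, 3), dtype=int), columns=["x", "y", "z"])
        b = pd.DataFrame(np.ones((4, 3), dtype=int), columns=["x", "y", "w"])
        with pytest.raises(ValueError, match="identical taxon set"):
            compare_timepoints(a, b)
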