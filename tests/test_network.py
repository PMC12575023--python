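"""Co-occurrence networks: Spearman, RMT threshold, topology, nulls, matching."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from micronet.core import ValidationError
from micronet.network import (
    CorrelationNetwork,
    build_network,
    match_modules,
    nnsd_poisson_pvalue,
    random_null,
    rmt_threshold_scan,
    spearman_matrix,
    topology,
)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2,
                             -np.arange(10.0)])
        rho, const = spearman_matrix(x)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)
        assert not const.any()

    def test_tie_correction_matches_hand_ranked_oracle(self):
        """Ranks computed by hand (mid-ranks for the tie), then Pearson."""
        a = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        b = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        ranks_a = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ranks_b = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        expected = float(np.corrcoef(ranks_a, ranks_b)[0, 1])
        rho, _ = spearman_matrix(np.column_stack([a, b]))
        assert rho[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_flagged_zero(self):
        x = np.column_stack([np.arange(6.0), np.full(6, 3.0)])
        rho, const = spearman_matrix(x)
        assert const.tolist() == [False, True]
        assert rho[0, 1] == 0.0
        assert rho[1, 1] == 1.0


def _block_corr(n_blocks=6, block=5, rho=0.9, n=None):
    """Block-diagonal correlation matrix of independent equicorrelated blocks."""
    size = n_blocks * block
    out = np.eye(size)
    for b in range(n_blocks):
        sl = slice(b * block, (b + 1) * block)
        out[sl, sl] = rho
    np.fill_diagonal(out, 1.0)
    return out


class TestRmtThreshold:
    def test_noise_spectrum_rejects_poisson_at_low_cutoff(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 120))
        rho = np.corrcoef(x, rowvar=False)
        scan = rmt_threshold_scan(rho, 0.3, 0.9, 0.1)
        by_s = {round(rec["s"], 2): rec["poisson_p"] for rec in scan["scan"]}
        assert by_s[0.3] < 0.05  # Wigner-like at a permissive cutoff

    def test_sparse_block_structure_is_poisson(self):
        rng = np.random.default_rng(1)
        corr = _block_corr(n_blocks=10, block=4, rho=0.95)
        noise = rng.normal(0, 0.02, corr.shape)
        corr = np.clip(corr + (noise + noise.T) / 2, -1, 1)
        np.fill_diagonal(corr, 1.0)
        a = np.where(np.abs(corr) >= 0.8, corr, 0.0)
        np.fill_diagonal(a, 1.0)
        eigvals = np.linalg.eigvalsh(a)
        from micronet.network import _unfolded_spacings

        p = nnsd_poisson_pvalue(_unfolded_spacings(eigvals))
        assert p > 0.05

    def test_edge_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((25, 40))
        rho = np.corrcoef(x, rowvar=False)
        scan = rmt_threshold_scan(rho, 0.2, 0.9, 0.1)
        edges = [rec["n_edges"] for rec in scan["scan"]]
        assert all(b <= a for a, b in zip(edges, edges[1:]))

    def test_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            rmt_threshold_scan(np.eye(10))


class TestBuildNetwork:
    def test_triangle_at_published_cutoff(self):
        corr = np.full((3, 3), 0.95)
        np.fill_diagonal(corr, 1.0)
        net = build_network(corr, 0.93, ("a", "b", "c"))
        assert net.graph.number_of_edges() == 3

    def test_cutoff_above_correlations_is_error(self):
        corr = np.full((3, 3), 0.95)
        np.fill_diagonal(corr, 1.0)
        with pytest.raises(ValidationError, match="threshold"):
            build_network(corr, 0.96, ("a", "b", "c"))

    def test_planted_modules_recovered(self):
        """Module detection on a simulated table matches planted truth."""
        from sklearn.metrics import adjusted_rand_score

        from micronet.differential import transform_log_relative
        from micronet.simulate import simulate_otu_table

        table, truth = simulate_otu_table(seed=1)
        rho, _ = spearman_matrix(transform_log_relative(table).to_numpy())
        net = build_network(rho, 0.55, table.otu_ids)
        members = [o for o in net.graph.nodes if o in truth.module_assignment]
        ari = adjusted_rand_score(
            [truth.module_assignment[o] for o in members],
            [net.module_of[o] for o in members],
        )
        assert ari >= 0.8

    def test_lower_threshold_gives_supergraph(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((20, 30))
        rho = np.corrcoef(x, rowvar=False)
        hi = build_network(rho, 0.5, tuple(map(str, range(30))))
        lo = build_network(rho, 0.4, tuple(map(str, range(30))))
        hi_edges = {frozenset(e) for e in hi.graph.edges}
        lo_edges = {frozenset(e) for e in lo.graph.edges}
        assert hi_edges <= lo_edges


def _net_from_graph(g):
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    module_of = {n: i for i, c in enumerate(comms) for n in c}
    for u, v in g.edges:
        g[u][v].setdefault("sign", 1)
    return CorrelationNetwork(g, 0.9, module_of)


class TestTopology:
    def test_complete_graph_k4(self):
        t = topology(_net_from_graph(nx.complete_graph(4)))
        assert t.avg_degree == pytest.approx(3.0)
        assert t.avg_clustering == pytest.approx(1.0)
        assert t.avg_path_distance == pytest.approx(1.0)

    def test_two_disjoint_triangles_modularity_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        net = CorrelationNetwork(
            g, 0.9, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        )
        for u, v in g.edges:
            g[u][v]["sign"] = 1
        t = topology(net)
        assert t.modularity == pytest.approx(0.5)
        assert t.n_modules == 2

    def test_star_has_zero_clustering(self):
        t = topology(_net_from_graph(nx.star_graph(4)))
        assert t.avg_clustering == 0.0

    def test_sign_percentages(self):
        g = nx.Graph()
        g.add_edge(0, 1, sign=1, rho=0.95)
        g.add_edge(1, 2, sign=-1, rho=-0.95)
        net = CorrelationNetwork(g, 0.9, {0: 0, 1: 0, 2: 0})
        t = topology(net)
        assert t.pct_positive == pytest.approx(50.0)
        assert t.pct_positive + t.pct_negative == pytest.approx(100.0)

    def test_brute_force_oracles_on_random_graphs(self):
        """Floyd–Warshall and per-node triangle counting agree with the
        implementation on 20 random 15-node graphs."""
        rng = np.random.default_rng(7)
        for rep in range(20):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            net = _net_from_graph(g)
            t = topology(net)
            # clustering oracle
            ccs = []
            for v in g.nodes:
                nbrs = list(g.neighbors(v))
                k = len(nbrs)
                if k < 2:
                    ccs.append(0.0)
                    continue
                links = sum(
                    1 for a, b in itertools.combinations(nbrs, 2)
                    if g.has_edge(a, b)
                )
                ccs.append(2.0 * links / (k * (k - 1)))
            assert t.avg_clustering == pytest.approx(np.mean(ccs), abs=1e-12)
            # shortest-path oracle (Floyd–Warshall over connected pairs)
            n = g.number_of_nodes()
            dist = np.full((n, n), np.inf)
            np.fill_diagonal(dist, 0.0)
            for u, v in g.edges:
                dist[u, v] = dist[v, u] = 1.0
            for k in range(n):
                dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
            iu = np.triu_indices(n, 1)
            finite = dist[iu][np.isfinite(dist[iu])]
            if len(finite):
                assert t.avg_path_distance == pytest.approx(
                    float(finite.mean()), abs=1e-12
                )


class TestRandomNull:
    @staticmethod
    def _planted_graph(seed=0):
        return nx.planted_partition_graph(3, 12, 0.85, 0.03, seed=seed)

    def test_degree_sequence_preserved(self):
        g = self._planted_graph()
        net = _net_from_graph(g)
        null = random_null(net, n_random=10, seed=1)
        # the rewiring contract is checked directly on one replicate
        r = g.copy()
        nx.double_edge_swap(r, nswap=10 * g.number_of_edges(),
                            max_tries=200 * g.number_of_edges(), seed=5)
        assert sorted(dict(r.degree).values()) == sorted(
            dict(g.degree).values()
        )
        assert null.n_random == 10

    def test_empirical_modularity_beats_null(self):
        net = _net_from_graph(self._planted_graph())
        null = random_null(net, n_random=30, seed=2)
        m = null.metrics["modularity"]
        assert m["empirical"] > m["mean"] + 2 * m["sd"]

    def test_fixed_seed_bit_reproducible(self):
        net = _net_from_graph(self._planted_graph())
        a = random_null(net, n_random=10, seed=3)
        b = random_null(net, n_random=10, seed=3)
        assert a.metrics == b.metrics
        assert a.values == b.values


class TestModuleMatching:
    @staticmethod
    def _net(mods):
        g = nx.Graph()
        module_of = {}
        for mid, members in mods.items():
            members = list(members)
            g.add_nodes_from(members)
            for a, b in zip(members, members[1:]):
                g.add_edge(a, b, sign=1)
            for x in members:
                module_of[x] = mid
        return CorrelationNetwork(g, 0.9, module_of)

    def test_identical_networks_fully_matched(self):
        universe = [f"n{i}" for i in range(40)]
        net = self._net({0: universe[:10], 1: universe[10:20]})
        mm = match_modules([net, net], universe)
        assert mm.n_matched >= 2
        assert mm.singletons == []

    def test_disjoint_modules_unmatched(self):
        universe = [f"n{i}" for i in range(40)]
        a = self._net({0: universe[:10]})
        b = self._net({0: universe[20:30]})
        mm = match_modules([a, b], universe)
        assert mm.n_matched == 0
        assert len(mm.singletons) == 2

    def test_fisher_p_equals_enumerated_hypergeometric(self):
        """8/10 overlap in a 40-node universe: the one-sided Fisher p equals
        the hypergeometric tail computed from binomial coefficients."""
        universe = [f"n{i}" for i in range(40)]
        a = self._net({0: universe[:10]})
        b = self._net({0: universe[2:12]})
        mm = match_modules([a, b], universe)
        overlap_p = mm.pairs[0]["p"]
        tail = sum(
            math.comb(10, k) * math.comb(30, 10 - k) / math.comb(40, 10)
            for k in range(8, 11)
        )
        assert overlap_p == pytest.approx(tail, rel=1e-12)
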