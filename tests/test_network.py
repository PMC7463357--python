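import itertools
from collections import deque

import numpy as np
import pandas as pd
import pytest

from glocerna.exceptions import ConsistencyError
from glocerna.network import (
    build_network,
    extract_subnetwork,
    intersect_networks,
    lncrna_nodes,
    lncrna_similarity,
    network_from_edges,
    node_betweenness,
    node_degree,
    pcg_nodes,
)


def results_frame(rows):
    return pd.DataFrame(
        rows, columns=["lncrna_id", "pcg_id", "functional"]
    ).assign(dec_score=9, cor=0.9, p_value=0.001, shared_mirna_count=1)


def bfs_betweenness(net):
    """All-pairs BFS path-counting oracle for unnormalized betweenness."""
    nodes = list(net.nodes)
    dist, sigma = {}, {}
    for s in nodes:
        d = {s: 0}
        sg = {s: 1}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in net.neighbors(u):
                if v not in d:
                    d[v] = d[u] + 1
                    sg[v] = 0
                    q.append(v)
                if d[v] == d[u] + 1:
                    sg[v] += sg[u]
        dist[s], sigma[s] = d, sg
    btw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        n_st = sigma[s][t]
        for v in nodes:
            if v in (s, t) or v not in dist[s] or v not in dist[t]:
                continue
            if dist[s][v] + dist[t][v] == d_st:
                btw[v] += sigma[s][v] * sigma[t][v] / n_st
    return btw


class TestBuildNetwork:
    def test_only_functional_rows_become_edges(self):
        res = results_frame(
            [
                ("L1", "G1", True),
                ("L1", "G2", True),
                ("L2", "G1", True),
                ("L2", "G3", False),
                ("L3", "G4", False),
            ]
        )
        net = build_network(res)
        assert net.number_of_edges() == 3
        assert lncrna_nodes(net) == {"L1", "L2"}
        assert pcg_nodes(net) == {"G1", "G2"}

    def test_empty_and_duplicate(self):
        assert build_network(results_frame([("L1", "G1", False)])).number_of_edges() == 0
        dup = results_frame([("L1", "G1", True), ("L1", "G1", True)])
        assert build_network(dup).number_of_edges() == 1

    def test_bipartite_by_construction(self, small_cohort):
        import networkx as nx
        from glocerna.core import run_glocerna
        from glocerna.pairing import build_candidate_pairs

        _, matrix, interactions, _ = small_cohort
        net = build_network(
            run_glocerna(matrix, build_candidate_pairs(interactions))
        )
        if net.number_of_nodes():
            assert nx.is_bipartite(net)
            for a, b in net.edges:
                assert {net.nodes[a]["kind"], net.nodes[b]["kind"]} == {"lncRNA", "PCG"}


class TestTopology:
    def test_star_degrees(self):
        net = network_from_edges([("L1", g) for g in ["G1", "G2", "G3", "G4"]])
        deg = node_degree(net)
        assert deg["L1"] == 4 and all(deg[g] == 1 for g in ["G1", "G2", "G3", "G4"])
        assert sum(deg.values()) == 2 * net.number_of_edges()

    def test_path_betweenness(self):
        net = network_from_edges([("L1", "G1"), ("L2", "G1")])
        btw = node_betweenness(net)
        assert btw["G1"] == pytest.approx(1.0)
        assert btw["L1"] == btw["L2"] == 0.0

    def test_star_betweenness_formula(self):
        net = network_from_edges([("L1", g) for g in ["G1", "G2", "G3"]])
        assert node_betweenness(net)["L1"] == pytest.approx(3 * 2 / 2)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bfs_oracle_on_random_graph(self, seed):
        rng = np.random.default_rng(seed)
        edges = set()
        while len(edges) < 20:
            edges.add((f"L{rng.integers(6)}", f"G{rng.integers(6)}"))
        net = network_from_edges(sorted(edges))
        expected = bfs_betweenness(net)
        got = node_betweenness(net)
        for node in net.nodes:
            assert got[node] == pytest.approx(expected[node], abs=1e-10)

    def test_leaf_in_tree_has_zero_betweenness(self):
        net = network_from_edges([("L1", "G1"), ("L2", "G1"), ("L2", "G2")])
        btw = node_betweenness(net)
        for node, deg in node_degree(net).items():
            if deg == 1:
                assert btw[node] == 0.0


class TestSimilarity:
    def test_shared_and_jaccard(self):
        net = network_from_edges(
            [("L1", "G1"), ("L1", "G2"), ("L2", "G2"), ("L2", "G3")]
        )
        sim = lncrna_similarity(net).set_index(["lncrna_a", "lncrna_b"])
        row = sim.loc[("L1", "L2")]
        assert row["shared_pcg_count"] == 1
        assert row["jaccard"] == pytest.approx(1 / 3)

    def test_disjoint_and_identical(self):
        net = network_from_edges(
            [("L1", "G1"), ("L2", "G2"), ("L3", "G1")]
        )
        sim = lncrna_similarity(net).set_index(["lncrna_a", "lncrna_b"])
        assert sim.loc[("L1", "L2"), "jaccard"] == 0.0
        assert sim.loc[("L1", "L3"), "jaccard"] == 1.0


class TestIntersect:
    universes = {"lncrnas": 10, "pcgs": 10, "edges": 20}

    def test_identical_networks(self):
        net = network_from_edges([("L1", "G1"), ("L2", "G2")])
        cons, overlap = intersect_networks(net, net, self.universes)
        assert cons.number_of_edges() == 2
        assert overlap.shared_edges == 2
        assert overlap.p_edges < 0.05

    def test_disjoint_edges(self):
        a = network_from_edges([("L1", "G1")])
        b = network_from_edges([("L2", "G2")])
        cons, overlap = intersect_networks(a, b, self.universes)
        assert cons.number_of_edges() == 0
        assert overlap.shared_edges == 0

    def test_commutative_counts(self):
        a = network_from_edges([("L1", "G1"), ("L2", "G2"), ("L3", "G3")])
        b = network_from_edges([("L1", "G1"), ("L4", "G4")])
        _, ab = intersect_networks(a, b, self.universes)
        _, ba = intersect_networks(b, a, self.universes)
        assert (ab.shared_lncrnas, ab.shared_pcgs, ab.shared_edges) == (
            ba.shared_lncrnas,
            ba.shared_pcgs,
            ba.shared_edges,
        )
        assert ab.p_edges == pytest.approx(ba.p_edges)

    def test_overlap_p_matches_enumeration(self):
        """Hypergeometric overlap p equals exhaustive enumeration on a
        10-item universe."""
        a = network_from_edges([("L1", "G1"), ("L2", "G2"), ("L3", "G3")])
        b = network_from_edges([("L1", "G1"), ("L2", "G2"), ("L4", "G4"), ("L5", "G5")])
        _, overlap = intersect_networks(
            a, b, {"lncrnas": 10, "pcgs": 10, "edges": 10}
        )
        # draw |A|=3 edges from 10 with |B|=4 successes, observe >= 2
        total = hits = 0
        for draw in itertools.combinations(range(10), 3):
            total += 1
            if len(set(draw) & {0, 1, 2, 3}) >= 2:
                hits += 1
        assert overlap.p_edges == pytest.approx(hits / total, rel=1e-12)

    def test_universe_too_small_is_error(self):
        a = network_from_edges([("L1", "G1"), ("L2", "G2")])
        with pytest.raises(ConsistencyError):
            intersect_networks(a, a, {"lncrnas": 1, "pcgs": 10, "edges": 10})


class TestSubnetwork:
    net = network_from_edges([("L1", "G1"), ("L1", "G2"), ("L2", "G2")])

    def test_first_neighbors_of_seed(self):
        sub = extract_subnetwork(self.net, ["L1"])
        assert set(sub.nodes) == {"L1", "G1", "G2"}
        assert {frozenset(e) for e in sub.edges} == {
            frozenset({"L1", "G1"}),
            frozenset({"L1", "G2"}),
        }

    def test_empty_seed_set(self):
        assert extract_subnetwork(self.net, []).number_of_nodes() == 0

    def test_all_seeds_is_identity(self):
        sub = extract_subnetwork(self.net, ["L1", "L2"])
        assert set(sub.edges) == set(self.net.edges)
        assert set(sub.nodes) == set(self.net.nodes)

    def test_non_lncrna_seeds_ignored(self):
        sub = extract_subnetwork(self.net, ["G1", "NOPE"])
        assert sub.number_of_nodes() == 0
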