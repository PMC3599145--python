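import numpy as np
import pytest

from mpick.io import MpickDataError
from mpick.modularity import (
    Partition,
    best_partition_bruteforce,
    iter_set_partitions,
    louvain_maximize,
    modularity_q,
)

from conftest import make_graph, modularity_double_loop, random_connected_graph


def assignments(g):
    """All partitions of g's vertices as assignment dicts."""
    for blocks in iter_set_partitions(list(range(g.n))):
        yield {
            g.vertices[i]: c for c, block in enumerate(blocks) for i in block
        }


class TestModularityQ:
    def test_fast_formula_equals_double_loop(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 11))
            g = random_connected_graph(rng, n)
            for _ in range(5):
                assignment = {v: int(rng.integers(0, 3)) for v in g.vertices}
                assert modularity_q(g, assignment) == pytest.approx(
                    modularity_double_loop(g, assignment), abs=1e-12
                )

    def test_single_cluster_is_zero(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, int(rng.integers(3, 11)))
            q = modularity_q(g, {v: 0 for v in g.vertices})
            assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_edges_split(self):
        g = make_graph(4, [(0, 1, 1.0), (2, 3, 1.0)])
        q = modularity_q(g, {"v0": 0, "v1": 0, "v2": 1, "v3": 1})
        assert q == pytest.approx(0.5)

    def test_single_edge_singletons(self):
        g = make_graph(2, [(0, 1, 1.0)])
        assert modularity_q(g, {"v0": 0, "v1": 1}) == pytest.approx(-0.5)

    def test_all_singletons_closed_form(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, int(rng.integers(3, 9)))
            q = modularity_q(g, {v: i for i, v in enumerate(g.vertices)})
            k = g.degrees
            m = g.total_weight
            assert q == pytest.approx(-float((k**2).sum()) / (2 * m) ** 2, abs=1e-12)
            assert q <= 0

    def test_invariant_under_relabeling(self, rng):
        g = random_connected_graph(rng, 7)
        a = {v: int(i) % 3 for i, v in enumerate(g.vertices)}
        b = {v: 10 - c for v, c in a.items()}
        assert modularity_q(g, a) == modularity_q(g, b)

    def test_q_bounded_by_one_over_all_partitions(self, rng):
        for _ in range(5):
            g = random_connected_graph(rng, int(rng.integers(3, 7)))
            assert max(modularity_q(g, a) for a in assignments(g)) <= 1.0

    def test_edgeless_graph_rejected(self):
        g = make_graph(3, [])
        with pytest.raises(MpickDataError):
            modularity_q(g, {v: 0 for v in g.vertices})

    def test_partial_partition_rejected(self):
        g = make_graph(2, [(0, 1, 1.0)])
        with pytest.raises(MpickDataError):
            modularity_q(g, {"v0": 0})


def two_cliques(n1, n2, bridge=True):
    edges = []
    for i in range(n1):
        for j in range(i + 1, n1):
            edges.append((i, j, 1.0))
    for i in range(n1, n1 + n2):
        for j in range(i + 1, n1 + n2):
            edges.append((i, j, 1.0))
    if bridge:
        edges.append((0, n1, 1.0))
    return make_graph(n1 + n2, edges)


class TestLouvain:
    def test_single_edge_merges(self):
        g = make_graph(2, [(0, 1, 1.0)])
        p = louvain_maximize(g, seed=1)
        assert p.n_clusters == 1
        assert p.q == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_with_bridge(self):
        g = two_cliques(3, 3)
        p = louvain_maximize(g, seed=42)
        clusters = {frozenset(vs) for vs in p.clusters().values()}
        assert clusters == {
            frozenset({"v0", "v1", "v2"}),
            frozenset({"v3", "v4", "v5"}),
        }

    def test_never_worse_than_singletons(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, int(rng.integers(2, 12)))
            p = louvain_maximize(g, seed=0)
            singles = {v: i for i, v in enumerate(g.vertices)}
            assert p.q >= modularity_q(g, singles) - 1e-12

    def test_attains_bruteforce_on_separated_cliques(self):
        for n1, n2 in [(3, 3), (4, 4), (4, 5), (5, 5)]:
            g = two_cliques(n1, n2)
            lv = louvain_maximize(g, seed=7)
            bf = best_partition_bruteforce(g)
            assert lv.q == pytest.approx(bf.q, abs=1e-9)

    def test_never_exceeds_bruteforce_on_random_graphs(self, rng):
        for _ in range(8):
            g = random_connected_graph(rng, int(rng.integers(3, 8)))
            lv = louvain_maximize(g, seed=3)
            bf = best_partition_bruteforce(g)
            assert lv.q <= bf.q + 1e-12

    def test_deterministic_given_seed(self, rng):
        g = random_connected_graph(rng, 15)
        p1 = louvain_maximize(g, seed=5)
        p2 = louvain_maximize(g, seed=5)
        assert p1.assignment == p2.assignment

    def test_local_maximum_no_single_move_improves(self, rng):
        g = random_connected_graph(rng, 10)
        p = louvain_maximize(g, seed=11)
        base = modularity_q(g, p.assignment)
        comms = set(p.assignment.values())
        for v in g.vertices:
            for c in comms:
                trial = dict(p.assignment)
                trial[v] = c
                assert modularity_q(g, trial) <= base + 1e-9

    def test_agrees_with_networkx_modularity_value(self, rng):
        nx = pytest.importorskip("networkx")
        from networkx.algorithms.community import modularity as nx_modularity

        g = random_connected_graph(rng, 12)
        p = louvain_maximize(g, seed=2)
        G = nx.Graph()
        G.add_nodes_from(g.vertices)
        for i, j, w in zip(g.edge_i, g.edge_j, g.weights):
            G.add_edge(g.vertices[int(i)], g.vertices[int(j)], weight=float(w))
        comms = [set(vs) for vs in p.clusters().values()]
        assert p.q == pytest.approx(nx_modularity(G, comms, weight="weight"), abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(MpickDataError):
            louvain_maximize(make_graph(3, []), seed=0)


class TestBruteForce:
    def test_single_edge_optimum_is_merge(self):
        g = make_graph(2, [(0, 1, 1.0)])
        p = best_partition_bruteforce(g)
        assert p.n_clusters == 1 and p.q == pytest.approx(0.0, abs=1e-12)

    def test_four_cycle_enumeration(self):
        g = make_graph(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (0, 3, 1.0)])
        p = best_partition_bruteforce(g)
        # enumerate by definition and cross-check the maximum Q
        best = max(modularity_q(g, a) for a in assignments(g))
        assert p.q == pytest.approx(best, abs=1e-12)

    def test_partition_count_is_bell_number(self):
        assert sum(1 for _ in iter_set_partitions(list(range(4)))) == 15
        assert sum(1 for _ in iter_set_partitions(list(range(6)))) == 203

    def test_disconnected_component_prefers_own_cluster(self, rng):
        # appending an isolated edge: giving it its own cluster never hurts
        for _ in range(5):
            n = int(rng.integers(2, 5))
            g = random_connected_graph(rng, n)
            edges = list(zip(g.edge_i.tolist(), g.edge_j.tolist(), g.weights.tolist()))
            g2 = make_graph(n + 2, edges + [(n, n + 1, 1.0)])
            own = {v: 0 for v in g2.vertices[:n]}
            own[f"v{n}"] = own[f"v{n + 1}"] = 1
            merged = {v: 0 for v in g2.vertices}
            assert modularity_q(g2, own) >= modularity_q(g2, merged) - 1e-12

    def test_size_cap(self):
        g = make_graph(13, [(i, i + 1, 1.0) for i in range(12)])
        with pytest.raises(MpickDataError):
            best_partition_bruteforce(g)
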