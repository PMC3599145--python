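import numpy as np
import pytest
from hypothesis import given, strategies as st

from mpick.distances import SparseDistanceMatrix, all_pairs
from mpick.graph import build_graph, connected_components, induced_subgraph
from mpick.io import MpickDataError

from conftest import random_connected_graph


def dm_abc():
    return SparseDistanceMatrix(labels=["a", "b", "c"], pairs={(0, 1): 0.02, (0, 2): 0.10})


class TestBuildGraph:
    def test_threshold_and_similarity_weights(self):
        g = build_graph(dm_abc(), epsilon=0.04)
        assert g.n_edges == 1
        assert g.total_weight == pytest.approx(0.98)
        assert g.degrees.tolist() == pytest.approx([0.98, 0.98, 0.0])

    def test_larger_epsilon_retains_both(self):
        g = build_graph(dm_abc(), epsilon=0.20)
        assert g.n_edges == 2
        assert g.total_weight == pytest.approx(1.88)

    def test_distance_exactly_epsilon_excluded(self):
        g = build_graph(dm_abc(), epsilon=0.10)
        assert g.n_edges == 1  # the d=0.10 pair is not retained

    def test_binary_mode(self):
        g = build_graph(dm_abc(), epsilon=0.2, weight_mode="binary")
        assert g.weights.tolist() == [1.0, 1.0]

    @pytest.mark.parametrize("eps,mode", [(0.0, "similarity"), (-1, "binary"), (1.5, "similarity")])
    def test_invalid_epsilon_rejected(self, eps, mode):
        with pytest.raises(MpickDataError):
            build_graph(dm_abc(), epsilon=eps, weight_mode=mode)

    def test_handshake_identity(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            g = random_connected_graph(rng, n)
            assert g.degrees.sum() == pytest.approx(2 * g.total_weight, abs=1e-12)

    @given(data=st.data())
    def test_edge_count_nondecreasing_in_epsilon(self, data):
        n = data.draw(st.integers(3, 8))
        ds = data.draw(
            st.lists(st.floats(0.001, 0.999), min_size=n, max_size=n * 2)
        )
        pairs = {}
        idx = 0
        for i in range(n):
            for j in range(i + 1, n):
                if idx < len(ds):
                    pairs[(i, j)] = ds[idx]
                    idx += 1
        dm = SparseDistanceMatrix(labels=[f"v{i}" for i in range(n)], pairs=pairs)
        counts = [build_graph(dm, e).n_edges for e in (0.1, 0.4, 0.7, 1.0)]
        assert counts == sorted(counts)

    def test_cutoff_limited_matrix_equivalent_below_cutoff(self, rng):
        from mpick.io import SequenceRecord

        records = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGT"), 50)))
            for i in range(6)
        ]
        full = all_pairs(records, mode="sequence")
        cut = all_pairs(records, mode="sequence", cutoff=0.5)
        for eps in (0.2, 0.4, 0.5):
            gf = build_graph(full, eps)
            gc = build_graph(cut, eps)
            assert sorted(zip(gf.edge_i, gf.edge_j, gf.weights)) == sorted(
                zip(gc.edge_i, gc.edge_j, gc.weights)
            )


class TestConnectedComponents:
    def test_edgeless_graph_all_singletons(self):
        dm = SparseDistanceMatrix(labels=["a", "b", "c"], pairs={})
        comps = connected_components(build_graph(dm, 0.1))
        assert comps == [["a"], ["b"], ["c"]]

    def test_path_plus_isolated(self):
        dm = SparseDistanceMatrix(
            labels=["a", "b", "c", "d"], pairs={(0, 1): 0.01, (1, 2): 0.01}
        )
        comps = connected_components(build_graph(dm, 0.1))
        assert [sorted(c) for c in comps] == [["a", "b", "c"], ["d"]]

    def test_partition_property_vs_bruteforce_reachability(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 10))
            g = random_connected_graph(rng, n)
            # randomly drop edges to break connectivity
            keep = rng.random(g.n_edges) < 0.5
            g.edge_i, g.edge_j, g.weights = g.edge_i[keep], g.edge_j[keep], g.weights[keep]
            g._adj = None
            comps = connected_components(g)
            flat = [v for c in comps for v in c]
            assert sorted(flat) == sorted(g.vertices)
            # brute-force reachability agreement
            adj = {v: set() for v in g.vertices}
            for i, j in zip(g.edge_i, g.edge_j):
                adj[g.vertices[int(i)]].add(g.vertices[int(j)])
                adj[g.vertices[int(j)]].add(g.vertices[int(i)])

            def reach(v):
                seen, stack = {v}, [v]
                while stack:
                    for u in adj[stack.pop()]:
                        if u not in seen:
                            seen.add(u)
                            stack.append(u)
                return seen

            for comp in comps:
                assert set(comp) == reach(comp[0])


class TestInducedSubgraph:
    def triangle(self):
        dm = SparseDistanceMatrix(
            labels=["a", "b", "c"],
            pairs={(0, 1): 0.01, (0, 2): 0.02, (1, 2): 0.03},
        )
        return build_graph(dm, 0.1)

    def test_pair_subset_keeps_single_edge(self):
        sub = induced_subgraph(self.triangle(), ["a", "b"])
        assert sub.vertices == ["a", "b"]
        assert sub.n_edges == 1
        assert sub.total_weight == pytest.approx(0.99)

    def test_full_subset_identity(self):
        g = self.triangle()
        sub = induced_subgraph(g, g.vertices)
        assert sub.vertices == g.vertices
        assert sub.total_weight == pytest.approx(g.total_weight)

    def test_unknown_vertex_rejected(self):
        with pytest.raises(MpickDataError):
            induced_subgraph(self.triangle(), ["a", "z"])

    def test_monotonicity_of_m_and_degrees(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 10))
            g = random_connected_graph(rng, n)
            size = int(rng.integers(1, n + 1))
            subset = list(rng.choice(g.vertices, size=size, replace=False))
            sub = induced_subgraph(g, subset)
            assert sub.total_weight <= g.total_weight + 1e-12
            kg = dict(zip(g.vertices, g.degrees))
            for v, k in zip(sub.vertices, sub.degrees):
                assert k <= kg[v] + 1e-12
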