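"""ARI, directed modularity, Louvain, motif census and null-model Z-scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibersym import (
    DirectedMultigraph,
    adjusted_rand_index,
    degree_preserving_randomize,
    directed_modularity,
    louvain_partition,
    motif_census,
    motif_zscores,
)

from .conftest import (
    ari_from_contingency,
    best_modularity_exhaustive,
    directed_modularity_by_communities,
    exhaustive_motif_counts,
    random_multigraph,
)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        x = [{"a", "b"}, {"c"}]
        assert adjusted_rand_index(x, x) == 1.0

    def test_reference_zero_case(self):
        x = [{1, 2}, {3, 4}]
        y = [{1, 2, 3}, {4}]
        assert adjusted_rand_index(x, y) == pytest.approx(0.0, abs=1e-12)
        assert ari_from_contingency(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_vs_one_block(self):
        x = [{i} for i in range(5)]
        y = [set(range(5))]
        assert adjusted_rand_index(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_contingency_evaluation(self):
        gen = np.random.default_rng(5)
        for _ in range(20):
            n = int(gen.integers(3, 15))
            lx = gen.integers(0, 3, size=n)
            ly = gen.integers(0, 3, size=n)
            x = [{i for i in range(n) if lx[i] == k} for k in set(lx)]
            y = [{i for i in range(n) if ly[i] == k} for k in set(ly)]
            assert adjusted_rand_index(x, y) == pytest.approx(
                ari_from_contingency(x, y), abs=1e-12
            )

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=12),
           st.lists(st.integers(0, 3), min_size=2, max_size=12))
    def test_symmetric_and_bounded(self, lx, ly):
        n = min(len(lx), len(ly))
        x = {i: lx[i] for i in range(n)}
        y = {i: ly[i] for i in range(n)}
        a, b = adjusted_rand_index(x, y), adjusted_rand_index(y, x)
        assert a == pytest.approx(b, abs=1e-12)
        assert a <= 1.0 + 1e-12

    def test_universe_completion_with_singletons(self):
        # y omits nodes c, d: completed as singletons, making x and y identical
        x = [{"a", "b"}, {"c"}, {"d"}]
        y = [{"a", "b"}]
        assert adjusted_rand_index(x, y) == 1.0
        with pytest.raises(ValueError):
            adjusted_rand_index(x, y, complete_universe=False)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([], [])


class TestDirectedModularity:
    def test_two_cycle_one_community(self):
        g = DirectedMultigraph.from_edges([("A", "B"), ("B", "A")])
        assert directed_modularity(g, {"A": 0, "B": 0}) == pytest.approx(0.0)

    def test_two_cycle_singletons(self):
        g = DirectedMultigraph.from_edges([("A", "B"), ("B", "A")])
        assert directed_modularity(g, {"A": 0, "B": 1}) == pytest.approx(-0.5)

    def test_two_disjoint_two_cycles(self):
        g = DirectedMultigraph.from_edges(
            [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C")]
        )
        labels = {"A": 0, "B": 0, "C": 1, "D": 1}
        assert directed_modularity(g, labels) == pytest.approx(0.5)

    def test_node_level_equals_community_level_evaluation(self, rng):
        for _ in range(10):
            g = random_multigraph(rng, int(rng.integers(3, 9)), edge_prob=0.4)
            if g.total_multiplicity() == 0:
                continue
            labels = {n: int(rng.integers(0, 3)) for n in g.nodes}
            assert directed_modularity(g, labels) == pytest.approx(
                directed_modularity_by_communities(g, labels), abs=1e-12
            )

    def test_edgeless_graph_rejected(self):
        g = DirectedMultigraph.from_edges([], nodes=["A"])
        with pytest.raises(ValueError):
            directed_modularity(g, {"A": 0})


class TestLouvain:
    @staticmethod
    def two_cliques():
        edges = []
        for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
            for u in block:
                for v in block:
                    if u != v:
                        edges.append((u, v))
        edges.append(("a1", "b1"))
        return DirectedMultigraph.from_edges(edges)

    def test_recovers_two_cliques(self):
        mp = louvain_partition(self.two_cliques(), seed=3)
        groups = {frozenset(g) for g in mp.groups()}
        assert groups == {
            frozenset({"a1", "a2", "a3", "a4"}),
            frozenset({"b1", "b2", "b3", "b4"}),
        }

    def test_single_two_cycle_one_community(self):
        g = DirectedMultigraph.from_edges([("A", "B"), ("B", "A")])
        mp = louvain_partition(g, seed=0)
        assert len(mp.groups()) == 1 and mp.q == pytest.approx(0.0)

    def test_seed_determinism(self):
        g = self.two_cliques()
        assert louvain_partition(g, seed=5) == louvain_partition(g, seed=5)

    def test_near_optimal_vs_exhaustive_search(self):
        gen = np.random.default_rng(17)
        for _ in range(5):
            g = random_multigraph(gen, 7, edge_prob=0.35, self_loops=False)
            if g.total_multiplicity() < 2:
                continue
            mp = louvain_partition(g, seed=1)
            optimum = best_modularity_exhaustive(g)
            assert mp.q >= 0.95 * optimum - 1e-9

    def test_edgeless_rejected(self):
        g = DirectedMultigraph.from_edges([], nodes=["A", "B"])
        with pytest.raises(ValueError):
            louvain_partition(g)


class TestMotifCensus:
    def test_single_ffl(self):
        g = DirectedMultigraph.from_edges([("A", "B"), ("A", "C"), ("B", "C")])
        assert motif_census(g) == {
            "feed_forward_loop": 1, "bifan": 0, "biparallel": 0, "cycle4": 0
        }

    def test_single_bifan(self):
        g = DirectedMultigraph.from_edges(
            [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]
        )
        assert motif_census(g)["bifan"] == 1

    def test_single_biparallel_and_cycle4(self):
        bp = DirectedMultigraph.from_edges(
            [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
        )
        assert motif_census(bp)["biparallel"] == 1
        c4 = DirectedMultigraph.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
        )
        assert motif_census(c4)["cycle4"] == 1

    @pytest.mark.parametrize("induced", [False, True])
    def test_matches_exhaustive_enumeration(self, induced):
        gen = np.random.default_rng(29)
        for _ in range(15):
            n = int(gen.integers(3, 10))
            g = random_multigraph(gen, n, edge_prob=0.3)
            assert motif_census(g, induced=induced) == exhaustive_motif_counts(
                g, induced=induced
            )

    def test_self_loops_ignored(self):
        g = DirectedMultigraph.from_edges(
            [("A", "A"), ("A", "B"), ("A", "C"), ("B", "C")]
        )
        assert motif_census(g)["feed_forward_loop"] == 1


class TestRandomization:
    def test_degree_sequences_preserved(self, rng):
        for _ in range(5):
            g = random_multigraph(rng, 10, edge_prob=0.3, self_loops=False)
            if g.number_of_edge_records() < 2:
                continue
            r = degree_preserving_randomize(g, n_swaps=200, seed=3)
            for n in g.nodes:
                assert len(g.predecessors(n)) == len(r.predecessors(n))
                assert len(g.successors(n)) == len(r.successors(n))
            assert r.total_multiplicity() == len(
                {(u, v) for u, v, _t, _m in g.edges()}
            )

    def test_zero_swaps_identity_on_simple_view(self):
        g = DirectedMultigraph.from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        assert degree_preserving_randomize(g, 0, seed=1) == g

    def test_seed_determinism(self):
        g = DirectedMultigraph.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C"), ("B", "D")]
        )
        r1 = degree_preserving_randomize(g, 100, seed=7)
        r2 = degree_preserving_randomize(g, 100, seed=7)
        assert r1 == r2

    def test_self_loops_preserved(self):
        g = DirectedMultigraph.from_edges(
            [("A", "A"), ("A", "B"), ("B", "C"), ("C", "A"), ("B", "D"), ("D", "B")]
        )
        r = degree_preserving_randomize(g, 50, seed=2)
        assert r.has_self_loop("A")


class TestMotifZscores:
    @staticmethod
    def planted_ffl_graph(n_ffl=20):
        edges = []
        for i in range(n_ffl):
            a, b, c = f"a{i}", f"b{i}", f"c{i}"
            edges += [(a, b), (a, c), (b, c)]
        # sprinkle connections so randomization can mix the structure
        for i in range(n_ffl - 1):
            edges.append((f"c{i}", f"a{i + 1}"))
        return DirectedMultigraph.from_edges(edges)

    def test_planted_ffls_significant(self):
        g = self.planted_ffl_graph()
        census = motif_zscores(g, n_random=200, seed=11)
        assert census.observed["feed_forward_loop"] == 20
        assert census.zscores["feed_forward_loop"] > 2
        assert census.significant["feed_forward_loop"]

    def test_sigma_zero_conventions(self):
        # frozen randomization (zero swaps): every null draw equals the
        # observed graph, sigma = 0, and Z is 0 (not inf) since N == <N>
        g = DirectedMultigraph.from_edges([("A", "B"), ("A", "C"), ("B", "C")])
        census = motif_zscores(g, n_random=3, n_swaps=0, seed=0)
        assert all(z == 0.0 for z in census.zscores.values())
        assert not any(census.significant.values())
        assert math.isfinite(census.null_sd["feed_forward_loop"])

    def test_n_random_validation(self):
        g = DirectedMultigraph.from_edges([("A", "B"), ("B", "C")])
        with pytest.raises(ValueError):
            motif_zscores(g, n_random=1)
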