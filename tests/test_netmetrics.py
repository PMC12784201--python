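"""Structure measures vs hand values and brute-force references."""

import networkx as nx
import numpy as np
import pytest

from tests import oracles
from traitnet.netmetrics import (
    clustering,
    degree_assortativity,
    degree_variation,
    mean_distance,
    trait_assortativity,
    trait_degree_correlation,
)


class TestHandValues:
    def test_degree_variation_regular_graph_is_zero(self, ring5):
        assert degree_variation(ring5) == 0.0

    def test_degree_variation_star(self, star10):
        # degrees {9, 1 x 9}: mean 1.8, sample sd sqrt(6.4)
        assert degree_variation(star10) == pytest.approx(np.sqrt(6.4) / 1.8)

    def test_star_assortativity_is_minus_one(self):
        assert degree_assortativity(nx.star_graph(3)) == pytest.approx(-1.0)

    def test_complete_graph_assortativity_undefined(self, complete10):
        assert np.isnan(degree_assortativity(complete10))

    def test_complete_graph_clustering_is_one(self, complete10):
        assert clustering(complete10) == pytest.approx(1.0)

    @pytest.mark.parametrize("tree", [nx.star_graph(5), nx.path_graph(6)])
    def test_tree_clustering_is_zero(self, tree):
        assert clustering(tree) == 0.0

    def test_triangle_with_pendant(self):
        # local coefficients {1/3, 1, 1, 0} -> mean 7/12
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (0, 3)])
        assert clustering(g) == pytest.approx(7 / 12)

    def test_mean_distance_complete(self, complete10):
        assert mean_distance(complete10) == pytest.approx(1.0)

    def test_mean_distance_path4(self, path4):
        assert mean_distance(path4) == pytest.approx(10 / 6)

    def test_mean_distance_ring5(self, ring5):
        assert mean_distance(ring5) == pytest.approx(1.5)

    def test_mean_distance_requires_connected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            mean_distance(g)

    def test_trait_identical_to_degree_gives_one(self, star10):
        deg = [d for _, d in star10.degree()]
        assert trait_degree_correlation(star10, deg) == pytest.approx(1.0)

    def test_two_block_categorical_graph_fully_assorted(self):
        g = nx.union(nx.complete_graph(4), nx.complete_graph(range(4, 8)))
        g.add_edge(0, 4)  # one bridge keeps it connected
        cats = [0] * 4 + [1] * 4
        assert trait_assortativity(g, cats, kind="categorical") > 0.8
        g2 = nx.union(nx.complete_graph(3), nx.complete_graph(range(3, 6)))
        assert trait_assortativity(g2, [0, 0, 0, 1, 1, 1],
                                   kind="categorical") == pytest.approx(1.0)

    def test_single_category_undefined(self, ring5):
        assert np.isnan(trait_assortativity(ring5, [1] * 5, kind="categorical"))

    def test_constant_trait_correlation_undefined(self, star10):
        assert np.isnan(trait_degree_correlation(star10, [1.0] * 10))


class TestPermutationNull:
    def test_independent_trait_correlation_centred_on_zero(self, rng):
        g = oracles.random_connected_graph(40, 0.15, rng)
        vals = rng.normal(size=40)
        stats = [
            trait_degree_correlation(g, rng.permutation(vals)) for _ in range(1000)
        ]
        assert abs(np.mean(stats)) < 4 * np.std(stats, ddof=1) / np.sqrt(1000)

    def test_independent_trait_assortativity_centred_on_zero(self, rng):
        g = oracles.random_connected_graph(40, 0.15, rng)
        vals = rng.normal(size=40)
        stats = [
            trait_assortativity(g, rng.permutation(vals), kind="numeric")
            for _ in range(1000)
        ]
        # endpoint Pearson carries a small O(1/n) negative bias (shared
        # nodes across edges), so test for near-zero, not exactly zero
        assert abs(np.mean(stats)) < 0.05


@pytest.fixture(scope="module")
def graphs():
    rng = np.random.default_rng(424242)
    out = []
    for _ in range(50):
        n = int(rng.integers(4, 13))
        g = oracles.random_connected_graph(n, 0.45, rng)
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.uniform(0.2, 2.0))
        out.append(g)
    return out


class TestBruteForceEquivalence:
    """Each measure matches an independent naive implementation on 50
    random connected graphs with n <= 12."""

    def test_degree_variation(self, graphs):
        for g in graphs:
            assert degree_variation(g) == pytest.approx(
                oracles.cv_degrees(g), abs=1e-10
            )

    def test_degree_assortativity(self, graphs):
        for g in graphs:
            ref = oracles.endpoint_pearson_assortativity(g)
            got = degree_assortativity(g)
            if np.isnan(ref):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(ref, abs=1e-10)

    def test_clustering(self, graphs):
        for g in graphs:
            assert clustering(g) == pytest.approx(
                oracles.triangle_clustering(g), abs=1e-10
            )

    def test_mean_distance(self, graphs):
        for g in graphs:
            assert mean_distance(g) == pytest.approx(
                oracles.floyd_warshall_mean_distance(g), abs=1e-10
            )
            assert mean_distance(g, weight="weight") == pytest.approx(
                oracles.floyd_warshall_mean_distance(g, weight="weight"), abs=1e-10
            )

    def test_categorical_assortativity_newman_formula(self, graphs):
        rng = np.random.default_rng(7)
        for g in graphs:
            cats = rng.integers(0, 3, size=g.number_of_nodes())
            ref = oracles.newman_categorical_assortativity(g, cats)
            got = trait_assortativity(g, cats, kind="categorical")
            if np.isnan(ref):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(ref, abs=1e-10)

    def test_numeric_assortativity_endpoint_pearson(self, graphs):
        rng = np.random.default_rng(8)
        for g in graphs:
            vals = rng.normal(size=g.number_of_nodes())
            assert trait_assortativity(g, vals, kind="numeric") == pytest.approx(
                oracles.endpoint_trait_pearson(g, vals), abs=1e-10
            )


class TestInvariances:
    def test_relabeling_invariance(self, rng):
        g = oracles.random_connected_graph(10, 0.4, rng)
        perm = rng.permutation(10)
        h = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(10)})
        h = nx.convert_node_labels_to_integers(
            h, ordering="sorted"
        )
        for fn in (degree_variation, clustering, mean_distance):
            assert fn(g) == pytest.approx(fn(h), abs=1e-10)

    def test_weighted_equals_unweighted_at_unit_weights(self, rng):
        g = oracles.random_connected_graph(12, 0.4, rng)
        for _, _, d in g.edges(data=True):
            d["weight"] = 1.0
        for fn in (degree_variation, degree_assortativity, clustering, mean_distance):
            unw, w = fn(g), fn(g, weight="weight")
            if np.isnan(unw):
                assert np.isnan(w)
            else:
                assert unw == pytest.approx(w, abs=1e-10)

    def test_circular_assortativity_detects_ring_structure(self, rng):
        # a ring of individuals ordered by circular trait is maximally
        # assorted; a random trait on the same ring is not
        n = 30
        g = nx.cycle_graph(n)
        ordered = np.arange(n) / n
        shuffled = rng.permutation(ordered)
        high = trait_assortativity(g, ordered, kind="circular")
        low = trait_assortativity(g, shuffled, kind="circular")
        assert high > 1.0  # edges far closer on the circle than random pairs
        assert abs(low) < high / 3
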