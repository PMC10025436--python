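"""Distance/similarity measures: worked examples, oracles and invariants."""

import numpy as np
import pytest
from scipy.linalg import expm

import netanova as na
from netanova.measures import MEASURES, MeasureSpec, pairwise_distances

from conftest import graph_from_adj, random_binary_graph


def _permuted(g, rng):
    """Same graph under a random node relabelling."""
    perm = rng.permutation(g.n_nodes)
    return graph_from_adj(g.adjacency[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# edge difference / hamming / gaussian
# ---------------------------------------------------------------------------

def test_edge_difference_single_edge_flip():
    g1 = graph_from_adj(np.zeros((3, 3)))
    g2 = graph_from_adj([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
    assert na.edge_difference_distance(g1, g2) == pytest.approx(np.sqrt(2))


def test_edge_difference_weighted_half_edge():
    g1 = graph_from_adj(np.zeros((2, 2)), weighted=True)
    g2 = graph_from_adj([[0, 0.5], [0.5, 0]], weighted=True)
    assert na.edge_difference_distance(g1, g2) == pytest.approx(
        np.sqrt(2 * 0.25)
    )


def test_edge_difference_node_mismatch_raises(triangle):
    other = na.LabeledGraph(["a", "b", "c"], triangle.adjacency)
    with pytest.raises(na.NodeCorrespondenceError):
        na.edge_difference_distance(triangle, other)


def test_hamming_one_edge_of_four_nodes():
    g1 = graph_from_adj(np.zeros((4, 4)))
    a = np.zeros((4, 4))
    a[0, 1] = a[1, 0] = 1
    g2 = graph_from_adj(a)
    assert na.hamming_distance(g1, g2) == pytest.approx(2 / 12)


def test_hamming_empty_vs_complete_is_one():
    n = 5
    empty = graph_from_adj(np.zeros((n, n)))
    full = graph_from_adj(np.ones((n, n)) - np.eye(n))
    assert na.hamming_distance(empty, full) == 1.0


def test_hamming_rejects_weighted():
    g = graph_from_adj([[0, 0.5], [0.5, 0]], weighted=True)
    with pytest.raises(na.UnsupportedMeasureError):
        na.hamming_distance(g, g)


def test_gaussian_known_value(triangle, path3):
    # adjacencies differ in one undirected edge -> squared norm 2
    assert na.gaussian_kernel(triangle, path3, sigma=1.0) == pytest.approx(
        np.exp(-1.0)
    )
    assert na.gaussian_kernel(triangle, triangle, sigma=1.0) == 1.0
    with pytest.raises(ValueError):
        na.gaussian_kernel(triangle, path3, sigma=0.0)


# ---------------------------------------------------------------------------
# shortest-path kernel
# ---------------------------------------------------------------------------

def test_sp_kernel_unlabeled_matches_enumeration(path3, rng):
    # oracle: enumerate ordered node pairs and count equal-length pairs
    def oracle(g1, g2):
        import networkx as nx
        def lengths(g):
            sp = dict(nx.all_pairs_shortest_path_length(g.to_networkx()))
            return [
                sp[u][v]
                for u in g.node_ids for v in g.node_ids
                if u != v and v in sp[u]
            ]
        l1, l2 = lengths(g1), lengths(g2)
        return sum(1 for a in l1 for b in l2 if a == b)

    assert na.shortest_path_kernel(
        path3, path3, ignore_node_ids=True
    ) == oracle(path3, path3)
    g1 = random_binary_graph(rng, n=6)
    g2 = random_binary_graph(rng, n=6)
    assert na.shortest_path_kernel(g1, g2, ignore_node_ids=True) == oracle(g1, g2)


def test_sp_kernel_unlabeled_invariant_under_relabelling(rng):
    g1 = random_binary_graph(rng, n=7)
    g2 = random_binary_graph(rng, n=7)
    k = na.shortest_path_kernel(g1, g2, ignore_node_ids=True)
    assert na.shortest_path_kernel(
        _permuted(g1, rng), g2, ignore_node_ids=True
    ) == pytest.approx(k)


def test_sp_kernel_node_identified_counts_agreeing_pairs(triangle, path3):
    # triangle: all 6 ordered pairs at length 1; path3: lengths 1,1,1,1,2,2
    # agreement on the 4 pairs adjacent in the path
    assert na.shortest_path_kernel(triangle, path3) == 4
    assert na.shortest_path_kernel(path3, path3) == 6


def test_sp_kernel_empty_graph_warns():
    g = graph_from_adj(np.zeros((3, 3)))
    with pytest.warns(UserWarning):
        assert na.shortest_path_kernel(g, g, ignore_node_ids=True) == 0.0


# ---------------------------------------------------------------------------
# random-walk kernel
# ---------------------------------------------------------------------------

def test_rw_kernel_kronecker_oracle(rng):
    # brute force on the explicit direct-product adjacency
    g1 = random_binary_graph(rng, n=5)
    g2 = random_binary_graph(rng, n=4)
    k, coeffs = 3, np.array([1.0, 0.5, 0.25, 0.125])
    w = np.kron(g1.adjacency, g2.adjacency)
    acc, wp = 0.0, np.eye(w.shape[0])
    for i in range(k + 1):
        acc += coeffs[i] * wp.sum()
        wp = wp @ w
    assert na.random_walk_kernel(
        g1, g2, k=k, coeffs=coeffs, ignore_node_ids=True
    ) == pytest.approx(acc)


def test_rw_kernel_two_single_edges_by_hand():
    # K2 x K2 product graph: 4 node pairs, I contributes 4, W contributes 4
    k2 = graph_from_adj([[0, 1], [1, 0]])
    assert na.random_walk_kernel(
        k2, k2, k=1, coeffs=[1, 1], ignore_node_ids=True
    ) == pytest.approx(8.0)


def test_rw_kernel_knc_no_shared_edges(triangle):
    empty = graph_from_adj(np.zeros((3, 3)))
    # steps >= 1 contribute nothing when no edge is shared
    assert na.random_walk_kernel(
        triangle, empty, k=2, coeffs=[0, 1, 1], knc=True
    ) == 0.0


def test_rw_kernel_parameter_validation(triangle):
    with pytest.raises(ValueError):
        na.random_walk_kernel(triangle, triangle, k=-1)
    with pytest.raises(ValueError):
        na.random_walk_kernel(triangle, triangle, k=2, coeffs=[1, 1])


def test_rw_kernel_normalized_self_similarity_dominates(rng):
    graphs = [random_binary_graph(rng, n=6, name=str(i)) for i in range(5)]
    k = pairwise_distances(
        graphs, MeasureSpec("random_walk_kernel", {"normalize": True})
    )
    # normalised kernel: d = 2 - 2*Ktilde >= 0 everywhere
    assert np.all(k.values >= -1e-12)


# ---------------------------------------------------------------------------
# deltacon / diffusion / gtom
# ---------------------------------------------------------------------------

def test_deltacon_oracle_triangle_vs_path(triangle, path3):
    eps = 0.1
    def affinity(g):
        a = g.adjacency
        d = np.diag(a.sum(axis=1))
        return np.linalg.inv(np.eye(3) + eps**2 * d - eps * a)
    expected = np.sqrt(
        ((np.sqrt(affinity(triangle)) - np.sqrt(affinity(path3))) ** 2).sum()
    )
    assert na.deltacon_distance(triangle, path3, eps=eps) == pytest.approx(expected)
    assert na.deltacon_distance(triangle, triangle) == 0.0


def test_diffusion_matches_expm_brute_force(triangle, path3):
    grid = np.geomspace(0.1, 5.0, 12)
    def lap(g):
        a = g.adjacency
        return np.diag(a.sum(axis=1)) - a
    fine = np.geomspace(0.1, 5.0, 600)
    oracle = max(
        np.linalg.norm(expm(-t * lap(triangle)) - expm(-t * lap(path3)), "fro")
        for t in fine
    )
    got = na.diffusion_distance(triangle, path3, t_grid=grid)
    assert got == pytest.approx(oracle, rel=1e-2)
    # identical Laplacians: zero up to eigendecomposition cancellation noise
    assert na.diffusion_distance(triangle, triangle) == pytest.approx(0.0, abs=1e-6)


def test_gtom_identical_and_isolated():
    empty = graph_from_adj(np.zeros((4, 4)))
    assert na.gtom_distance(empty, empty) == 0.0  # both overlap mats = identity


def test_gtom_hand_computed_overlap():
    # star (hub 0) vs path 0-1-2-3, m=1
    star = graph_from_adj(
        [[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]
    )
    path = graph_from_adj(
        [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]]
    )

    def overlap(g):
        a = g.adjacency
        n = 4
        t = np.eye(n)
        deg = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(
                    1 for k in range(n) if a[i, k] and a[j, k]
                )
                t[i, j] = (shared + a[i, j]) / (min(deg[i], deg[j]) + 1 - a[i, j])
        return t

    expected = np.linalg.norm(overlap(star) - overlap(path), "fro")
    assert na.gtom_distance(star, path, m=1) == pytest.approx(expected)


def test_gtom_rejects_weighted():
    g = graph_from_adj([[0, 0.3], [0.3, 0]], weighted=True)
    with pytest.raises(na.UnsupportedMeasureError):
        na.gtom_distance(g, g)


# ---------------------------------------------------------------------------
# kernel -> distance
# ---------------------------------------------------------------------------

def test_kernel_to_distance_examples():
    d = na.kernel_to_distance(np.eye(3))
    assert np.all(np.diag(d.values) == 0)
    off = d.values[np.triu_indices(3, k=1)]
    assert np.all(off == 2.0)
    d2 = na.kernel_to_distance(np.array([[4.0, 1.0], [1.0, 9.0]]))
    assert d2.values[0, 1] == pytest.approx(11.0)


def test_kernel_to_distance_is_squared_feature_distance(rng):
    # explicit feature vectors: K = X X' must give squared Euclidean distances
    x = rng.normal(size=(6, 4))
    d = na.kernel_to_distance(x @ x.T).values
    from scipy.spatial.distance import pdist, squareform
    expected = squareform(pdist(x, "sqeuclidean"))
    assert np.allclose(d, expected, atol=1e-10)


def test_kernel_to_distance_rejects_asymmetric():
    with pytest.raises(ValueError):
        na.kernel_to_distance(np.array([[1.0, 2.0], [0.0, 1.0]]))


# ---------------------------------------------------------------------------
# pairwise driver: contracts and naive-loop oracle
# ---------------------------------------------------------------------------

_SINGLE = {
    "edge_difference": lambda a, b: na.edge_difference_distance(a, b),
    "hamming": lambda a, b: na.hamming_distance(a, b),
    "deltacon": None,  # shared-eps semantics checked separately
    "gtom": lambda a, b: na.gtom_distance(a, b, m=1),
    "diffusion": lambda a, b: na.diffusion_distance(a, b),
}


@pytest.mark.parametrize("measure", sorted(MEASURES))
def test_pairwise_identity_symmetry_nonnegative(measure, rng):
    graphs = [random_binary_graph(rng, n=7, name=str(i)) for i in range(5)]
    graphs.append(graphs[0].copy())  # duplicate -> zero distance somewhere
    d = pairwise_distances(graphs, measure)
    v = d.values
    assert np.allclose(v, v.T)
    assert np.all(np.diag(v) == 0)
    assert np.all(v >= 0)
    assert v[0, 5] == pytest.approx(0.0, abs=1e-6)  # duplicate graph


@pytest.mark.parametrize("measure", ["edge_difference", "hamming", "gtom", "diffusion"])
def test_pairwise_matches_naive_loop(measure, rng):
    graphs = [random_binary_graph(rng, n=6, name=str(i)) for i in range(5)]
    d = pairwise_distances(graphs, measure)
    fn = _SINGLE[measure]
    for i in range(5):
        for j in range(i + 1, 5):
            assert d.values[i, j] == pytest.approx(
                fn(graphs[i], graphs[j]), rel=1e-9, abs=1e-9
            )


def test_pairwise_deltacon_uses_one_global_eps(rng):
    graphs = [random_binary_graph(rng, n=6, name=str(i)) for i in range(4)]
    from netanova.measures import default_deltacon_eps
    eps = default_deltacon_eps(*graphs)
    d = pairwise_distances(graphs, "deltacon")
    for i in range(4):
        for j in range(i + 1, 4):
            assert d.values[i, j] == pytest.approx(
                na.deltacon_distance(graphs[i], graphs[j], eps=eps), rel=1e-9
            )


def test_pairwise_knc_rejects_heterogeneous_node_sets(rng):
    g1 = random_binary_graph(rng, n=5, name="a")
    g2 = na.LabeledGraph(["x0", "x1", "x2", "x3", "x4"], g1.adjacency, name="b")
    with pytest.raises(na.NodeCorrespondenceError, match="b"):
        pairwise_distances([g1, g2], "edge_difference")


def test_unlabeled_kernels_invariant_under_relabelling(rng):
    g1 = random_binary_graph(rng, n=7)
    g2 = random_binary_graph(rng, n=7)
    g1p = _permuted(g1, rng)
    assert na.random_walk_kernel(
        g1p, g2, ignore_node_ids=True
    ) == pytest.approx(na.random_walk_kernel(g1, g2, ignore_node_ids=True))
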