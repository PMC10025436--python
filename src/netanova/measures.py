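"""Between-graph distance and similarity measures.

Nine measures are provided.  Five require a known node correspondence (KNC):
edge difference, the node-identified random-walk kernel, DeltaCon, GTOM and
the Gaussian kernel on vectorised adjacencies.  Four act on topology alone
(UNC): Hamming, shortest-path kernel, k-step random-walk kernel and the graph
diffusion distance.  Kernels are turned into squared-norm distances through

    d(G1, G2) = K(G1, G1) + K(G2, G2) - 2 K(G1, G2),

which is the squared feature-space distance and guarantees d(G, G) = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from .graphs import LabeledGraph, NodeCorrespondenceError, require_same_nodes

__all__ = [
    "MeasureSpec",
    "DistanceMatrix",
    "UnsupportedMeasureError",
    "edge_difference_distance",
    "hamming_distance",
    "shortest_path_kernel",
    "random_walk_kernel",
    "deltacon_distance",
    "diffusion_distance",
    "gaussian_kernel",
    "gtom_distance",
    "kernel_to_distance",
    "pairwise_distances",
    "MEASURES",
    "KNC_MEASURES",
]

#: measures requiring a shared, identically ordered node set
KNC_MEASURES = frozenset(
    {"edge_difference", "random_walk_kernel_knc", "deltacon", "gtom", "gaussian"}
)
MEASURES = (
    "edge_difference",
    "hamming",
    "shortest_path_kernel",
    "random_walk_kernel",
    "random_walk_kernel_knc",
    "deltacon",
    "diffusion",
    "gaussian",
    "gtom",
)


class UnsupportedMeasureError(ValueError):
    """Measure cannot be applied to this kind of graph (e.g. weighted input)."""


@dataclass
class MeasureSpec:
    """A named measure plus its parameters.

    Parameters of interest: ``k`` and ``coeffs`` (random walk), ``sigma``
    (Gaussian; ``None`` means the median heuristic over the input set),
    ``m`` (GTOM overlap order), ``eps`` (DeltaCon affinity scale; ``None``
    means 1/(1+max degree)), ``t_grid`` (diffusion search grid) and
    ``normalize`` (cosine-normalise kernels before conversion).
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MEASURES:
            raise ValueError(f"unknown measure {self.name!r}; choose from {MEASURES}")

    @property
    def knc(self) -> bool:
        return self.name in KNC_MEASURES


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix of between-graph distances."""

    labels: list[str]
    values: np.ndarray
    measure_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix side must equal number of labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


# ---------------------------------------------------------------------------
# individual measures
# ---------------------------------------------------------------------------

def edge_difference_distance(g1: LabeledGraph, g2: LabeledGraph) -> float:
    """Frobenius norm of the adjacency difference ||A1 - A2||_F (KNC)."""
    require_same_nodes(g1, g2)
    return float(np.linalg.norm(g1.adjacency - g2.adjacency, "fro"))


def hamming_distance(g1: LabeledGraph, g2: LabeledGraph) -> float:
    """Fraction of differing off-diagonal adjacency entries, in [0, 1].

    Defined for binary graphs of equal size only.
    """
    if g1.weighted or g2.weighted:
        raise UnsupportedMeasureError("Hamming distance is undefined for weighted graphs")
    if g1.n_nodes != g2.n_nodes:
        raise NodeCorrespondenceError("Hamming distance requires equal node counts")
    n = g1.n_nodes
    return float(np.abs(g1.adjacency - g2.adjacency).sum() / (n * (n - 1)))


def _path_length_histogram(g: LabeledGraph, use_weights: bool) -> dict:
    """Multiset of finite shortest-path lengths over ordered node pairs i != j."""
    a = g.adjacency if use_weights else (g.adjacency != 0).astype(float)
    sp = shortest_path(csr_matrix(a), directed=g.directed, unweighted=not use_weights)
    mask = np.isfinite(sp) & ~np.eye(g.n_nodes, dtype=bool)
    lengths = sp[mask]
    vals, counts = np.unique(lengths, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def _sp_matrix(g: LabeledGraph, use_weights: bool) -> np.ndarray:
    a = g.adjacency if use_weights else (g.adjacency != 0).astype(float)
    return shortest_path(csr_matrix(a), directed=g.directed, unweighted=not use_weights)


def shortest_path_kernel(
    g1: LabeledGraph,
    g2: LabeledGraph,
    use_weights: bool = False,
    ignore_node_ids: bool = False,
) -> float:
    """Shortest-path kernel with a Dirac base kernel.

    The base kernel compares path endpoints and path length.  When the two
    graphs share one ordered node set, endpoints are identified by node id,
    so the kernel counts node pairs (i, j) whose shortest-path length agrees
    in both graphs (both finite).  Without a node correspondence — or with
    ``ignore_node_ids`` — endpoints are unlabelled and the kernel counts
    equal-length pairs of paths, one from each graph (histogram product).
    Unreachable pairs contribute nothing; edge weights are ignored unless
    ``use_weights`` is set (then lengths are weighted and compared exactly).
    """
    if not ignore_node_ids and g1.node_ids == g2.node_ids:
        s1 = _sp_matrix(g1, use_weights)
        s2 = _sp_matrix(g2, use_weights)
        both = np.isfinite(s1) & np.isfinite(s2) & ~np.eye(g1.n_nodes, dtype=bool)
        if not both.any():
            warnings.warn(
                "shortest-path kernel of an edgeless graph is 0", stacklevel=2
            )
        return float(np.count_nonzero(both & (s1 == s2)))
    h1 = _path_length_histogram(g1, use_weights)
    h2 = _path_length_histogram(g2, use_weights)
    if not h1 or not h2:
        warnings.warn("shortest-path kernel of an edgeless graph is 0", stacklevel=2)
        return 0.0
    return float(sum(c * h2.get(length, 0) for length, c in h1.items()))


def _entry_sums_of_powers(a: np.ndarray, k: int) -> np.ndarray:
    """s_i = 1^T A^i 1 for i = 0..k, via repeated matrix-vector products."""
    n = a.shape[0]
    v = np.ones(n)
    out = np.empty(k + 1)
    out[0] = n
    for i in range(1, k + 1):
        v = a @ v
        out[i] = v.sum()
    return out


def random_walk_kernel(
    g1: LabeledGraph,
    g2: LabeledGraph,
    k: int = 3,
    coeffs=None,
    knc: bool = False,
    ignore_node_ids: bool = False,
) -> float:
    """k-step random-walk kernel, counting common walks up to length k.

    The kernel is the sum over entries of sum_i coeffs_i W^i where W is the
    direct-product-graph adjacency.  The direct product respects node
    identity: when the two graphs share one ordered node set, only
    identically labelled nodes pair up, so W is the elementwise topology
    product and the kernel counts walks along edges present in both graphs
    through the same nodes.  Without a correspondence — or with
    ``ignore_node_ids`` — every node pairs with every node, W = A1 (x) A2,
    computed via 1'(A1 (x) A2)^i 1 = (1'A1^i 1)(1'A2^i 1).

    ``knc=True`` selects the customised known-node-correspondence variant:
    the same node-identified series but on the weight product A1 * A2, so
    edge weights (not just shared topology) enter the walk counts; it
    requires identical node sets and coincides with the default on binary
    graphs.
    """
    if k < 0:
        raise ValueError("step count k must be >= 0")
    if coeffs is None:
        coeffs = np.ones(k + 1)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (k + 1,):
        raise ValueError(f"need exactly k+1 = {k + 1} step coefficients")
    if knc:
        require_same_nodes(g1, g2)
        prod = g1.adjacency * g2.adjacency
        return float(coeffs @ _entry_sums_of_powers(prod, k))
    if not ignore_node_ids and g1.node_ids == g2.node_ids:
        prod = ((g1.adjacency != 0) & (g2.adjacency != 0)).astype(float)
        return float(coeffs @ _entry_sums_of_powers(prod, k))
    s1 = _entry_sums_of_powers(g1.adjacency, k)
    s2 = _entry_sums_of_powers(g2.adjacency, k)
    return float(coeffs @ (s1 * s2))


def _deltacon_affinity(g: LabeledGraph, eps: float) -> np.ndarray:
    """S = [I + eps^2 D - eps A]^{-1}; D uses weighted degrees for weighted graphs."""
    a = g.adjacency
    d = np.diag(a.sum(axis=1))
    n = g.n_nodes
    try:
        s = np.linalg.inv(np.eye(n) + eps**2 * d - eps * a)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological eps
        raise np.linalg.LinAlgError(
            f"singular DeltaCon system for graph {g.name or '?'} (eps={eps})"
        ) from exc
    # affinities are positive in exact arithmetic; clip numerical dust
    return np.clip(s, 0.0, None)


def default_deltacon_eps(*graphs: LabeledGraph) -> float:
    """1 / (1 + max degree) over all supplied graphs."""
    return 1.0 / (1.0 + max(int(g.degrees().max(initial=0)) for g in graphs))


def deltacon_distance(
    g1: LabeledGraph, g2: LabeledGraph, eps: float | None = None
) -> float:
    """Root-Euclidean (Matusita) distance between DeltaCon affinity matrices."""
    require_same_nodes(g1, g2)
    if eps is None:
        eps = default_deltacon_eps(g1, g2)
    s1 = _deltacon_affinity(g1, eps)
    s2 = _deltacon_affinity(g2, eps)
    return float(np.sqrt(((np.sqrt(s1) - np.sqrt(s2)) ** 2).sum()))


def default_t_grid() -> np.ndarray:
    """Log-spaced 50-point search grid on [1e-2, 1e2] for the diffusion time."""
    return np.geomspace(1e-2, 1e2, 50)


def _laplacian_eig(g: LabeledGraph):
    a = g.adjacency
    lap = np.diag(a.sum(axis=1)) - a
    return np.linalg.eigh(lap)


def _xi_squared(w1, u1, w2, u2, ts) -> np.ndarray:
    """||exp(-t L1) - exp(-t L2)||_F^2 on a grid, via the trace identity."""
    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    m = (u1.T @ u2) ** 2
    cross = np.add.outer(w1, w2).ravel()
    mflat = m.ravel()
    self1 = np.exp(-2.0 * np.outer(ts, w1)).sum(axis=1)
    self2 = np.exp(-2.0 * np.outer(ts, w2)).sum(axis=1)
    crossterm = np.exp(-np.outer(ts, cross)) @ mflat
    return np.clip(self1 + self2 - 2.0 * crossterm, 0.0, None)


def _refine_t(tgrid: np.ndarray, idx: int, points: int = 8) -> np.ndarray:
    lo = tgrid[max(idx - 1, 0)]
    hi = tgrid[min(idx + 1, len(tgrid) - 1)]
    return np.geomspace(lo, hi, points)


def diffusion_distance(
    g1: LabeledGraph, g2: LabeledGraph, t_grid=None
) -> float:
    """Graph diffusion distance: max_t ||exp(-t L1) - exp(-t L2)||_F.

    L = D - A is the combinatorial Laplacian.  A coarse log-spaced grid is
    scanned and refined once around the coarse maximiser.
    """
    if g1.n_nodes != g2.n_nodes:
        raise ValueError("diffusion distance requires equal node counts")
    tgrid = np.asarray(t_grid if t_grid is not None else default_t_grid(), dtype=float)
    w1, u1 = _laplacian_eig(g1)
    w2, u2 = _laplacian_eig(g2)
    xi2 = _xi_squared(w1, u1, w2, u2, tgrid)
    idx = int(np.argmax(xi2))
    best = xi2[idx]
    fine = _refine_t(tgrid, idx)
    best = max(best, float(np.max(_xi_squared(w1, u1, w2, u2, fine))))
    return float(np.sqrt(best))


def gaussian_kernel(g1: LabeledGraph, g2: LabeledGraph, sigma: float) -> float:
    """Gaussian (RBF) kernel on the vectorised adjacencies."""
    require_same_nodes(g1, g2)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sq = float(((g1.adjacency - g2.adjacency) ** 2).sum())
    return float(np.exp(-sq / (2.0 * sigma**2)))


def _gtom_matrix(g: LabeledGraph, m: int) -> np.ndarray:
    """Order-m generalised topological overlap matrix.

    N_m(i) is the set of nodes (excluding i) reachable from i in <= m steps;
    T_ij = (|N_m(i) & N_m(j)| + a_ij) / (min(|N_m(i)|, |N_m(j)|) + 1 - a_ij)
    off-diagonal, T_ii = 1.
    """
    a = g.adjacency
    n = g.n_nodes
    base = np.eye(n, dtype=bool) | (a != 0)
    reach = base.copy()
    for _ in range(m - 1):
        reach = (reach.astype(np.int64) @ base.astype(np.int64)) > 0
    nb = reach & ~np.eye(n, dtype=bool)  # m-step neighbourhoods, self excluded
    nb_f = nb.astype(float)
    overlap = nb_f @ nb_f.T
    sizes = nb_f.sum(axis=1)
    min_sizes = np.minimum.outer(sizes, sizes)
    t = (overlap + a) / (min_sizes + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    return t


def gtom_distance(g1: LabeledGraph, g2: LabeledGraph, m: int = 1) -> float:
    """Frobenius distance between order-m topological overlap matrices (KNC)."""
    if g1.weighted or g2.weighted:
        raise UnsupportedMeasureError("GTOM is undefined for weighted graphs")
    require_same_nodes(g1, g2)
    if m < 1:
        raise ValueError("overlap order m must be >= 1")
    return float(np.linalg.norm(_gtom_matrix(g1, m) - _gtom_matrix(g2, m), "fro"))


# ---------------------------------------------------------------------------
# kernel -> distance and the pairwise driver
# ---------------------------------------------------------------------------

def kernel_to_distance(
    kernel_values: np.ndarray, labels=None, measure_name: str = ""
) -> DistanceMatrix:
    """D_ij = K_ii + K_jj - 2 K_ij (squared feature-space distance).

    The input should be symmetric and positive semi-definite; a warning is
    emitted (and the offending entries clipped to 0) if any distance comes
    out negative.
    """
    k = np.asarray(kernel_values, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("kernel matrix must be square")
    if not np.allclose(k, k.T):
        raise ValueError("kernel matrix must be symmetric")
    diag = np.diag(k)
    d = diag[:, None] + diag[None, :] - 2.0 * k
    if np.any(d < -1e-9 * max(1.0, np.abs(diag).max())):
        warnings.warn(
            "kernel matrix is not positive semi-definite: negative distances "
            "clipped to 0",
            stacklevel=2,
        )
    d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    if labels is None:
        labels = [str(i) for i in range(k.shape[0])]
    return DistanceMatrix(list(labels), d, measure_name=measure_name)


def _normalize_kernel(k: np.ndarray) -> np.ndarray:
    diag = np.sqrt(np.clip(np.diag(k), 1e-300, None))
    return k / np.outer(diag, diag)


def _vec_upper(graphs) -> np.ndarray:
    """Stack full vectorised adjacencies into an (N, n^2) design matrix."""
    return np.stack([g.adjacency.ravel() for g in graphs])


def _labels(graphs) -> list[str]:
    return [g.name if g.name is not None else str(i) for i, g in enumerate(graphs)]


def _pairwise_edge_difference(graphs, params) -> np.ndarray:
    return squareform(pdist(_vec_upper(graphs), "euclidean"))


def _pairwise_hamming(graphs, params) -> np.ndarray:
    for g in graphs:
        if g.weighted:
            raise UnsupportedMeasureError(
                "Hamming distance is undefined for weighted graphs"
            )
    n = graphs[0].n_nodes
    return squareform(pdist(_vec_upper(graphs), "cityblock")) / (n * (n - 1))


def _pairwise_gaussian(graphs, params) -> np.ndarray:
    x = _vec_upper(graphs)
    norms = pdist(x, "euclidean")
    sigma = params.get("sigma")
    if sigma is None:  # median heuristic over the input set
        pos = norms[norms > 0]
        sigma = float(np.median(pos)) if pos.size else 1.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = np.exp(-squareform(norms) ** 2 / (2.0 * sigma**2))
    return k


def _shared_node_set(graphs, params) -> bool:
    if params.get("ignore_node_ids", False):
        return False
    ref = graphs[0].node_ids
    return all(g.node_ids == ref for g in graphs)


def _pairwise_shortest_path_kernel(graphs, params) -> np.ndarray:
    use_weights = bool(params.get("use_weights", False))
    if _shared_node_set(graphs, params):
        n = len(graphs)
        nn = graphs[0].n_nodes
        off = ~np.eye(nn, dtype=bool).ravel()
        sps = [_sp_matrix(g, use_weights).ravel()[off] for g in graphs]
        fin = [np.isfinite(s) for s in sps]
        out = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                both = fin[i] & fin[j]
                out[i, j] = out[j, i] = np.count_nonzero(
                    both & (sps[i] == sps[j])
                )
        return out
    hists = [_path_length_histogram(g, use_weights) for g in graphs]
    if any(not h for h in hists):
        warnings.warn("shortest-path kernel of an edgeless graph is 0", stacklevel=2)
    support = sorted({length for h in hists for length in h})
    idx = {length: i for i, length in enumerate(support)}
    x = np.zeros((len(graphs), len(support)))
    for row, h in zip(x, hists):
        for length, c in h.items():
            row[idx[length]] = c
    return x @ x.T


def _pairwise_random_walk(graphs, params) -> np.ndarray:
    k = int(params.get("k", 3))
    coeffs = params.get("coeffs")
    if coeffs is None:
        coeffs = np.ones(k + 1)
    coeffs = np.asarray(coeffs, dtype=float)
    if k < 0 or coeffs.shape != (k + 1,):
        raise ValueError("need k >= 0 and exactly k+1 step coefficients")
    if _shared_node_set(graphs, params):
        n = len(graphs)
        pats = [(g.adjacency != 0) for g in graphs]
        out = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                prod = (pats[i] & pats[j]).astype(float)
                out[i, j] = out[j, i] = coeffs @ _entry_sums_of_powers(prod, k)
        return out
    s = np.stack([_entry_sums_of_powers(g.adjacency, k) for g in graphs])
    return (s * coeffs) @ s.T


def _pairwise_random_walk_knc(graphs, params) -> np.ndarray:
    k = int(params.get("k", 3))
    coeffs = params.get("coeffs")
    n = len(graphs)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = random_walk_kernel(
                graphs[i], graphs[j], k=k, coeffs=coeffs, knc=True
            )
    return out


def _pairwise_deltacon(graphs, params) -> np.ndarray:
    # one epsilon for the whole set so every graph's affinity matrix is
    # computed once and all pairs live on the same affinity scale
    eps = params.get("eps")
    if eps is None:
        eps = default_deltacon_eps(*graphs)
    roots = np.stack(
        [np.sqrt(_deltacon_affinity(g, eps)).ravel() for g in graphs]
    )
    return squareform(pdist(roots, "euclidean"))


def _pairwise_gtom(graphs, params) -> np.ndarray:
    m = int(params.get("m", 1))
    for g in graphs:
        if g.weighted:
            raise UnsupportedMeasureError("GTOM is undefined for weighted graphs")
    mats = np.stack([_gtom_matrix(g, m).ravel() for g in graphs])
    return squareform(pdist(mats, "euclidean"))


def _pairwise_diffusion(graphs, params) -> np.ndarray:
    tgrid = np.asarray(
        params.get("t_grid") if params.get("t_grid") is not None else default_t_grid(),
        dtype=float,
    )
    n = len(graphs)
    sizes = {g.n_nodes for g in graphs}
    if len(sizes) != 1:
        raise ValueError("diffusion distance requires equal node counts")
    eigs = [_laplacian_eig(g) for g in graphs]
    nn = graphs[0].n_nodes
    best = np.zeros((n, n))
    argt = np.zeros((n, n), dtype=int)
    # coarse scan: Gram trick on vectorised heat kernels, shared across pairs
    for ti, t in enumerate(tgrid):
        x = np.stack(
            [((u * np.exp(-t * w)) @ u.T).ravel() for w, u in eigs]
        )
        sq = np.einsum("ij,ij->i", x, x)
        gram = x @ x.T
        d2 = sq[:, None] + sq[None, :] - 2.0 * gram
        better = d2 > best
        best[better] = d2[better]
        argt[better] = ti
    # one local refinement per pair around its coarse maximiser
    for i in range(n):
        wi, ui = eigs[i]
        for j in range(i + 1, n):
            wj, uj = eigs[j]
            fine = _refine_t(tgrid, argt[i, j])
            refined = float(np.max(_xi_squared(wi, ui, wj, uj, fine)))
            best[i, j] = best[j, i] = max(best[i, j], refined)
    np.fill_diagonal(best, 0.0)
    return np.sqrt(np.clip(best, 0.0, None))


_KERNELS = {
    "shortest_path_kernel": _pairwise_shortest_path_kernel,
    "random_walk_kernel": _pairwise_random_walk,
    "random_walk_kernel_knc": _pairwise_random_walk_knc,
    "gaussian": _pairwise_gaussian,
}
_DISTANCES = {
    "edge_difference": _pairwise_edge_difference,
    "hamming": _pairwise_hamming,
    "deltacon": _pairwise_deltacon,
    "gtom": _pairwise_gtom,
    "diffusion": _pairwise_diffusion,
}


def pairwise_distances(graphs, spec: MeasureSpec | str) -> DistanceMatrix:
    """Distance matrix over a collection of graphs for one measure.

    Kernel measures are routed through :func:`kernel_to_distance`.  KNC
    measures require every graph to share one ordered node set.
    """
    if isinstance(spec, str):
        spec = MeasureSpec(spec)
    graphs = list(graphs)
    if len(graphs) < 2:
        raise ValueError("need at least two graphs")
    if spec.knc:
        ref = graphs[0].node_ids
        bad = [
            g.name or str(i)
            for i, g in enumerate(graphs)
            if g.node_ids != ref
        ]
        if bad:
            raise NodeCorrespondenceError(
                f"measure {spec.name!r} requires a shared ordered node set; "
                f"offending graphs: {bad}"
            )
    labels = _labels(graphs)
    if spec.name in _KERNELS:
        k = _KERNELS[spec.name](graphs, spec.params)
        if spec.params.get("normalize", False):
            k = _normalize_kernel(k)
        return kernel_to_distance(k, labels=labels, measure_name=spec.name)
    values = _DISTANCES[spec.name](graphs, spec.params)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DistanceMatrix(labels, values, measure_name=spec.name)
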