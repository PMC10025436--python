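"""Synthetic-network generators and the two simulation experiments.

The study conditions emulated here: an original Erdős–Rényi graph with 100
nodes and density 0.05 (binary), from which group and individual networks
are derived by degree-preserving rewiring of a stated fraction of edges
(double edge swaps).  Variants: Barabási–Albert and planted-cluster
originals, add/remove/switch perturbations, and weighted networks whose edge
values are N(0.5, 0.25) draws min–max scaled globally across the whole set.

Two experiment drivers are provided:

* :func:`type1_experiment` — a single homogeneous population per replicate;
  a replicate counts as a false positive when the workflow detects >= 2
  clusters.  The type I error rate is #FP / #replicates.
* :func:`power_experiment` — a two-level hierarchy (groups, then individuals
  within groups); recovery is scored with the pairwise co-membership Jaccard
  index against the true groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .anova import GroupLabeling
from .graphs import LabeledGraph
from .measures import MeasureSpec, pairwise_distances
from .tree import NetAnovaParams, netanova_fit

__all__ = [
    "SimulationConfig",
    "ExperimentReport",
    "generate_er",
    "generate_structured",
    "rewire_degree_preserving",
    "perturb_edges",
    "perturb",
    "weight_and_scale",
    "type1_experiment",
    "power_experiment",
    "jaccard_index",
]

PERTURB_TYPES = ("rewire_degree_preserving", "add", "remove", "switch")
STRUCTURES = ("erdos_renyi", "barabasi_albert", "planted_cluster")


@dataclass
class SimulationConfig:
    """All knobs of the type-I-error and power simulations."""

    n_nodes: int = 100
    density: float = 0.05
    structure: str = "erdos_renyi"
    weighted: bool = False
    n_groups: int = 10
    networks_per_group: int = 10
    n_networks: int = 50  # type-I runs: graphs per replicate
    perturb_fraction: float = 0.40
    perturb_type: str = "rewire_degree_preserving"
    n_replicates: int = 1000
    netanova: NetAnovaParams = field(default_factory=NetAnovaParams)
    measure: MeasureSpec = field(default_factory=lambda: MeasureSpec("edge_difference"))
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 < self.perturb_fraction <= 1:
            raise ValueError("perturbation fraction must lie in (0, 1]")
        if self.perturb_type not in PERTURB_TYPES:
            raise ValueError(f"perturbation type must be one of {PERTURB_TYPES}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")


@dataclass
class ExperimentReport:
    config: SimulationConfig
    per_replicate: list
    type1_rate: float | None = None
    mean_jaccard: float | None = None
    mean_n_clusters: float | None = None

    def to_dict(self) -> dict:
        out = {"per_replicate": self.per_replicate}
        if self.type1_rate is not None:
            out["type1_rate"] = self.type1_rate
        if self.mean_jaccard is not None:
            out["mean_jaccard"] = self.mean_jaccard
        if self.mean_n_clusters is not None:
            out["mean_n_clusters"] = self.mean_n_clusters
        return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _ids(m: int) -> list[str]:
    return [str(i) for i in range(m)]


def generate_er(m: int, d: float, rng: np.random.Generator) -> LabeledGraph:
    """Undirected binary G(m, p=d) Erdős–Rényi graph, no self-loops."""
    if m < 2:
        raise ValueError("need at least two nodes")
    iu = np.triu_indices(m, k=1)
    a = np.zeros((m, m))
    edges = rng.random(iu[0].size) < d
    a[iu] = edges.astype(float)
    a += a.T
    return LabeledGraph(_ids(m), a)


def generate_structured(
    structure: str, m: int, d: float, rng: np.random.Generator
) -> LabeledGraph:
    """Scale-free (Barabási–Albert) or planted-cluster original networks.

    The BA per-step attachment count is chosen so the expected edge count is
    closest to d*m*(m-1)/2.  The planted-cluster model uses 4 equal blocks
    with within-block probability 5x the between-block one, calibrated so
    the overall expected density is d.
    """
    target_edges = d * m * (m - 1) / 2.0
    if structure == "erdos_renyi":
        return generate_er(m, d, rng)
    if structure == "barabasi_albert":
        best = min(
            range(1, m), key=lambda k: abs(k * (m - k) - target_edges)
        )
        g = nx.barabasi_albert_graph(m, best, seed=int(rng.integers(2**31)))
        lg = LabeledGraph.from_networkx(g)
        lg.node_ids = _ids(m)
        return lg
    if structure == "planted_cluster":
        blocks = np.array_split(np.arange(m), 4)
        labels = np.empty(m, dtype=int)
        for b, idx in enumerate(blocks):
            labels[idx] = b
        iu = np.triu_indices(m, k=1)
        within = labels[iu[0]] == labels[iu[1]]
        f_in = within.mean()
        p_out = d / (5.0 * f_in + (1.0 - f_in))
        p_in = min(5.0 * p_out, 1.0)
        probs = np.where(within, p_in, p_out)
        a = np.zeros((m, m))
        a[iu] = (rng.random(iu[0].size) < probs).astype(float)
        a += a.T
        return LabeledGraph(_ids(m), a)
    raise ValueError(f"unknown structure {structure!r}")


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def rewire_degree_preserving(
    g: LabeledGraph, fraction: float, rng: np.random.Generator
) -> LabeledGraph:
    """Double-edge-swap rewiring preserving every node's degree.

    round(fraction * |E|) swap attempts are made.  Each attempt picks two
    edges (a,b) and (c,d) and replaces them with (a,d) and (c,b) provided
    neither new edge already exists and no self-loop would arise; failed
    attempts are consumed, matching attempt-counting rewiring semantics.
    """
    edges = [tuple(e) for e in g.edge_array()]
    n_attempts = int(round(fraction * len(edges)))
    if len(edges) < 2:
        if n_attempts > 0:
            warnings.warn("too few edges to rewire; returning the input graph",
                          stacklevel=2)
        return g.copy()
    edge_set = {frozenset(e) for e in edges}
    for _ in range(n_attempts):
        i, j = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            c, d = d, c
        if a == d or c == b:
            continue
        if frozenset((a, d)) in edge_set or frozenset((c, b)) in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(frozenset((a, d)))
        edge_set.add(frozenset((c, b)))
        edges[i] = (a, d)
        edges[j] = (c, b)
    a_new = np.zeros_like(g.adjacency)
    for u, v in edges:
        a_new[u, v] = a_new[v, u] = 1.0
    return LabeledGraph(list(g.node_ids), a_new, weighted=False, name=g.name)


def perturb_edges(
    g: LabeledGraph, kind: str, fraction: float, rng: np.random.Generator
) -> LabeledGraph:
    """Add, remove or switch (relocate) round(fraction * |E|) edges.

    ``switch`` moves edges to uniformly chosen non-edge positions, so degrees
    are generally not preserved.
    """
    edges = g.edge_array()
    m_edges = len(edges)
    n_mod = int(round(fraction * m_edges))
    iu = np.triu_indices(g.n_nodes, k=1)
    present = g.adjacency[iu] != 0
    non_edge_idx = np.flatnonzero(~present)
    edge_idx = np.flatnonzero(present)
    a_new = g.adjacency.copy()

    def _set(flat_idx, value):
        rows, cols = iu[0][flat_idx], iu[1][flat_idx]
        a_new[rows, cols] = value
        a_new[cols, rows] = value

    if kind == "add":
        if n_mod > non_edge_idx.size:
            raise ValueError("not enough non-edges to add the requested number")
        _set(rng.choice(non_edge_idx, size=n_mod, replace=False), 1.0)
    elif kind == "remove":
        if n_mod > edge_idx.size:
            raise ValueError("cannot remove more edges than the graph has")
        _set(rng.choice(edge_idx, size=n_mod, replace=False), 0.0)
    elif kind == "switch":
        if n_mod > edge_idx.size or n_mod > non_edge_idx.size:
            raise ValueError("switch request infeasible for this graph")
        _set(rng.choice(edge_idx, size=n_mod, replace=False), 0.0)
        _set(rng.choice(non_edge_idx, size=n_mod, replace=False), 1.0)
    else:
        raise ValueError("kind must be 'add', 'remove' or 'switch'")
    return LabeledGraph(list(g.node_ids), a_new, weighted=False, name=g.name)


def perturb(
    g: LabeledGraph, kind: str, fraction: float, rng: np.random.Generator
) -> LabeledGraph:
    """Dispatch to degree-preserving rewiring or add/remove/switch."""
    if kind == "rewire_degree_preserving":
        return rewire_degree_preserving(g, fraction, rng)
    return perturb_edges(g, kind, fraction, rng)


def weight_and_scale(
    graphs, mu: float = 0.5, sd: float = 0.25, rng: np.random.Generator | None = None
):
    """Replace present edges by N(mu, sd^2) draws, then min–max scale globally.

    One min and one max are taken across ALL edge values of ALL graphs, so
    every weighted adjacency ends up in [0, 1] on a shared scale.  A constant
    pooled value set (degenerate range) maps to 0.5 with a warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    weighted = []
    for g in graphs:
        a = g.adjacency.copy()
        iu = np.triu_indices(g.n_nodes, k=1)
        mask = a[iu] != 0
        draws = rng.normal(mu, sd, size=int(mask.sum()))
        vals = a[iu]
        vals[mask] = draws
        a[iu] = vals
        a.T[iu] = vals
        weighted.append(a)
    pooled = np.concatenate(
        [a[np.triu_indices(a.shape[0], k=1)] for a in weighted]
    )
    pooled = pooled[pooled != 0]
    out = []
    if pooled.size == 0:
        lo = hi = 0.0
    else:
        lo, hi = float(pooled.min()), float(pooled.max())
    for g, a in zip(graphs, weighted):
        scaled = a.copy()
        mask = scaled != 0
        if hi > lo:
            scaled[mask] = (scaled[mask] - lo) / (hi - lo)
        else:
            warnings.warn(
                "degenerate edge-value range; mapping constant values to 0.5",
                stacklevel=2,
            )
            scaled[mask] = 0.5
        out.append(
            LabeledGraph(list(g.node_ids), scaled, weighted=True, name=g.name)
        )
    return out


# ---------------------------------------------------------------------------
# partition agreement
# ---------------------------------------------------------------------------

def jaccard_index(true_labels, found_labels) -> float:
    """Pairwise co-membership Jaccard: n11 / (n11 + n10 + n01).

    n11 counts object pairs clustered together in both partitions; n10/n01
    pairs together in exactly one.
    """
    a = true_labels.labels if isinstance(true_labels, GroupLabeling) else np.asarray(true_labels)
    b = found_labels.labels if isinstance(found_labels, GroupLabeling) else np.asarray(found_labels)
    if a.size != b.size:
        raise ValueError("partitions must cover the same objects")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    n11 = (cont * (cont - 1) // 2).sum()
    rows = cont.sum(axis=1)
    cols = cont.sum(axis=0)
    pairs_a = (rows * (rows - 1) // 2).sum()
    pairs_b = (cols * (cols - 1) // 2).sum()
    denom = pairs_a + pairs_b - n11  # n11 + n10 + n01
    if denom == 0:
        return 1.0  # both partitions are all-singletons
    return float(n11 / denom)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _replicate_rngs(seed, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _fit_params(cfg: SimulationConfig, rng: np.random.Generator) -> NetAnovaParams:
    return replace(cfg.netanova, seed=int(rng.integers(2**31)))


def type1_experiment(cfg: SimulationConfig) -> ExperimentReport:
    """Null simulation: one homogeneous population of rewired graphs.

    A replicate is a false positive when >= 2 clusters are detected; the
    type I error rate is the false-positive fraction.
    """
    records = []
    for rng in _replicate_rngs(cfg.seed, cfg.n_replicates):
        original = generate_structured(cfg.structure, cfg.n_nodes, cfg.density, rng)
        graphs = [
            perturb(original, cfg.perturb_type, cfg.perturb_fraction, rng)
            for _ in range(cfg.n_networks)
        ]
        if cfg.weighted:
            graphs = weight_and_scale(graphs, rng=rng)
        dmat = pairwise_distances(graphs, cfg.measure)
        _, _, n_clusters = netanova_fit(dmat, _fit_params(cfg, rng))
        records.append({"n_clusters": int(n_clusters), "fp": bool(n_clusters >= 2)})
    rate = sum(r["fp"] for r in records) / len(records)
    return ExperimentReport(config=cfg, per_replicate=records, type1_rate=rate)


def simulate_power_population(cfg: SimulationConfig, rng: np.random.Generator):
    """One power-study population: groups of individual networks plus truth."""
    original = generate_structured(cfg.structure, cfg.n_nodes, cfg.density, rng)
    graphs, truth = [], []
    for gidx in range(cfg.n_groups):
        group_net = perturb(original, cfg.perturb_type, cfg.perturb_fraction, rng)
        for _ in range(cfg.networks_per_group):
            graphs.append(
                perturb(group_net, cfg.perturb_type, cfg.perturb_fraction, rng)
            )
            truth.append(gidx)
    if cfg.weighted:
        graphs = weight_and_scale(graphs, rng=rng)
    return graphs, GroupLabeling(np.asarray(truth))


def power_experiment_multi(cfg: SimulationConfig, measures) -> dict:
    """Power study for several measures on the same simulated populations.

    Each replicate's networks are generated once and scored under every
    measure, which keeps the comparison across measures paired.  Returns
    ``{measure_name: ExperimentReport}``.
    """
    if cfg.n_groups < 2:
        raise ValueError("power simulation needs at least two groups")
    specs = [MeasureSpec(m) if isinstance(m, str) else m for m in measures]
    records: dict = {s.name: [] for s in specs}
    for rng in _replicate_rngs(cfg.seed, cfg.n_replicates):
        graphs, truth = simulate_power_population(cfg, rng)
        for spec in specs:
            dmat = pairwise_distances(graphs, spec)
            _, found, n_clusters = netanova_fit(dmat, _fit_params(cfg, rng))
            records[spec.name].append(
                {
                    "jaccard": jaccard_index(truth, found),
                    "n_clusters": int(n_clusters),
                }
            )
    return {
        name: ExperimentReport(
            config=replace(cfg, measure=spec),
            per_replicate=recs,
            mean_jaccard=float(np.mean([r["jaccard"] for r in recs])),
            mean_n_clusters=float(np.mean([r["n_clusters"] for r in recs])),
        )
        for (name, recs), spec in zip(records.items(), specs)
    }


def power_experiment(cfg: SimulationConfig) -> ExperimentReport:
    """Two-level hierarchy recovery, scored with the co-membership Jaccard."""
    if cfg.n_groups < 2:
        raise ValueError("power simulation needs at least two groups")
    records = []
    for rng in _replicate_rngs(cfg.seed, cfg.n_replicates):
        graphs, truth = simulate_power_population(cfg, rng)
        dmat = pairwise_distances(graphs, cfg.measure)
        _, found, n_clusters = netanova_fit(dmat, _fit_params(cfg, rng))
        records.append(
            {
                "jaccard": jaccard_index(truth, found),
                "n_clusters": int(n_clusters),
            }
        )
    return ExperimentReport(
        config=cfg,
        per_replicate=records,
        mean_jaccard=float(np.mean([r["jaccard"] for r in records])),
        mean_n_clusters=float(np.mean([r["n_clusters"] for r in records])),
    )
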