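"""Readers and writers for graphs, distance matrices and run outputs.

Supported graph formats: whitespace-delimited edge lists (``u v [w]`` per
line), square adjacency CSV with a header row of node ids, and GraphML.
Distance matrices travel as square CSV with a graph-id header.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .graphs import LabeledGraph
from .measures import DistanceMatrix
from .tree import ClusterTreeNode

__all__ = [
    "read_edgelist",
    "read_adjacency_csv",
    "read_graphml",
    "read_graph_set",
    "align_node_universe",
    "write_distance_csv",
    "read_distance_csv",
    "write_edgelist",
    "write_run_outputs",
]

_FORMATS = ("edgelist", "adjacency_csv", "graphml")


def read_edgelist(path) -> LabeledGraph:
    """Whitespace edge list, one ``u v [w]`` triple per line; ``#`` comments."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    weights: list[float] = []
    seen: dict[frozenset, int] = {}
    any_weight = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 'u v [w]', got {line!r}")
            u, v = parts[0], parts[1]
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u!r} not supported")
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            any_weight = any_weight or len(parts) == 3
            key = frozenset((u, v))
            if key in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate edge {u}-{v} collapsed",
                    stacklevel=2,
                )
                weights[seen[key]] = w
                continue
            seen[key] = len(edges)
            edges.append((u, v))
            weights.append(w)
    return LabeledGraph.from_edges(
        edges,
        weights=weights if any_weight else None,
        name=path.stem,
    )


def read_adjacency_csv(path) -> LabeledGraph:
    """Square adjacency CSV; the header row carries the node ids."""
    path = Path(path)
    df = pd.read_csv(path, index_col=None)
    a = df.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"{path}: adjacency CSV must be square, got {a.shape}")
    node_ids = [str(c) for c in df.columns]
    weighted = bool(np.any((a != 0) & (a != 1)))
    return LabeledGraph(node_ids, a, weighted=weighted, name=path.stem)


def read_graphml(path) -> LabeledGraph:
    path = Path(path)
    g = nx.read_graphml(path)
    lg = LabeledGraph.from_networkx(g, name=path.stem)
    return lg


_READERS = {
    "edgelist": read_edgelist,
    "adjacency_csv": read_adjacency_csv,
    "graphml": read_graphml,
}
_EXTENSIONS = {
    ".graphml": "graphml",
    ".csv": "adjacency_csv",
    ".edgelist": "edgelist",
    ".edges": "edgelist",
    ".txt": "edgelist",
    ".tsv": "edgelist",
}


def read_graph_set(paths, format: str | None = None, align: bool = False):
    """Read many graph files; optionally align all to a common node universe."""
    graphs = []
    for p in paths:
        p = Path(p)
        fmt = format or _EXTENSIONS.get(p.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format of {p}; pass format=...")
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}")
        graphs.append(_READERS[fmt](p))
    if align:
        graphs = align_node_universe(graphs)
    return graphs


def align_node_universe(graphs):
    """Re-order every graph onto the sorted union of all node ids.

    Graphs missing some nodes get isolated placeholders, so known-node-
    correspondence measures can be applied across the whole set.
    """
    universe = sorted({v for g in graphs for v in g.node_ids})
    index = {v: i for i, v in enumerate(universe)}
    out = []
    for g in graphs:
        a = np.zeros((len(universe), len(universe)))
        idx = np.array([index[v] for v in g.node_ids])
        a[np.ix_(idx, idx)] = g.adjacency
        out.append(
            LabeledGraph(universe, a, directed=g.directed, weighted=g.weighted,
                         name=g.name)
        )
    return out


def write_distance_csv(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.values, columns=d.labels).to_csv(path, index=False)


def read_distance_csv(path, measure_name: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=None)
    return DistanceMatrix(
        [str(c) for c in df.columns], df.to_numpy(dtype=float), measure_name
    )


def write_edgelist(g: LabeledGraph, path) -> None:
    with open(path, "w") as fh:
        for i, j in g.edge_array():
            if g.weighted:
                fh.write(f"{g.node_ids[i]} {g.node_ids[j]} {g.adjacency[i, j]:g}\n")
            else:
                fh.write(f"{g.node_ids[i]} {g.node_ids[j]}\n")


def write_run_outputs(
    root: ClusterTreeNode,
    clusters,
    labels,
    prefix,
    config: dict | None = None,
) -> dict:
    """Write clusters TSV, tree JSON and a config echo; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cluster_labels = clusters.labels if hasattr(clusters, "labels") else np.asarray(clusters)
    paths = {
        "clusters": prefix.with_suffix(".clusters.tsv"),
        "tree": prefix.with_suffix(".tree.json"),
    }
    pd.DataFrame(
        {"object_id": list(labels), "cluster_id": cluster_labels + 1}
    ).to_csv(paths["clusters"], sep="\t", index=False)
    with open(paths["tree"], "w") as fh:
        json.dump(root.to_dict(), fh, indent=1, sort_keys=True)
    if config is not None:
        paths["config"] = prefix.with_suffix(".config.yaml")
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
    return paths
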