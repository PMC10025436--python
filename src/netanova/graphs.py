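"""Graph containers used throughout netANOVA.

A :class:`LabeledGraph` holds one network as a dense adjacency matrix plus an
ordered list of node identifiers.  Binary graphs store 0/1 entries; weighted
graphs store reals (in [0, 1] after global min-max scaling in the simulation
pipeline).  Undirected graphs keep a symmetric adjacency with a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["LabeledGraph", "NodeCorrespondenceError"]


class NodeCorrespondenceError(ValueError):
    """Raised when a known-node-correspondence measure gets misaligned graphs."""


@dataclass
class LabeledGraph:
    node_ids: list[str]
    adjacency: np.ndarray
    directed: bool = False
    weighted: bool = False
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.node_ids = [str(v) for v in self.node_ids]
        n = len(self.node_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{n} node identifiers"
            )
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not supported (nonzero diagonal)")
        if not self.directed and not np.allclose(
            self.adjacency, self.adjacency.T
        ):
            raise ValueError("undirected graph requires a symmetric adjacency")
        if not self.weighted:
            vals = np.unique(self.adjacency)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binary graph has entries outside {0, 1}")

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        nz = np.count_nonzero(self.adjacency)
        return nz if self.directed else nz // 2

    def degrees(self) -> np.ndarray:
        """Node degrees (number of incident edges, ignoring weights)."""
        return np.count_nonzero(self.adjacency, axis=1)

    def edge_array(self) -> np.ndarray:
        """Undirected edges as an (m, 2) index array with u < v."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju])

    # -- constructors / conversions ---------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges,
        node_ids=None,
        weights=None,
        directed: bool = False,
        name: str | None = None,
    ) -> "LabeledGraph":
        """Build a graph from an iterable of (u, v) node-id pairs."""
        edges = list(edges)
        if node_ids is None:
            seen: dict = {}
            for u, v in edges:
                seen.setdefault(str(u), None)
                seen.setdefault(str(v), None)
            node_ids = list(seen)
        node_ids = [str(v) for v in node_ids]
        index = {v: i for i, v in enumerate(node_ids)}
        a = np.zeros((len(node_ids), len(node_ids)))
        weighted = weights is not None
        if weights is None:
            weights = [1.0] * len(edges)
        for (u, v), w in zip(edges, weights):
            i, j = index[str(u)], index[str(v)]
            a[i, j] = w
            if not directed:
                a[j, i] = w
        return cls(node_ids, a, directed=directed, weighted=weighted, name=name)

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str | None = None) -> "LabeledGraph":
        nodes = [str(v) for v in g.nodes]
        a = nx.to_numpy_array(g, nodelist=list(g.nodes), weight="weight")
        np.fill_diagonal(a, 0.0)
        weighted = any("weight" in d for _, _, d in g.edges(data=True))
        return cls(nodes, a, directed=g.is_directed(), weighted=weighted, name=name)

    def to_networkx(self) -> nx.Graph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.node_ids)
        it = zip(*np.nonzero(self.adjacency))
        for i, j in it:
            if not self.directed and i > j:
                continue
            g.add_edge(
                self.node_ids[i], self.node_ids[j], weight=self.adjacency[i, j]
            )
        return g

    def reorder(self, node_ids) -> "LabeledGraph":
        """Return a copy with rows/columns aligned to ``node_ids``."""
        node_ids = [str(v) for v in node_ids]
        if set(node_ids) != set(self.node_ids):
            raise NodeCorrespondenceError(
                f"graph {self.name or '?'} has node set "
                f"{sorted(self.node_ids)[:5]}... incompatible with requested order"
            )
        idx = [self.node_ids.index(v) for v in node_ids]
        return LabeledGraph(
            node_ids,
            self.adjacency[np.ix_(idx, idx)],
            directed=self.directed,
            weighted=self.weighted,
            name=self.name,
        )

    def copy(self) -> "LabeledGraph":
        return LabeledGraph(
            list(self.node_ids),
            self.adjacency.copy(),
            directed=self.directed,
            weighted=self.weighted,
            name=self.name,
        )


def require_same_nodes(g1: LabeledGraph, g2: LabeledGraph) -> None:
    """Check the two graphs share one ordered node set (KNC precondition)."""
    if g1.node_ids != g2.node_ids:
        raise NodeCorrespondenceError(
            "known-node-correspondence measure requires identical ordered "
            f"node sets; got graphs {g1.name or '?'} and {g2.name or '?'} "
            f"with {g1.n_nodes} vs {g2.n_nodes} nodes"
        )
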