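"""Recursive dendrogram testing: from a distance matrix to significant clusters.

The workflow builds an agglomerative dendrogram and walks it from the root
down.  At each node the two branches of the top merge are compared with the
permuted-distance-matrix F test.  Recursion stops when the branches are too
small or not significantly different; leaves of the resulting decision tree
are the final clusters.

Undersized branches get special treatment: when exactly one branch falls
below the minimum group size t, the split is *not* tested.  The walk descends
into the larger branch (without incrementing the test depth) and tests that
branch's own split; if it is significant the small branch is regarded as an
outlying, independent group, otherwise the whole parent node remains one
cluster.

Two multiple-testing corrections along the tree are available: depth-based
(p_adj = p x depth, no correction at the root) and the Meinshausen node-wise
threshold alpha_adj = alpha (N_j - 1)/(N - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anova import (
    LINKAGES,
    GroupLabeling,
    PermutationResult,
    permutation_test,
    two_group_cut,
)

__all__ = [
    "NetAnovaParams",
    "SplitTestResult",
    "ClusterTreeNode",
    "agglomerative_two_split",
    "depth_correction",
    "meinshausen_alpha",
    "classify_new_depth",
    "netanova_fit",
]


@dataclass
class NetAnovaParams:
    """Knobs of the recursive testing procedure.

    min_group_size : smallest group that may enter a test (t)
    n_perm         : permutation replicates per test (paper default 99)
    perm_fraction  : fraction of the distance matrix shuffled per replicate
    linkage        : 'complete' or 'average' (dissimilarities only need to be
                     symmetric and nonnegative, so metric-free linkages only)
    alpha          : significance threshold
    correction     : 'depth', 'meinshausen' or 'none'
    """

    min_group_size: int = 10
    n_perm: int = 99
    perm_fraction: float = 0.2
    linkage: str = "complete"
    alpha: float = 0.05
    correction: str = "depth"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_group_size < 2:
            raise ValueError("minimum group size must be >= 2")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.correction not in ("depth", "meinshausen", "none"):
            raise ValueError("correction must be 'depth', 'meinshausen' or 'none'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SplitTestResult:
    group_a: np.ndarray
    group_b: np.ndarray
    f_stat: float
    p_raw: float
    p_adj: float | None
    alpha_adj: float | None
    significant: bool
    n_valid: int = 0

    def to_dict(self) -> dict:
        return {
            "group_a": [int(i) for i in self.group_a],
            "group_b": [int(i) for i in self.group_b],
            "f_stat": float(self.f_stat),
            "p_raw": float(self.p_raw),
            "p_adj": None if self.p_adj is None else float(self.p_adj),
            "alpha_adj": None if self.alpha_adj is None else float(self.alpha_adj),
            "significant": bool(self.significant),
            "n_valid": int(self.n_valid),
        }


@dataclass
class ClusterTreeNode:
    members: np.ndarray
    depth_level: int
    status: str = "leaf_cluster"
    children: list = field(default_factory=list)
    test: SplitTestResult | None = None

    STATUSES = (
        "tested_significant",
        "tested_not_significant",
        "too_small",
        "outlier_group",
        "leaf_cluster",
        "untested_bypass",
    )

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def to_dict(self) -> dict:
        return {
            "members": [int(i) for i in self.members],
            "depth_level": int(self.depth_level),
            "status": self.status,
            "test": None if self.test is None else self.test.to_dict(),
            "children": [c.to_dict() for c in self.children],
        }


def agglomerative_two_split(values: np.ndarray, method: str = "complete"):
    """Two branches obtained by cutting the dendrogram at its top merge.

    Input only needs to be symmetric and nonnegative (no triangle
    inequality).  Returns two sorted index arrays.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("need a square matrix")
    if not np.allclose(values, values.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two objects to split")
    if n == 2:
        return np.array([0]), np.array([1])
    labels = two_group_cut(values, method)
    return np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)


def depth_correction(p_raw: float, depth_level: int) -> float:
    """p_adj = p x depth, capped at 1; no correction at the root (depth 1)."""
    if depth_level < 1:
        raise ValueError("depth level starts at 1 (root)")
    return min(1.0, p_raw * depth_level)


def meinshausen_alpha(alpha: float, n_node: int, n_total: int) -> float:
    """Node-wise threshold alpha (N_j - 1)/(N - 1) controlling tree-wise FWER."""
    if n_total < 2:
        raise ValueError("total sample size must be >= 2")
    if not 2 <= n_node <= n_total:
        raise ValueError("need 2 <= N_j <= N")
    return alpha * (n_node - 1) / (n_total - 1)


def classify_new_depth(depth_level: int, tested: bool) -> int:
    """Child depth: incremented only when a test was performed at the node."""
    return depth_level + 1 if tested else depth_level


def _evaluate_split(res: PermutationResult, depth, n_node, n_total, params):
    """Apply the configured multiple-testing rule to a raw permutation p."""
    if params.correction == "depth":
        p_adj = depth_correction(res.p_value, depth)
        return p_adj, None, p_adj < params.alpha
    if params.correction == "meinshausen":
        a_adj = meinshausen_alpha(params.alpha, n_node, n_total)
        return None, a_adj, res.p_value < a_adj
    return res.p_value, None, res.p_value < params.alpha


def netanova_fit(d, params: NetAnovaParams | None = None):
    """Run the full recursive procedure on a distance matrix.

    Returns ``(root, final_clusters, n_clusters)`` where ``final_clusters``
    is a :class:`GroupLabeling` with one index per object (cluster ids in
    order of first appearance in a left-to-right leaf scan).
    """
    if params is None:
        params = NetAnovaParams()
    values = d.values if hasattr(d, "values") else np.asarray(d, dtype=float)
    values = np.asarray(values, dtype=float)
    n_total = values.shape[0]
    t = params.min_group_size
    rng = np.random.default_rng(params.seed)

    if n_total < 2 * t:
        warnings.warn(
            f"{n_total} objects cannot contain two groups of size >= {t}; "
            "returning a single cluster",
            stacklevel=2,
        )
        root = ClusterTreeNode(np.arange(n_total), 1, status="too_small")
        return root, GroupLabeling(np.zeros(n_total, dtype=int)), 1

    def descend(members: np.ndarray, depth: int) -> ClusterTreeNode:
        node = ClusterTreeNode(members, depth)
        if members.size < 2:
            node.status = "too_small"
            return node
        sub = values[np.ix_(members, members)]
        ia, ib = agglomerative_two_split(sub, params.linkage)
        ga, gb = members[ia], members[ib]
        small_a, small_b = ga.size < t, gb.size < t

        if not small_a and not small_b:
            labels = np.zeros(members.size, dtype=int)
            labels[ib] = 1
            res = permutation_test(
                sub,
                labels,
                n_perm=params.n_perm,
                fraction=params.perm_fraction,
                min_size=t,
                method=params.linkage,
                rng=rng,
            )
            p_adj, a_adj, significant = _evaluate_split(
                res, depth, members.size, n_total, params
            )
            node.test = SplitTestResult(
                ga, gb, res.f_obs, res.p_value, p_adj, a_adj, significant,
                n_valid=res.n_valid,
            )
            if significant:
                node.status = "tested_significant"
                child_depth = classify_new_depth(depth, tested=True)
                node.children = [descend(ga, child_depth), descend(gb, child_depth)]
            else:
                node.status = "tested_not_significant"
            return node

        if small_a and small_b:
            node.status = "too_small"
            return node

        # exactly one branch is undersized: do not test this split; descend
        # into the larger branch at the same depth and test its own split
        big, small = (gb, ga) if small_a else (ga, gb)
        big_node = descend(big, classify_new_depth(depth, tested=False))
        if not big_node.is_leaf:
            # the larger branch split significantly: the small branch is an
            # outlying, independent group
            small_node = ClusterTreeNode(small, depth, status="outlier_group")
            node.status = "untested_bypass"
            node.children = [small_node, big_node]
        else:
            node.status = "leaf_cluster"  # small branch folds back in
        return node

    root = descend(np.arange(n_total), 1)
    labels = np.empty(n_total, dtype=int)
    n_clusters = 0
    for leaf in root.leaves():
        labels[leaf.members] = n_clusters
        n_clusters += 1
    return root, GroupLabeling(labels), n_clusters
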