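"""Distance-wise ANOVA and the permuted-distance-matrix significance test.

The decomposition avoids any notion of a mean graph: by the interpoint
identity, the sum of squared deviations of points from their centroid equals
the sum of squared interpoint distances divided by the number of points, so

    SST = (1/N)    sum_{i<j} d_ij^2
    SSW = sum_l (1/n_l) sum_{i<j in group l} d_ij^2
    SSA = SST - SSW
    F   = (SSA / (k-1)) / (SSW / (N-k))

Significance cannot come from permuting group labels (the groups were chosen
by clustering the same distances, which would inflate type I error).  Instead
a fraction of the distance-matrix entries is shuffled, the clustering is
re-applied to the shuffled matrix to obtain two fresh groups, and the F
statistic of that replicate enters the null distribution:

    p = (#(F_perm >= F_obs) + 1) / (n_valid + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "GroupLabeling",
    "AnovaResult",
    "PermutationResult",
    "sum_of_squares",
    "f_statistic",
    "permute_distance_matrix",
    "permutation_test",
    "two_group_cut",
    "DegenerateNullError",
]

LINKAGES = ("complete", "average")


class DegenerateNullError(RuntimeError):
    """No valid permutation replicate could be generated."""


@dataclass
class GroupLabeling:
    """Per-object group assignment over k groups (indices 0..k-1)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        uniq, counts = np.unique(self.labels, return_counts=True)
        self._uniq = uniq
        self._counts = counts

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return self._uniq.size

    @property
    def group_sizes(self) -> np.ndarray:
        return self._counts

    def masks(self):
        for g in self._uniq:
            yield self.labels == g


@dataclass(frozen=True)
class AnovaResult:
    sst: float
    ssw: float
    ssa: float
    f_stat: float
    n_objects: int
    n_groups: int


@dataclass
class PermutationResult:
    f_obs: float
    f_perm: np.ndarray
    p_value: float
    n_valid: int
    n_attempted: int

    def to_dict(self) -> dict:
        return {
            "f_obs": float(self.f_obs),
            "p_value": float(self.p_value),
            "n_valid": int(self.n_valid),
            "n_attempted": int(self.n_attempted),
        }


def _as_square(d) -> np.ndarray:
    values = d.values if hasattr(d, "values") else np.asarray(d, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance input must be a square matrix")
    return values


def _as_labeling(grouping) -> GroupLabeling:
    if isinstance(grouping, GroupLabeling):
        return grouping
    return GroupLabeling(np.asarray(grouping))


def sum_of_squares(d, grouping) -> AnovaResult:
    """SST / SSW / SSA decomposition from squared pairwise distances."""
    values = _as_square(d)
    grouping = _as_labeling(grouping)
    n = values.shape[0]
    if grouping.n != n:
        raise ValueError("grouping must cover every object of the distance matrix")
    d2 = values**2
    iu = np.triu_indices(n, k=1)
    sst = float(d2[iu].sum() / n)
    ssw = 0.0
    for mask in grouping.masks():
        nl = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ssw += sub[np.triu_indices(nl, k=1)].sum() / nl
    ssw = float(ssw)
    ssa = sst - ssw
    return AnovaResult(
        sst=sst,
        ssw=ssw,
        ssa=max(ssa, 0.0) if abs(ssa) < 1e-12 * max(sst, 1.0) else ssa,
        f_stat=math.nan,
        n_objects=n,
        n_groups=grouping.k,
    )


def f_statistic(d, grouping) -> float:
    """Pseudo-F ratio (SSA/(k-1)) / (SSW/(N-k)) for a k-group labelling.

    Perfect separation (SSW = 0 with SSA > 0) returns +inf so it always
    rejects; the fully degenerate SSW = SSA = 0 case returns 0 with a warning.
    """
    grouping = _as_labeling(grouping)
    res = sum_of_squares(d, grouping)
    k, n = res.n_groups, res.n_objects
    if k < 2:
        raise ValueError("F statistic needs at least two groups")
    if n <= k:
        raise ValueError("need more objects than groups")
    if res.ssw <= 0.0:
        if res.ssa > 0.0:
            return math.inf
        warnings.warn(
            "all pairwise distances are zero: F undefined, reported as 0",
            stacklevel=2,
        )
        return 0.0
    return (res.ssa / (k - 1)) / (res.ssw / (n - k))


def permute_distance_matrix(d, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Shuffle a fraction of the off-diagonal distances.

    ceil(fraction * N(N-1)/2) upper-triangle positions are drawn uniformly
    and their values permuted among themselves, then mirrored to the lower
    triangle.  The result stays symmetric, nonnegative, zero-diagonal, but
    generally violates the triangle inequality, so it is not a distance
    matrix in the metric sense.
    """
    values = _as_square(d)
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 objects to permute a distance matrix")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    iu = np.triu_indices(n, k=1)
    m = iu[0].size
    n_sel = math.ceil(fraction * m)
    sel = rng.choice(m, size=n_sel, replace=False)
    flat = values[iu].copy()
    flat[sel] = flat[sel[rng.permutation(n_sel)]]
    out = np.zeros_like(values)
    out[iu] = flat
    out += out.T
    return out


def two_group_cut(values: np.ndarray, method: str) -> np.ndarray:
    """Agglomerate a symmetric dissimilarity matrix and cut into two groups.

    Returns 0/1 labels.  Works on shuffled matrices too: complete and average
    linkage only require symmetry and nonnegativity, not the triangle
    inequality.
    """
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    z = linkage(squareform(values, checks=False), method=method)
    labels = fcluster(z, t=2, criterion="maxclust")
    if np.unique(labels).size != 2:  # tie fallback: split at the top merge
        n = values.shape[0]
        members = {i: [i] for i in range(n)}
        for row, (a, b) in enumerate(z[:-1, :2].astype(int)):
            members[n + row] = members.pop(a) + members.pop(b)
        labels = np.zeros(n, dtype=int)
        labels[members[int(z[-1, 1])]] = 1
        return labels
    return (labels - labels.min()).astype(int)


def permutation_test(
    d,
    observed,
    n_perm: int = 99,
    fraction: float = 0.2,
    min_size: int = 2,
    method: str = "complete",
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Permuted-distance-matrix test of a two-group split.

    Each replicate shuffles ``fraction`` of the distances, re-clusters the
    shuffled matrix into two groups with the given linkage and, if both
    groups reach ``min_size``, records its F statistic.  Replicates failing
    the size threshold are discarded and re-drawn, up to 10 * n_perm
    attempts; the p-value denominator counts valid replicates only.
    """
    values = _as_square(d)
    observed = _as_labeling(observed)
    if observed.k != 2:
        raise ValueError("the observed split must have exactly two groups")
    if rng is None:
        rng = np.random.default_rng()
    f_obs = f_statistic(values, observed)
    f_perm: list[float] = []
    attempts = 0
    cap = 10 * n_perm
    while len(f_perm) < n_perm and attempts < cap:
        attempts += 1
        perm = permute_distance_matrix(values, fraction, rng)
        labels = two_group_cut(perm, method)
        sizes = np.bincount(labels)
        if sizes.min() < min_size:
            continue
        f_perm.append(f_statistic(perm, labels))
    n_valid = len(f_perm)
    if n_valid == 0:
        raise DegenerateNullError(
            "no permutation replicate produced two groups of size >= "
            f"{min_size} in {attempts} attempts; use larger groups or a "
            "smaller minimum group size"
        )
    f_arr = np.asarray(f_perm)
    p = (int(np.sum(f_arr >= f_obs)) + 1) / (n_valid + 1)
    return PermutationResult(
        f_obs=f_obs, f_perm=f_arr, p_value=p, n_valid=n_valid, n_attempted=attempts
    )
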