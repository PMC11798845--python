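"""The multivariate crossmatch two-sample test and the MFV-TT parabola fit.

The crossmatch test compares two multivariate samples without any
distributional assumption: pool the points, pair them by a minimum-weight
non-bipartite perfect matching of inter-point distances, and count the
pairs with one point from each group (A1).  If the groups share one
distribution, group labels are exchangeable given the matching structure,
and A1 has an exact combinatorial null distribution with mean
n0*n1/(N-1); few cross-group pairs indicate the distributions differ, so
the one-sided p-value is P(A1 <= a1_observed).

Here the points are (MFV, transit time) pairs from the two exposure
groups; coordinates are standardized over the pooled sample before
computing Euclidean distances since MFV (au/s) and transit time (s) are
incommensurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, factorial

import networkx as nx
import numpy as np

from .errors import InputError

__all__ = [
    "CrossmatchResult",
    "ParabolaFit",
    "pooled_distance_matrix",
    "optimal_nonbipartite_matching",
    "crossmatch_null_pmf",
    "crossmatch_test",
    "fit_parabola",
]


@dataclass
class CrossmatchResult:
    n0: int
    n1: int
    matching: list[tuple[int, int]]
    a1: int
    null_pmf: dict[int, float]
    p_value: float
    pooled_mean: np.ndarray = field(default=None, repr=False)
    pooled_std: np.ndarray = field(default=None, repr=False)

    @property
    def null_mean(self) -> float:
        """E[A1] under the null; equals n0*n1/(N-1) for even N."""
        return sum(a * p for a, p in self.null_pmf.items())


def pooled_distance_matrix(points0, points1) -> np.ndarray:
    """Euclidean distances between pooled, coordinate-wise standardized points.

    Each coordinate is z-scored (mean 0, unit sample variance) over the
    pooled sample, which makes the matrix invariant to separate affine
    rescaling of each coordinate.  A coordinate with zero pooled variance
    carries no information and is dropped with a warning; if every
    coordinate is degenerate an error is raised.
    """
    p0 = np.atleast_2d(np.asarray(points0, dtype=float))
    p1 = np.atleast_2d(np.asarray(points1, dtype=float))
    if p0.shape[1] != p1.shape[1]:
        raise InputError("point sets must share dimensionality")
    pooled = np.vstack([p0, p1])
    if pooled.shape[0] < 2:
        raise InputError("need at least 2 points in the pool")
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0, ddof=1)
    keep = std > 0
    if not keep.any():
        raise InputError("all coordinates are constant over the pooled sample")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance coordinate(s) before "
            "distance computation",
            RuntimeWarning,
            stacklevel=2,
        )
    z = (pooled[:, keep] - mean[keep]) / std[keep]
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def optimal_nonbipartite_matching(D: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-total-distance perfect matching of the pooled points.

    For an odd number of points a ghost point at distance zero to all
    others is appended; its partner is left unmatched and the ghost pair is
    discarded from the result.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError("distance matrix must be square")
    n = D.shape[0]
    if n < 2:
        raise InputError("need at least 2 points to match")
    if n % 2:
        padded = np.zeros((n + 1, n + 1))
        padded[:n, :n] = D
        D = padded
    m = D.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(m))
    for i in range(m):
        for j in range(i + 1, m):
            graph.add_edge(i, j, weight=float(D[i, j]))
    matching = nx.min_weight_matching(graph, weight="weight")
    pairs = sorted(tuple(sorted(edge)) for edge in matching)
    return [(i, j) for i, j in pairs if j < n]


def crossmatch_null_pmf(n0: int, n1: int) -> dict[int, float]:
    """Exact null distribution of the cross-group pair count A1.

    Under random labeling of N = n0 + n1 matched points (floor(N/2)
    disjoint pairs, plus one unmatched point when N is odd),

        P(A1 = a) = 2^a (N/2)! / [ C(N, n1) ((n0-a)/2)! a! ((n1-a)/2)! ]

    for even N and a with n1 - a even; the odd-N variant sums over the
    label of the unmatched point.  The pmf sums to one and, for even N,
    has mean n0*n1/(N-1).
    """
    if n0 < 1 or n1 < 1:
        raise InputError("both groups must be nonempty")
    N = n0 + n1
    k = N // 2  # matched pairs
    singletons = N - 2 * k  # 0 or 1
    denom = comb(N, n1)
    pmf: dict[int, float] = {}
    for a in range(min(n0, n1) + 1):
        count = 0
        for single_label in ((0,) if singletons == 0 else (0, 1)):
            n1_pairs = n1 - (single_label if singletons else 0)
            n0_pairs = n0 - ((1 - single_label) if singletons else 0)
            rem = n1_pairs - a
            if rem < 0 or rem % 2:
                continue
            b = rem // 2  # pairs with both points in group 1
            c = k - a - b  # pairs with both points in group 0
            if c < 0 or 2 * c + a != n0_pairs:
                continue
            count += factorial(k) // (factorial(a) * factorial(b) * factorial(c)) * 2**a
        if count:
            pmf[a] = count / denom
    return pmf


def crossmatch_test(points0, points1) -> CrossmatchResult:
    """Crossmatch two-sample test on pooled standardized points.

    ``points0`` and ``points1`` are (n, d) arrays (rows are observations,
    e.g. (MFV, transit time) per exam).  Returns the observed cross-group
    pair count, the exact null pmf, and the one-sided p-value
    P(A1 <= a1).
    """
    p0 = np.atleast_2d(np.asarray(points0, dtype=float))
    p1 = np.atleast_2d(np.asarray(points1, dtype=float))
    n0, n1 = p0.shape[0], p1.shape[0]
    if n0 < 2 or n1 < 2:
        raise InputError("each group needs at least 2 points")
    pooled = np.vstack([p0, p1])
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0, ddof=1)
    D = pooled_distance_matrix(p0, p1)
    matching = optimal_nonbipartite_matching(D)
    a1 = sum(1 for i, j in matching if (i < n0) != (j < n0))
    pmf = crossmatch_null_pmf(n0, n1)
    p_value = float(sum(p for a, p in pmf.items() if a <= a1))
    return CrossmatchResult(
        n0=n0,
        n1=n1,
        matching=matching,
        a1=a1,
        null_pmf=pmf,
        p_value=p_value,
        pooled_mean=mean,
        pooled_std=std,
    )


@dataclass
class ParabolaFit:
    """Least-squares fit of TT = c0 + c1*V + c2*V^2 within one group."""

    group: str
    c0: float
    c1: float
    c2: float
    r_squared: float

    def predict(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return self.c0 + self.c1 * v + self.c2 * v**2


def fit_parabola(V, TT, group: str = "") -> ParabolaFit:
    """Ordinary least squares of transit time on (1, MFV, MFV^2)."""
    V = np.asarray(V, dtype=float)
    TT = np.asarray(TT, dtype=float)
    if V.shape != TT.shape or V.ndim != 1:
        raise InputError("V and TT must be paired 1-D arrays")
    if V.size < 4:
        raise InputError("parabola fit needs at least 4 points")
    if np.unique(V).size < 3:
        raise InputError("parabola fit needs at least 3 distinct V values")
    X = np.column_stack([np.ones_like(V), V, V**2])
    coef, _, rank, _ = np.linalg.lstsq(X, TT, rcond=None)
    if rank < 3:
        raise InputError("design matrix is rank-deficient")
    resid = TT - X @ coef
    ss_tot = float(np.sum((TT - TT.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ParabolaFit(group=group, c0=float(coef[0]), c1=float(coef[1]), c2=float(coef[2]), r_squared=r_squared)
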