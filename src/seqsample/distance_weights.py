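"""Distances, distance ranks, and preliminary weight schemes.

The preliminary weight ``w~_k(i)`` is the design-chosen influence of
individual k's sampling outcome on individual i's inclusion probability.
Rows are constrained to sum to one so the realized sample size stays close
to the target m; the run-time bounds that keep probabilities in [0, 1] are
applied later, inside the sampler.

Supported schemes:

``zero``
    All weights zero; inclusion probabilities never move (simple random /
    Poisson-type sampling at pi0).
``uniform``
    1/(n-1) on every other individual: sample-size control without spatial
    balance.
``knn``
    1/k on the k nearest neighbors in auxiliary space, 0 elsewhere: local
    balance, hence well-spread samples.
``group``
    1/(n_g - 1) within the individual's own group: balance within disjoint
    strata.
``linear_rank``
    mu + c * lambda as a linear function of the distance rank c (lambda <= 0),
    clipped at zero and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .population_io import Population

__all__ = [
    "DistanceSpec",
    "WeightScheme",
    "PreliminaryWeights",
    "pairwise_distance",
    "rank_distances",
    "build_weights",
    "whitening_transform",
]


@dataclass
class DistanceSpec:
    """How to measure distance between individuals in auxiliary space."""

    metric: str = "mahalanobis"  # mahalanobis | euclidean | manhattan
    covariance: np.ndarray | None = None  # population covariance of x; estimated if None

    def resolve_covariance(self, x: np.ndarray) -> np.ndarray:
        if self.covariance is not None:
            return np.asarray(self.covariance, dtype=float)
        if x.shape[0] <= x.shape[1]:
            raise ValueError("need n > d_x to estimate the covariance of x")
        return np.cov(x, rowvar=False)


def whitening_transform(cov: np.ndarray) -> np.ndarray:
    """Matrix W with ||W(x_i - x_k)|| equal to the Mahalanobis distance.

    Raises if the covariance is not symmetric positive-definite, with advice
    to regularize (e.g. add a ridge to the diagonal).
    """
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance matrix must be symmetric")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "covariance matrix is singular or indefinite; regularize it "
            "(e.g. cov + eps*I) or drop collinear auxiliary variables"
        ) from err
    # W = inv(L) so that W cov W' = I
    return np.linalg.solve(chol, np.eye(cov.shape[0]))


def whitened_coordinates(pop: Population, spec: DistanceSpec | None = None) -> np.ndarray:
    """Coordinates in which the requested metric becomes plain Euclidean
    (only defined for mahalanobis/euclidean)."""
    spec = spec or DistanceSpec()
    if pop.x is None:
        raise ValueError("population has no auxiliary variables x")
    if spec.metric == "euclidean":
        return pop.x
    if spec.metric == "mahalanobis":
        W = whitening_transform(spec.resolve_covariance(pop.x))
        return pop.x @ W.T
    raise ValueError(f"no Euclidean embedding for metric {spec.metric!r}")


def pairwise_distance(pop: Population, spec: DistanceSpec | None = None) -> np.ndarray:
    """Full symmetric distance matrix between individuals (zero diagonal)."""
    spec = spec or DistanceSpec()
    if pop.x is None:
        raise ValueError("population has no auxiliary variables x")
    x = pop.x
    if spec.metric == "manhattan":
        d = cdist(x, x, metric="cityblock")
    elif spec.metric == "euclidean":
        d = cdist(x, x, metric="euclidean")
    elif spec.metric == "mahalanobis":
        xw = whitened_coordinates(pop, spec)
        d = cdist(xw, xw, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {spec.metric!r}")
    np.fill_diagonal(d, 0.0)
    return d


def rank_distances(distances: np.ndarray) -> np.ndarray:
    """Ascending distance ranks c_k(i) over k != i, for every target i.

    ranks[i, k] is 1 for the individual closest to i, 2 for the second
    closest, ...; ranks[i, i] = 0 by convention.  Exact ties are broken by
    the smaller individual index (stable sort), so ranks are deterministic.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    work = d.copy()
    np.fill_diagonal(work, np.inf)  # self is excluded from ranking
    order = np.argsort(work, axis=1, kind="stable")
    ranks = np.empty((n, n), dtype=np.int64)
    cols = np.arange(n)
    for i in range(n):
        ranks[i, order[i]] = cols + 1
    np.fill_diagonal(ranks, 0)
    return ranks


@dataclass
class WeightScheme:
    """Specification of a preliminary weight scheme (see module docstring)."""

    kind: str = "zero"  # zero | uniform | knn | group | linear_rank
    k: int = 50
    mu: float = 0.0
    lam: float = 0.0
    metric: str = "mahalanobis"

    def __post_init__(self) -> None:
        valid = {"zero", "uniform", "knn", "group", "linear_rank"}
        if self.kind not in valid:
            raise ValueError(f"kind must be one of {sorted(valid)}")
        if self.kind == "knn" and self.k < 1:
            raise ValueError("knn scheme needs k >= 1")
        if self.kind == "linear_rank" and self.lam > 0:
            raise ValueError("linear_rank requires lambda <= 0")


class PreliminaryWeights:
    """Populated preliminary weights w~_k(i), queried row-wise.

    Rows sum to 1 exactly for every kind except ``zero`` (all-zero rows) and
    singleton groups under the ``group`` kind, which fall back to the zero
    (simple random sampling) behavior.
    """

    def __init__(self, kind: str, n: int):
        self.kind = kind
        self.n = n
        self.uniform_value: float | None = None
        self.neighbors: np.ndarray | None = None  # (n, k) ascending indices
        self.knn_value: float | None = None
        self.group_members: dict[int, np.ndarray] | None = None
        self.group_pos: np.ndarray | None = None  # position of i in its group list
        self.group_value: np.ndarray | None = None  # per-individual 1/(n_g-1)
        self.group_of: np.ndarray | None = None
        self.dense: np.ndarray | None = None  # (n, n) for linear_rank

    # -- full row (reference / small-n use) ---------------------------------
    def row(self, i: int) -> np.ndarray:
        """Dense weight vector over all k (entry i is 0)."""
        w = np.zeros(self.n)
        if self.kind == "zero":
            return w
        if self.kind == "uniform":
            w[:] = self.uniform_value
            w[i] = 0.0
            return w
        if self.kind == "knn":
            w[self.neighbors[i]] = self.knn_value
            return w
        if self.kind == "group":
            members = self.group_members[int(self.group_of[i])]
            if members.size > 1:
                w[members] = self.group_value[i]
                w[i] = 0.0
            return w
        return self.dense[i].copy()

    # -- sparse view used by the sampler ------------------------------------
    def sources_before(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices k < i with nonzero weight (ascending) and their weights."""
        if self.kind == "zero":
            return _EMPTY_IDX, _EMPTY_W
        if self.kind == "uniform":
            return self._arange[:i], self._uniform_row[:i]
        if self.kind == "knn":
            nb = self.neighbors[i]
            cut = np.searchsorted(nb, i)
            return nb[:cut], self._knn_row[:cut]
        if self.kind == "group":
            members = self.group_members[int(self.group_of[i])]
            if members.size <= 1:
                return _EMPTY_IDX, _EMPTY_W
            cut = self.group_pos[i]
            return members[:cut], np.full(cut, self.group_value[i])
        w = self.dense[i, :i]
        idx = np.nonzero(w)[0]
        return idx, w[idx]

    def _finalize(self) -> None:
        self._arange = np.arange(self.n, dtype=np.int64)
        if self.kind == "uniform":
            self._uniform_row = np.full(self.n, self.uniform_value)
        if self.kind == "knn":
            self._knn_row = np.full(self.neighbors.shape[1], self.knn_value)


_EMPTY_IDX = np.empty(0, dtype=np.int64)
_EMPTY_W = np.empty(0, dtype=float)


def build_weights(
    pop: Population,
    scheme: WeightScheme,
    ranks: np.ndarray | None = None,
) -> PreliminaryWeights:
    """Populate a weight scheme for a concrete population.

    ``ranks`` (from :func:`rank_distances`) may be supplied to reuse a
    precomputed ranking; otherwise the distances needed by the scheme are
    computed internally (k-NN queries use the whitened-space nearest-neighbor
    index rather than the full n x n matrix).
    """
    n = pop.n
    out = PreliminaryWeights(scheme.kind, n)

    if scheme.kind == "zero":
        pass

    elif scheme.kind == "uniform":
        if n < 2:
            raise ValueError("uniform weights need n >= 2")
        out.uniform_value = 1.0 / (n - 1)

    elif scheme.kind == "knn":
        k = scheme.k
        if k > n - 1:
            raise ValueError("k cannot exceed n - 1")
        if ranks is not None:
            nb = np.argsort(np.where((ranks >= 1) & (ranks <= k), ranks, n + 1), axis=1)[:, :k]
            nb = np.sort(nb, axis=1)
        else:
            from sklearn.neighbors import NearestNeighbors

            coords = whitened_coordinates(pop, DistanceSpec(metric=scheme.metric))
            nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
            idx = nn.kneighbors(coords, return_distance=False)
            # drop self from each row (keep the first k others), vectorized
            mask = idx != np.arange(n)[:, None]
            mask &= mask.cumsum(axis=1) <= k
            nb = idx[mask].reshape(n, k)
            nb.sort(axis=1)
        out.neighbors = nb.astype(np.int64)
        out.knn_value = 1.0 / k

    elif scheme.kind == "group":
        if pop.group is None:
            raise ValueError("group weights need group labels")
        g = pop.group
        out.group_of = g
        out.group_members = {}
        out.group_pos = np.zeros(n, dtype=np.int64)
        out.group_value = np.zeros(n)
        for label in np.unique(g):
            members = np.flatnonzero(g == label)
            out.group_members[int(label)] = members
            out.group_pos[members] = np.arange(members.size)
            if members.size > 1:
                out.group_value[members] = 1.0 / (members.size - 1)

    elif scheme.kind == "linear_rank":
        if ranks is None:
            ranks = rank_distances(pairwise_distance(pop, DistanceSpec(metric=scheme.metric)))
        w = scheme.mu + ranks.astype(float) * scheme.lam
        np.fill_diagonal(w, 0.0)
        w = np.clip(w, 0.0, None)
        np.fill_diagonal(w, 0.0)
        totals = w.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("linear_rank weights vanish for some rows; increase mu")
        out.dense = w / totals[:, None]

    out._finalize()
    return out
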