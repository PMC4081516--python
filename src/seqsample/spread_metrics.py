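"""Voronoi-polytope diagnostic of how well spread a recruited sample is.

Every population individual is assigned to the nearest participant in
auxiliary space (ties split equally among the tied participants).  For a
participant i, ``q_i`` is the sum of initial inclusion probabilities over
its polytope; a sample is well spread when every q_i is close to one.  The
scalar measure aggregates the squared deviations:

    R = (1 / norm) * sum_{i in s} (q_i - 1)^2

The package exposes both normalization conventions: ``per_sample_size``
divides by the number of participants (the convention of the spread
literature this diagnostic comes from, and the package default) and
``per_population_n`` divides by the population size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .distance_weights import DistanceSpec, whitened_coordinates
from .population_io import DesignSpec, Population

__all__ = ["SpreadResult", "voronoi_assign", "spread_R"]

#: Default normalization for R (see module docstring).
DEFAULT_NORMALIZATION = "per_sample_size"


@dataclass
class SpreadResult:
    """Fractional polytope assignment, per-participant q, and the measure R."""

    assignment: np.ndarray  # (n, |s|) fractional membership, rows sum to 1
    sample_indices: np.ndarray
    q: np.ndarray  # (|s|,) polytope sums of initial inclusion probabilities
    R: float
    normalization: str


def _round_sig(d: np.ndarray, digits: int = 12) -> np.ndarray:
    """Round distances to `digits` significant digits so that exact-tie
    splitting is reproducible across BLAS/platform variations."""
    out = d.copy()
    pos = out > 0
    mag = np.floor(np.log10(out[pos]))
    scale = 10.0 ** (digits - 1 - mag)
    out[pos] = np.round(out[pos] * scale) / scale
    return out


def voronoi_assign(
    pop: Population,
    sample: np.ndarray,
    spec: DistanceSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional assignment of every individual to nearest sample member(s).

    ``sample`` is either a boolean/0-1 indicator vector of length n or an
    array of sample indices.  Returns ``(assignment, sample_indices)`` where
    assignment[j, a] is the fraction of individual j belonging to the
    polytope of sample member a; t-way distance ties contribute 1/t each.
    """
    sample = np.asarray(sample)
    if sample.dtype == bool or (sample.ndim == 1 and sample.size == pop.n and set(np.unique(sample)) <= {0, 1}):
        sample_idx = np.flatnonzero(sample)
    else:
        sample_idx = sample.astype(np.int64)
    if sample_idx.size == 0:
        raise ValueError("sample is empty")
    spec = spec or DistanceSpec()
    if spec.metric == "manhattan":
        d = cdist(pop.x, pop.x[sample_idx], metric="cityblock")
    else:
        coords = whitened_coordinates(pop, spec)
        d = cdist(coords, coords[sample_idx], metric="euclidean")
    d = _round_sig(d)
    nearest = d.min(axis=1)
    ties = d <= nearest[:, None]
    assignment = ties / ties.sum(axis=1, keepdims=True)
    return assignment, sample_idx


def spread_R(
    assignment: np.ndarray,
    design: DesignSpec,
    normalization: str = DEFAULT_NORMALIZATION,
    sample_indices: np.ndarray | None = None,
) -> SpreadResult:
    """Aggregate polytope masses into the spread measure R (lower = better)."""
    if normalization not in {"per_sample_size", "per_population_n"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    assignment = np.asarray(assignment, dtype=float)
    n, n_s = assignment.shape
    q = assignment.T @ design.pi0
    denom = n_s if normalization == "per_sample_size" else n
    R = float(np.sum((q - 1.0) ** 2) / denom)
    return SpreadResult(
        assignment=assignment,
        sample_indices=sample_indices if sample_indices is not None else np.arange(n_s),
        q=q,
        R=R,
        normalization=normalization,
    )


def sample_spread(
    pop: Population,
    sample: np.ndarray,
    design: DesignSpec,
    spec: DistanceSpec | None = None,
    normalization: str = DEFAULT_NORMALIZATION,
) -> SpreadResult:
    """Convenience wrapper: Voronoi assignment followed by R."""
    assignment, sample_idx = voronoi_assign(pop, sample, spec)
    return spread_R(assignment, design, normalization, sample_indices=sample_idx)
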