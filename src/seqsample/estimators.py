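"""Horvitz--Thompson estimation of a population total from a recruited sample.

The total Y = sum_i y_i is estimated by Y_hat = sum_{j in s} y_j / pi_j^(0),
with the *initial* inclusion probabilities specified before recruitment.
Its variance estimate needs second-order inclusion probabilities pi_ij,
which the sequential design does not provide in closed form; they are
approximated by the Hajek asymptotic formula

    pi_ij ~= pi_i pi_j * [1 - (1 - pi_i)(1 - pi_j) / d],
    d = sum_k pi_k (1 - pi_k)  over the whole population.

Confidence intervals are Wald intervals at the normal quantile.  Negative
variance estimates (possible for pathological designs) are flagged, never
silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "HTResult",
    "ht_total",
    "hajek_joint_inclusion",
    "hajek_joint_matrix",
    "ht_variance",
    "ht_confidence",
    "estimate_total",
]


@dataclass
class HTResult:
    y_hat: float
    var_hat: float
    ci: tuple[float, float] | None
    level: float
    variance_defined: bool
    covered: bool | None = None  # set when the true total is known (simulations)


def ht_total(y: np.ndarray, pi0: np.ndarray) -> float:
    """sum of y_j / pi_j over participants (arrays restricted to the sample)."""
    y = np.asarray(y, dtype=float)
    pi0 = np.asarray(pi0, dtype=float)
    if (pi0 <= 0).any():
        raise ValueError("participants must have positive inclusion probability")
    return float(np.sum(y / pi0))


def _hajek_d(pi0_pop: np.ndarray) -> float:
    d = float(np.sum(pi0_pop * (1.0 - pi0_pop)))
    if d <= 0:
        raise ValueError("degenerate design: sum pi(1-pi) is zero")
    return d


def hajek_joint_inclusion(pi0_pop: np.ndarray, i: int, j: int) -> float:
    """Approximate joint inclusion probability of individuals i and j.

    ``pi0_pop`` are the initial inclusion probabilities of the *whole*
    population (the normalizer d sums over everyone).
    """
    pi0_pop = np.asarray(pi0_pop, dtype=float)
    d = _hajek_d(pi0_pop)
    pi, pj = pi0_pop[i], pi0_pop[j]
    return float(pi * pj * (1.0 - (1.0 - pi) * (1.0 - pj) / d))


def hajek_joint_matrix(pi0_pop: np.ndarray, sample_idx: np.ndarray) -> np.ndarray:
    """Matrix of approximated pi_ij over sampled pairs; diagonal pi_ii = pi_i."""
    pi0_pop = np.asarray(pi0_pop, dtype=float)
    d = _hajek_d(pi0_pop)
    pi_s = pi0_pop[np.asarray(sample_idx, dtype=np.int64)]
    one_minus = 1.0 - pi_s
    pij = np.outer(pi_s, pi_s) * (1.0 - np.outer(one_minus, one_minus) / d)
    np.fill_diagonal(pij, pi_s)
    return pij


def ht_variance(y: np.ndarray, pi0: np.ndarray, pi_pair: np.ndarray) -> float:
    """Horvitz--Thompson variance estimate over sampled pairs.

    ``y`` and ``pi0`` are restricted to the participants, ``pi_pair`` is the
    matching matrix of joint inclusion probabilities (diagonal = pi_i).
    """
    y = np.asarray(y, dtype=float)
    pi0 = np.asarray(pi0, dtype=float)
    pi_pair = np.asarray(pi_pair, dtype=float)
    if pi_pair.shape != (len(y), len(y)):
        raise ValueError("pi_pair must be a square matrix over the sample")
    if (pi_pair <= 0).any():
        raise ValueError("zero joint inclusion probability for a sampled pair")
    w = (pi_pair - np.outer(pi0, pi0)) / pi_pair
    t = y / pi0
    return float(t @ w @ t)


def ht_confidence(y_hat: float, var_hat: float, level: float = 0.95) -> HTResult:
    """Wald interval y_hat +/- z * sqrt(var_hat); undefined if var_hat < 0."""
    if var_hat < 0:
        return HTResult(y_hat, var_hat, None, level, variance_defined=False)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var_hat)
    return HTResult(y_hat, var_hat, (y_hat - half, y_hat + half), level, True)


def estimate_total(
    y_pop: np.ndarray,
    s: np.ndarray,
    pi0_pop: np.ndarray,
    level: float = 0.95,
    true_total: float | None = None,
) -> HTResult:
    """Full pipeline on one recruited sample: Y_hat, Hajek pi_ij, variance, CI."""
    s = np.asarray(s)
    sample_idx = np.flatnonzero(s == 1)
    y_s = np.asarray(y_pop, dtype=float)[sample_idx]
    pi_s = np.asarray(pi0_pop, dtype=float)[sample_idx]
    y_hat = ht_total(y_s, pi_s)
    pij = hajek_joint_matrix(pi0_pop, sample_idx)
    var_hat = ht_variance(y_s, pi_s, pij)
    res = ht_confidence(y_hat, var_hat, level)
    if true_total is not None and res.ci is not None:
        res.covered = bool(res.ci[0] <= true_total <= res.ci[1])
    return res
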