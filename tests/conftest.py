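"""Shared fixtures and reference (oracle) implementations for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from seqsample import (
    ParticipationTruth,
    Population,
    PreliminaryWeights,
    ResponseOracle,
)
from seqsample.sampler_core import clamp_weight


@pytest.fixture
def tiny_pop() -> Population:
    """Five individuals with 2-d auxiliary/covariate structure."""
    rng = np.random.default_rng(7)
    return Population(
        ids=np.arange(1, 6),
        x=rng.standard_normal((5, 2)),
        z=rng.standard_normal((5, 2)),
    )


@pytest.fixture
def grouped_pop() -> Population:
    g = np.array([1, 1, 2, 2, 2, 3, 1, 2])
    y = np.array([0, 1, 1, 0, 1, 0, 0, 1])
    return Population(ids=np.arange(1, 9), group=g, y=y)


def dense_weights(W: np.ndarray) -> PreliminaryWeights:
    """Wrap an arbitrary dense preliminary-weight matrix (rows = targets)."""
    W = np.asarray(W, dtype=float)
    pw = PreliminaryWeights("linear_rank", W.shape[0])
    pw.dense = W
    pw._finalize()
    return pw


def random_row_stochastic(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random nonnegative weights with zero diagonal and unit row sums."""
    W = rng.random((n, n))
    np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)


def rowwise_reference(pi0: np.ndarray, W: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Row-wise sequential update oracle (immediate responses).

    After evaluating individual i with outcome s_i, every not-yet-evaluated
    j has its inclusion probability moved by -(s_i - pi_i) * w, with w the
    preliminary weight W[j, i] clamped by the admissible-interval bounds.
    Returns the probabilities pi_i^(i-1) actually used at each evaluation.
    """
    n = len(pi0)
    pi = np.asarray(pi0, dtype=float).copy()
    used = np.empty(n)
    for i in range(n):
        used[i] = pi[i]
        for j in range(i + 1, n):
            w = clamp_weight(W[j, i], pi[j], pi[i])
            pi[j] = pi[j] - (s[i] - pi[i]) * w
            pi[j] = min(max(pi[j], 0.0), 1.0)
    return used


def constant_phi_oracle(pop: Population, phi: float, seed, delay_mean: float = 0.0) -> ResponseOracle:
    """Response oracle with constant participation probability phi.

    Implemented through a one-group truth so it works for any population.
    """
    truth = ParticipationTruth(group_probs=np.array([phi]), delay_mean=delay_mean)
    as_one_group = Population(ids=pop.ids, x=pop.x, z=pop.z,
                              group=np.ones(pop.n, dtype=int), y=pop.y)
    return ResponseOracle(truth, as_one_group, seed)


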