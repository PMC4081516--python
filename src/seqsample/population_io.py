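"""Population tables and the two benchmark synthetic populations.

A :class:`Population` is the finite list of individuals the recruiter walks
through: auxiliary variables ``x`` (known a priori, used to measure spread),
participation covariates ``z`` or a categorical group label, and an optional
binary outcome ``y``.  The stored row order *is* the evaluation order of the
sequential sampler.

Two generators reproduce the benchmark study conditions:

* :func:`generate_sim1_population` -- continuous 4-d auxiliary and covariate
  vectors, logistic participation with intercept 1 and weights
  (0.3, -0.7, 0.1, 0.4), Poisson(15) response delays.
* :func:`generate_sim2_population` -- five unequally sized groups with
  group-wise participation 50--90% and outcome prevalence 10--50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Population",
    "DesignSpec",
    "ParticipationTruth",
    "ColumnSchema",
    "read_population",
    "write_population",
    "generate_sim1_population",
    "generate_sim2_population",
    "make_design_sim2",
    "SIM1_COV",
    "SIM1_ALPHA",
    "SIM1_BETA",
    "SIM2_GROUP_PROBS",
    "SIM2_PARTICIPATION",
    "SIM2_OUTCOME_PREVALENCE",
    "SIM2_PI0_BY_GROUP",
    "DEFAULT_DELAY_MEAN",
]

#: Covariance of the 4-d auxiliary vector x in simulation design 1.
SIM1_COV = np.array(
    [
        [1.00, 0.20, -0.50, 0.30],
        [0.20, 1.00, 0.20, -0.40],
        [-0.50, 0.20, 1.00, -0.20],
        [0.30, -0.40, -0.20, 1.00],
    ]
)
SIM1_ALPHA = 1.0
SIM1_BETA = np.array([0.3, -0.7, 0.1, 0.4])

SIM2_GROUP_PROBS = np.array([0.40, 0.20, 0.20, 0.10, 0.10])
SIM2_PARTICIPATION = np.array([0.50, 0.60, 0.70, 0.80, 0.90])
SIM2_OUTCOME_PREVALENCE = np.array([0.10, 0.20, 0.30, 0.40, 0.50])
#: Initial inclusion probability per group: oversample the small groups so
#: that each group is expected with equal frequency among participants.
SIM2_PI0_BY_GROUP = {1: 0.05, 2: 0.10, 3: 0.10, 4: 0.20, 5: 0.20}

#: Expectation of the Poisson response-delay distribution (in evaluations).
DEFAULT_DELAY_MEAN = 15.0


@dataclass
class Population:
    """A finite population, one row per individual, in evaluation order."""

    ids: np.ndarray
    x: np.ndarray | None = None  # (n, d_x) continuous auxiliary variables
    z: np.ndarray | None = None  # (n, d_z) participation covariates
    group: np.ndarray | None = None  # (n,) integer labels 1..G
    y: np.ndarray | None = None  # (n,) binary outcome, optional

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if self.ids.ndim != 1 or self.ids.size == 0:
            raise ValueError("ids must be a non-empty 1-d sequence")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual identifiers")
        n = len(self.ids)
        for name in ("x", "z"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.atleast_2d(np.asarray(arr, dtype=float))
                if arr.shape[0] == 1 and n > 1:
                    arr = arr.T
                if arr.shape[0] != n:
                    raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
                setattr(self, name, arr)
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=int)
            if self.group.shape != (n,):
                raise ValueError("group label must be one integer per individual")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (n,):
                raise ValueError("y must be one value per individual")
            if not np.isin(self.y, (0, 1)).all():
                raise ValueError("y must be binary (0/1)")
            self.y = self.y.astype(int)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d_x(self) -> int:
        return 0 if self.x is None else self.x.shape[1]

    @property
    def d_z(self) -> int:
        return 0 if self.z is None else self.z.shape[1]


@dataclass
class DesignSpec:
    """Initial inclusion probabilities pi0 and the target sample size m.

    The pi0 sum to m for a fixed-size design.  Group-proportional designs
    (e.g. the five-group benchmark) have a random, generally non-integer
    sum because pi0 is specified per group; there ``m`` is recorded as
    ``round(sum(pi0))`` and only the per-individual pi0 drive the sampler.
    """

    pi0: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.pi0 = np.asarray(self.pi0, dtype=float)
        if self.pi0.ndim != 1:
            raise ValueError("pi0 must be 1-d")
        if (self.pi0 < 0).any() or (self.pi0 > 1).any():
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        if self.m <= 0:
            raise ValueError("target sample size m must be positive")

    @classmethod
    def equal(cls, n: int, m: int) -> "DesignSpec":
        """Equal probabilities m/n for a representative ('miniature') sample."""
        spec = cls(np.full(n, m / n), m)
        spec.require_integer_total()
        return spec

    @classmethod
    def from_pi0(cls, pi0: Sequence[float], require_integer: bool = True) -> "DesignSpec":
        pi0 = np.asarray(pi0, dtype=float)
        total = pi0.sum()
        spec = cls(pi0, int(round(total)))
        if require_integer:
            spec.require_integer_total()
        return spec

    def require_integer_total(self, tol: float = 1e-9) -> None:
        total = self.pi0.sum()
        if abs(total - round(total)) > tol:
            raise ValueError(f"sum of pi0 ({total}) is not an integer sample size")

    @property
    def total(self) -> float:
        return float(self.pi0.sum())


@dataclass
class ParticipationTruth:
    """Ground-truth participation process used by simulation oracles."""

    alpha_true: float | None = None
    beta_true: np.ndarray | None = None
    group_probs: np.ndarray | None = None  # indexed by group label - 1
    delay_mean: float = DEFAULT_DELAY_MEAN

    def __post_init__(self) -> None:
        if self.beta_true is not None:
            self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.group_probs is not None:
            self.group_probs = np.asarray(self.group_probs, dtype=float)
            if ((self.group_probs <= 0) | (self.group_probs > 1)).any():
                raise ValueError("group participation probabilities must lie in (0, 1]")
        if self.delay_mean < 0:
            raise ValueError("delay_mean must be nonnegative")

    def true_phi(self, pop: Population) -> np.ndarray:
        """True participation probability phi_i = p(s_i=1 | b_i=1) per individual."""
        if self.group_probs is not None:
            if pop.group is None:
                raise ValueError("group-wise truth requires group labels")
            return self.group_probs[pop.group - 1]
        if self.alpha_true is None or self.beta_true is None:
            raise ValueError("incomplete participation truth")
        if pop.z is None:
            raise ValueError("covariate truth requires z")
        eta = self.alpha_true + pop.z @ self.beta_true
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ColumnSchema:
    """Declared column mapping for delimited population files."""

    id: str = "id"
    x: Sequence[str] = ()
    z: Sequence[str] = ()
    group: str | None = None
    y: str | None = None


def _schema_from(schema: ColumnSchema | Mapping) -> ColumnSchema:
    if isinstance(schema, ColumnSchema):
        return schema
    return ColumnSchema(**dict(schema))


def read_population(path: str | Path, schema: ColumnSchema | Mapping) -> Population:
    """Read a population CSV, preserving file row order as the list order."""
    schema = _schema_from(schema)
    df = pd.read_csv(path)
    needed = [schema.id, *schema.x, *schema.z]
    if schema.group:
        needed.append(schema.group)
    if schema.y:
        needed.append(schema.y)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns in {path}: {missing}")
    for col in (*schema.x, *schema.z):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"column {col!r} must be numeric")
    return Population(
        ids=df[schema.id].to_numpy(),
        x=df[list(schema.x)].to_numpy(float) if schema.x else None,
        z=df[list(schema.z)].to_numpy(float) if schema.z else None,
        group=df[schema.group].to_numpy(int) if schema.group else None,
        y=df[schema.y].to_numpy(int) if schema.y else None,
    )


def write_population(pop: Population, path: str | Path, schema: ColumnSchema | Mapping | None = None) -> ColumnSchema:
    """Write a population as CSV; returns the schema used (default names)."""
    if schema is None:
        schema = ColumnSchema(
            x=[f"x{j + 1}" for j in range(pop.d_x)],
            z=[f"z{j + 1}" for j in range(pop.d_z)],
            group="group" if pop.group is not None else None,
            y="y" if pop.y is not None else None,
        )
    schema = _schema_from(schema)
    data: dict = {schema.id: pop.ids}
    for j, col in enumerate(schema.x):
        data[col] = pop.x[:, j]
    for j, col in enumerate(schema.z):
        data[col] = pop.z[:, j]
    if schema.group:
        data[schema.group] = pop.group
    if schema.y:
        data[schema.y] = pop.y
    pd.DataFrame(data).to_csv(path, index=False)
    return schema


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_sim1_population(n: int, seed) -> tuple[Population, ParticipationTruth]:
    """Continuous benchmark population: 4-d x ~ MVN(0, SIM1_COV), z ~ MVN(0, I4).

    Participation truth: logistic in z with intercept 1 and weights
    (0.3, -0.7, 0.1, 0.4); response delays Poisson with mean 15.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    z = rng.standard_normal((n, 4))
    chol = np.linalg.cholesky(SIM1_COV)
    x = rng.standard_normal((n, 4)) @ chol.T
    pop = Population(ids=np.arange(1, n + 1), x=x, z=z)
    truth = ParticipationTruth(alpha_true=SIM1_ALPHA, beta_true=SIM1_BETA.copy(),
                               delay_mean=DEFAULT_DELAY_MEAN)
    return pop, truth


def generate_sim2_population(n: int, seed) -> tuple[Population, ParticipationTruth]:
    """Categorical benchmark population: five groups with unequal frequency.

    Group frequencies (40, 20, 20, 10, 10)%, group-wise participation
    (50, ..., 90)% and outcome prevalence (10, ..., 50)%; delays Poisson(15).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    g = rng.choice(np.arange(1, 6), size=n, p=SIM2_GROUP_PROBS)
    y = (rng.random(n) < SIM2_OUTCOME_PREVALENCE[g - 1]).astype(int)
    pop = Population(ids=np.arange(1, n + 1), group=g, y=y)
    truth = ParticipationTruth(group_probs=SIM2_PARTICIPATION.copy(),
                               delay_mean=DEFAULT_DELAY_MEAN)
    return pop, truth


def make_design_sim2(pop: Population) -> DesignSpec:
    """Group-proportional initial inclusion probabilities for the 5-group design."""
    if pop.group is None:
        raise ValueError("population has no group labels")
    unknown = set(np.unique(pop.group)) - set(SIM2_PI0_BY_GROUP)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    lut = np.zeros(6)
    for g, p in SIM2_PI0_BY_GROUP.items():
        lut[g] = p
    return DesignSpec.from_pi0(lut[pop.group], require_integer=False)


def expected_sim2_total(n: int) -> float:
    """Analytic E(Y) = n * sum_g p(y=1|g) p(g) for the five-group design."""
    return float(n * (SIM2_OUTCOME_PREVALENCE * SIM2_GROUP_PROBS).sum())
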