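"""The adaptive list sequential sampling loop.

Individuals are evaluated once each, in list order.  Evaluating individual i
means:

1. compute the current inclusion probability pi_i^(i-1) with the bounded
   column-wise update, substituting phi_hat_k * b_k for any participation
   indicator that is still pending (invited, no response yet);
2. invite with probability pi_tilde = min(1, pi_i^(i-1) / phi_hat_i), drawn
   from an independent decision stream;
3. collect any responses that become observable at this evaluation;
4. if new responses arrived, refit the Bayesian participation posterior on
   all responded invitees.

Invitation decisions and the response process (participation draws and
Poisson delays) use two independent random streams, so competing weight
schemes can be compared against identical response randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import column_sweep
from .distance_weights import PreliminaryWeights
from .participation_model import Responders
from .population_io import DesignSpec, ParticipationTruth, Population

__all__ = [
    "ResponseOracle",
    "SamplerState",
    "RunResult",
    "AdaptiveListSampler",
    "clamp_weight",
    "invite_probability",
    "current_inclusion_probability",
    "run",
]


def clamp_weight(w_tilde: float, pi_target: float, pi_source: float) -> float:
    """Bound a preliminary weight so the update keeps probabilities in [0, 1].

    Returns min(w~, pi_target / (1 - pi_source), (1 - pi_target) / pi_source),
    with a ratio treated as +inf when its denominator is zero and its
    numerator positive (the limit of the admissible-weight interval).
    """
    if w_tilde < 0:
        raise ValueError("preliminary weights must be nonnegative")
    b1 = pi_target / (1.0 - pi_source) if pi_source < 1.0 else np.inf
    b2 = (1.0 - pi_target) / pi_source if pi_source > 0.0 else np.inf
    return min(w_tilde, b1, b2)


def invite_probability(pi_current: float, phi_hat_i: float) -> float:
    """Inclusion probability inflated by 1/phi_hat and capped at one."""
    if phi_hat_i <= 0:
        raise ValueError("phi_hat must be positive")
    return min(1.0, pi_current / phi_hat_i)


class ResponseOracle:
    """Simulated response process: participation draws plus Poisson delays.

    All participation outcomes and delays are drawn up front from the
    oracle's own stream, so two samplers driven by the same oracle seed face
    identical response randomness.  An individual invited at evaluation i
    becomes observable after evaluation i + t_i (t_i = 0: observable from
    the next evaluation on).
    """

    def __init__(self, truth: ParticipationTruth, pop: Population, seed):
        rng = np.random.default_rng(seed)
        self.truth = truth
        self.phi_true = truth.true_phi(pop)
        n = pop.n
        self._would_participate = rng.random(n) < self.phi_true
        self.delays = rng.poisson(truth.delay_mean, size=n)
        self._delivered = np.zeros(n, dtype=bool)
        self._invited = np.zeros(n, dtype=bool)
        self._due_at: dict[int, list[int]] = {}  # evaluation -> invitees due
        self._cleared = -1  # evaluations processed so far

    def invite(self, i: int, eval_index: int) -> None:
        if self._invited[i]:
            raise RuntimeError(f"individual {i} invited twice")
        self._invited[i] = True
        self._due_at.setdefault(eval_index + int(self.delays[i]), []).append(i)

    def due_responses(self, eval_index: int) -> list[tuple[int, int]]:
        """Responses observable once evaluation ``eval_index`` has completed."""
        out = []
        for e in range(self._cleared + 1, eval_index + 1):
            for j in self._due_at.pop(e, ()):
                self._delivered[j] = True
                out.append((j, int(self._would_participate[j])))
        self._cleared = max(self._cleared, eval_index)
        return out

    def drain(self) -> list[tuple[int, int]]:
        """Resolve every outstanding invitation (end of the recruitment period)."""
        out = []
        for e in sorted(self._due_at):
            for j in self._due_at[e]:
                self._delivered[j] = True
                out.append((j, int(self._would_participate[j])))
        self._due_at.clear()
        return out


@dataclass
class SamplerState:
    """Mutable per-run state of the sequential sampler."""

    n: int
    cursor: int = 0
    b: np.ndarray = None  # invitation indicators
    s: np.ndarray = None  # participation indicators (valid where resolved)
    resolved: np.ndarray = None  # response observed (b=0 counts as resolved)
    e: np.ndarray = None  # effective outcome: s if resolved else phi_hat*b
    pi_hist: np.ndarray = None  # pi_k^(k-1) for evaluated k
    pi_tilde: np.ndarray = None  # invitation probability used at each evaluation
    phi_used: np.ndarray = None  # phi_hat_i^(i-1) at each evaluation
    pending: list = field(default_factory=list)
    shortfall: int = 0  # evaluations where pi/phi_hat exceeded 1 (capped)

    def __post_init__(self) -> None:
        n = self.n
        self.b = np.zeros(n, dtype=np.int8)
        self.s = np.zeros(n, dtype=np.int8)
        self.resolved = np.zeros(n, dtype=bool)
        self.e = np.zeros(n)
        self.pi_hist = np.full(n, np.nan)
        self.pi_tilde = np.full(n, np.nan)
        self.phi_used = np.full(n, np.nan)


def current_inclusion_probability(
    j: int,
    state: SamplerState,
    design: DesignSpec,
    weights: PreliminaryWeights,
) -> float:
    """pi_j^(j-1): the column-wise bounded update over all evaluated k < j.

    Pending responders enter through ``state.e`` as phi_hat_k * b_k; the
    caller is responsible for having refreshed those entries with the latest
    posterior.
    """
    idx, w = weights.sources_before(j)
    if idx.size == 0:
        return float(design.pi0[j])
    pi = column_sweep(float(design.pi0[j]), idx, w, state.e, state.pi_hist)
    if not 0.0 <= pi <= 1.0:  # pragma: no cover - guarded in the kernel
        raise AssertionError(f"inclusion probability {pi} outside [0,1] at j={j}")
    return float(pi)


@dataclass
class RunResult:
    """Trace of one recruitment run."""

    b: np.ndarray
    s: np.ndarray
    pi_hist: np.ndarray
    pi_tilde: np.ndarray
    phi_used: np.ndarray
    n_participants: int
    n_invited: int
    shortfall: int
    responder_log: list  # (evaluation, individual, s) in arrival order

    @property
    def sample_indices(self) -> np.ndarray:
        return np.flatnonzero(self.s == 1)


class AdaptiveListSampler:
    """Drives one recruitment run; see the module docstring for the step logic."""

    def __init__(
        self,
        pop: Population,
        design: DesignSpec,
        weights: PreliminaryWeights,
        oracle: ResponseOracle,
        model,
        seed,
    ):
        if len(design.pi0) != pop.n:
            raise ValueError("design and population sizes differ")
        self.pop = pop
        self.design = design
        self.weights = weights
        self.oracle = oracle
        self.model = model
        self.rng = np.random.default_rng(seed)  # invitation-decision stream
        self.state = SamplerState(pop.n)
        self.X = model.design_matrix(pop)
        self._resp_idx: list[int] = []
        self._resp_s: list[int] = []
        self.responder_log: list[tuple[int, int, int]] = []
        # phi_hat cache, invalidated per individual by posterior version
        self._phi_vals = np.zeros(pop.n)
        self._phi_ver = np.full(pop.n, -1, dtype=np.int64)

    def _phi_hat(self, indices: list[int]) -> np.ndarray:
        """phi_hat under the current posterior, cached per individual."""
        ver = self.model.version
        stale = [j for j in indices if self._phi_ver[j] != ver]
        if stale:
            self._phi_vals[stale] = self.model.phi_from_design(self.X[stale])
            self._phi_ver[stale] = ver
        return self._phi_vals[indices]

    # -- one evaluation -----------------------------------------------------
    def step(self) -> None:
        st = self.state
        i = st.cursor
        if i >= self.pop.n:
            raise RuntimeError("all individuals already evaluated")

        # phi_hat^(i-1) for the pending invitees and the current individual
        phi = self._phi_hat(st.pending + [i])
        if st.pending:
            st.e[st.pending] = phi[:-1]
        phi_i = float(phi[-1])

        pi_i = current_inclusion_probability(i, st, self.design, self.weights)
        raw = pi_i / phi_i
        if raw > 1.0:
            st.shortfall += 1
        pi_tilde = invite_probability(pi_i, phi_i)

        invited = self.rng.random() < pi_tilde
        if invited:
            st.b[i] = 1
            self.oracle.invite(i, i)
            st.pending.append(i)
            st.e[i] = phi_i  # expected outcome until the response arrives
        else:
            st.resolved[i] = True  # s_i = 0 known immediately
            st.e[i] = 0.0

        arrivals = self.oracle.due_responses(i)
        for j, s_j in arrivals:
            st.s[j] = s_j
            st.resolved[j] = True
            st.e[j] = float(s_j)
            st.pending.remove(j)
            self._resp_idx.append(j)
            self._resp_s.append(s_j)
            self.responder_log.append((i, j, s_j))
        if arrivals:
            self._refit()

        st.pi_hist[i] = pi_i
        st.pi_tilde[i] = pi_tilde
        st.phi_used[i] = phi_i
        st.cursor += 1

    def _refit(self) -> None:
        responders = Responders(self.X[self._resp_idx], np.array(self._resp_s, dtype=float))
        self.model.fit(responders)

    # -- full run -------------------------------------------------------------
    def run(self) -> RunResult:
        for _ in range(self.pop.n):
            self.step()
        st = self.state
        # recruitment list exhausted: wait out the outstanding responses
        for j, s_j in self.oracle.drain():
            st.s[j] = s_j
            st.resolved[j] = True
            st.e[j] = float(s_j)
            st.pending.remove(j)
            self._resp_idx.append(j)
            self._resp_s.append(s_j)
            self.responder_log.append((self.pop.n, j, s_j))
        return RunResult(
            b=st.b.copy(),
            s=st.s.copy(),
            pi_hist=st.pi_hist.copy(),
            pi_tilde=st.pi_tilde.copy(),
            phi_used=st.phi_used.copy(),
            n_participants=int(st.s.sum()),
            n_invited=int(st.b.sum()),
            shortfall=st.shortfall,
            responder_log=list(self.responder_log),
        )


def run(
    pop: Population,
    design: DesignSpec,
    weights: PreliminaryWeights,
    oracle: ResponseOracle,
    model,
    seed,
) -> RunResult:
    """Evaluate all n individuals once, in list order; returns the full trace."""
    return AdaptiveListSampler(pop, design, weights, oracle, model, seed).run()
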