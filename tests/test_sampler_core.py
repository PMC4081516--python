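"""Sequential sampler: bounds, updates, reductions, and exactness checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqsample import (
    AdaptiveListSampler,
    DesignSpec,
    FixedParticipationModel,
    ParticipationModel,
    ParticipationTruth,
    Population,
    ResponseOracle,
    WeightScheme,
    build_weights,
    clamp_weight,
    invite_probability,
    run,
)
from seqsample.sampler_core import SamplerState, current_inclusion_probability

from conftest import (
    constant_phi_oracle,
    dense_weights,
    random_row_stochastic,
    rowwise_reference,
)


class TestClampWeight:
    def test_not_binding(self):
        assert clamp_weight(0.02, 0.1, 0.1) == pytest.approx(0.02)

    def test_symmetric_case(self):
        assert clamp_weight(1.0, 0.5, 0.5) == pytest.approx(1.0)

    def test_first_bound_binds(self):
        assert clamp_weight(0.5, 0.1, 0.1) == pytest.approx(1 / 9)

    def test_source_probability_one(self):
        # the pi/(1-pi_source) ratio degenerates; the other bound still applies
        assert clamp_weight(2.0, 0.4, 1.0) == pytest.approx(0.6)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            clamp_weight(-0.1, 0.5, 0.5)

    @given(
        st.floats(0, 5), st.floats(0, 1), st.floats(0, 1), st.integers(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_update_stays_in_unit_interval(self, w, pi_t, pi_s, s):
        wc = clamp_weight(w, pi_t, pi_s)
        new_pi = pi_t - (s - pi_s) * wc
        assert -1e-12 <= new_pi <= 1 + 1e-12


class TestInviteProbability:
    def test_inflation(self):
        assert invite_probability(0.25, 0.5) == pytest.approx(0.5)

    def test_cap_at_one(self):
        assert invite_probability(0.25, 0.1) == pytest.approx(1.0)

    def test_full_participation(self):
        assert invite_probability(0.25, 1.0) == pytest.approx(0.25)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            invite_probability(0.25, 0.0)


def _two_person_state(e1: float, pi1_hist: float = 0.5) -> SamplerState:
    st_ = SamplerState(2)
    st_.pi_hist[0] = pi1_hist
    st_.e[0] = e1
    st_.resolved[0] = True
    st_.cursor = 1
    return st_


class TestCurrentInclusionProbability:
    def test_zero_weights_leave_pi_unchanged(self):
        design = DesignSpec(np.array([0.5, 0.5]), 1)
        pop = Population(ids=[1, 2], x=np.array([[0.0], [1.0]]))
        w = build_weights(pop, WeightScheme(kind="zero"))
        assert current_inclusion_probability(1, _two_person_state(1.0), design, w) == 0.5

    def test_one_of_two_complementarity(self):
        # m=1 of n=2 with full weight: the second decision is forced
        design = DesignSpec(np.array([0.5, 0.5]), 1)
        w = dense_weights(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert current_inclusion_probability(1, _two_person_state(1.0), design, w) == pytest.approx(0.0)
        assert current_inclusion_probability(1, _two_person_state(0.0), design, w) == pytest.approx(1.0)

    def test_pending_expectation_equal_to_prior_means_no_change(self):
        # b_1=1 pending with phi_hat = pi_1^(0): expected outcome equals the
        # stored probability, so the update moves nothing
        design = DesignSpec(np.array([0.5, 0.5]), 1)
        w = dense_weights(np.array([[0.0, 1.0], [1.0, 0.0]]))
        st_ = _two_person_state(0.5)
        st_.resolved[0] = False
        st_.b[0] = 1
        assert current_inclusion_probability(1, st_, design, w) == pytest.approx(0.5)


def _population(n, seed):
    rng = np.random.default_rng(seed)
    return Population(ids=np.arange(n), x=rng.standard_normal((n, 2)),
                      z=rng.standard_normal((n, 2)))


class TestColumnRowEquivalence:
    """With immediate responses, the column-wise update must reproduce the
    row-wise sequential update exactly, clamping included."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances(self, seed):
        n = 15
        rng = np.random.default_rng(seed)
        pop = _population(n, seed)
        pi0 = rng.uniform(0.05, 0.9, size=n)
        design = DesignSpec(pi0, max(1, int(round(pi0.sum()))))
        W = random_row_stochastic(n, rng)
        # inflate some weights so the clamp genuinely binds
        W[rng.random((n, n)) < 0.2] *= 5
        np.fill_diagonal(W, 0.0)
        weights = dense_weights(W)
        phi = 0.7
        oracle = constant_phi_oracle(pop, phi, seed + 1000)
        result = run(pop, design, weights, oracle, FixedParticipationModel(phi), seed + 2000)
        expected = rowwise_reference(pi0, W, result.s.astype(float))
        np.testing.assert_allclose(result.pi_hist, expected, atol=1e-12)

    def test_probabilities_always_in_unit_interval(self):
        n = 15
        rng = np.random.default_rng(99)
        pop = _population(n, 99)
        pi0 = rng.uniform(0.01, 0.99, size=n)
        design = DesignSpec(pi0, max(1, int(round(pi0.sum()))))
        W = random_row_stochastic(n, rng) * 10  # heavy clamping regime
        weights = dense_weights(W)
        oracle = constant_phi_oracle(pop, 0.6, 7)
        result = run(pop, design, weights, oracle, FixedParticipationModel(0.6), 8)
        assert np.all(result.pi_hist >= 0) and np.all(result.pi_hist <= 1)


class TestConservation:
    def test_mass_conserved_each_step(self):
        """Full immediate response and, for every evaluated individual, its
        weights over the not-yet-evaluated individuals summing to one: after
        every evaluation, realized outcomes plus remaining probability mass
        equal the target m exactly (no clamp or cap active)."""
        n = 12
        pop = _population(n, 21)
        pi0 = np.full(n, 0.5)
        design = DesignSpec(pi0, 6)
        # source i spreads its outcome equally over the remaining n-1-i
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i + 1:, i] = 1.0 / (n - 1 - i)
        sampler = AdaptiveListSampler(
            pop, design, dense_weights(W), constant_phi_oracle(pop, 1.0, 3),
            FixedParticipationModel(1.0), 4,
        )
        # row-wise bookkeeping of the full probability vector
        pi = pi0.astype(float).copy()
        for i in range(n):
            sampler.step()
            s_i = float(sampler.state.s[i])
            for j in range(i + 1, n):
                w = clamp_weight(W[j, i], pi[j], pi[i])
                assert w == pytest.approx(W[j, i]), "clamp unexpectedly active"
                pi[j] -= (s_i - pi[i]) * w
            pi[i] = s_i
            assert np.sum(pi) == pytest.approx(6.0, abs=1e-9)


class TestReductions:
    def test_poisson_sampling_reduction(self):
        # phi = 1, zero delays, zero weights: independent Bernoulli(pi0)
        # invitations, every invitee participates
        n = 2000
        pop = _population(n, 31)
        design = DesignSpec.equal(n, 200)
        w = build_weights(pop, WeightScheme(kind="zero"))
        oracle = constant_phi_oracle(pop, 1.0, 5)
        result = run(pop, design, w, oracle, FixedParticipationModel(1.0), 6)
        np.testing.assert_array_equal(result.s, result.b)
        np.testing.assert_allclose(result.pi_tilde, 0.1)
        count = result.n_participants
        assert abs(count - 200) < 4 * np.sqrt(200 * 0.9)

    def test_initial_invitation_uses_prior_phi_half(self):
        # first individual: flat symmetric prior gives phi_hat = 0.5, so the
        # invitation probability is pi0 / 0.5
        n = 5
        pop = _population(n, 41)
        design = DesignSpec(np.full(n, 0.1), 1)
        w = build_weights(pop, WeightScheme(kind="zero"))
        truth = ParticipationTruth(alpha_true=1.0, beta_true=np.zeros(2), delay_mean=15.0)
        sampler = AdaptiveListSampler(
            pop, design, w, ResponseOracle(truth, pop, 1),
            ParticipationModel(kind="linear", d_z=2), 2,
        )
        sampler.step()
        assert sampler.state.phi_used[0] == pytest.approx(0.5, abs=1e-12)
        assert sampler.state.pi_tilde[0] == pytest.approx(0.2, abs=1e-10)

    def test_srs_invariant_to_list_order_in_distribution(self):
        # zero weights: participant-count distribution does not depend on
        # the evaluation order (same response oracle, permuted list)
        n = 400
        pop = _population(n, 51)
        design = DesignSpec.equal(n, 40)
        w = build_weights(pop, WeightScheme(kind="zero"))
        counts = {"orig": [], "perm": []}
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        pop_perm = Population(ids=pop.ids[perm], x=pop.x[perm], z=pop.z[perm])
        for r in range(200):
            counts["orig"].append(
                run(pop, design, w, constant_phi_oracle(pop, 0.8, r), FixedParticipationModel(0.8), r).n_participants
            )
            counts["perm"].append(
                run(pop_perm, design, w, constant_phi_oracle(pop_perm, 0.8, r + 10_000), FixedParticipationModel(0.8), r + 10_000).n_participants
            )
        a, b = np.mean(counts["orig"]), np.mean(counts["perm"])
        se = np.sqrt(np.var(counts["orig"]) / 200 + np.var(counts["perm"]) / 200)
        assert abs(a - b) < 4 * se


class TestEnumeration:
    def test_four_person_run_matches_exhaustive_enumeration(self):
        """Full participation, uniform weights, pi0 = 1/2 each: the exact
        distribution of the participant count follows from enumerating all
        Bernoulli decision paths with the row-wise update."""
        n = 4
        pi0 = np.full(n, 0.5)
        W = np.full((n, n), 1 / 3)
        np.fill_diagonal(W, 0.0)

        dist = np.zeros(n + 1)

        def recurse(pi, i, prob):
            if i == n:
                dist[int(round(sum_s[0]))] += prob
                return
            p = pi[i]
            for s_i in (1, 0):
                branch = prob * (p if s_i else 1 - p)
                if branch == 0:
                    continue
                new_pi = pi.copy()
                for j in range(i + 1, n):
                    w = clamp_weight(W[j, i], new_pi[j], p)
                    new_pi[j] -= (s_i - p) * w
                sum_s[0] += s_i
                recurse(new_pi, i + 1, branch)
                sum_s[0] -= s_i

        sum_s = [0]
        recurse(pi0.astype(float), 0, 1.0)
        assert dist.sum() == pytest.approx(1.0)
        assert np.dot(dist, np.arange(n + 1)) == pytest.approx(2.0)
        assert dist[0] == 0 and dist[4] == 0  # weights forbid extremes

        pop = _population(n, 61)
        design = DesignSpec(pi0, 2)
        weights = dense_weights(W)
        reps = 20_000
        observed = np.zeros(n + 1)
        for r in range(reps):
            res = run(pop, design, weights, constant_phi_oracle(pop, 1.0, r),
                      FixedParticipationModel(1.0), r + 500_000)
            observed[res.n_participants] += 1
        observed /= reps
        se = np.sqrt(dist * (1 - dist) / reps)
        assert np.all(np.abs(observed - dist) < 4 * np.maximum(se, 1e-4))


class TestTraceAndReproducibility:
    def test_identical_seeds_identical_traces(self):
        pop, truth = _sim1_small()
        design = DesignSpec.equal(pop.n, 20)
        w = build_weights(pop, WeightScheme(kind="knn", k=10))
        runs = []
        for _ in range(2):
            oracle = ResponseOracle(truth, pop, 123)
            model = ParticipationModel(kind="linear", d_z=4)
            runs.append(run(pop, design, w, oracle, model, 456))
        np.testing.assert_array_equal(runs[0].s, runs[1].s)
        np.testing.assert_array_equal(runs[0].b, runs[1].b)
        np.testing.assert_allclose(runs[0].pi_hist, runs[1].pi_hist, rtol=0, atol=0)
        np.testing.assert_allclose(runs[0].phi_used, runs[1].phi_used, rtol=0, atol=0)

    def test_double_invitation_rejected(self):
        pop, truth = _sim1_small()
        oracle = ResponseOracle(truth, pop, 5)
        oracle.invite(3, 3)
        with pytest.raises(RuntimeError, match="twice"):
            oracle.invite(3, 10)

    def test_delayed_responses_resolve_after_drain(self):
        pop, truth = _sim1_small()
        design = DesignSpec.equal(pop.n, 20)
        w = build_weights(pop, WeightScheme(kind="zero"))
        oracle = ResponseOracle(truth, pop, 7)
        result = run(pop, design, w, oracle, ParticipationModel(kind="linear", d_z=4), 8)
        # every invitee eventually resolved; participants subset of invitees
        assert np.all(result.s <= result.b)
        assert result.n_participants == result.s.sum()


def _sim1_small():
    from seqsample import generate_sim1_population

    return generate_sim1_population(200, seed=77)
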