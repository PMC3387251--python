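"""Effect statistics, objective functions, and the multinomial choice rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    brute_effect_statistics,
    brute_network_choice,
    make_actors,
    random_scenario,
)
from sabm import (
    EffectParameterSet,
    InvalidChoiceError,
    InvalidContextError,
    InvalidStateError,
    ModelContext,
    SimilarityContext,
    behavior_choice_probabilities,
    behavior_objective,
    choice_probabilities_from_objectives,
    effect_statistics,
    network_choice_probabilities,
    network_objective,
    similarity,
    softmax,
)
from sabm.core import behavior_candidate_objectives, make_eval_cache


def simple_ctx(**kw):
    defaults = dict(
        age=SimilarityContext("age", 5.0),
        income=SimilarityContext("income", 80.0),
        behavior=SimilarityContext("beh", 6.0),
        z_avg=3.0,
        z_min=0,
        z_max=6,
    )
    defaults.update(kw)
    return ModelContext(**defaults)


class TestSimilarity:
    def test_identical_values_score_one(self):
        assert similarity(5, 5, SimilarityContext("a", 10.0)) == 1.0

    def test_maximal_difference_scores_zero(self):
        assert similarity(0, 10, SimilarityContext("a", 10.0)) == 0.0

    def test_centering_subtracts_mean(self):
        ctx = SimilarityContext("a", 10.0, sim_avg=0.3)
        assert similarity(5, 5, ctx) == pytest.approx(0.7)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(InvalidContextError):
            SimilarityContext("a", 0.0)
        with pytest.raises(InvalidContextError):
            SimilarityContext("a", -1.0)

    def test_backed_out_bmi_similarity_scaling(self):
        # the per-unit similarity increment implied by the two published
        # worked-scenario objective triples is ~0.0302, i.e. an effective
        # BMI range of ~33.1; the centering mean must be a valid similarity
        from sabm import backout_worked_constants

        consts = backout_worked_constants()
        assert consts.per_unit_increment == pytest.approx(0.0302, abs=0.0005)
        assert consts.range_used == pytest.approx(33.1, abs=0.2)
        assert 0.0 <= consts.sim_avg <= 1.0
        s = consts.centered_similarities
        assert s[0] < s[1] < s[2] < 0  # moving toward the alters raises sim

    @given(
        v1=st.floats(0, 40), v2=st.floats(0, 40),
        rng_used=st.floats(40, 100), avg=st.floats(0, 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_symmetric_and_bounded(self, v1, v2, rng_used, avg):
        ctx = SimilarityContext("a", rng_used, avg)
        s12, s21 = similarity(v1, v2, ctx), similarity(v2, v1, ctx)
        assert s12 == s21
        assert 0.0 <= s12 + avg <= 1.0  # uncentered value in [0, 1]


class TestEffectStatistics:
    def test_isolate_has_zero_statistics(self):
        x = np.zeros((4, 4), dtype=np.int8)
        attrs = make_actors(sex=[0, 1, 0, 1])
        stats = effect_statistics(0, x, attrs, np.array([1, 2, 3, 4]), simple_ctx())
        assert np.all(stats == 0.0)

    def test_complete_triad(self):
        # complete directed 3-graph: ego 0 has outdegree 2, both ties mutual,
        # and both ordered alter pairs (1,2), (2,1) close a transitive triplet
        x = np.ones((3, 3), dtype=np.int8) - np.eye(3, dtype=np.int8)
        attrs = make_actors(sex=[0, 0, 1])
        stats = effect_statistics(0, x, attrs, np.zeros(3, dtype=int), simple_ctx())
        outdeg, rec, ttip = stats[:3]
        assert (outdeg, rec, ttip) == (2.0, 2.0, 2.0)

    def test_same_sex_counts_matching_ties(self):
        x = np.zeros((3, 3), dtype=np.int8)
        x[0, 1] = x[0, 2] = 1
        attrs = make_actors(sex=[1, 1, 1])
        stats = effect_statistics(0, x, attrs, np.zeros(3, dtype=int), simple_ctx())
        assert stats[3] == 2.0

    def test_dimension_mismatch_raises(self):
        x = np.zeros((3, 3), dtype=np.int8)
        attrs = make_actors(sex=[0, 1])
        with pytest.raises(InvalidStateError):
            effect_statistics(0, x, attrs, np.zeros(3, dtype=int), simple_ctx())

    def test_matches_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            x, attrs, z, params, ctx = random_scenario(rng)
            for i in range(x.shape[0]):
                expected = brute_effect_statistics(i, x, attrs, z, ctx)
                got = effect_statistics(i, x, attrs, z, ctx)
                np.testing.assert_allclose(got, expected, atol=1e-10)


class TestNetworkObjective:
    def test_zero_betas_give_zero(self, rng):
        x, attrs, z, _, ctx = random_scenario(rng)
        assert network_objective(0, x, attrs, z, EffectParameterSet(), ctx) == 0.0

    def test_outdegree_only_is_minus_tie_count(self, rng):
        x, attrs, z, _, ctx = random_scenario(rng, n=5)
        params = EffectParameterSet(beta_deg=-1.0)
        for i in range(5):
            assert network_objective(i, x, attrs, z, params, ctx) == pytest.approx(
                -x[i].sum()
            )

    def test_linear_in_betas(self, rng):
        x, attrs, z, params, ctx = random_scenario(rng, n=5)
        doubled = EffectParameterSet.from_dict(
            {k: 2 * v for k, v in params.to_dict().items() if not k.startswith("rate")}
        )
        f1 = network_objective(1, x, attrs, z, params, ctx)
        f2 = network_objective(1, x, attrs, z, doubled, ctx)
        assert f2 == pytest.approx(2 * f1)


class TestChoiceRule:
    def test_distribution_normalized(self, rng):
        for _ in range(10):
            x, attrs, z, params, ctx = random_scenario(rng)
            dist = network_choice_probabilities(0, x, attrs, z, params, ctx)
            assert np.all(dist.probabilities >= 0)
            assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance(self, rng):
        for _ in range(20):
            objs = rng.normal(0, 3, size=int(rng.integers(2, 8)))
            shift = float(rng.normal(0, 50))
            p1 = choice_probabilities_from_objectives(range(len(objs)), objs)
            p2 = choice_probabilities_from_objectives(range(len(objs)), objs + shift)
            np.testing.assert_allclose(p1.probabilities, p2.probabilities, atol=1e-12)

    def test_equal_objectives_are_uniform(self):
        for k in (2, 3, 10):
            p = softmax(np.full(k, -4.2))
            np.testing.assert_allclose(p, np.full(k, 1.0 / k))

    def test_overflow_guarded(self):
        p = softmax(np.array([1e4, 1e4 - 1.0]))
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0)

    def test_matches_exhaustive_candidate_enumeration(self):
        # the delta-based candidate objectives must equal full re-evaluation
        # of the objective on every toggled network, for random scenarios
        rng = np.random.default_rng(21)
        for _ in range(25):
            x, attrs, z, params, ctx = random_scenario(rng)
            i = int(rng.integers(x.shape[0]))
            actions, objs, probs = brute_network_choice(i, x, attrs, z, params, ctx)
            dist = network_choice_probabilities(i, x, attrs, z, params, ctx)
            assert list(dist.actions) == actions
            np.testing.assert_allclose(dist.probabilities, probs, atol=1e-10)

    def test_eval_cache_equals_direct_path(self):
        rng = np.random.default_rng(3)
        x, attrs, z, params, ctx = random_scenario(rng, n=6)
        cache = make_eval_cache(attrs, params, ctx)
        from sabm.core import network_candidate_objectives

        a1, o1 = network_candidate_objectives(2, x, attrs, z, params, ctx)
        a2, o2 = network_candidate_objectives(2, x, attrs, z, params, ctx, cache=cache)
        assert a1 == a2
        np.testing.assert_allclose(o1, o2, atol=1e-12)


class TestBehaviorObjective:
    def bmi_ctx(self, range_used=33.0594, sim_avg=0.0):
        return ModelContext(
            age=SimilarityContext("age", 1.0),
            income=SimilarityContext("income", 1.0),
            behavior=SimilarityContext("bmi", range_used, sim_avg),
            z_avg=22.6,
            z_min=14,
            z_max=44,
        )

    def test_zero_parameters_give_zero(self):
        ctx = self.bmi_ctx()
        x = np.zeros((1, 1), dtype=np.int8)
        for cand in (22, 23, 24):
            assert behavior_objective(0, cand, x, np.array([23]),
                                      EffectParameterSet(), ctx) == 0.0

    def test_friendless_ego_shape_terms_only(self):
        # ego at BMI 23 with no friends: objectives for (down, same, up)
        # should match (-0.093, 0.0689, 0.260) within 0.01
        params = EffectParameterSet(beta_lin=0.16, beta_quad=0.015, beta_avsim=14.10)
        ctx = self.bmi_ctx()
        x = np.zeros((1, 1), dtype=np.int8)
        z = np.array([23])
        objs = [behavior_objective(0, c, x, z, params, ctx) for c in (22, 23, 24)]
        np.testing.assert_allclose(objs, [-0.093, 0.0689, 0.260], atol=0.01)

    def test_two_heavier_alters_pull_upward(self):
        # same ego with two alters at BMI 30: (-1.608, -1.019, -0.402) +/- 0.02
        params = EffectParameterSet(beta_lin=0.16, beta_quad=0.015, beta_avsim=14.10)
        from sabm import backout_worked_constants

        consts = backout_worked_constants()
        ctx = self.bmi_ctx(range_used=consts.range_used, sim_avg=consts.sim_avg)
        x = np.zeros((3, 3), dtype=np.int8)
        x[0, 1] = x[0, 2] = 1
        z = np.array([23, 30, 30])
        objs = [behavior_objective(0, c, x, z, params, ctx) for c in (22, 23, 24)]
        np.testing.assert_allclose(objs, [-1.608, -1.019, -0.402], atol=0.02)

    def test_out_of_bounds_candidate_rejected(self):
        ctx = self.bmi_ctx()
        x = np.zeros((1, 1), dtype=np.int8)
        with pytest.raises(InvalidChoiceError):
            behavior_objective(0, 13, x, np.array([14]), EffectParameterSet(), ctx)


class TestBehaviorChoice:
    def test_printed_probability_triples(self):
        for objs, expected in (
            ((-0.093, 0.0689, 0.260), (0.278, 0.327, 0.395)),
            ((-1.608, -1.019, -0.402), (0.163, 0.293, 0.544)),
        ):
            p = softmax(np.array(objs))
            np.testing.assert_allclose(p, expected, atol=1e-3)

    def test_upper_bound_truncates_candidates(self):
        ctx = ModelContext(
            age=SimilarityContext("age", 1.0),
            income=SimilarityContext("income", 1.0),
            behavior=SimilarityContext("beh", 6.0),
            z_avg=3.0, z_min=0, z_max=6,
        )
        x = np.zeros((1, 1), dtype=np.int8)
        dist = behavior_choice_probabilities(
            0, x, np.array([6]), EffectParameterSet(beta_lin=0.5), ctx
        )
        assert list(dist.actions) == [-1, 0]
        assert dist.probabilities.sum() == pytest.approx(1.0)
        dist = behavior_choice_probabilities(
            0, x, np.array([0]), EffectParameterSet(beta_lin=0.5), ctx
        )
        assert list(dist.actions) == [0, 1]

    def test_centering_constant_cancels_with_uniform_alters(self):
        # when all alters share one behavior value, sim_avg shifts every
        # candidate objective equally, so the choice probabilities match
        params = EffectParameterSet(beta_lin=0.1, beta_quad=0.02, beta_avsim=4.0)
        x = np.zeros((4, 4), dtype=np.int8)
        x[0, 1:] = 1
        z = np.array([3, 5, 5, 5])
        rng = np.random.default_rng(5)
        reference = None
        for sim_avg in rng.uniform(0, 1, size=6):
            ctx = ModelContext(
                age=SimilarityContext("age", 1.0),
                income=SimilarityContext("income", 1.0),
                behavior=SimilarityContext("beh", 6.0, float(sim_avg)),
                z_avg=3.0, z_min=0, z_max=6,
            )
            dist = behavior_choice_probabilities(0, x, z, params, ctx)
            if reference is None:
                reference = dist.probabilities
            np.testing.assert_allclose(dist.probabilities, reference, atol=1e-12)

    def test_candidate_objectives_consistent_with_objective_fn(self, rng):
        x, attrs, z, params, ctx = random_scenario(rng, n=5)
        params = params.replace(linear_shape=0.2, quadratic_shape=0.05,
                                average_similarity=2.0)
        i = 2
        deltas, objs = behavior_candidate_objectives(i, x, z, params, ctx)
        for d, o in zip(deltas, objs):
            assert o == pytest.approx(
                behavior_objective(i, int(z[i]) + d, x, z, params, ctx)
            )
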