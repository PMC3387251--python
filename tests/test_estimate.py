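"""Method-of-moments targets, standard errors, and fit behavior."""

import warnings

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import make_actors
from sabm import (
    BehaviorPanel,
    EffectParameterSet,
    EstimationError,
    InvalidStateError,
    ModelContext,
    NetworkPanel,
    SimilarityContext,
    mc_standard_errors,
    observed_targets,
    robbins_monro_fit,
    simulate_period,
)
from sabm.estimate import FitConfig, drop_degenerate_effects, state_targets


def toy_panel():
    """4 actors; wave 1 has 3 mutual pairs, wave 2 rewires 2 tie variables."""
    x0 = np.zeros((4, 4), dtype=np.int8)
    for i, j in ((0, 1), (1, 2), (2, 3)):
        x0[i, j] = x0[j, i] = 1  # 3 mutual ties
    x1 = x0.copy()
    x1[0, 1] = 0  # delete one direction
    x1[0, 3] = 1  # create a new tie
    net = NetworkPanel([x0, x1])
    beh = BehaviorPanel("beh", np.array([[1, 2, 3, 2], [2, 2, 3, 2]]), 0, 6)
    attrs = make_actors(sex=[0, 1, 0, 1])
    return net, beh, attrs


class TestObservedTargets:
    def test_hand_counted_toy_panel(self):
        net, beh, attrs = toy_panel()
        effects = ["rate_net", "rate_beh", "outdegree", "reciprocity"]
        t = observed_targets(net, beh, attrs, effects)
        assert t[0] == 2.0  # two tie variables changed between waves
        assert t[1] == 1.0  # one actor moved one behavior unit
        assert t[2] == 6.0  # wave-2 tie count
        assert t[3] == 4.0  # wave-2 mutual-tie statistic (2 mutual pairs)

    def test_empty_second_wave_gives_zero_tie_target(self):
        x0 = np.zeros((3, 3), dtype=np.int8)
        x0[0, 1] = 1
        net = NetworkPanel([x0, np.zeros((3, 3), dtype=np.int8)])
        beh = BehaviorPanel("beh", np.zeros((2, 3), dtype=int), 0, 3)
        attrs = make_actors(sex=[0, 1, 0])
        t = observed_targets(net, beh, attrs, ["outdegree"])
        assert t[0] == 0.0

    def test_single_wave_rejected(self):
        x0 = np.zeros((3, 3), dtype=np.int8)
        net = NetworkPanel([x0])
        beh = BehaviorPanel("beh", np.zeros((1, 3), dtype=int), 0, 3)
        attrs = make_actors(sex=[0, 1, 0])
        with pytest.raises(InvalidStateError):
            observed_targets(net, beh, attrs, ["outdegree"])


class TestDegenerateEffects:
    def test_constant_attribute_effect_dropped_with_warning(self):
        attrs = make_actors(sex=[0, 1, 0], black=[0, 0, 0])
        with pytest.warns(UserWarning, match="same_black"):
            kept, dropped = drop_degenerate_effects(
                ["outdegree", "same_black", "same_sex"], attrs
            )
        assert dropped == ["same_black"]
        assert kept == ["outdegree", "same_sex"]


class TestMcStandardErrors:
    def make_draws(self, n, seed=0):
        rng = np.random.default_rng(seed)
        sigma = np.array([[4.0, 1.0], [1.0, 2.0]])
        return rng.multivariate_normal([10.0, 5.0], sigma, size=n)

    def test_requires_enough_simulations(self):
        with pytest.raises(EstimationError, match="100"):
            mc_standard_errors(self.make_draws(50), np.eye(2))

    def test_zero_variance_target_is_an_error(self):
        draws = self.make_draws(200)
        draws[:, 1] = 7.0
        with pytest.raises(EstimationError, match="zero simulated-target variance"):
            mc_standard_errors(draws, np.eye(2), ["alpha", "beta"])

    def test_singular_derivative_names_collinear_effects(self):
        D = np.array([[1.0, 2.0], [2.0, 4.0]])
        with pytest.raises(EstimationError, match="collinear"):
            mc_standard_errors(self.make_draws(200), D, ["alpha", "beta"])

    def test_doubling_simulations_leaves_ses_stable(self):
        D = np.array([[3.0, 0.5], [0.2, 2.0]])
        se1 = mc_standard_errors(self.make_draws(300, seed=1), D)
        se2 = mc_standard_errors(self.make_draws(600, seed=2), D)
        np.testing.assert_allclose(se1, se2, rtol=0.2)


class TestTwoActorClosedForm:
    """A 2-actor network model whose moments are enumerable exactly.

    With only the out-degree effect active, each actor's single tie toggles
    with softmax probability sigma(+/- beta_deg) at opportunities arriving
    at the network rate, giving a 4-state continuous-time Markov chain whose
    unit-time distribution is a matrix exponential.  The simulator and the
    delta-method standard errors are checked against this oracle.
    """

    RATE, BDEG = 1.2, -0.5
    X0 = np.array([[0, 1], [0, 0]], dtype=np.int8)

    def targets(self, x12, x21):
        # rate target: Hamming distance from X0; effect target: tie count
        return np.array([(1 - x12) + x21, x12 + x21], dtype=float)

    def exact_distribution(self, rate, bdeg):
        states = [(0, 0), (1, 0), (0, 1), (1, 1)]
        Q = np.zeros((4, 4))
        for a, (x12, x21) in enumerate(states):
            for actor, bit in ((0, x12), (1, x21)):
                delta = bdeg * (1.0 - 2.0 * bit)  # objective change of toggle
                p_toggle = 1.0 / (1.0 + np.exp(-delta))
                target_state = (1 - x12, x21) if actor == 0 else (x12, 1 - x21)
                b = states.index(target_state)
                Q[a, b] += rate * p_toggle
        np.fill_diagonal(Q, -Q.sum(axis=1))
        start = states.index((1, 0))
        pi = expm(Q)[start]
        T = np.array([self.targets(*s) for s in states])
        mean = pi @ T
        cov = (T - mean).T @ np.diag(pi) @ (T - mean)
        return pi, mean, cov

    def exact_derivative(self, eps=1e-6):
        D = np.zeros((2, 2))
        theta = np.array([self.RATE, self.BDEG])
        for k in range(2):
            hi, lo = theta.copy(), theta.copy()
            hi[k] += eps
            lo[k] -= eps
            D[:, k] = (
                self.exact_distribution(*hi)[1] - self.exact_distribution(*lo)[1]
            ) / (2 * eps)
        return D

    def simulate_draws(self, n_sims, seed=0):
        attrs = make_actors(sex=[0, 1])
        ctx = ModelContext(
            age=SimilarityContext("age", 1.0),
            income=SimilarityContext("income", 1.0),
            behavior=SimilarityContext("beh", 2.0),
            z_avg=1.0, z_min=0, z_max=2,
        )
        params = EffectParameterSet(
            beta_deg=self.BDEG, rate_net=self.RATE, rate_beh=0.5
        )
        z0 = np.array([1, 1])
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_sims):
            trace = simulate_period(
                self.X0, z0, attrs, params, ctx,
                np.random.default_rng(int(rng.integers(2**31))),
                record_steps=False,
            )
            draws.append(self.targets(trace.x1[0, 1], trace.x1[1, 0]))
        return np.array(draws)

    def test_simulated_moments_match_markov_chain(self):
        _, mean, _ = self.exact_distribution(self.RATE, self.BDEG)
        draws = self.simulate_draws(1500, seed=4)
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.05)

    def test_standard_errors_match_closed_form(self):
        _, _, cov_targets = self.exact_distribution(self.RATE, self.BDEG)
        D = self.exact_derivative()
        Dinv = np.linalg.inv(D)
        closed = np.sqrt(np.diag(Dinv @ cov_targets @ Dinv.T))
        draws = self.simulate_draws(600, seed=9)
        got = mc_standard_errors(draws, D, ["rate_net", "outdegree"])
        np.testing.assert_allclose(got, closed, rtol=0.10)


class TestRobbinsMonroFit:
    def small_panel(self, seed=1):
        from conftest import recovery_school
        from sabm.synth import generate_panel

        cfg = recovery_school("influence", n_actors=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return generate_panel(cfg, seed=seed)

    def quick_config(self):
        return FitConfig(
            phase1_sims_per_side=3,
            phase2_iterations=(15, 25),
            phase3_sims=100,
            phase3_fd_sims_per_side=2,
            max_restarts=0,
            t_threshold=0.15,
        )

    def test_seed_reproducible_end_to_end(self):
        panel = self.small_panel()
        effects = ["rate_net", "rate_beh", "outdegree", "reciprocity"]
        results = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = robbins_monro_fit(
                    panel.network, panel.behavior, panel.actors, effects,
                    self.quick_config(), rng=123,
                )
            results.append(res)
        assert results[0].estimates == results[1].estimates
        assert results[0].standard_errors == results[1].standard_errors
        assert results[0].seed == 123

    def test_self_consistency_at_true_parameters(self):
        # a full fit started at the data-generating parameters should end
        # with every convergence t-ratio near zero
        panel = self.small_panel(seed=5)
        effects = ["rate_net", "rate_beh", "outdegree", "reciprocity",
                   "average_similarity"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = robbins_monro_fit(
                panel.network, panel.behavior, panel.actors, effects,
                FitConfig().reduced(), rng=7, init=panel.ground_truth,
            )
        assert max(abs(t) for t in res.t_ratios.values()) < 0.15
        assert res.converged

    def test_result_layout_reports_all_effects(self):
        panel = self.small_panel(seed=3)
        effects = ["rate_net", "rate_beh", "outdegree", "reciprocity"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = robbins_monro_fit(
                panel.network, panel.behavior, panel.actors, effects,
                self.quick_config(), rng=5,
            )
        d = res.to_dict()
        assert [row["effect"] for row in d["effects"]] == effects
        for row in d["effects"]:
            lo, hi = row["ci95"]
            assert lo < row["estimate"] < hi
        assert d["se_method"] == "monte_carlo_delta"
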