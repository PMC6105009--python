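import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from relsal.hgf import (
    BranchState,
    LearnParams,
    branch_step,
    precision_of_prediction,
    relevance_weights,
    run_two_branch,
)
from relsal.task import TaskConfig, generate_task

from conftest import make_task


class TestPrecision:
    def test_minimum_at_half_is_four(self):
        assert precision_of_prediction(0.5) == pytest.approx(4.0)

    def test_direct_value(self):
        assert precision_of_prediction(0.8) == pytest.approx(6.25)

    @given(st.floats(0.01, 0.99))
    @settings(derandomize=True, max_examples=50)
    def test_symmetric_and_bounded_below(self, p):
        assert precision_of_prediction(p) == pytest.approx(precision_of_prediction(1 - p))
        assert precision_of_prediction(p) >= 4.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.3])
    def test_rejects_degenerate_predictions(self, bad):
        with pytest.raises(ValueError):
            precision_of_prediction(bad)


class TestRelevanceWeights:
    def test_symmetry_at_minimum(self):
        assert relevance_weights(4.0, 4.0) == pytest.approx((0.5, 0.5))

    def test_direct_value(self):
        rc, rs = relevance_weights(6.25, 4.0)
        assert rc == pytest.approx(6.25 / 10.25)
        assert rs == pytest.approx(4.0 / 10.25)

    @given(st.floats(4.0, 1e6), st.floats(4.0, 1e6))
    @settings(derandomize=True, max_examples=50)
    def test_weights_sum_to_one(self, a, b):
        rc, rs = relevance_weights(a, b)
        assert rc + rs == pytest.approx(1.0)

    def test_rejects_precision_below_minimum(self):
        with pytest.raises(ValueError):
            relevance_weights(3.0, 5.0)


class TestBranchStep:
    def test_agnostic_prior_predicts_half(self):
        state = BranchState(mu2=0.0, sigma2=0.05)
        out = branch_step(state, 1.0, LearnParams(omega=-2.0))
        assert out.mu1hat == pytest.approx(0.5)
        assert out.delta1 == pytest.approx(0.5)
        assert out.mu2 > 0.0  # belief moved toward the observed input

    def test_zero_relevance_weight_freezes_mean(self):
        state = BranchState(mu2=0.3, sigma2=0.05)
        out = branch_step(state, 1.0, LearnParams(variant="2HGFprecfb"), rel_weight=0.0)
        assert out.mu2 == pytest.approx(state.mu2)

    def test_constant_input_matches_hand_iterated_update(self):
        """Independent oracle: iterate the printed binary update equations in
        plain python and compare; beliefs approach 1 monotonically."""
        omega, sigma2_0 = -2.0, 0.05
        mu2, s2 = 0.0, sigma2_0
        oracle_mu1hat = []
        for _ in range(30):
            mu1hat = 1.0 / (1.0 + math.exp(-mu2))
            oracle_mu1hat.append(mu1hat)
            delta1 = 1.0 - mu1hat
            s2hat = s2 + math.exp(omega)
            pi2 = 1.0 / s2hat + mu1hat * (1.0 - mu1hat)
            s2 = 1.0 / pi2
            mu2 = mu2 + s2 * delta1

        params = LearnParams(omega=omega, sigma2_0=sigma2_0)
        state = BranchState(mu2=0.0, sigma2=sigma2_0)
        got = []
        for _ in range(30):
            state = branch_step(state, 1.0, params)
            got.append(state.mu1hat)
        np.testing.assert_allclose(got, oracle_mu1hat, rtol=1e-12)
        assert np.all(np.diff(got) > 0) and got[-1] > 0.9

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            branch_step(BranchState(mu2=0.0, sigma2=0.05), 0.5, LearnParams())


def symmetric_task(n=16):
    """Task in which color and shape branch inputs coincide on every trial."""
    rows = []
    for k in range(n):
        coin = k % 3 != 0
        rows.append(
            {
                "trial": k + 1,
                # u_color = 1 iff colorful&coin or grey&circle; pick colorful/triangle
                # together so u_color == u_shape always
                "color": "colorful" if k % 2 == 0 else "grey",
                "shape": "triangle" if k % 2 == 0 else "square",
                "outcome": "coin" if coin else "circle",
                "relevant_dimension": "color",
                "rewarded_manifestation": "colorful",
                "expected": "expected",
            }
        )
    return make_task(pd.DataFrame(rows))


class TestRunTwoBranch:
    def test_first_trial_is_symmetric(self, default_task):
        traj = run_two_branch(default_task, LearnParams(omega=-2.0))
        assert traj.mu1hat_color[0] == pytest.approx(0.5)
        assert traj.mu1hat_shape[0] == pytest.approx(0.5)
        assert traj.rel_color[0] == pytest.approx(0.5)

    def test_invariants_hold_throughout(self, default_task):
        for variant in ("2HGF", "2HGFprecfb", "3HGF", "3HGFprecfb"):
            traj = run_two_branch(default_task, LearnParams(omega=-2.0, variant=variant))
            assert traj.valid
            np.testing.assert_allclose(traj.rel_color + traj.rel_shape, 1.0, rtol=1e-12)
            assert np.all(traj.pi1hat_color >= 4.0 - 1e-12)
            assert np.all(np.abs(traj.delta1_color) <= 1.0)
            at_min = np.isclose(traj.pi1hat_shape, 4.0, rtol=0, atol=1e-9)
            np.testing.assert_allclose(traj.mu1hat_shape[at_min], 0.5, atol=1e-4)

    def test_predictive_feature_gains_relevance(self):
        """When shape predicts the outcome deterministically and color is
        50/50, the shape branch's relevance weight dominates."""
        cfg = TaskConfig(
            contingency=1.0, first_relevant_dimension="shape", seed=3, exact_counts=False
        )
        task = generate_task(cfg)
        traj = run_two_branch(task, LearnParams(omega=-2.0))
        last = slice(60, 80)
        assert traj.rel_shape[last].mean() > traj.rel_color[last].mean()

    def test_precfb_reduces_to_plain_under_symmetry(self):
        """With both branches receiving identical inputs the relevance
        weights stay pinned at 0.5 and the precision-feedback coupling
        vanishes: trajectories equal the plain 2HGF exactly."""
        task = symmetric_task()
        plain = run_two_branch(task, LearnParams(omega=-2.0, variant="2HGF"))
        fb = run_two_branch(task, LearnParams(omega=-2.0, variant="2HGFprecfb"))
        np.testing.assert_allclose(fb.rel_color, 0.5, rtol=1e-12)
        np.testing.assert_allclose(fb.mu1hat_color, plain.mu1hat_color, rtol=1e-12)
        np.testing.assert_allclose(fb.delta1_shape, plain.delta1_shape, rtol=1e-12)

    def test_outcome_relabel_flips_beliefs(self, default_task):
        """Flipping the arbitrary branch-input coding mirrors the belief
        trajectory as mu1hat -> 1 - mu1hat."""
        flipped = default_task.trials.copy()
        flipped["outcome"] = np.where(flipped["outcome"] == "coin", "circle", "coin")
        task2 = make_task(flipped, config=default_task.config)
        a = run_two_branch(default_task, LearnParams(omega=-2.0))
        b = run_two_branch(task2, LearnParams(omega=-2.0))
        np.testing.assert_allclose(b.mu1hat_color, 1.0 - a.mu1hat_color, atol=1e-12)
        np.testing.assert_allclose(b.pi1hat_color, a.pi1hat_color, rtol=1e-9)

    def test_frozen_learner_keeps_prior_beliefs(self, default_task):
        traj = run_two_branch(default_task, LearnParams(omega=-40.0, sigma2_0=1e-10))
        np.testing.assert_allclose(traj.mu1hat_color, 0.5, atol=1e-6)
        np.testing.assert_allclose(
            traj.delta1_color, traj.u_color - 0.5, atol=1e-6
        )

    @pytest.mark.parametrize("variant", ["2HGFprecfb", "3HGF"])
    def test_matches_stepwise_reference(self, default_task, variant):
        """The array runner agrees with trial-by-trial branch_step calls."""
        params = LearnParams(omega=-2.0, variant=variant)
        traj = run_two_branch(default_task, params)
        state_c = BranchState(mu2=0.0, sigma2=params.sigma2_0,
                              mu3=params.mu3_0, sigma3=params.sigma3_0)
        state_s = BranchState(mu2=0.0, sigma2=params.sigma2_0,
                              mu3=params.mu3_0, sigma3=params.sigma3_0)
        rel_c = rel_s = 0.5
        for k in range(20):
            wc = rel_c if params.precision_feedback else None
            ws = rel_s if params.precision_feedback else None
            new_c = branch_step(state_c, traj.u_color[k], params, rel_weight=wc)
            new_s = branch_step(state_s, traj.u_shape[k], params, rel_weight=ws)
            assert new_c.mu1hat == pytest.approx(traj.mu1hat_color[k], rel=1e-12)
            assert new_s.delta1 == pytest.approx(traj.delta1_shape[k], rel=1e-12)
            rel_c, rel_s = relevance_weights(new_c.pi1hat, new_s.pi1hat)
            assert rel_c == pytest.approx(traj.rel_color[k], rel=1e-12)
            state_c, state_s = new_c, new_s
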