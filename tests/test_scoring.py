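"""Abstraction scores: empirical scores, exact losses, successor features."""

import numpy as np
import pytest

from abstraxion.abstraction import canonicalize, compress, identity_partition, inflate
from abstraxion.mdp_core import (
    TabularMDP,
    deterministic_policy,
    expected_rewards,
    uniform_random_policy,
    value_iteration,
)
from abstraxion.scoring import (
    batch_loss_maximizing,
    batch_loss_predictive,
    discount_bound_constant,
    loss_maximizing,
    loss_predictive,
    predictive_distance_matrix,
    reward_sequence_error,
    successor_features,
    total_reward_score,
)
from conftest import random_mdp


def cycle_mdp(gamma=0.9):
    p = np.zeros((3, 2, 3))
    r = np.zeros_like(p)
    for s in range(3):
        p[s, 0, (s + 1) % 3] = 1.0   # action 0 advances
        p[s, 1, s] = 1.0             # action 1 stays
    r[2, 0, 0] = 1.0
    return TabularMDP(transition=p, reward=r, discount=gamma)


class TestTotalReward:
    def test_zero_reward_mdp_scores_zero(self, rng):
        mdp = random_mdp(4, 2, rng, reward_scale=0.0)
        assert total_reward_score(mdp, uniform_random_policy(mdp), 10, 10, rng) == 0.0

    def test_cycle_three_laps_in_ten_steps(self):
        # from the state just after the rewarded arc, the optimal policy
        # completes the rewarded arc on steps 3, 6 and 9 → total reward 3
        mdp = cycle_mdp()
        start = np.zeros(3)
        start[0] = 1.0
        mdp = TabularMDP(mdp.transition, mdp.reward, mdp.discount, start_distribution=start)
        policy = deterministic_policy([0, 0, 0], 2)
        rng = np.random.default_rng(0)
        assert total_reward_score(mdp, policy, 1, 10, rng) == pytest.approx(3.0)

    def test_matches_exact_propagation_oracle(self, rng):
        mdp = random_mdp(4, 2, rng)
        policy = uniform_random_policy(mdp)
        n, horizon = 10_000, 6
        est = total_reward_score(mdp, policy, n, horizon, rng)
        # exact expectation by distribution propagation
        P = np.einsum("ij,ijk->ik", policy.probs, mdp.transition)
        r_pi = np.einsum("ij,ij->i", policy.probs, expected_rewards(mdp))
        dist, exact = mdp.start_distribution.copy(), 0.0
        for _ in range(horizon):
            exact += dist @ r_pi
            dist = dist @ P
        sem = horizon * 0.3 / np.sqrt(n)  # conservative per-trial spread bound
        assert abs(est - exact) < 3 * max(sem, 0.01)


class TestRSError:
    def test_identity_partition_error_zero(self, rng):
        mdp = random_mdp(5, 2, rng)
        ab = compress(mdp, identity_partition(5))
        assert reward_sequence_error(mdp, ab, 20, 10, rng) == pytest.approx(0.0, abs=1e-10)

    def test_column_partition_error_zero(self, column_world, rng):
        from abstraxion.task_suite import column_partition

        ab = compress(column_world, column_partition())
        assert reward_sequence_error(column_world, ab, 20, 10, rng) == pytest.approx(0.0, abs=1e-10)

    def test_one_state_partition_error_positive(self, column_world, rng):
        ab = compress(column_world, canonicalize([0] * 9))
        assert reward_sequence_error(column_world, ab, 20, 10, rng) > 0.05


class TestSuccessorFeatures:
    def test_gamma_zero_gives_one_hot_features(self, rng):
        mdp = random_mdp(4, 2, rng, discount=0.0)
        part = canonicalize([0, 1, 0, 1])
        psi = successor_features(mdp, part).psi
        for s in range(4):
            for a in range(2):
                expected = np.zeros(2)
                expected[part(s)] = 1.0
                assert np.allclose(psi[s, a], expected)

    def test_column_states_share_sf_rows(self, column_world):
        from abstraxion.task_suite import column_partition

        part = column_partition()
        _, pi_star = value_iteration(column_world)
        psi = successor_features(column_world, part, pi_star).psi
        for col in range(3):
            states = [col, col + 3, col + 6]
            assert np.allclose(psi[states[0]], psi[states[1]], atol=1e-9)
            assert np.allclose(psi[states[0]], psi[states[2]], atol=1e-9)

    def test_total_occupancy_identity(self, rng):
        mdp = random_mdp(6, 3, rng)
        part = canonicalize([0, 0, 1, 1, 2, 2])
        psi = successor_features(mdp, part).psi
        assert np.allclose(psi.sum(axis=2), 1.0 / (1.0 - mdp.discount), atol=1e-9)

    def test_matches_truncated_monte_carlo(self, rng):
        mdp = random_mdp(3, 2, rng)
        part = identity_partition(3)
        policy = uniform_random_policy(mdp)
        psi = successor_features(mdp, part, policy).psi
        n, horizon = 20_000, 50
        acc = np.zeros((n, 3))
        states = np.zeros(n, dtype=int)
        first_action = 1
        for t in range(horizon):
            feat = np.zeros((n, 3))
            feat[np.arange(n), states] = 1.0
            acc += mdp.discount**t * feat
            if t == 0:
                acts = np.full(n, first_action)
            else:
                acts = rng.integers(2, size=n)
            u = rng.random((n, 1))
            states = (u > mdp.transition[states, acts].cumsum(axis=1)).sum(axis=1)
        mc = acc.mean(axis=0)
        sem = acc.std(axis=0, ddof=1) / np.sqrt(n)
        truncation = mdp.discount**horizon / (1 - mdp.discount)
        assert np.all(np.abs(mc - psi[0, first_action]) < 3 * sem + truncation)


class TestLossMaximizing:
    def test_identity_partition_zero(self, rng):
        mdp = random_mdp(5, 2, rng)
        assert loss_maximizing(mdp, identity_partition(5)) < 1e-6

    def test_column_world_one_state_zero(self, column_world):
        assert loss_maximizing(column_world, canonicalize([0] * 9)) < 1e-6

    def test_wall_task_one_state_positive(self):
        from abstraxion.task_suite import make_barrier_grid

        # goal on the left with a barrier: the 1-state compression plans a
        # single action everywhere, which strands the agent at the wall
        task_b = make_barrier_grid(goal_column=0, barriers=[((1, 1), (1, 0))])
        assert loss_maximizing(task_b, canonicalize([0] * 9)) > 0.1

    def test_batch_agrees_with_scalar(self, rng):
        mdp = random_mdp(5, 2, rng)
        parts = [identity_partition(5), canonicalize([0, 0, 1, 1, 2]), canonicalize([0] * 5)]
        labels = np.stack([p.array() for p in parts])
        batch = batch_loss_maximizing(mdp, labels)
        for p, b in zip(parts, batch):
            assert b == pytest.approx(loss_maximizing(mdp, p), abs=1e-6)


class TestLossPredictive:
    def test_identity_partition_zero(self, rng):
        mdp = random_mdp(5, 2, rng)
        assert loss_predictive(mdp, identity_partition(5)) == pytest.approx(0.0, abs=1e-9)

    def test_hidden_partition_of_inflated_mdp_zero(self, rng):
        mdp = random_mdp(3, 2, rng)
        ground, hidden = inflate(mdp, [3, 3, 3], rng)
        assert loss_predictive(ground, hidden) < 1e-9

    def test_column_world_contrast(self, column_world):
        from abstraxion.task_suite import column_partition

        assert loss_predictive(column_world, column_partition()) < 1e-9
        assert loss_predictive(column_world, canonicalize([0] * 9)) > 0.1

    def test_monotone_under_refinement(self, rng):
        """Refining any partition never increases the loss."""
        for _ in range(20):
            mdp = random_mdp(6, 2, rng)
            coarse = canonicalize(rng.integers(0, 2, size=6))
            fine_labels = [2 * c + int(rng.random() < 0.5) for c in coarse.assignment]
            fine = canonicalize(fine_labels)
            assert fine.refines(coarse)
            assert loss_predictive(mdp, fine) <= loss_predictive(mdp, coarse) + 1e-12

    def test_batch_agrees_with_scalar(self, rng):
        mdp = random_mdp(5, 2, rng)
        D, _ = predictive_distance_matrix(mdp)
        parts = [canonicalize([0, 0, 1, 1, 2]), canonicalize([0, 1, 0, 1, 0])]
        labels = np.stack([p.array() for p in parts])
        batch = batch_loss_predictive(D, labels)
        for p, b in zip(parts, batch):
            assert b == pytest.approx(loss_predictive(mdp, p), abs=1e-12)


class TestZeroLossSoundness:
    def test_zero_predictive_loss_implies_zero_rs_error(self, rng):
        """Over random (MDP, partition) pairs: l_pred = 0 ⟹ RS_error = 0, and
        l_pred = 0 ⟹ the planning loss is negligible."""
        checked_zero = 0
        for i in range(200):
            if i % 2 == 0:
                mdp = random_mdp(3, 2, rng)
                ground, part = inflate(mdp, [2, 2, 2], rng)
            else:
                ground = random_mdp(6, 2, rng)
                part = canonicalize(rng.integers(0, 3, size=6))
            lp = loss_predictive(ground, part)
            if lp < 1e-9:
                checked_zero += 1
                err = reward_sequence_error(ground, compress(ground, part), 10, 8, rng)
                assert err < 1e-9
                assert loss_maximizing(ground, part) < 1e-6
        assert checked_zero >= 50  # the inflated half guarantees plenty of zeros


def test_discount_bound_constant_geometric():
    assert discount_bound_constant(0.5, 3) == pytest.approx(1.75)
    assert discount_bound_constant(0.0, 5) == pytest.approx(1.0)
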