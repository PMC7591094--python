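"""Q-learning / SF-learning on latent spaces, and the lifelong driver."""

import numpy as np

from abstraxion.abstraction import canonicalize, identity_partition, inflate
from abstraxion.agents import LifelongConfig, QAgent, SFAgent, epsilon_schedule, run_lifelong
from abstraxion.mdp_core import TabularMDP, value_iteration
from abstraxion.scoring import successor_features
from abstraxion.task_suite import CurriculumSpec, make_guitar_task, guitar_scale_partition
from conftest import random_mdp


def two_armed_bandit():
    """One state, two actions, arm 0 pays 1, arm 1 pays 0 (self-loops)."""
    p = np.zeros((1, 2, 1))
    p[:, :, 0] = 1.0
    r = np.zeros_like(p)
    r[0, 0, 0] = 1.0
    return TabularMDP(p, r, 0.5)


class TestQAgent:
    def test_update_generalizes_across_cell_mates(self):
        part = canonicalize([0, 0, 1])
        agent = QAgent(part, n_actions=2, discount=0.9, learning_rate=1.0)
        agent.update(s=0, a=1, r=5.0, s_next=2, terminal=True)
        # cell-mate state 1 sees the same greedy action as state 0
        assert np.argmax(agent.Q[part(1)]) == 1
        assert agent.action_probs(1, 0.0)[1] == 1.0

    def test_learning_rate_one_gamma_zero_copies_reward(self):
        agent = QAgent(identity_partition(2), 2, discount=0.0, learning_rate=1.0)
        agent.update(0, 1, 3.5, 1, terminal=False)
        assert agent.Q[0, 1] == 3.5

    def test_greedy_bandit_converges_within_ten_steps(self):
        mdp = two_armed_bandit()
        agent = QAgent(identity_partition(1), 2, mdp.discount,
                       learning_rate=0.5, q_init=mdp.reward.max() / (1 - mdp.discount))
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = int(rng.choice(2, p=agent.action_probs(0, 0.0)))
            agent.update(0, a, float(mdp.reward[0, a, 0]), 0, terminal=False)
        assert np.argmax(agent.Q[0]) == 0

    def test_epsilon_schedule_anneals_linearly(self):
        assert epsilon_schedule(1, 80) == 1.0
        assert epsilon_schedule(80, 80) == 0.0
        assert epsilon_schedule(200, 80) == 0.0
        mid = epsilon_schedule(40, 80)
        assert 0.4 < mid < 0.6


class TestSFAgent:
    def test_gamma_zero_features_stay_one_hot(self):
        agent = SFAgent(identity_partition(2), 2, discount=0.0, lr_sf=1.0, lr_w=1.0)
        agent.update(0, 1, -1.0, 1, terminal=False)
        assert np.allclose(agent.F[0, 1], [1.0, 0.0])
        # with γ = 0 the action values reduce to the one-step reward estimates
        assert agent.q_values(0)[1] == -1.0
        assert agent.q_values(0)[0] == 0.0

    def test_converged_sf_matches_exact_successor_features(self, rng):
        """TD-learned F under a fixed greedy policy approaches the linear
        fixed point computed by ``successor_features`` (decaying step sizes,
        uniform generative sampling of (s, a))."""
        mdp = random_mdp(4, 2, rng, discount=0.8)
        part = identity_partition(4)
        fixed = value_iteration(mdp)[1]
        greedy = fixed.greedy_actions()
        agent = SFAgent(part, 2, mdp.discount, lr_sf=0.1, lr_w=0.1)
        visits = np.zeros((4, 2))
        for _ in range(80_000):
            s = int(rng.integers(4))
            a = int(rng.integers(2))
            s_next = int(rng.choice(4, p=mdp.transition[s, a]))
            visits[s, a] += 1
            lr = 1.0 / visits[s, a] ** 0.7
            e_s = np.zeros(4)
            e_s[s] = 1.0
            target = e_s + mdp.discount * agent.F[s_next, greedy[s_next]]
            agent.F[s, a] += lr * (target - agent.F[s, a])
        psi = successor_features(mdp, part, fixed).psi
        assert np.max(np.abs(agent.F - psi)) < 5e-2

    def test_converged_q_on_deterministic_chain_matches_planner(self):
        # 3-state chain: action 0 advances (reward 1 at the end), action 1 stays
        p = np.zeros((3, 2, 3))
        r = np.zeros_like(p)
        p[0, 0, 1] = p[1, 0, 2] = 1.0
        p[2, 0, 2] = 1.0
        p[:, 1, :] = np.eye(3)
        r[1, 0, 2] = 1.0
        mdp = TabularMDP(p, r, 0.9, absorbing={2})
        agent = SFAgent(identity_partition(3), 2, 0.9, lr_sf=0.5, lr_w=0.5)
        rng = np.random.default_rng(1)
        for episode in range(400):
            eps = max(0.0, 1.0 - episode / 200)          # annealed exploration
            s = int(rng.integers(2))
            for _ in range(20):
                a = int(rng.choice(2, p=agent.action_probs(s, eps)))
                s_next = int(np.argmax(mdp.transition[s, a]))
                agent.update(s, a, float(mdp.reward[s, a, s_next]), s_next,
                             terminal=s_next == 2 and s != 2)
                s = s_next
                if s == 2:
                    break
        # the greedy policy recovered from Q̂ = F·w is the optimal one, and
        # the on-policy action values match the planner's
        assert int(np.argmax(agent.q_values(0))) == 0
        assert int(np.argmax(agent.q_values(1))) == 0
        assert abs(agent.q_values(1)[0] - 1.0) < 0.05    # Q*(1, advance) = 1
        assert abs(agent.q_values(0)[0] - 0.9) < 0.05    # Q*(0, advance) = γ

    def test_transfer_modes_reset_semantics(self):
        agent = SFAgent(identity_partition(2), 2, 0.9, transfer_mode="sf_transfer")
        agent.F += 1.0
        agent.w += 1.0
        agent.new_task()
        assert np.allclose(agent.w, 0.0)
        assert not np.allclose(agent.F, np.tile(np.eye(2)[:, None, :], (1, 2, 1)))
        keep = SFAgent(identity_partition(2), 2, 0.9, transfer_mode="sf_and_reward_transfer")
        keep.F += 1.0
        keep.w += 1.0
        keep.new_task()
        assert np.allclose(keep.w, 1.0)


class TestLifelong:
    def test_seeded_runs_reproducible(self):
        curr = _tiny_curriculum()
        cfg = LifelongConfig(model="crp_predictive", episodes_per_task=20,
                             exploration="greedy", posterior_update_every=1, seed=11)
        a = run_lifelong(curr, cfg)
        b = run_lifelong(curr, cfg)
        assert a.equals(b)

    def test_zero_loss_abstraction_matches_identity_policy(self, rng):
        """Q-learning through an exactly reward-predictive partition reaches
        the same greedy policy quality as the identity partition."""
        latent = random_mdp(3, 2, rng, discount=0.9)
        ground, hidden = inflate(latent, [2, 2, 2], rng)
        V_star, _ = value_iteration(ground)
        gaps = []
        for part in (identity_partition(6), hidden):
            agent = QAgent(part, 2, 0.9, learning_rate=1.0)
            visits = np.zeros((part.n_latent, 2))
            s = 0
            for step in range(10_000):
                eps = max(0.2, 1.0 - step / 5000)
                a = int(rng.choice(2, p=agent.action_probs(s, eps)))
                s_next = int(rng.choice(6, p=ground.transition[s, a]))
                visits[part(s), a] += 1
                agent.learning_rate = 1.0 / visits[part(s), a] ** 0.6
                agent.update(s, a, float(ground.reward[s, a, s_next]), s_next, False)
                s = s_next
            from abstraxion.mdp_core import policy_evaluation

            V_pi = policy_evaluation(ground, agent.greedy_policy(6))
            gaps.append(np.max(V_star - V_pi))
        # both reach near-optimal policies; compressing through the hidden
        # partition loses nothing
        assert gaps[0] < 0.05
        assert gaps[1] < 0.05

    def test_guitar_reuses_learned_abstraction(self):
        """After learning scale 1, the belief holds the octave-merging
        abstraction and re-uses it on scale 2."""
        curr = _guitar_curriculum()
        cfg = LifelongConfig(model="crp_predictive", episodes_per_task=100,
                             exploration="greedy", posterior_update_every=1, seed=3)
        df = run_lifelong(curr, cfg)
        task1 = df[df.task == 1]
        assert task1.iloc[-1]["belief_size"] == 1
        learned = task1.iloc[-1]["chosen"]
        assert learned == guitar_scale_partition(7).to_string()
        task2 = df[df.task == 2]
        assert task2.iloc[-1]["chosen"] == learned    # re-used, not re-invented


def _tiny_curriculum():
    tasks = tuple(make_guitar_task(("C", "D", "E")) for _ in range(2))
    hidden = tuple(guitar_scale_partition(3) for _ in range(2))
    return CurriculumSpec(name="tiny", tasks=tasks, hidden_partitions=hidden)


def _guitar_curriculum():
    scales = (("C", "D", "E", "F", "G", "A", "B"), ("A", "B", "C", "D", "E", "F", "G"))
    return CurriculumSpec(
        name="guitar",
        tasks=tuple(make_guitar_task(s) for s in scales),
        hidden_partitions=tuple(guitar_scale_partition(7) for _ in scales),
    )
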