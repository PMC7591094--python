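"""Online learners over (latent) state spaces and the lifelong-learning driver.

A :class:`QAgent` runs tabular Q-learning on the latent indices of an
attached state partition, so one temporal-difference update generalizes to
every ground state in the updated cell.  A :class:`SFAgent` learns successor
features and one-step reward weights instead, supporting the transfer modes
compared in the experiments (reset, SF re-use, SF + reward re-use).

``run_lifelong`` drives a task curriculum: the mixture-of-experts agent
keeps one Q-learner per belief abstraction plus one on the identity
abstraction, selects actions from the posterior-weighted mixture of their
policies, estimates transition/reward tables while acting, and after each
task learns a candidate abstraction and updates its belief through the CRP
posterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abstraction import StatePartition, compress, identity_partition, lift_policy
from .abstraction_learning import (
    learn_reward_maximizing,
    learn_reward_predictive,
)
from .crp_transfer import BeliefSet, posterior, select_and_update
from .mdp_core import Policy, TabularMDP, expected_rewards, policy_evaluation, value_iteration
from .scoring import successor_features
from .task_suite import CurriculumSpec

__all__ = [
    "QAgent",
    "SFAgent",
    "LifelongConfig",
    "epsilon_schedule",
    "run_lifelong",
]

_TIE_TOL = 1e-9

MODELS = (
    "q_baseline",
    "crp_predictive",
    "crp_maximizing",
    "sf_reset",
    "sf_transfer",
    "sf_reward_transfer",
)


def epsilon_schedule(episode: int, end_episode: int, start: float = 1.0, end: float = 0.0) -> float:
    """Linear anneal of the exploration rate: ``start`` at episode 1 down to
    ``end`` by ``end_episode`` (1-based), constant afterwards."""
    if end_episode <= 1:
        return end
    frac = min(1.0, (episode - 1) / (end_episode - 1))
    return start + frac * (end - start)


def _greedy_probs(q_row: np.ndarray, epsilon: float) -> np.ndarray:
    """ε-greedy action distribution with uniform-random tie-breaking."""
    n = len(q_row)
    best = q_row >= q_row.max() - _TIE_TOL
    probs = np.where(best, (1.0 - epsilon) / best.sum(), 0.0)
    return probs + epsilon / n


class QAgent:
    """Tabular Q-learning on the latent space of a state partition."""

    def __init__(
        self,
        partition: StatePartition,
        n_actions: int,
        discount: float,
        learning_rate: float = 0.9,
        q_init: float = 0.0,
    ):
        self.partition = partition
        self.n_actions = n_actions
        self.discount = discount
        self.learning_rate = learning_rate
        self.Q = np.full((partition.n_latent, n_actions), float(q_init))

    def action_probs(self, s: int, epsilon: float) -> np.ndarray:
        return _greedy_probs(self.Q[self.partition(s)], epsilon)

    def update(self, s: int, a: int, r: float, s_next: int, terminal: bool) -> None:
        x, y = self.partition(s), self.partition(s_next)
        bootstrap = 0.0 if terminal else self.discount * self.Q[y].max()
        self.Q[x, a] += self.learning_rate * (r + bootstrap - self.Q[x, a])

    def greedy_policy(self, n_states: int) -> Policy:
        probs = np.stack([_greedy_probs(self.Q[self.partition(s)], 0.0) for s in range(n_states)])
        return Policy(probs)


class SFAgent:
    """SF-learning: successor features ``F`` plus one-step reward weights ``w``.

    ``F[x, a]`` is updated by a TD rule toward ``e_x + γ F[φ(s'), a*]`` with
    ``a*`` the current greedy action at ``s'``; ``w[x, a]`` by a delta rule
    toward the observed reward.  Action values use the successor-representation
    decomposition ``Q̂(s, a) = w[x, a] + (F[x, a] − e_x) · ρ`` where
    ``ρ(y) = w[y, a*_y]`` prices every future occupied cell at the reward of
    the action the current policy would take there (a cached greedy table,
    refreshed at the cells each transition touches).  Pricing at the policy's
    own action — not the best one-step reward — makes the reward-consistent
    policy the only stable fixed point: a cycling policy values its loop at
    zero and breaks out through random tie-breaking.  The transfer mode
    decides what survives a task switch: nothing (``reset``), the SFs
    (``sf_transfer``), or SFs and reward weights (``sf_and_reward_transfer``).
    """

    def __init__(
        self,
        partition: StatePartition,
        n_actions: int,
        discount: float,
        lr_sf: float = 0.9,
        lr_w: float = 0.5,
        transfer_mode: str = "reset",
    ):
        if transfer_mode not in ("reset", "sf_transfer", "sf_and_reward_transfer"):
            raise ValueError(f"unknown transfer mode {transfer_mode!r}")
        self.partition = partition
        self.n_actions = n_actions
        self.discount = discount
        self.lr_sf = lr_sf
        self.lr_w = lr_w
        self.transfer_mode = transfer_mode
        k = partition.n_latent
        self.F = np.tile(np.eye(k)[:, None, :], (1, n_actions, 1))   # F[x, a] ≈ e_x initially
        self.w = np.zeros((k, n_actions))
        self.greedy = np.zeros(k, dtype=int)

    def _rho(self) -> np.ndarray:
        return self.w[np.arange(self.partition.n_latent), self.greedy]

    def q_values(self, x: int) -> np.ndarray:
        e_x = np.zeros(self.partition.n_latent)
        e_x[x] = 1.0
        return self.w[x] + (self.F[x] - e_x) @ self._rho()

    def action_probs(self, s: int, epsilon: float) -> np.ndarray:
        return _greedy_probs(self.q_values(self.partition(s)), epsilon)

    def update(self, s: int, a: int, r: float, s_next: int, terminal: bool) -> None:
        x, y = self.partition(s), self.partition(s_next)
        e_x = np.zeros(self.partition.n_latent)
        e_x[x] = 1.0
        if terminal:
            target = e_x
        else:
            target = e_x + self.discount * self.F[y, int(self.greedy[y])]
        self.F[x, a] += self.lr_sf * (target - self.F[x, a])
        self.w[x, a] += self.lr_w * (r - self.w[x, a])
        for cell in (x, y):
            self.greedy[cell] = int(np.argmax(self.q_values(cell)))

    def new_task(self) -> None:
        """Apply the transfer mode at a task boundary."""
        k = self.partition.n_latent
        if self.transfer_mode == "reset":
            self.F = np.tile(np.eye(k)[:, None, :], (1, self.n_actions, 1))
            self.w = np.zeros((k, self.n_actions))
            self.greedy = np.zeros(k, dtype=int)
        elif self.transfer_mode == "sf_transfer":
            self.w = np.zeros((k, self.n_actions))
        # sf_and_reward_transfer keeps both


# ---------------------------------------------------------------------------
# Lifelong learning driver


@dataclass(frozen=True)
class LifelongConfig:
    """Configuration of one lifelong run.

    ``model`` is one of ``q_baseline``, ``crp_predictive``, ``crp_maximizing``,
    ``sf_reset``, ``sf_transfer``, ``sf_reward_transfer``.  Exploration is
    ε-greedy annealed linearly from 1 to 0 by ``anneal_end_episode``
    (``exploration="egreedy"``), or pure greedy action selection on an
    optimistically initialized table (``exploration="greedy"``).
    """

    model: str = "q_baseline"
    episodes_per_task: int = 200
    max_steps: int = 5000
    learning_rate: float = 0.9
    lr_w: float = 0.5
    exploration: str = "egreedy"
    anneal_end_episode: int = 80
    q_init: float = 0.0
    alpha: float = 0.05
    beta: float = 5.0
    learn_epsilon: float = 0.8
    posterior_update_every: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.exploration not in ("egreedy", "greedy"):
            raise ValueError("exploration must be 'egreedy' or 'greedy'")


class _TableEstimator:
    """Incremental transition counts and reward sums for one task."""

    def __init__(self, n_states: int, n_actions: int):
        self.counts = np.zeros((n_states, n_actions, n_states))
        self.reward_sums = np.zeros_like(self.counts)

    def add(self, s, a, r, s_next):
        self.counts[s, a, s_next] += 1.0
        self.reward_sums[s, a, s_next] += r

    @property
    def observed_sa(self) -> np.ndarray:
        return self.counts.sum(axis=2) > 0

    @property
    def observed_states(self) -> np.ndarray:
        return self.observed_sa.any(axis=1)

    def mdp(self, discount: float) -> TabularMDP:
        totals = self.counts.sum(axis=2)
        p = np.where(
            (totals > 0)[:, :, None],
            self.counts / np.maximum(totals, 1.0)[:, :, None],
            0.0,
        )
        unobs_s, unobs_a = np.nonzero(totals == 0)
        p[unobs_s, unobs_a, unobs_s] = 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.counts > 0, self.reward_sums / np.maximum(self.counts, 1.0), 0.0)
        return TabularMDP(transition=p, reward=r, discount=discount)


def _member_loss_predictive(
    tables: TabularMDP,
    observed_sa: np.ndarray,
    partition: StatePartition,
) -> float:
    """Reward-prediction misfit of one partition on estimated tables.

    Mean, over merged state pairs, of the disagreement between one-step
    reward estimates plus SF rows (features = the partition's own one-hots,
    uniform reference policy), restricted to state/action pairs actually
    observed — unvisited states carry no evidence against an abstraction.
    Averaging (rather than the max used by the exact loss) keeps the
    estimate robust to a few noise-contaminated pairs in sampled tables.
    """
    observed_state = observed_sa.any(axis=1)
    psi = successor_features(tables, partition).psi            # (S, A, K)
    r_sa = expected_rewards(tables)
    deviations = []
    for cell in partition.cells():
        members = [s for s in cell if observed_state[s]]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                s, u = members[i], members[j]
                both = observed_sa[s] & observed_sa[u]
                if not both.any():
                    continue
                d_r = np.max(np.abs(r_sa[s, both] - r_sa[u, both]))
                d_psi = np.max(np.abs(psi[s, both] - psi[u, both]))
                deviations.append(float(d_r + d_psi))
    return float(np.mean(deviations)) if deviations else 0.0


def _member_loss_maximizing(
    tables: TabularMDP,
    observed_sa: np.ndarray,
    partition: StatePartition,
) -> float:
    """Planning loss of one partition on estimated tables, over observed states."""
    observed_state = observed_sa.any(axis=1)
    if not observed_state.any():
        return 0.0
    V_star, _ = value_iteration(tables)
    abstract = compress(tables, partition)
    _, pi_latent = value_iteration(abstract.mdp)
    V_lift = policy_evaluation(tables, Policy(lift_policy(partition, pi_latent)))
    gap = (V_star - V_lift)[observed_state]
    return max(0.0, float(gap.max()))


def _make_learner(partition, n_actions, gamma, config):
    return QAgent(
        partition,
        n_actions,
        gamma,
        learning_rate=config.learning_rate,
        q_init=config.q_init,
    )


def _mixture_action(learners, weights, s, epsilon, rng) -> int:
    probs = np.zeros(learners[0].n_actions)
    for learner, w in zip(learners, weights):
        if w > 0:
            probs += w * learner.action_probs(s, epsilon)
    probs = probs / probs.sum()
    return int(rng.choice(len(probs), p=probs))


def run_lifelong(curriculum: CurriculumSpec, config: LifelongConfig) -> pd.DataFrame:
    """Run one lifelong-learning model through a task curriculum.

    Returns one row per (task, episode) with columns ``task``, ``episode``,
    ``steps``, ``return``, ``belief_size``, ``posterior`` (JSON list over
    belief members + the identity component), ``chosen`` (the abstraction
    sampled at the end of the task, as a partition string) and ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    gamma = curriculum.tasks[0].discount
    n_actions = curriculum.tasks[0].n_actions
    is_crp = config.model in ("crp_predictive", "crp_maximizing")
    is_sf = config.model.startswith("sf_")
    member_loss = (
        _member_loss_predictive if config.model == "crp_predictive" else _member_loss_maximizing
    )
    learn_candidate = (
        (lambda tables: learn_reward_predictive(tables, epsilon=config.learn_epsilon))
        if config.model == "crp_predictive"
        else (lambda tables: learn_reward_maximizing(tables, epsilon=config.learn_epsilon))
    )

    belief = BeliefSet(alpha=config.alpha, beta=config.beta)
    sf_agent: SFAgent | None = None
    rows = []

    for task_idx, mdp in enumerate(curriculum.tasks):
        identity = identity_partition(mdp.n_states)
        if is_sf:
            if sf_agent is None:
                sf_agent = SFAgent(
                    identity,
                    n_actions,
                    gamma,
                    lr_sf=config.learning_rate,
                    lr_w=config.lr_w,
                    transfer_mode={
                        "sf_reset": "reset",
                        "sf_transfer": "sf_transfer",
                        "sf_reward_transfer": "sf_and_reward_transfer",
                    }[config.model],
                )
            else:
                sf_agent.new_task()
            learners = [sf_agent]
            weights = np.ones(1)
        elif is_crp:
            learners = [
                _make_learner(phi, n_actions, gamma, config) for phi in belief.abstractions
            ] + [_make_learner(identity, n_actions, gamma, config)]
            weights = posterior(belief, identity, np.zeros(len(belief) + 1))
        else:
            learners = [_make_learner(identity, n_actions, gamma, config)]
            weights = np.ones(1)

        estimator = _TableEstimator(mdp.n_states, n_actions)

        for episode in range(1, config.episodes_per_task + 1):
            if is_crp and len(belief) and (episode - 1) % config.posterior_update_every == 0 and len(estimator.counts.nonzero()[0]):
                tables = estimator.mdp(gamma)
                losses = [
                    member_loss(tables, estimator.observed_sa, phi)
                    for phi in belief.abstractions
                ] + [0.0]
                weights = posterior(belief, identity, losses)
            epsilon = (
                0.0
                if config.exploration == "greedy"
                else epsilon_schedule(episode, config.anneal_end_episode)
            )
            s = int(rng.choice(mdp.n_states, p=mdp.start_distribution))
            ep_return, steps = 0.0, 0
            for _ in range(config.max_steps):
                a = _mixture_action(learners, weights, s, epsilon, rng)
                s_next = int(rng.choice(mdp.n_states, p=mdp.transition[s, a]))
                r = float(mdp.reward[s, a, s_next])
                terminal = s_next in mdp.absorbing
                for learner in learners:
                    learner.update(s, a, r, s_next, terminal)
                estimator.add(s, a, r, s_next)
                ep_return += r
                steps += 1
                s = s_next
                if terminal:
                    break
            rows.append(
                {
                    "task": task_idx + 1,
                    "episode": episode,
                    "steps": steps,
                    "return": ep_return,
                    "belief_size": len(belief),
                    "posterior": json.dumps([round(float(x), 6) for x in weights]),
                    "chosen": "",
                    "seed": config.seed,
                }
            )

        if is_crp:
            tables = estimator.mdp(gamma)
            candidate = learn_candidate(tables)
            losses = [
                member_loss(tables, estimator.observed_sa, phi) for phi in belief.abstractions
            ] + [member_loss(tables, estimator.observed_sa, candidate)]
            post = posterior(belief, candidate, losses)
            chosen, belief = select_and_update(belief, post, candidate, rng)
            rows[-1]["chosen"] = chosen.to_string()
            rows[-1]["belief_size"] = len(belief)

    return pd.DataFrame(rows)
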