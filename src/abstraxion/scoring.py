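"""Abstraction scores: empirical transfer scores and exact loss functions.

Four quantities rank a state abstraction φ on a task:

* ``total_reward_score`` — empirical total reward of the policy planned in
  the compressed task, measured by rollouts (the reward-maximizing score).
* ``reward_sequence_error`` — empirical mean absolute error between reward
  sequences predicted by the compressed task and the exact expected reward
  sequences of the ground task, over random start/action-sequence pairs
  (the reward-predictive score).
* ``loss_maximizing`` — the exact planning loss: how much value the greedy
  policy of the compressed task gives up relative to the optimal policy,
  maximized over states.
* ``loss_predictive`` — an exact reward-prediction loss whose zero set is
  precisely the reward-predictive partitions.  Two states are
  reward-predictively equivalent when they have identical one-step expected
  rewards and identical successor features computed over the coarsest
  reward-predictive partition of the task; ``loss_predictive`` is the largest
  pairwise deviation of these quantities over state pairs merged by φ.
  Because the pairwise deviation does not depend on φ, the loss is exactly
  monotone: refining a partition can only shrink it.

Successor features (SFs) are computed exactly as the solution of their
linear fixed-point equation, never by iteration or sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abstraction import AbstractMDP, StatePartition, compress, lift_policy
from .mdp_core import (
    Policy,
    TabularMDP,
    expected_reward_sequence,
    expected_rewards,
    policy_evaluation,
    rollout,
    uniform_random_policy,
    value_iteration,
)

__all__ = [
    "SFMatrix",
    "AbstractionScore",
    "successor_features",
    "total_reward_score",
    "reward_sequence_error",
    "loss_maximizing",
    "loss_predictive",
    "predictive_distance_matrix",
    "batch_loss_predictive",
    "batch_loss_maximizing",
    "batch_abstract_greedy",
    "discount_bound_constant",
]


@dataclass(frozen=True)
class SFMatrix:
    """Successor features ``ψ^π(s, a)`` over a partition's one-hot features."""

    psi: np.ndarray                 # (n_states, n_actions, n_latent)
    partition: StatePartition
    policy: Policy = field(compare=False)
    discount: float = 0.0


@dataclass(frozen=True)
class AbstractionScore:
    """All four scores of one partition on one task, with sampling metadata."""

    partition: StatePartition
    R_total: float
    RS_error: float
    l_max: float
    l_pred: float
    metadata: dict = field(default_factory=dict, compare=False)


def discount_bound_constant(gamma: float, t: int) -> float:
    """Reporting constant ``Σ_{k<t} γ^k`` relating a per-step prediction loss
    to a cumulative reward-sequence bound over horizon ``t``."""
    return float(sum(gamma**k for k in range(t)))


def successor_features(
    mdp: TabularMDP,
    partition: StatePartition,
    policy: Policy | None = None,
) -> SFMatrix:
    """Exact SFs ``ψ(s,a) = e_{φ(s)} + γ Σ_{s'} p(s,a,s') Σ_{a'} π(a'|s') ψ(s',a')``.

    Solved as one linear system at the state level: the policy-averaged SF
    ``m(s) = Σ_a π(a|s) ψ(s,a)`` satisfies ``(I − γP_π) m = Φ`` where Φ is the
    partition's one-hot feature matrix, and ψ follows by one Bellman backup.
    """
    if policy is None:
        policy = uniform_random_policy(mdp)
    gamma = mdp.discount
    phi = partition.indicator()
    P_pi = np.einsum("ij,ijk->ik", policy.probs, mdp.transition)
    m = np.linalg.solve(np.eye(mdp.n_states) - gamma * P_pi, phi)   # (S, K)
    psi = phi[:, None, :] + gamma * np.einsum("sat,tk->sak", mdp.transition, m)
    return SFMatrix(psi=psi, partition=partition, policy=policy, discount=gamma)


def total_reward_score(
    mdp: TabularMDP,
    policy: Policy,
    n_trials: int,
    horizon: int,
    rng: np.random.Generator,
) -> float:
    """Mean total reward of ``N`` independent rollouts of at most ``T`` steps,
    started from the task's start distribution."""
    if n_trials < 1 or horizon < 1:
        raise ValueError("n_trials and horizon must be >= 1")
    total = 0.0
    for _ in range(n_trials):
        traj = rollout(mdp, policy, max_steps=horizon, rng=rng)
        total += float(traj.rewards.sum())
    return total / n_trials


def reward_sequence_error(
    mdp: TabularMDP,
    abstract: AbstractMDP,
    n_sequences: int,
    horizon: int,
    rng: np.random.Generator,
) -> float:
    """Mean cumulative absolute error between ground-truth expected reward
    sequences and those predicted in the compressed task.

    Start states are drawn uniformly over ground states and action sequences
    are uniform random walks; both tasks see the same (start, actions) pairs,
    the ground task from ``s`` and the compressed task from ``φ(s)``.  Each
    sequence is evaluated exactly by distribution propagation.
    """
    partition = abstract.source_partition
    if partition.n_states != mdp.n_states:
        raise ValueError("abstract MDP was not built from this MDP's states")
    if n_sequences < 1 or horizon < 1:
        raise ValueError("n_sequences and horizon must be >= 1")
    err = 0.0
    for _ in range(n_sequences):
        s = int(rng.integers(mdp.n_states))
        actions = rng.integers(mdp.n_actions, size=horizon)
        true_seq = expected_reward_sequence(mdp, s, actions)
        pred_seq = expected_reward_sequence(abstract.mdp, partition(s), actions)
        err += float(np.abs(true_seq - pred_seq).sum())
    return err / n_sequences


def loss_maximizing(mdp: TabularMDP, partition: StatePartition, tol: float = 1e-8) -> float:
    """Planning loss ``max_s (V^{π*}(s) − V^{π_φ}(s))``.

    ``π_φ`` is the greedy policy of the compressed task, lifted back to ground
    states through φ and evaluated exactly in the ground task.
    """
    V_star, _ = value_iteration(mdp, tol=tol)
    abstract = compress(mdp, partition)
    _, pi_latent = value_iteration(abstract.mdp, tol=tol)
    pi_ground = Policy(lift_policy(partition, pi_latent))
    V_lifted = policy_evaluation(mdp, pi_ground)
    return max(0.0, float(np.max(V_star - V_lifted)))


def predictive_distance_matrix(
    mdp: TabularMDP,
    reference_policy: Policy | None = None,
    refine_tol: float = 1e-9,
) -> tuple[np.ndarray, StatePartition]:
    """Pairwise reward-predictive deviation ``D[s, u]`` between all states.

    ``D[s, u] = max_a |r(s,a) − r(u,a)| + max_a ‖ψ*(s,a) − ψ*(u,a)‖_∞`` where
    ``ψ*`` are SFs under the reference policy (uniform-random by default) over
    the coarsest exactly reward-predictive partition φ* of the task.
    ``D[s, u] = 0`` iff s and u fall in the same cell of φ*.  Also returns φ*.
    """
    from .abstraction_learning import refine_reward_predictive  # local: avoids cycle

    if reference_policy is None:
        reference_policy = uniform_random_policy(mdp)
    phi_star = refine_reward_predictive(mdp, epsilon=refine_tol, reference_policy=reference_policy)
    psi = successor_features(mdp, phi_star, reference_policy).psi     # (S, A, K)
    r_sa = expected_rewards(mdp)                                      # (S, A)
    d_r = np.max(np.abs(r_sa[:, None, :] - r_sa[None, :, :]), axis=2)
    d_psi = np.max(np.abs(psi[:, None] - psi[None, :]), axis=(2, 3))
    return d_r + d_psi, phi_star


def loss_predictive(
    mdp: TabularMDP,
    partition: StatePartition,
    reference_policy: Policy | None = None,
) -> float:
    """Reward-prediction loss of φ: the largest pairwise reward-predictive
    deviation over state pairs that φ merges.

    Zero exactly when every merged pair is reward-predictively equivalent,
    i.e. when the compressed task predicts every expected reward sequence of
    the ground task; strictly positive otherwise, with magnitude grading how
    badly merged states disagree.  Monotone under refinement by construction.
    """
    if partition.n_states != mdp.n_states:
        raise ValueError("partition does not match the MDP's state space")
    D, _ = predictive_distance_matrix(mdp, reference_policy)
    return batch_loss_predictive(D, partition.array()[None, :])[0]


def batch_loss_predictive(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized ``loss_predictive`` for many partitions of one task.

    ``D`` is the task's pairwise deviation matrix; ``labels`` has shape
    ``(n_partitions, n_states)``.  Returns one loss per partition.
    """
    labels = np.asarray(labels, dtype=int)
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    merged = labels[:, iu] == labels[:, ju]              # (B, n_pairs)
    pairs = D[iu, ju][None, :]
    return np.where(merged, pairs, 0.0).max(axis=1, initial=0.0)


# ---------------------------------------------------------------------------
# Batch planning-loss machinery (used by the enumeration experiments, where
# thousands of partitions of one task are scored at once).

def _batch_compress(mdp: TabularMDP, labels: np.ndarray, n_latent: int):
    """Uniform-weighting compressed tables for a batch of partitions.

    Partitions with fewer than ``n_latent`` cells are padded with absorbing
    zero-reward latent states, which never interact with the lifted policy.
    Returns latent ``p̄`` (B,K,A,K) and expected latent rewards ``r̄`` (B,K,A).
    """
    B, S = labels.shape
    A = mdp.n_actions
    phi = np.zeros((B, S, n_latent))
    np.put_along_axis(phi, labels[:, :, None], 1.0, axis=2)
    sizes = phi.sum(axis=1)                                   # (B, K)
    w = np.take_along_axis(1.0 / np.maximum(sizes, 1.0), labels, axis=1)  # (B, S)
    t_phi = np.einsum("saj,bjy->bsay", mdp.transition, phi)
    p_bar = np.einsum("bs,bsx,bsay->bxay", w, phi, t_phi)
    pr = mdp.transition * mdp.reward
    pr_phi = np.einsum("saj,bjy->bsay", pr, phi)
    pr_bar = np.einsum("bs,bsx,bsay->bxay", w, phi, pr_phi)
    empty = sizes == 0                                        # padded cells
    if empty.any():
        b_idx, k_idx = np.nonzero(empty)
        p_bar[b_idx, k_idx] = 0.0
        p_bar[b_idx, k_idx, :, k_idx] = 1.0
        pr_bar[b_idx, k_idx] = 0.0
    r_bar_sa = pr_bar.sum(axis=3)                             # Σ_y p̄ r̄ = Σ_y pr̄
    p_bar = p_bar / p_bar.sum(axis=3, keepdims=True)
    return p_bar, r_bar_sa


def _batch_plan(p_bar, r_bar_sa, gamma):
    """Exact optimal planning for a batch of small MDPs via policy iteration.

    Each Howard iteration evaluates the current greedy policies with one
    batched linear solve and re-greedifies; convergence (policy unchanged)
    is reached in a handful of iterations and the result is exactly optimal.
    Ties in the greedy step take the lowest action index.
    """
    B, K, A, _ = p_bar.shape
    greedy = r_bar_sa.argmax(axis=2)
    eye = np.eye(K)[None]
    b_idx = np.arange(B)[:, None]
    k_idx = np.arange(K)[None, :]
    for _ in range(200):
        P_pi = p_bar[b_idx, k_idx, greedy]                      # (B, K, K)
        R_pi = r_bar_sa[b_idx, k_idx, greedy]                   # (B, K)
        V = np.linalg.solve(eye - gamma * P_pi, R_pi[:, :, None])[:, :, 0]
        Q = r_bar_sa + gamma * np.einsum("bxay,by->bxa", p_bar, V)
        new_greedy = Q.argmax(axis=2)
        # keep the incumbent action unless strictly improved: guarantees
        # monotone policy improvement and termination
        incumbent_q = Q[b_idx, k_idx, greedy]
        improved = Q[b_idx, k_idx, new_greedy] > incumbent_q + 1e-12
        new_greedy = np.where(improved, new_greedy, greedy)
        if np.array_equal(new_greedy, greedy):
            break
        greedy = new_greedy
    # final greedy with the same lowest-index tie rule as value_iteration
    Q = r_bar_sa + gamma * np.einsum("bxay,by->bxa", p_bar, V)
    return V, Q.argmax(axis=2)                                  # (B, K) each


def batch_abstract_greedy(mdp: TabularMDP, labels: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Greedy ground action table (B, S): plan in each compressed task, lift via φ."""
    labels = np.asarray(labels, dtype=int)
    n_latent = int(labels.max()) + 1
    p_bar, r_bar_sa = _batch_compress(mdp, labels, n_latent)
    _, greedy_latent = _batch_plan(p_bar, r_bar_sa, mdp.discount)
    return np.take_along_axis(greedy_latent, labels, axis=1)  # (B, S)


def batch_loss_maximizing(mdp: TabularMDP, labels: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Vectorized ``loss_maximizing`` over many partitions of one task."""
    labels = np.asarray(labels, dtype=int)
    V_star, _ = value_iteration(mdp, tol=tol)
    actions = batch_abstract_greedy(mdp, labels, tol)         # (B, S)
    B, S = actions.shape
    P_pi = mdp.transition[np.arange(S)[None, :], actions]     # (B, S, S)
    r_sa = expected_rewards(mdp)
    R_pi = r_sa[np.arange(S)[None, :], actions]               # (B, S)
    A_mat = np.eye(S)[None] - mdp.discount * P_pi
    V_lift = np.linalg.solve(A_mat, R_pi[:, :, None])[:, :, 0]
    return np.maximum(0.0, (V_star[None, :] - V_lift).max(axis=1))


def score_abstraction(
    mdp: TabularMDP,
    partition: StatePartition,
    n_trials: int = 20,
    horizon: int = 10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> AbstractionScore:
    """Convenience: all four scores of one partition on one task."""
    if rng is None:
        rng = np.random.default_rng(seed)
    abstract = compress(mdp, partition)
    _, pi_latent = value_iteration(abstract.mdp)
    pi_ground = Policy(lift_policy(partition, pi_latent))
    return AbstractionScore(
        partition=partition,
        R_total=total_reward_score(mdp, pi_ground, n_trials, horizon, rng),
        RS_error=reward_sequence_error(mdp, abstract, n_trials, horizon, rng),
        l_max=loss_maximizing(mdp, partition),
        l_pred=loss_predictive(mdp, partition),
        metadata={"N": n_trials, "T": horizon, "seed": seed, "gamma": mdp.discount},
    )
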