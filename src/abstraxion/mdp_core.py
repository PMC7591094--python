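"""Finite Markov decision processes as dense tables, with exact solvers.

A task is a quintuple ``⟨S, A, p, r, γ⟩``: a finite state space, a finite
action space, a transition kernel ``p(s, a, s')``, a reward function
``r(s, a, s')`` and a discount factor ``γ ∈ [0, 1)``.  Everything downstream
(abstractions, scoring, learning agents) operates on this one container.

Planning is exact: value iteration for optimal values, a direct linear solve
for policy evaluation, and exact forward propagation of state distributions
for expected reward sequences.  Sampling only happens in :func:`rollout`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TabularMDP",
    "Policy",
    "Trajectory",
    "value_iteration",
    "policy_evaluation",
    "expected_reward_sequence",
    "expected_rewards",
    "rollout",
    "load_mdp_json",
    "save_mdp_json",
    "uniform_random_policy",
    "deterministic_policy",
    "permute_states",
]

_ATOL = 1e-9


class MDPValidationError(ValueError):
    """Raised when a transition/reward table violates the MDP contract."""


@dataclass(frozen=True)
class TabularMDP:
    """Finite MDP ``⟨S, A, p, r, γ⟩`` stored as dense numpy tables.

    Parameters
    ----------
    transition
        Array of shape ``(n_states, n_actions, n_states)``; ``transition[s, a]``
        is a probability vector over successor states.
    reward
        Array of the same shape; ``reward[s, a, s']`` is the scalar reward for
        that transition.
    discount
        Discount factor γ in ``[0, 1)``.
    start_distribution
        Probability vector over states; defaults to uniform.
    absorbing
        Indices of absorbing states.  Absorbing states must self-transition
        with probability one and yield zero reward under every action.
    labels
        Optional human-readable names, e.g. ``{"states": [...], "actions": [...]}``.
    """

    transition: np.ndarray
    reward: np.ndarray
    discount: float
    start_distribution: np.ndarray | None = None
    absorbing: frozenset[int] = frozenset()
    labels: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        p = np.asarray(self.transition, dtype=float)
        r = np.asarray(self.reward, dtype=float)
        if p.ndim != 3 or p.shape[0] != p.shape[2]:
            raise MDPValidationError(f"transition table must be (S, A, S), got {p.shape}")
        if r.shape != p.shape:
            raise MDPValidationError(f"reward shape {r.shape} != transition shape {p.shape}")
        if not (0.0 <= self.discount < 1.0):
            raise MDPValidationError(f"discount must lie in [0, 1), got {self.discount}")
        if np.any(p < -_ATOL) or np.any(p > 1 + _ATOL):
            raise MDPValidationError("transition probabilities must lie in [0, 1]")
        if not np.all(np.isfinite(r)):
            raise MDPValidationError("rewards must be finite")
        rowsum = p.sum(axis=2)
        bad = np.argwhere(np.abs(rowsum - 1.0) > 1e-9)
        if bad.size:
            s, a = bad[0]
            raise MDPValidationError(
                f"transition row (s={s}, a={a}) sums to {rowsum[s, a]:.12f}, not 1"
            )
        mu = self.start_distribution
        if mu is None:
            mu = np.full(p.shape[0], 1.0 / p.shape[0])
        else:
            mu = np.asarray(mu, dtype=float)
            if mu.shape != (p.shape[0],) or np.any(mu < -_ATOL):
                raise MDPValidationError("start_distribution must be a probability vector over states")
            if abs(mu.sum() - 1.0) > 1e-9:
                raise MDPValidationError(f"start_distribution sums to {mu.sum():.12f}, not 1")
        absorbing = frozenset(int(i) for i in self.absorbing)
        for s in absorbing:
            if not (0 <= s < p.shape[0]):
                raise MDPValidationError(f"absorbing state {s} out of range")
            if not np.allclose(p[s, :, s], 1.0, atol=1e-9) or np.any(np.abs(r[s]) > 1e-9):
                raise MDPValidationError(
                    f"absorbing state {s} must self-loop with probability 1 and zero reward"
                )
        object.__setattr__(self, "transition", p)
        object.__setattr__(self, "reward", r)
        object.__setattr__(self, "start_distribution", mu)
        object.__setattr__(self, "absorbing", absorbing)

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_actions(self) -> int:
        return self.transition.shape[1]

    def with_discount(self, gamma: float) -> "TabularMDP":
        return replace(self, discount=gamma)

    def __eq__(self, other):
        if not isinstance(other, TabularMDP):
            return NotImplemented
        return (
            self.transition.shape == other.transition.shape
            and np.array_equal(self.transition, other.transition)
            and np.array_equal(self.reward, other.reward)
            and self.discount == other.discount
            and np.array_equal(self.start_distribution, other.start_distribution)
            and self.absorbing == other.absorbing
        )


@dataclass(frozen=True)
class Policy:
    """Stochastic policy as an action-probability table ``π[s, a]``."""

    probs: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.probs, dtype=float)
        if pi.ndim != 2:
            raise MDPValidationError("policy table must be 2-D (states × actions)")
        if np.any(pi < -_ATOL) or np.any(np.abs(pi.sum(axis=1) - 1.0) > 1e-9):
            raise MDPValidationError("policy rows must be probability vectors")
        object.__setattr__(self, "probs", pi)

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    @property
    def n_actions(self) -> int:
        return self.probs.shape[1]

    def greedy_actions(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


@dataclass(frozen=True)
class Trajectory:
    """A sampled episode: chained ``(s, a, r, s')`` quadruples."""

    states: np.ndarray        # length T+1
    actions: np.ndarray       # length T
    rewards: np.ndarray       # length T
    terminated: bool          # entered an absorbing state before the step cap
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.actions)

    def quadruples(self):
        """Iterate over ``(s, a, r, s')`` tuples."""
        for i in range(len(self.actions)):
            yield (
                int(self.states[i]),
                int(self.actions[i]),
                float(self.rewards[i]),
                int(self.states[i + 1]),
            )


def uniform_random_policy(mdp: TabularMDP) -> Policy:
    return Policy(np.full((mdp.n_states, mdp.n_actions), 1.0 / mdp.n_actions))


def deterministic_policy(actions: np.ndarray, n_actions: int) -> Policy:
    """One-hot policy taking ``actions[s]`` in state ``s``."""
    actions = np.asarray(actions, dtype=int)
    pi = np.zeros((len(actions), n_actions))
    pi[np.arange(len(actions)), actions] = 1.0
    return Policy(pi)


def expected_rewards(mdp: TabularMDP) -> np.ndarray:
    """One-step expected reward table ``r(s, a) = Σ_s' p(s,a,s') r(s,a,s')``."""
    return np.einsum("ijk,ijk->ij", mdp.transition, mdp.reward)


def _policy_transition(mdp: TabularMDP, policy: Policy) -> np.ndarray:
    """State-to-state kernel ``P_π[s, s'] = Σ_a π(a|s) p(s,a,s')``."""
    return np.einsum("ij,ijk->ik", policy.probs, mdp.transition)


def value_iteration(mdp: TabularMDP, tol: float = 1e-8) -> tuple[np.ndarray, Policy]:
    """Compute optimal state values and a deterministic greedy policy.

    Iterates the Bellman optimality operator until the sup-norm update falls
    below ``tol·(1−γ)/γ``, which bounds the distance of the returned values
    from the fixed point by ``tol``.  Greedy ties are broken toward the lowest
    action index so the result is deterministic.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    gamma = mdp.discount
    r_sa = expected_rewards(mdp)
    V = np.zeros(mdp.n_states)
    stop = tol * (1 - gamma) / gamma if gamma > 0 else np.inf
    for _ in range(1_000_000):
        Q = r_sa + gamma * mdp.transition @ V
        V_new = Q.max(axis=1)
        if np.max(np.abs(V_new - V)) < stop:
            V = V_new
            break
        V = V_new
    Q = r_sa + gamma * mdp.transition @ V
    greedy = Q.argmax(axis=1)  # argmax takes the lowest index on ties
    return V, deterministic_policy(greedy, mdp.n_actions)


def policy_evaluation(mdp: TabularMDP, policy: Policy) -> np.ndarray:
    """Exact ``V^π`` via the linear Bellman equations ``(I − γP_π)V = R_π``."""
    if policy.probs.shape != (mdp.n_states, mdp.n_actions):
        raise MDPValidationError("policy shape does not match the MDP")
    P_pi = _policy_transition(mdp, policy)
    R_pi = np.einsum("ij,ij->i", policy.probs, expected_rewards(mdp))
    A = np.eye(mdp.n_states) - mdp.discount * P_pi
    return np.linalg.solve(A, R_pi)


def action_values(mdp: TabularMDP, V: np.ndarray) -> np.ndarray:
    """Q-table induced by a state-value vector: ``Q(s,a) = r(s,a) + γ Σ p V``."""
    return expected_rewards(mdp) + mdp.discount * mdp.transition @ np.asarray(V, float)


def expected_reward_sequence(
    mdp: TabularMDP, start: int, actions: list[int] | np.ndarray
) -> np.ndarray:
    """Expected reward sequence ``(r_1, …, r_t)`` for a fixed action sequence.

    The state distribution is propagated exactly through the transition kernel,
    so the k-th entry is the expectation of the k-th reward over every
    trajectory consistent with the action sequence — no sampling involved.
    """
    actions = list(actions)
    if not actions:
        raise ValueError("action sequence must be non-empty")
    if not (0 <= start < mdp.n_states):
        raise ValueError(f"start state {start} out of range")
    r_sa = expected_rewards(mdp)
    dist = np.zeros(mdp.n_states)
    dist[start] = 1.0
    out = np.empty(len(actions))
    for k, a in enumerate(actions):
        if not (0 <= a < mdp.n_actions):
            raise ValueError(f"action {a} out of range")
        out[k] = dist @ r_sa[:, a]
        dist = dist @ mdp.transition[:, a, :]
    return out


def rollout(
    mdp: TabularMDP,
    policy: Policy,
    max_steps: int,
    rng: np.random.Generator,
    start: int | None = None,
) -> Trajectory:
    """Sample a trajectory under ``p`` and ``π``.

    Stops after ``max_steps`` transitions or upon entering an absorbing state,
    whichever comes first.  The same generator state always yields the same
    trajectory.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    s = int(rng.choice(mdp.n_states, p=mdp.start_distribution)) if start is None else int(start)
    states, acts, rews = [s], [], []
    terminated = s in mdp.absorbing
    for _ in range(max_steps):
        if terminated:
            break
        a = int(rng.choice(mdp.n_actions, p=policy.probs[s]))
        s_next = int(rng.choice(mdp.n_states, p=mdp.transition[s, a]))
        acts.append(a)
        rews.append(mdp.reward[s, a, s_next])
        states.append(s_next)
        s = s_next
        if s in mdp.absorbing:
            terminated = True
    return Trajectory(
        states=np.array(states, dtype=int),
        actions=np.array(acts, dtype=int),
        rewards=np.array(rews, dtype=float),
        terminated=terminated,
    )


def permute_states(mdp: TabularMDP, perm: np.ndarray) -> TabularMDP:
    """Relabel states by a permutation: new index ``perm[s]`` ↔ old index ``s``."""
    perm = np.asarray(perm, dtype=int)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    p = mdp.transition[inv][:, :, inv]
    r = mdp.reward[inv][:, :, inv]
    mu = mdp.start_distribution[inv]
    return TabularMDP(
        transition=p,
        reward=r,
        discount=mdp.discount,
        start_distribution=mu,
        absorbing=frozenset(int(perm[s]) for s in mdp.absorbing),
    )


# ---------------------------------------------------------------------------
# JSON interchange

def save_mdp_json(mdp: TabularMDP, path) -> None:
    payload = {
        "n_states": mdp.n_states,
        "n_actions": mdp.n_actions,
        "gamma": mdp.discount,
        "transition": mdp.transition.tolist(),
        "reward": mdp.reward.tolist(),
        "start_distribution": mdp.start_distribution.tolist(),
        "absorbing": sorted(mdp.absorbing),
        "labels": mdp.labels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_mdp_json(path) -> TabularMDP:
    with open(path) as fh:
        payload = json.load(fh)
    mdp = TabularMDP(
        transition=np.array(payload["transition"], dtype=float),
        reward=np.array(payload["reward"], dtype=float),
        discount=float(payload["gamma"]),
        start_distribution=np.array(payload["start_distribution"], dtype=float),
        absorbing=frozenset(payload.get("absorbing", [])),
        labels=payload.get("labels", {}),
    )
    if mdp.n_states != payload["n_states"] or mdp.n_actions != payload["n_actions"]:
        raise MDPValidationError("declared sizes do not match table shapes")
    return mdp
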