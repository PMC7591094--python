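"""Learning state abstractions from experience.

Two learners, both operating on transition/reward tables (exact ones, or
tables estimated from transition quadruples):

* ``learn_reward_predictive`` — a partition-refinement fixed point in the
  spirit of linear successor-feature models: start from states with matching
  one-step expected reward profiles, then repeatedly split cells whose
  members' successor features (computed over the current partition's one-hot
  features, under a uniform-random reference policy) disagree.  At the fixed
  point merged states have equal rewards and equal SFs, which makes the
  partition reward-predictive; with a zero tolerance it is the *coarsest*
  such partition.

* ``learn_reward_maximizing`` — cluster states with approximately equal
  optimal Q-vectors; the lifted greedy policy of the result is optimal when
  the tolerance is zero.

Tolerance-based merging uses single linkage over the ε-closeness graph;
ε-closeness is not transitive, so linkage choice matters for ε > 0 (it only
affects the granularity ranking, never the ε = 0 result).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abstraction import StatePartition, canonicalize
from .mdp_core import Policy, TabularMDP, Trajectory, action_values, expected_rewards, uniform_random_policy, value_iteration

__all__ = [
    "TransitionDataset",
    "estimate_tables",
    "refine_reward_predictive",
    "learn_reward_predictive",
    "learn_reward_maximizing",
    "single_linkage_clusters",
]

#: numerical slack used when a tolerance of exactly zero is requested;
#: table entries come out of linear solves and carry float noise.
_EXACT_TOL = 1e-9


@dataclass
class TransitionDataset:
    """A set of ``(s, a, r, s')`` quadruples with episode boundaries."""

    n_states: int
    n_actions: int
    s: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    r: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    s_next: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    episode: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=int)
        self.a = np.asarray(self.a, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        self.s_next = np.asarray(self.s_next, dtype=int)
        self.episode = np.asarray(self.episode, dtype=int)
        n = len(self.s)
        if not (len(self.a) == len(self.r) == len(self.s_next) == len(self.episode) == n):
            raise ValueError("all quadruple columns must have equal length")
        if n:
            if self.s.min() < 0 or max(self.s.max(), self.s_next.max()) >= self.n_states:
                raise ValueError("state index out of declared range")
            if self.a.min() < 0 or self.a.max() >= self.n_actions:
                raise ValueError("action index out of declared range")
            if not np.all(np.isfinite(self.r)):
                raise ValueError("rewards must be finite")

    def __len__(self) -> int:
        return len(self.s)

    def append_trajectory(self, traj: Trajectory, episode: int) -> None:
        quads = np.array(list(traj.quadruples()), dtype=float).reshape(-1, 4)
        self.s = np.concatenate([self.s, quads[:, 0].astype(int)])
        self.a = np.concatenate([self.a, quads[:, 1].astype(int)])
        self.r = np.concatenate([self.r, quads[:, 2]])
        self.s_next = np.concatenate([self.s_next, quads[:, 3].astype(int)])
        self.episode = np.concatenate([self.episode, np.full(len(quads), episode, dtype=int)])

    def to_csv(self, path) -> None:
        step = np.concatenate([np.arange(np.sum(self.episode == e)) for e in np.unique(self.episode)]) if len(self) else np.empty(0, dtype=int)
        pd.DataFrame(
            {"episode": self.episode, "step": step, "s": self.s, "a": self.a, "r": self.r, "s_next": self.s_next}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_states: int, n_actions: int) -> "TransitionDataset":
        df = pd.read_csv(path)
        return cls(
            n_states=n_states,
            n_actions=n_actions,
            s=df["s"].to_numpy(),
            a=df["a"].to_numpy(),
            r=df["r"].to_numpy(),
            s_next=df["s_next"].to_numpy(),
            episode=df["episode"].to_numpy(),
        )


def estimate_tables(
    data: TransitionDataset,
    discount: float = 0.9,
) -> TabularMDP:
    """Maximum-likelihood transition frequencies and mean rewards per (s, a, s').

    Unobserved (s, a) rows default to a zero-reward self-loop; the affected
    pairs are recorded under ``labels["unobserved_sa"]`` so callers can treat
    sparse coverage with suspicion rather than as ground truth.
    """
    if len(data) == 0:
        raise ValueError("cannot estimate tables from an empty dataset")
    S, A = data.n_states, data.n_actions
    counts = np.zeros((S, A, S))
    np.add.at(counts, (data.s, data.a, data.s_next), 1.0)
    reward_sums = np.zeros((S, A, S))
    np.add.at(reward_sums, (data.s, data.a, data.s_next), data.r)
    totals = counts.sum(axis=2)
    observed = totals > 0
    p = np.zeros_like(counts)
    p[observed] = counts[observed] / totals[observed][:, None]
    unobserved = np.argwhere(~observed)
    for s, a in unobserved:
        p[s, a, s] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(counts > 0, reward_sums / np.where(counts > 0, counts, 1.0), 0.0)
    return TabularMDP(
        transition=p,
        reward=r,
        discount=discount,
        labels={
            "unobserved_sa": [[int(s), int(a)] for s, a in unobserved],
            "n_transitions": int(len(data)),
        },
    )


def single_linkage_clusters(rows: np.ndarray, epsilon: float) -> np.ndarray:
    """Cluster row vectors whose sup-norm distance graph (≤ ε edges) is connected.

    Returns integer labels (not canonicalized).  With ε = 0 this groups rows
    that are equal up to the numerical slack.
    """
    n = len(rows)
    eps = max(float(epsilon), _EXACT_TOL)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    flat = rows.reshape(n, -1)
    for i in range(n - 1):
        d = np.max(np.abs(flat[i + 1:] - flat[i]), axis=1)
        for j in np.flatnonzero(d <= eps):
            ri, rj = find(i), find(int(i + 1 + j))
            if ri != rj:
                parent[rj] = ri
    return np.array([find(i) for i in range(n)])


def _split_by_rows(labels: np.ndarray, rows: np.ndarray, epsilon: float) -> np.ndarray:
    """Refine ``labels`` by clustering rows within each existing cell."""
    out = np.empty_like(labels)
    next_label = 0
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        sub = single_linkage_clusters(rows[members], epsilon)
        for k in np.unique(sub):
            out[members[sub == k]] = next_label
            next_label += 1
    return out


def refine_reward_predictive(
    tables: TabularMDP,
    epsilon: float = 1e-6,
    reference_policy: Policy | None = None,
) -> StatePartition:
    """Partition-refinement fixed point merging states with matching one-step
    expected rewards and matching successor features.

    Cells start as ε-clusters of one-step expected reward profiles and are
    iteratively split wherever members' SF rows (over the current partition's
    one-hot features) drift more than ε apart in sup-norm.  The cell count
    never decreases, so the loop terminates within ``n_states`` iterations.
    """
    from .scoring import successor_features  # local import: scoring also uses us

    if reference_policy is None:
        reference_policy = uniform_random_policy(tables)
    r_sa = expected_rewards(tables)
    labels = single_linkage_clusters(r_sa, epsilon)
    for _ in range(tables.n_states):
        partition = canonicalize(labels)
        psi = successor_features(tables, partition, reference_policy).psi
        new_labels = _split_by_rows(labels, psi.reshape(tables.n_states, -1), epsilon)
        if len(np.unique(new_labels)) == len(np.unique(labels)):
            break
        labels = new_labels
    return canonicalize(labels)


def learn_reward_predictive(
    tables: TabularMDP,
    epsilon: float = 1e-6,
    reference_policy: Policy | None = None,
) -> StatePartition:
    """Learn a reward-predictive partition from (estimated or exact) tables.

    ``epsilon`` controls how much two merged states' reward profiles and
    successor features may disagree; use a tolerance around 0.05 for tables
    estimated from sampled transitions and the (default) tight tolerance for
    exact tables.  With ``epsilon = 0`` the result is the coarsest exactly
    reward-predictive partition; the worst case is the identity partition.
    """
    return refine_reward_predictive(tables, epsilon=epsilon, reference_policy=reference_policy)


def learn_reward_maximizing(
    tables: TabularMDP,
    epsilon: float = 0.0,
    tol: float = 1e-8,
) -> StatePartition:
    """Cluster states with approximately equal optimal Q-vectors.

    Computes ``Q*`` by value iteration and merges states whose Q-vectors are
    within ε in sup-norm (single linkage).  With ε = 0, states in one cell
    share their optimal Q-vector, so the lifted greedy policy is optimal.
    """
    V, _ = value_iteration(tables, tol=tol)
    Q = action_values(tables, V)
    # with ε = 0 widen the slack to the planner's own tolerance
    labels = single_linkage_clusters(Q, max(epsilon, 10 * tol))
    return canonicalize(labels)
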