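"""State partitions (abstractions φ) and compression/inflation of MDPs.

A state abstraction is a surjective map φ from ground states to latent
states; it partitions the state space into cells of states treated as
equivalent.  The hypothesis space of all abstractions of an n-state task is
the set of set partitions of n elements, enumerated here in restricted-growth
order.  ``compress`` averages an MDP's tables within cells to build the
abstract MDP an agent would plan in; ``inflate`` does the reverse, embedding
a small MDP into a larger state space with a hidden, exactly
reward-predictive partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mdp_core import TabularMDP

__all__ = [
    "StatePartition",
    "AbstractMDP",
    "identity_partition",
    "canonicalize",
    "enumerate_partitions",
    "count_partitions",
    "compress",
    "inflate",
    "lift_policy",
    "partition_from_string",
]


@dataclass(frozen=True)
class StatePartition:
    """Surjective map from ``n_states`` ground states onto ``n_latent`` cells.

    The assignment is stored in canonical restricted-growth form: latent
    labels appear in order of first occurrence, so two partitions describe
    the same grouping iff their canonical assignments are identical.
    Construct via :func:`canonicalize` (or pass an already-canonical
    assignment).
    """

    assignment: tuple[int, ...]

    def __post_init__(self):
        a = tuple(int(x) for x in self.assignment)
        if not a:
            raise ValueError("partition of zero states is not allowed")
        seen = 0
        for x in a:
            if x > seen or x < 0:
                raise ValueError(
                    f"assignment {a} is not in restricted-growth form; use canonicalize()"
                )
            seen = max(seen, x + 1)
        object.__setattr__(self, "assignment", a)

    @property
    def n_states(self) -> int:
        return len(self.assignment)

    @property
    def n_latent(self) -> int:
        return max(self.assignment) + 1

    def __call__(self, s: int) -> int:
        return self.assignment[s]

    def array(self) -> np.ndarray:
        return np.asarray(self.assignment, dtype=int)

    def indicator(self) -> np.ndarray:
        """One-hot matrix Φ of shape ``(n_states, n_latent)``."""
        phi = np.zeros((self.n_states, self.n_latent))
        phi[np.arange(self.n_states), self.assignment] = 1.0
        return phi

    def cells(self) -> list[np.ndarray]:
        a = self.array()
        return [np.flatnonzero(a == x) for x in range(self.n_latent)]

    def refines(self, other: "StatePartition") -> bool:
        """True if every cell of this partition lies inside a cell of ``other``."""
        if self.n_states != other.n_states:
            raise ValueError("partitions must cover the same state space")
        mapping: dict[int, int] = {}
        for mine, theirs in zip(self.assignment, other.assignment):
            if mapping.setdefault(mine, theirs) != theirs:
                return False
        return True

    def to_string(self) -> str:
        return ",".join(str(x) for x in self.assignment)


def partition_from_string(text: str) -> StatePartition:
    return canonicalize([int(tok) for tok in text.strip().split(",")])


def identity_partition(n: int) -> StatePartition:
    return StatePartition(tuple(range(n)))


def canonicalize(assignment) -> StatePartition:
    """Relabel an arbitrary surjective assignment into restricted-growth form."""
    labels = [int(x) for x in (assignment.assignment if isinstance(assignment, StatePartition) else assignment)]
    relabel: dict[int, int] = {}
    out = []
    for x in labels:
        if x not in relabel:
            relabel[x] = len(relabel)
        out.append(relabel[x])
    return StatePartition(tuple(out))


def enumerate_partitions(n: int, k: int | None = None, max_n: int = 12):
    """Yield every set partition of ``n`` states exactly once, canonically.

    Partitions are produced as restricted-growth strings in lexicographic
    order; with ``k`` given, only partitions with exactly ``k`` cells are
    yielded.  ``n`` is capped (default 12) because the Bell numbers explode;
    pass a larger ``max_n`` explicitly to override.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds the enumeration guard ({max_n}); "
            "restrict to k cells or raise max_n explicitly"
        )
    if k is not None and not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")

    a = [0] * n          # restricted-growth string
    m = [0] * n          # m[i] = max(a[:i+1])
    while True:
        if k is None or m[n - 1] + 1 == k:
            yield StatePartition(tuple(a))
        # advance to the next restricted-growth string
        i = n - 1
        while i > 0 and a[i] == m[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        m[i] = max(m[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            m[j] = m[i]


def count_partitions(n: int, k: int | None = None) -> int:
    """Bell number B(n), or the Stirling number S(n, k), via the standard recurrence."""
    # S(n, k) table: S(n, k) = k·S(n−1, k) + S(n−1, k−1)
    S = np.zeros((n + 1, n + 1), dtype=object)
    S[0, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, i + 1):
            S[i, j] = j * S[i - 1, j] + S[i - 1, j - 1]
    if k is None:
        return int(sum(S[n, j] for j in range(n + 1)))
    return int(S[n, k])


@dataclass(frozen=True)
class AbstractMDP:
    """A compressed MDP over latent states plus how it was built."""

    mdp: TabularMDP
    source_partition: StatePartition
    weighting: np.ndarray = field(compare=False)


def compress(
    mdp: TabularMDP,
    partition: StatePartition,
    weighting: np.ndarray | None = None,
) -> AbstractMDP:
    """Average an MDP's tables within partition cells to form the abstract MDP.

    The latent transition is ``p̄(x, a, y) = Σ_{s∈x} w_s Σ_{s'∈y} p(s, a, s')``
    with weights ``w`` summing to one inside each cell (uniform by default),
    and the latent reward is the matching ``w``- and ``p``-weighted average of
    ``r(s, a, s')`` (zero where the transition mass is zero).
    """
    if partition.n_states != mdp.n_states:
        raise ValueError("partition does not match the MDP's state space")
    n_latent = partition.n_latent
    phi = partition.indicator()                      # (S, K)
    if weighting is None:
        cell_sizes = phi.sum(axis=0)
        w = (phi / cell_sizes).sum(axis=1)           # uniform within each cell
    else:
        w = np.asarray(weighting, dtype=float)
        if w.shape != (mdp.n_states,) or np.any(w < 0):
            raise ValueError("weighting must be a non-negative per-state vector")
        mass = phi.T @ w
        if np.any(mass <= 0):
            raise ValueError("weighting has zero total mass in some cell")
        w = w / mass[partition.array()]
    # p̄[x,a,y] = Σ_s w_s Φ[s,x] Σ_s' p[s,a,s'] Φ[s',y]
    p_bar = np.einsum("s,sx,say->xay", w, phi, mdp.transition @ phi)
    pr = mdp.transition * mdp.reward
    pr_bar = np.einsum("s,sx,say->xay", w, phi, pr @ phi)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_bar = np.where(p_bar > 0, pr_bar / np.where(p_bar > 0, p_bar, 1.0), 0.0)
    # renormalize away accumulated floating error so rows are exactly stochastic
    p_bar = p_bar / p_bar.sum(axis=2, keepdims=True)
    mu_bar = phi.T @ (mdp.start_distribution)
    latent_absorbing = _absorbing_cells(mdp, partition, p_bar, r_bar)
    abstract = TabularMDP(
        transition=p_bar,
        reward=r_bar,
        discount=mdp.discount,
        start_distribution=mu_bar / mu_bar.sum(),
        absorbing=latent_absorbing,
    )
    return AbstractMDP(mdp=abstract, source_partition=partition, weighting=w)


def _random_canonical_assignment(cell_sizes: list[int], rng: np.random.Generator) -> np.ndarray:
    """Uniformly shuffle which ground index lands in which cell, keeping the
    assignment in restricted-growth form and cell ``x`` of size ``cell_sizes[x]``.

    A uniform shuffle of the label multiset is relabelled by first occurrence;
    that preserves per-cell sizes directly when all sizes are equal, otherwise
    shuffles are redrawn until the relabelling is size-preserving (cheap for
    the handful of cells used here) with a deterministic block layout as the
    last resort.
    """
    k = len(cell_sizes)
    base = np.repeat(np.arange(k), cell_sizes)
    for _ in range(10_000):
        pattern = rng.permutation(base)
        order = []  # labels in order of first appearance
        seen = set()
        for lab in pattern:
            if lab not in seen:
                seen.add(int(lab))
                order.append(int(lab))
        if all(cell_sizes[order[i]] == cell_sizes[i] for i in range(k)):
            inv = {lab: i for i, lab in enumerate(order)}
            return np.array([inv[int(x)] for x in pattern], dtype=int)
    return base


def _absorbing_cells(mdp, partition, p_bar, r_bar) -> frozenset[int]:
    """Cells made up entirely of absorbing states stay absorbing in the latent task."""
    if not mdp.absorbing:
        return frozenset()
    out = set()
    for x, cell in enumerate(partition.cells()):
        if all(int(s) in mdp.absorbing for s in cell):
            if np.allclose(p_bar[x, :, x], 1.0) and np.allclose(r_bar[x], 0.0):
                out.add(x)
    return frozenset(out)


def lift_policy(partition: StatePartition, latent_policy) -> "np.ndarray":
    """Lift a latent policy table to ground states: ``π(s, a) = π̄(φ(s), a)``."""
    probs = latent_policy.probs if hasattr(latent_policy, "probs") else np.asarray(latent_policy)
    return probs[partition.array()]


def inflate(
    abstract: TabularMDP,
    cell_sizes: list[int] | None = None,
    rng: np.random.Generator | None = None,
    hidden: StatePartition | None = None,
) -> tuple[TabularMDP, StatePartition]:
    """Expand each latent state into several ground states.

    Ground state ``s`` in cell ``x`` moves under action ``a`` to cell ``y``
    with the latent probability ``p̄(x, a, y)``, spread uniformly over the
    members of ``y``; rewards copy ``r̄(x, a, y)``.  The returned hidden
    partition maps ground states back to latents and is exactly
    reward-predictive by construction: compressing the inflated MDP with it
    reproduces the input tables.

    Either pass ``cell_sizes`` (one per latent state) with an ``rng`` that
    shuffles which ground index lands in which cell, or pass an explicit
    ``hidden`` partition (latent ``x`` of the input ↔ cell ``x`` of the
    partition) to embed the same abstraction into several tasks.
    """
    if hidden is not None:
        if hidden.n_latent != abstract.n_states:
            raise ValueError("hidden partition must have one cell per latent state")
        latent_of = hidden.array()
        cell_sizes = [int(np.sum(latent_of == x)) for x in range(abstract.n_states)]
        n = hidden.n_states
    else:
        if cell_sizes is None:
            raise ValueError("provide cell_sizes (with rng) or an explicit hidden partition")
        if rng is None:
            raise ValueError("an rng is required when inflating with cell_sizes")
        cell_sizes = [int(c) for c in cell_sizes]
        if len(cell_sizes) != abstract.n_states:
            raise ValueError("need one cell size per latent state")
        if any(c < 1 for c in cell_sizes):
            raise ValueError("every cell size must be >= 1")
        n = sum(cell_sizes)
        latent_of = _random_canonical_assignment(cell_sizes, rng)
    members = [np.flatnonzero(latent_of == x) for x in range(abstract.n_states)]
    p = np.zeros((n, abstract.n_actions, n))
    r = np.zeros_like(p)
    for x in range(abstract.n_states):
        for a in range(abstract.n_actions):
            for y in range(abstract.n_states):
                share = abstract.transition[x, a, y] / cell_sizes[y]
                p[np.ix_(members[x], [a], members[y])] = share
                r[np.ix_(members[x], [a], members[y])] = abstract.reward[x, a, y]
    mu = np.zeros(n)
    for x in range(abstract.n_states):
        mu[members[x]] = abstract.start_distribution[x] / cell_sizes[x]
    absorbing = frozenset(
        int(s) for x in abstract.absorbing for s in members[x] if cell_sizes[x] == 1
    ) if abstract.absorbing else frozenset()
    # absorbing latents with several ground members would need within-cell
    # self-loops; keep them non-absorbing at ground level unless singleton
    hidden = StatePartition(tuple(int(x) for x in latent_of))
    ground = TabularMDP(
        transition=p,
        reward=r,
        discount=abstract.discount,
        start_distribution=mu,
        absorbing=absorbing,
    )
    return ground, hidden
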