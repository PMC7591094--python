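"""Non-parametric Bayesian belief over state abstractions.

Across a task sequence the agent maintains a belief set ``B_t`` of
previously used abstractions with use counts ``c_t``.  A Chinese restaurant
process prior (concentration α) favours re-use proportional to counts while
reserving ``α/(t−1+α)`` mass for a fresh candidate; a softmax likelihood
``∝ exp(−β·l(φ))`` scores how well each abstraction fits the current task's
loss.  The posterior is their normalized product; β = ∞ collapses it onto
the minimum-loss abstraction, ignoring the prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .abstraction import StatePartition, partition_from_string
from .mdp_core import Policy

__all__ = [
    "BeliefSet",
    "crp_prior",
    "abstraction_likelihood",
    "posterior",
    "select_and_update",
    "mixture_policy",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class BeliefSet:
    """Abstractions retained so far, their use counts, and the model parameters.

    ``counts`` always sum to ``t − 1`` where ``t`` is the index of the task
    about to be processed (1-based); abstractions are pairwise distinct in
    canonical form.  ``beta`` may be ``math.inf``.
    """

    alpha: float
    beta: float
    abstractions: tuple[StatePartition, ...] = ()
    counts: tuple[int, ...] = ()

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if len(self.abstractions) != len(self.counts):
            raise ValueError("one count per abstraction required")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be positive integers")
        if len({phi.assignment for phi in self.abstractions}) != len(self.abstractions):
            raise ValueError("belief abstractions must be pairwise distinct")

    @property
    def t(self) -> int:
        """Index of the next task (1-based): counts sum to t − 1."""
        return sum(self.counts) + 1

    def __len__(self) -> int:
        return len(self.abstractions)

    def index_of(self, candidate: StatePartition) -> int | None:
        for i, phi in enumerate(self.abstractions):
            if phi.assignment == candidate.assignment:
                return i
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "beta": "inf" if math.isinf(self.beta) else self.beta,
                "abstractions": [phi.to_string() for phi in self.abstractions],
                "counts": list(self.counts),
                "t": self.t,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BeliefSet":
        obj = json.loads(text)
        beta = math.inf if obj["beta"] == "inf" else float(obj["beta"])
        return cls(
            alpha=float(obj["alpha"]),
            beta=beta,
            abstractions=tuple(partition_from_string(s) for s in obj["abstractions"]),
            counts=tuple(int(c) for c in obj["counts"]),
        )


def crp_prior(belief: BeliefSet, include_candidate: bool = True) -> np.ndarray:
    """CRP prior over belief members (+ one candidate slot appended last).

    Member φ gets ``c_t(φ)/(t−1+α)``; the candidate slot gets ``α/(t−1+α)``.
    With an empty belief the candidate receives probability one.
    """
    t = belief.t
    denom = (t - 1) + belief.alpha
    probs = [c / denom for c in belief.counts]
    if include_candidate:
        probs.append(belief.alpha / denom)
    out = np.asarray(probs, dtype=float)
    if not include_candidate:
        if out.size == 0:
            raise ValueError("empty belief has no members to normalize over")
        out = out / out.sum()
    return out


def abstraction_likelihood(losses, beta: float) -> np.ndarray:
    """Softmax fit probability ``∝ exp(−β·l(φ))`` over the evaluated set.

    β = 0 is uniform; β = ∞ puts all mass on the minimum loss (first index on
    ties).  Losses must be finite and non-negative.
    """
    losses = np.asarray(losses, dtype=float)
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if not np.all(np.isfinite(losses)) or np.any(losses < 0):
        raise ValueError("losses must be finite and non-negative")
    if math.isinf(beta):
        out = np.zeros_like(losses)
        out[int(np.argmin(losses))] = 1.0
        return out
    logits = -beta * (losses - losses.min())       # shift for numerical safety
    weights = np.exp(logits)
    return weights / weights.sum()


def _argmin_with_preference(belief: BeliefSet, losses: np.ndarray) -> int:
    """β = ∞ tie rule: among minimal losses prefer existing members over the
    candidate, then the highest count, then insertion order."""
    lo = losses.min()
    tied = np.flatnonzero(losses <= lo + _TIE_TOL)
    members = [i for i in tied if i < len(belief)]
    if members:
        return max(members, key=lambda i: (belief.counts[i], -i))
    return int(tied[0])


def posterior(belief: BeliefSet, candidate: StatePartition, losses) -> np.ndarray:
    """Posterior over ``B_t ∪ {candidate}``: prior × likelihood, renormalized.

    ``losses`` must align with the belief members followed by the candidate.
    With β = ∞ the posterior is the loss-argmin indicator (prior ignored,
    ties resolved toward existing members, then higher counts).
    """
    losses = np.asarray(losses, dtype=float)
    if len(losses) != len(belief) + 1:
        raise ValueError("need one loss per belief member plus the candidate")
    if math.isinf(belief.beta):
        out = np.zeros(len(losses))
        out[_argmin_with_preference(belief, losses)] = 1.0
        return out
    prior = crp_prior(belief, include_candidate=True)
    like = abstraction_likelihood(losses, belief.beta)
    product = prior * like
    total = product.sum()
    if total <= 0:
        raise RuntimeError("posterior mass vanished; this cannot occur for α > 0 and finite losses")
    return product / total


def select_and_update(
    belief: BeliefSet,
    posterior_probs: np.ndarray,
    candidate: StatePartition,
    rng: np.random.Generator,
) -> tuple[StatePartition, BeliefSet]:
    """Sample one abstraction from the posterior and update the belief.

    A sampled member has its count incremented; a sampled novel candidate is
    appended with count one (a candidate canonically equal to a member just
    increments that member).  Either way the task index advances by one.
    """
    posterior_probs = np.asarray(posterior_probs, dtype=float)
    if len(posterior_probs) != len(belief) + 1:
        raise ValueError("posterior length must be members + 1")
    idx = int(rng.choice(len(posterior_probs), p=posterior_probs))
    if idx < len(belief):
        chosen = belief.abstractions[idx]
    else:
        chosen = candidate
        existing = belief.index_of(candidate)
        if existing is not None:
            idx = existing
    if idx < len(belief):
        counts = list(belief.counts)
        counts[idx] += 1
        updated = replace(belief, counts=tuple(counts))
    else:
        updated = replace(
            belief,
            abstractions=belief.abstractions + (candidate,),
            counts=belief.counts + (1,),
        )
    return chosen, updated


def mixture_policy(posterior_probs: np.ndarray, component_policies: list[Policy]) -> Policy:
    """Posterior-weighted convex combination of component policies."""
    posterior_probs = np.asarray(posterior_probs, dtype=float)
    if len(posterior_probs) != len(component_policies):
        raise ValueError("one posterior weight per component policy required")
    stacked = np.stack([p.probs for p in component_policies])
    return Policy(np.einsum("m,msa->sa", posterior_probs, stacked))
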