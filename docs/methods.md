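# Methods

`abstraxion` studies which *state abstractions* — surjective maps
φ : S → S_φ from the states of a finite Markov decision process (MDP) onto a
smaller latent space — can be re-used across tasks whose transition and
reward functions both change. It implements two competing notions of a good
abstraction, exact and empirical scores for each, learners that extract them
from data, a non-parametric Bayesian agent that accumulates and re-uses a
belief set of abstractions across a task sequence, and generators for all
the simulation environments the experiments run on.

## The model

A task is a finite MDP ⟨S, A, p, r, γ⟩ with dense tables
p(s, a, s′), r(s, a, s′) and discount γ ∈ [0, 1). Compressing a task through
a partition φ with within-cell weights w (uniform by default) yields the
abstract MDP with

    p̄(x, a, y) = Σ_{s∈x} w_s Σ_{s′∈y} p(s, a, s′),
    r̄(x, a, y) = the matching w- and p-weighted average of r(s, a, s′),

with r̄ set to 0 on zero-probability latent arcs (those terms never enter
any score). The inverse operation, *inflation*, expands each latent state
into several ground states, spreading transition mass uniformly over target
cells; this plants a hidden partition that is exactly reward-predictive by
construction and makes `compress(inflate(M), hidden)` reproduce M to
machine precision.

**Reward-maximizing abstractions.** φ is reward-maximizing when the greedy
policy of the compressed task, lifted back through φ, is optimal in the
ground task. The exact loss is

    l_max(φ) = max_s ( V*(s) − V^{π_φ}(s) ),

computed with exact planners (value iteration to a sup-norm residual of
tol·(1−γ)/γ, tol = 1e-8; policy evaluation by direct linear solve).

**Reward-predictive abstractions.** φ is reward-predictive when the
compressed task predicts, for every start state and action sequence, the
expected reward sequence of the ground task. Successor features (SFs)

    ψ^π(s, a) = E[ e_{φ(s₁)} + γ e_{φ(s₂)} + γ² e_{φ(s₃)} + … | s₁ = s, a₁ = a, π ]

are computed exactly as the solution of their linear fixed point. Two states
are *reward-predictively equivalent* when they agree in one-step expected
rewards for every action and in their SF rows over the coarsest
reward-predictive partition φ\* (uniform-random reference policy, chosen
because reward-predictive abstractions are policy-independent). The package
scores a partition by the pairwise deviation metric

    D(s, u) = max_a |r(s,a) − r(u,a)| + max_a ‖ψ*(s,a) − ψ*(u,a)‖_∞,
    l_pred(φ) = max { D(s, u) : φ(s) = φ(u) },

where ψ\* are the SFs over φ\*. Because D is a fixed metric on state pairs,
l_pred is *exactly monotone under refinement* (a finer partition merges a
subset of the pairs) and its zero set is exactly the partitions refining
φ\* — the condition under which compressed reward-sequence predictions are
exact. An alternative formulation that measures SF spread over the evaluated
partition's *own* features has the same zero set but is not monotone
(splitting a cell of equivalent states redistributes occupancy mass between
the new cells and can raise the sup-norm spread), which is why the fixed
metric is used. The magnitude of l_pred grades how badly merged states
disagree; it is a ranking device, not a calibrated bound. The companion
constant `discount_bound_constant(γ, t) = Σ_{k<t} γ^k` is exposed for
reporting a cumulative-error bound over a horizon, nothing more.

Empirical counterparts: `total_reward_score` (mean total reward of N
rollouts of T steps from the start distribution) and
`reward_sequence_error` (mean cumulative |true − predicted| reward over
random start states and uniform random action sequences, with both
sequences evaluated by exact distribution propagation, starts drawn
uniformly over states).

## Learning abstractions from tables

`learn_reward_predictive` runs a partition-refinement fixed point: initial
cells cluster states whose one-step expected reward profiles are within ε
(single linkage, sup-norm); each iteration recomputes SFs over the current
partition's one-hot features and splits cells whose members' SF rows drift
more than ε apart. Cells only split, so the loop terminates within |S|
iterations. With ε → 0 the result is the coarsest exactly reward-predictive
partition: every reward-predictive partition refines every iterate (its
cells have equal reward rows and equal SFs, which aggregate consistently),
so the fixed point is coarsest, and its own cells satisfy the equal-reward /
equal-SF condition that makes it reward-predictive.

`learn_reward_maximizing` clusters states whose optimal Q-vectors are
within ε in sup-norm (single linkage); at ε = 0 the lifted greedy policy is
optimal.

ε defaults: 1e-6 for exact tables (pure float-noise absorption; a zero
tolerance is interpreted as 1e-9 because table entries come from linear
solves), 0.8 for tables estimated from the online runs below. The online
value was calibrated once on pilot rollouts of the maze generator: with
roughly 200 episodes of ε-greedy data the median (s, a) pair is visited ~10
times, SF estimates carry noise of a few tenths, while genuinely distinct
maze positions differ by ≥ 1 in reward units (the cliff sits at ε = 1.0,
where reward-distinct states start to merge); 0.8 recovers ~100–116 latent
cells out of 200 states and always refines the true hidden partition on
both maze variants. Single-linkage ε-closeness is not transitive; the
linkage choice only affects granularity for ε > 0, never the ε = 0 result.

## The belief model

Across a task sequence the agent keeps a belief set B_t of abstractions
with use counts c_t. The prior is a Chinese restaurant process with
concentration α: a member gets c_t(φ)/(t−1+α), a fresh candidate
α/(t−1+α). The likelihood of φ fitting the current task is
softmax(−β·l(φ)) over the evaluated set; the posterior is the normalized
product. β = ∞ selects the minimum-loss abstraction outright (ties prefer
existing members, then higher counts, then insertion order — keeping belief
sets minimal); the belief is updated by *sampling* the posterior, not by
MAP. The evaluation policy is the posterior-weighted mixture of the
per-abstraction policies.

**Oracle setting** (cycle curriculum): the candidate is the exhaustive loss
argmin over all 3025 partitions of 9 states into exactly 3 cells, excluding
current members; the identity abstraction is excluded by the 9→3
constraint. The mixture policy is evaluated for 10 steps per task as an
exact expectation over the start distribution (equivalent to averaging
rollouts from every start state, without sampling noise).

**Online setting** (maze and guitar curricula): one tabular Q-learner per
belief member plus one on the identity abstraction; the identity learner
occupies the candidate slot of the CRP prior and is never added to the
belief. Actions are drawn from the posterior mixture. While acting, the
agent estimates transition/reward tables from all observed quadruples
(unobserved (s, a) default to zero-reward self-loops and are flagged); the
posterior is refreshed every 5 episodes using member losses evaluated *on
the estimated tables, restricted to observed state/action pairs* — an
unvisited state carries no evidence against an abstraction. For these
noisy estimates the member loss averages the pairwise deviations over
merged pairs instead of taking the maximum, which keeps one
noise-contaminated pair from vetoing an otherwise correct abstraction; the
exact scoring loss remains the max form. After 200 episodes the candidate
abstraction is learned from the tables and the belief updated by posterior
sampling. Online defaults α = 0.05, β = 5 were fixed once from the same
pilot calibration: the correct member's observed-pair loss floors around
0.2 on sampled maze tables while a wrong member sits at 1.5–5, so β = 5
separates them (e^{−1} vs e^{−7.5}) while α = 0.05 keeps the identity
learner a minority partner once a member fits.

## Agents

Q-learning operates on latent indices: one update generalizes over the
whole cell. Exploration is ε-greedy annealed linearly from 1 to 0 by
episode 80 (the maze experiments), or pure greedy on an optimistically
initialized table (the guitar experiments, where all rewards are ≤ 0 and a
zero initialization is optimistic). Greedy ties break uniformly at random.
Defaults: learning rate 0.9 (Q and SF), 0.5 for reward weights, 200
episodes per task, a 5,000-step episode cap to bound pre-learning random
walks.

SF-learning maintains successor features F[x, a] (TD update toward
e_x + γ F[φ(s′), a*]) and one-step reward estimates w[x, a] (delta rule).
Action values use the successor-representation decomposition
Q̂(s, a) = w[x, a] + (F[x, a] − e_x)·ρ with ρ(y) = w[y, a*_y] the reward of
the action the current policy would take at y (a cached greedy table
refreshed at the cells each transition touches). Two design points matter
here. First, reward weights are indexed per (latent, action): a per-state
reward vector cannot represent action-dependent rewards, and the resulting
value model provably mis-ranks self-loops (a state whose best action pays 1
would make *waiting* at that state look worth 1/(1−γ)). Second, pricing
future occupancies at the policy's own action rather than the best
one-step reward makes a reward-consistent policy the only stable fixed
point: a policy that cycles without collecting reward values its own loop
at zero and is broken up by random tie-breaking. Transfer modes at a task
switch: `reset` (fresh F and w), `sf_transfer` (keep F, reset w),
`sf_and_reward_transfer` (keep both).

## Task suite

* **Column world** — 3×3 deterministic grid; entering the right column from
  the centre column under "move right" pays +1 (three rewarded (s, a)
  pairs). The rewarded column is absorbing; this is what makes the
  all-states-in-one compression reward-maximizing (after the reward,
  nothing is left to decide). Columns form the reward-predictive partition.
* **Barrier grids** — the same construction with impassable wall edges and
  a configurable goal column; the 8-task family permutes two goal columns
  with four wall placements.
* **Random inflated sets** — random 3-state MDPs (flat-Dirichlet transition
  rows, Bernoulli(½) unit rewards per latent arc) inflated to 9 states
  through one shared random surjective partition; tasks differ in both
  transitions and rewards but share the abstraction.
* **Cycle curriculum** — 20 tasks; each is a 3-state ring where exactly one
  (randomly labelled) action advances at each state and one arc pays +1,
  inflated with hidden abstraction φ_A (probability 0.75) or φ_B. The
  optimal policy collects 1 per 3 steps.
* **Maze curriculum** — five 10×10 grid mazes: A-light/dark, A-coloured,
  A-light/dark, B-light/dark, B-coloured, with maze B the left-right mirror
  of A. Moves succeed with probability 0.95 (else the agent stays); the
  goal is absorbing and pays +1. The light/dark bit resamples uniformly
  every step and doubles the state space to 200; the colour variable
  triples only right-half cells (also 200 states). States are exposed as
  opaque indices; the hidden partition merging the irrelevant variable has
  100 cells and zero predictive loss. The default wall layout (two
  staggered horizontal barriers forcing an S-shaped route) is a package
  fixture; every comparison is within-layout, so conclusions do not depend
  on the specific map.
* **Guitar scales** — play a note sequence on a fret board: 12 note
  actions; a start state plus one fret-board configuration per scale
  position in each of three octaves (22 states for 7-note scales); the
  first correct note lands in a uniformly random octave; correct notes
  advance (reward 0), wrong notes self-loop (−1); the final position is
  absorbing. Merging the three octaves position-wise is the hidden
  reward-predictive partition. Fret-board bit matrices (6 strings × 10
  frets, standard tuning) are attached as metadata.

γ = 0.9 everywhere by default, configurable per task.

## What the generators do and do not emulate

The synthetic tasks realize the structural premises being studied — shared
latent structure under changing transitions/rewards, irrelevant state
variables, interchangeable action contexts — with small, exactly solvable
state spaces. They do not model perceptual noise, continuous or factored
state, non-stationarity within a task, or reward magnitudes beyond ±1.
Passing tests therefore demonstrate the abstraction-transfer mechanisms
under exactly-compressible (or mildly lossy) conditions, not performance on
naturalistic domains.

## Problem sizes and numerical choices

Experiments default to the full protocol sizes (20-task curricula,
200 episodes per maze task, 100 per guitar task, 20 trials × 10 steps for
empirical scores). The test suite and worked examples run reduced repeat
counts chosen as the package's own desk-scale defaults: 10–20 cycle
curricula for belief statistics, 5–10 seeds for online comparisons, 9→3
enumeration restricted to three-cell partitions where the full
21,147-partition space is not required. Batch planning over thousands of
compressed tasks uses exact policy iteration (batched linear solves);
scalar planning uses value iteration with tol = 1e-8. Greedy planner ties
break toward the lowest action index for reproducibility; behaving agents
break ties uniformly at random to preserve exploration. All randomness
flows through explicitly passed seeds or `numpy` generators; seeded runs
are bit-reproducible.

## Known limitations

* l_pred magnitudes are comparable within one task but are not a
  calibrated bound on reward-sequence error; only the zero set and ranking
  are load-bearing.
* Over-compression (lossy abstractions fed to a learner) is out of scope;
  the agents always retain an identity-abstraction learner.
* The online member-loss heuristic (observed-pair averaging) is a
  pragmatic estimator; with very sparse coverage it can be optimistic
  about a wrong abstraction until more of the state space is visited.
* Action abstractions, soft state aggregation, and function approximation
  are not modelled.
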