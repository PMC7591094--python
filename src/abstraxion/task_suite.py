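"""Seeded generators for every simulation environment and curriculum.

* ``make_column_world`` — the 3×3 motivating grid world whose columns form a
  reward-predictive abstraction.
* ``make_barrier_grid`` / ``make_grid_task_family`` — grid worlds with
  impassable wall edges and a rewarded goal column; the 8-task family
  permutes two reward locations and four wall placements.
* ``make_random_inflated_set`` — random 3-state MDPs inflated to 9 ground
  states through one shared hidden partition.
* ``make_cycle_curriculum`` — the 20-task cycle curriculum: a 3-state ring
  task with randomly permuted action labels and reward arc, inflated with
  one of two hidden abstractions (75% / 25% usage).
* ``make_maze_curriculum`` — two mirrored 10×10 mazes augmented with an
  irrelevant light/dark bit or a right-half colour variable (200 states).
* ``make_guitar_task`` — playing a musical scale on a fret board: 12 note
  actions, three octaves of interchangeable positions, −1 per wrong note.

All generators are deterministic given their seed/rng and every output
passes the MDP validity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .abstraction import StatePartition, canonicalize, inflate
from .mdp_core import TabularMDP, save_mdp_json

__all__ = [
    "CurriculumSpec",
    "MazeLayout",
    "make_column_world",
    "column_partition",
    "make_barrier_grid",
    "make_grid_task_family",
    "make_random_inflated_set",
    "make_cycle_curriculum",
    "make_maze_curriculum",
    "make_guitar_task",
    "guitar_scale_partition",
    "NOTES",
    "DEFAULT_MAZE_A",
]

GAMMA_DEFAULT = 0.9

# action order used by every grid task
UP, DOWN, LEFT, RIGHT = 0, 1, 2, 3
_GRID_ACTIONS = ("up", "down", "left", "right")
_DELTAS = {UP: (-1, 0), DOWN: (1, 0), LEFT: (0, -1), RIGHT: (0, 1)}


@dataclass(frozen=True)
class CurriculumSpec:
    """An ordered task sequence with its hidden ground-truth abstractions.

    The hidden partitions exist for evaluation only — agents never see them.
    Every hidden partition is exactly reward-predictive on its task, and all
    tasks share one action space.
    """

    name: str
    tasks: tuple[TabularMDP, ...]
    hidden_partitions: tuple[StatePartition, ...]
    seed: int | None = None
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(self.tasks) != len(self.hidden_partitions):
            raise ValueError("one hidden partition per task required")
        n_actions = {m.n_actions for m in self.tasks}
        if len(n_actions) > 1:
            raise ValueError("curriculum tasks must share the action space")

    def __len__(self) -> int:
        return len(self.tasks)

    def export(self, directory) -> None:
        """Write task JSONs, hidden partition files, and a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, (task, hidden) in enumerate(zip(self.tasks, self.hidden_partitions)):
            task_file = f"task_{i:03d}.json"
            part_file = f"hidden_{i:03d}.txt"
            save_mdp_json(task, directory / task_file)
            (directory / part_file).write_text(hidden.to_string() + "\n")
            entries.append({"task": task_file, "hidden_partition": part_file})
        manifest = {
            "name": self.name,
            "seed": self.seed,
            "params": {k: v for k, v in self.params.items() if _json_safe(v)},
            "tasks": entries,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# Grid worlds

def _build_grid(
    width: int,
    height: int,
    goal_cells: set[int],
    barriers: set[frozenset[int]],
    slip: float = 1.0,
    discount: float = GAMMA_DEFAULT,
    absorbing_goals: bool = False,
    reward: float = 1.0,
) -> TabularMDP:
    """Grid MDP: moves succeed with probability ``slip`` (else the agent
    stays), off-grid and barrier moves self-loop, and entering a goal cell
    from outside pays ``reward``."""
    n = width * height
    p = np.zeros((n, 4, n))
    r = np.zeros_like(p)
    for row in range(height):
        for col in range(width):
            s = row * width + col
            for a, (dr, dc) in _DELTAS.items():
                nr, nc = row + dr, col + dc
                target = nr * width + nc
                blocked = (
                    not (0 <= nr < height and 0 <= nc < width)
                    or frozenset((s, target)) in barriers
                )
                if s in goal_cells and absorbing_goals:
                    p[s, a, s] = 1.0
                    continue
                if blocked:
                    p[s, a, s] = 1.0
                else:
                    p[s, a, target] += slip
                    p[s, a, s] += 1.0 - slip
                    if target in goal_cells and s not in goal_cells:
                        r[s, a, target] = reward
    absorbing = frozenset(goal_cells) if absorbing_goals else frozenset()
    labels = {"states": [f"({row},{col})" for row in range(height) for col in range(width)],
              "actions": list(_GRID_ACTIONS)}
    return TabularMDP(transition=p, reward=r, discount=discount,
                      absorbing=absorbing, labels=labels)


def make_column_world(discount: float = GAMMA_DEFAULT) -> TabularMDP:
    """3×3 deterministic grid world rewarding entry into the right column.

    The only rewarded transitions move from the centre column into the right
    column under "move right" — three rewarded (s, a) pairs in total.  The
    rewarded column is absorbing, which is what makes the one-state
    compression reward-maximizing: after the reward is collected no further
    decision matters.
    """
    goal = {row * 3 + 2 for row in range(3)}
    return _build_grid(3, 3, goal_cells=goal, barriers=set(), discount=discount,
                       absorbing_goals=True)


def column_partition(width: int = 3, height: int = 3) -> StatePartition:
    """Merge states by grid column (the reward-predictive abstraction)."""
    return canonicalize([row * 0 + col for row in range(height) for col in range(width)])


def make_barrier_grid(
    width: int = 3,
    height: int = 3,
    goal_column: int = 2,
    barriers: list[tuple[tuple[int, int], tuple[int, int]]] = (),
    slip: float = 1.0,
    discount: float = GAMMA_DEFAULT,
) -> TabularMDP:
    """Grid world with impassable wall edges and a rewarded goal column.

    ``barriers`` lists blocked cell-edge pairs as ((row, col), (row, col));
    attempting to cross one self-loops.  With no barriers and the right
    column rewarded this reduces exactly to the column world.
    """
    if not (0 <= goal_column < width):
        raise ValueError("goal column outside the grid")
    goal = {row * width + goal_column for row in range(height)}
    edge_set = set()
    for (r1, c1), (r2, c2) in barriers:
        if abs(r1 - r2) + abs(c1 - c2) != 1:
            raise ValueError("barriers must join adjacent cells")
        edge_set.add(frozenset((r1 * width + c1, r2 * width + c2)))
    return _build_grid(width, height, goal_cells=goal, barriers=edge_set,
                       slip=slip, discount=discount, absorbing_goals=True)


# four wall placements permuted with two reward locations → 8 distinct tasks
_WALL_PLACEMENTS = (
    [((0, 0), (0, 1))],
    [((1, 1), (1, 2))],
    [((2, 0), (2, 1))],
    [((1, 0), (2, 0))],
)


def make_grid_task_family(discount: float = GAMMA_DEFAULT) -> list[TabularMDP]:
    """8 grid tasks: two goal columns (left, right) × four wall placements."""
    return [
        make_barrier_grid(goal_column=goal, barriers=walls, discount=discount)
        for goal in (0, 2)
        for walls in _WALL_PLACEMENTS
    ]


# ---------------------------------------------------------------------------
# Randomly inflated MDP sets

def _random_surjective_partition(n_ground: int, n_latent: int, rng) -> StatePartition:
    while True:
        labels = rng.integers(n_latent, size=n_ground)
        if len(np.unique(labels)) == n_latent:
            return canonicalize(labels)


def _random_latent_mdp(n_latent: int, n_actions: int, rng, discount: float) -> TabularMDP:
    p = rng.dirichlet(np.ones(n_latent), size=(n_latent, n_actions))
    r = (rng.random((n_latent, n_actions, n_latent)) < 0.5).astype(float)
    return TabularMDP(transition=p, reward=r, discount=discount)


def make_random_inflated_set(
    n_tasks: int,
    n_latent: int = 3,
    n_ground: int = 9,
    n_actions: int = 4,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    discount: float = GAMMA_DEFAULT,
) -> CurriculumSpec:
    """Random latent MDPs inflated through one shared hidden partition.

    One random surjective ``n_ground → n_latent`` partition is drawn for the
    whole set; each task draws fresh latent transitions (flat Dirichlet rows)
    and rewards (Bernoulli(½) per latent arc) and is inflated with it, so the
    tasks differ in transitions and rewards but share the abstraction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hidden = _random_surjective_partition(n_ground, n_latent, rng)
    tasks = []
    for _ in range(n_tasks):
        latent = _random_latent_mdp(n_latent, n_actions, rng, discount)
        ground, _ = inflate(latent, hidden=hidden)
        tasks.append(ground)
    return CurriculumSpec(
        name="random_inflated",
        tasks=tuple(tasks),
        hidden_partitions=tuple([hidden] * n_tasks),
        seed=seed,
        params={"n_tasks": n_tasks, "n_latent": n_latent, "n_ground": n_ground},
    )


# ---------------------------------------------------------------------------
# Cycle curriculum (transfer with multiple abstractions)

def _random_cycle_mdp(n_states: int, n_actions: int, rng, discount: float) -> TabularMDP:
    """Ring task: at each state exactly one (random) action advances the
    cycle, all others self-loop; exactly one cycle arc pays +1."""
    p = np.zeros((n_states, n_actions, n_states))
    r = np.zeros_like(p)
    advance = rng.integers(n_actions, size=n_states)
    for s in range(n_states):
        for a in range(n_actions):
            if a == advance[s]:
                p[s, a, (s + 1) % n_states] = 1.0
            else:
                p[s, a, s] = 1.0
    rewarded = int(rng.integers(n_states))
    r[rewarded, advance[rewarded], (rewarded + 1) % n_states] = 1.0
    return TabularMDP(transition=p, reward=r, discount=discount)


def make_cycle_curriculum(
    n_tasks: int = 20,
    majority: float = 0.75,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    n_latent: int = 3,
    n_ground: int = 9,
    n_actions: int = 3,
    discount: float = GAMMA_DEFAULT,
) -> CurriculumSpec:
    """The 20-task cycle curriculum with two competing hidden abstractions.

    Each task is a fresh 3-state ring (random action labelling, random
    rewarded arc) inflated to 9 states with hidden abstraction φ_A (drawn
    with probability ``majority``, 0.75 by default) or φ_B.  Which partition
    each task used is recorded in ``params["uses_majority"]``.
    """
    if not (0.0 < majority < 1.0):
        raise ValueError("majority frequency must lie strictly between 0 and 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    phi_a = _random_surjective_partition(n_ground, n_latent, rng)
    while True:
        phi_b = _random_surjective_partition(n_ground, n_latent, rng)
        if phi_b.assignment != phi_a.assignment:
            break
    tasks, hiddens, uses_majority = [], [], []
    for _ in range(n_tasks):
        latent = _random_cycle_mdp(n_latent, n_actions, rng, discount)
        use_a = bool(rng.random() < majority)
        hidden = phi_a if use_a else phi_b
        ground, _ = inflate(latent, hidden=hidden)
        tasks.append(ground)
        hiddens.append(hidden)
        uses_majority.append(use_a)
    return CurriculumSpec(
        name="cycle",
        tasks=tuple(tasks),
        hidden_partitions=tuple(hiddens),
        seed=seed,
        params={
            "n_tasks": n_tasks,
            "majority": majority,
            "uses_majority": uses_majority,
            "phi_A": phi_a,
            "phi_B": phi_b,
        },
    )


# ---------------------------------------------------------------------------
# Maze curriculum (online learning)

@dataclass(frozen=True)
class MazeLayout:
    """10×10 maze map: wall edges (pairs of adjacent cells), start and goal."""

    width: int
    height: int
    walls: frozenset[frozenset[int]]
    start: tuple[int, int]
    goal: tuple[int, int]

    def mirrored(self) -> "MazeLayout":
        """Left-right mirror image (column c ↦ width−1−c)."""
        def m(cell: int) -> int:
            row, col = divmod(cell, self.width)
            return row * self.width + (self.width - 1 - col)

        return MazeLayout(
            width=self.width,
            height=self.height,
            walls=frozenset(frozenset(m(c) for c in wall) for wall in self.walls),
            start=(self.start[0], self.width - 1 - self.start[1]),
            goal=(self.goal[0], self.width - 1 - self.goal[1]),
        )


def _wall_edges(width, segments) -> frozenset[frozenset[int]]:
    edges = set()
    for (r1, c1), (r2, c2) in segments:
        edges.add(frozenset((r1 * width + c1, r2 * width + c2)))
    return frozenset(edges)


# Default 10×10 layout: two staggered horizontal barriers forcing an S-shaped
# route from the bottom-left start to the top-right goal.  The exact map is a
# package fixture — all curriculum comparisons are within-layout.
DEFAULT_MAZE_A = MazeLayout(
    width=10,
    height=10,
    walls=_wall_edges(
        10,
        [((2, c), (3, c)) for c in range(0, 7)]
        + [((6, c), (7, c)) for c in range(3, 10)],
    ),
    start=(9, 0),
    goal=(0, 9),
)


def _maze_base_dynamics(layout: MazeLayout, slip: float):
    """Per-cell intended moves: returns target[s, a] with blocked moves = s."""
    n = layout.width * layout.height
    target = np.zeros((n, 4), dtype=int)
    for row in range(layout.height):
        for col in range(layout.width):
            s = row * layout.width + col
            for a, (dr, dc) in _DELTAS.items():
                nr, nc = row + dr, col + dc
                t = nr * layout.width + nc
                if (
                    not (0 <= nr < layout.height and 0 <= nc < layout.width)
                    or frozenset((s, t)) in layout.walls
                ):
                    t = s
                target[s, a] = t
    return target


def _augmented_maze(
    layout: MazeLayout,
    variants_of_cell,
    slip: float,
    discount: float,
) -> TabularMDP:
    """Build a maze whose cells are augmented with an irrelevant variable.

    ``variants_of_cell(cell) -> int`` gives how many copies each grid cell
    has; the variable resamples uniformly at every step.  Goal states are
    absorbing; entering any goal copy pays +1.
    """
    width = layout.width
    goal_cell = layout.goal[0] * width + layout.goal[1]
    start_cell = layout.start[0] * width + layout.start[1]
    n_cells = width * layout.height
    counts = [variants_of_cell(c) for c in range(n_cells)]
    index = {}
    states = []
    for cell in range(n_cells):
        for v in range(counts[cell]):
            index[(cell, v)] = len(states)
            states.append((cell, v))
    n = len(states)
    target = _maze_base_dynamics(layout, slip)
    p = np.zeros((n, 4, n))
    r = np.zeros_like(p)
    for (cell, v), s in index.items():
        if cell == goal_cell:
            for a in range(4):
                p[s, a, s] = 1.0
            continue
        for a in range(4):
            for dest_cell, prob in ((target[cell, a], slip), (cell, 1.0 - slip)):
                if prob <= 0.0:
                    continue
                k = counts[dest_cell]
                for dv in range(k):
                    d = index[(dest_cell, dv)]
                    p[s, a, d] += prob / k
                    if dest_cell == goal_cell:
                        r[s, a, d] = 1.0
    mu = np.zeros(n)
    for v in range(counts[start_cell]):
        mu[index[(start_cell, v)]] = 1.0 / counts[start_cell]
    absorbing = frozenset(index[(goal_cell, v)] for v in range(counts[goal_cell]))
    labels = {"states": [f"cell{c}/v{v}" for c, v in states]}
    mdp = TabularMDP(transition=p, reward=r, discount=discount,
                     start_distribution=mu, absorbing=absorbing, labels=labels)
    hidden = canonicalize([cell for cell, _ in states])
    mdp.labels["hidden_partition"] = hidden.to_string()
    return mdp


def _maze_light_dark(layout: MazeLayout, slip: float, discount: float) -> TabularMDP:
    return _augmented_maze(layout, lambda cell: 2, slip, discount)


def _maze_coloured(layout: MazeLayout, slip: float, discount: float) -> TabularMDP:
    half = layout.width // 2
    return _augmented_maze(
        layout,
        lambda cell: 3 if (cell % layout.width) >= half else 1,
        slip,
        discount,
    )


def make_maze_curriculum(
    layout_a: MazeLayout | None = None,
    layout_b: MazeLayout | None = None,
    slip: float = 0.95,
    discount: float = GAMMA_DEFAULT,
) -> CurriculumSpec:
    """Five maze tasks with irrelevant state variables.

    Order: A light/dark, A coloured, A light/dark, B light/dark, B coloured,
    with maze B the left-right mirror of maze A.  The light/dark bit doubles
    the 100 grid cells to 200 states; the colour variable triples only the
    right-half cells (also 200 states).  Moves succeed with probability
    ``slip`` (0.95), the goal is absorbing with reward +1, and the hidden
    partition of every task merges the irrelevant variable (100 latents).
    """
    layout_a = layout_a or DEFAULT_MAZE_A
    layout_b = layout_b or layout_a.mirrored()
    tasks = (
        _maze_light_dark(layout_a, slip, discount),
        _maze_coloured(layout_a, slip, discount),
        _maze_light_dark(layout_a, slip, discount),
        _maze_light_dark(layout_b, slip, discount),
        _maze_coloured(layout_b, slip, discount),
    )
    hiddens = tuple(
        canonicalize([int(tok) for tok in t.labels["hidden_partition"].split(",")])
        for t in tasks
    )
    return CurriculumSpec(
        name="maze",
        tasks=tasks,
        hidden_partitions=hiddens,
        params={"slip": slip, "order": ["A-lightdark", "A-coloured", "A-lightdark",
                                        "B-lightdark", "B-coloured"]},
    )


# ---------------------------------------------------------------------------
# Guitar-scale task

NOTES = ("A", "A#", "B", "C", "C#", "D", "D#", "E", "F", "F#", "G", "G#")
_STANDARD_TUNING = ("E", "A", "D", "G", "B", "E")   # open-string notes
N_OCTAVES = 3


def guitar_fretboard(note: str, n_frets: int = 10) -> np.ndarray:
    """6×``n_frets`` bit matrix marking where ``note`` sits on a standard-tuned
    fret board (cosmetic metadata for state labels)."""
    if note not in NOTES:
        raise ValueError(f"unknown note {note!r}")
    board = np.zeros((len(_STANDARD_TUNING), n_frets), dtype=bool)
    for i, open_note in enumerate(_STANDARD_TUNING):
        base = NOTES.index(open_note)
        for fret in range(n_frets):
            if NOTES[(base + fret) % 12] == note:
                board[i, fret] = True
    return board


def make_guitar_task(
    scale: list[str] = ("C", "D", "E", "F", "G", "A", "B"),
    discount: float = GAMMA_DEFAULT,
) -> TabularMDP:
    """Scale-playing MDP: progress through a note sequence on the fret board.

    States: one start state, then one fret-board configuration per scale
    position in each of three octaves; the final positions are absorbing.
    Actions are the 12 notes.  Playing the correct next note advances within
    the current octave (reward 0); any wrong note self-loops with reward −1.
    The transition out of the start state under the scale's first note lands
    in a uniformly random octave.
    """
    scale = list(scale)
    if not scale:
        raise ValueError("scale must contain at least one note")
    for note in scale:
        if note not in NOTES:
            raise ValueError(f"unknown note {note!r}")
    L = len(scale)
    n = 1 + N_OCTAVES * L
    idx = lambda octave, pos: 1 + octave * L + pos
    p = np.zeros((n, 12, n))
    r = np.zeros_like(p)
    first = NOTES.index(scale[0])
    for a in range(12):
        if a == first:
            for o in range(N_OCTAVES):
                p[0, a, idx(o, 0)] = 1.0 / N_OCTAVES
        else:
            p[0, a, 0] = 1.0
            r[0, a, 0] = -1.0
    for o in range(N_OCTAVES):
        for pos in range(L):
            s = idx(o, pos)
            if pos == L - 1:
                for a in range(12):
                    p[s, a, s] = 1.0
                continue
            correct = NOTES.index(scale[pos + 1])
            for a in range(12):
                if a == correct:
                    p[s, a, idx(o, pos + 1)] = 1.0
                else:
                    p[s, a, s] = 1.0
                    r[s, a, s] = -1.0
    mu = np.zeros(n)
    mu[0] = 1.0
    absorbing = frozenset(idx(o, L - 1) for o in range(N_OCTAVES))
    labels = {
        "states": ["start"] + [f"{scale[pos]}@octave{o}" for o in range(N_OCTAVES) for pos in range(L)],
        "actions": list(NOTES),
        "scale": scale,
    }
    return TabularMDP(transition=p, reward=r, discount=discount,
                      start_distribution=mu, absorbing=absorbing, labels=labels)


def guitar_scale_partition(scale_length: int) -> StatePartition:
    """Merge the three octaves' fret boards of the same scale position."""
    labels = [0] + [1 + pos for _ in range(N_OCTAVES) for pos in range(scale_length)]
    return canonicalize(labels)
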