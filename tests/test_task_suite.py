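"""Environment generators: validity, stated sizes, hidden-abstraction checks."""

import numpy as np
import pytest

from abstraxion.abstraction import compress
from abstraxion.mdp_core import expected_rewards, rollout, value_iteration
from abstraxion.scoring import loss_predictive, reward_sequence_error
from abstraxion.task_suite import (
    DEFAULT_MAZE_A,
    NOTES,
    column_partition,
    guitar_fretboard,
    guitar_scale_partition,
    make_barrier_grid,
    make_column_world,
    make_cycle_curriculum,
    make_grid_task_family,
    make_guitar_task,
    make_maze_curriculum,
    make_random_inflated_set,
)


class TestColumnWorld:
    def test_sizes(self, column_world):
        assert column_world.n_states == 9
        assert column_world.n_actions == 4

    def test_exactly_three_rewarded_state_action_pairs(self, column_world):
        r_sa = expected_rewards(column_world)
        rewarded = np.argwhere(r_sa > 1e-12)
        assert len(rewarded) == 3
        assert all(a == 3 for _, a in rewarded)          # all via "move right"
        assert sorted(s for s, _ in rewarded) == [1, 4, 7]  # the centre column

    def test_column_partition_reward_sequence_exact(self, column_world, rng):
        ab = compress(column_world, column_partition())
        assert reward_sequence_error(column_world, ab, 30, 10, rng) == pytest.approx(0.0, abs=1e-10)


class TestBarrierGrid:
    def test_no_barriers_right_goal_equals_column_world(self, column_world):
        grid = make_barrier_grid(goal_column=2)
        assert grid == column_world

    def test_barrier_edge_self_loops(self):
        grid = make_barrier_grid(goal_column=2, barriers=[((1, 0), (1, 1))])
        s = 1 * 3 + 0
        assert grid.transition[s, 3, s] == 1.0           # "right" into the wall stays

    def test_family_has_eight_distinct_tasks(self):
        family = make_grid_task_family()
        assert len(family) == 8
        keys = {(m.transition.tobytes(), m.reward.tobytes()) for m in family}
        assert len(keys) == 8

    def test_goal_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            make_barrier_grid(goal_column=5)


class TestRandomInflatedSet:
    def test_task_count_and_sizes(self):
        spec = make_random_inflated_set(100, seed=0)
        assert len(spec) == 100
        assert all(t.n_states == 9 for t in spec.tasks)

    def test_shared_hidden_partition_zero_loss_on_every_task(self):
        spec = make_random_inflated_set(10, seed=1)
        hidden = spec.hidden_partitions[0]
        assert all(h.assignment == hidden.assignment for h in spec.hidden_partitions)
        for task in spec.tasks:
            assert loss_predictive(task, hidden) < 1e-9

    def test_distinct_seeds_distinct_rewards(self):
        a = make_random_inflated_set(3, seed=2)
        b = make_random_inflated_set(3, seed=3)
        assert not np.allclose(a.tasks[0].reward, b.tasks[0].reward)

    def test_seed_determinism(self):
        a = make_random_inflated_set(3, seed=4)
        b = make_random_inflated_set(3, seed=4)
        for x, y in zip(a.tasks, b.tasks):
            assert x == y


class TestCycleCurriculum:
    def test_shape_and_compressibility(self):
        spec = make_cycle_curriculum(seed=0)
        assert len(spec) == 20
        for task, hidden in zip(spec.tasks, spec.hidden_partitions):
            assert task.n_states == 9
            assert hidden.n_latent == 3
            assert loss_predictive(task, hidden) < 1e-9

    def test_majority_frequency(self):
        rng = np.random.default_rng(5)
        counts = [
            sum(make_cycle_curriculum(rng=rng).params["uses_majority"])
            for _ in range(60)
        ]
        assert abs(np.mean(counts) - 15.0) < 1.0

    def test_optimal_policy_one_reward_per_three_steps(self):
        spec = make_cycle_curriculum(seed=6)
        for task in spec.tasks[:3]:
            V, policy = value_iteration(task)
            rng = np.random.default_rng(0)
            traj = rollout(task, policy, max_steps=30, rng=rng)
            assert traj.rewards.sum() >= 9  # ≥ 9 rewards in 30 steps: a lap each 3
            # and never two rewards within the same lap
            assert traj.rewards.sum() <= 11


@pytest.fixture(scope="module")
def curriculum():
    return make_maze_curriculum()


class TestMazeCurriculum:
    def test_five_tasks_of_200_states(self, curriculum):
        assert len(curriculum) == 5
        assert all(t.n_states == 200 for t in curriculum.tasks)

    def test_move_success_probability(self, curriculum):
        task = curriculum.tasks[0]
        # a free interior move of the light-dark maze: mass 0.95 to the
        # target cell (split over both bits), 0.05 to the current cell
        probs = task.transition[0, 1]                    # state (cell 0, light), "down"
        target_cell_mass = probs.reshape(100, 2)[DEFAULT_MAZE_A.width].sum()
        assert target_cell_mass == pytest.approx(0.95)

    def test_hidden_partitions_merge_variants_zero_loss(self, curriculum):
        for task, hidden in zip(curriculum.tasks[:2], curriculum.hidden_partitions[:2]):
            assert hidden.n_latent == 100
            assert loss_predictive(task, hidden) < 1e-9

    def test_goal_absorbing_with_unit_reward(self, curriculum):
        task = curriculum.tasks[0]
        assert task.absorbing
        for g in task.absorbing:
            assert np.allclose(task.transition[g, :, g], 1.0)
        assert task.reward.max() == 1.0

    def test_mirror_layout_swaps_start_column(self):
        b = DEFAULT_MAZE_A.mirrored()
        assert b.start == (9, 9)
        assert b.goal == (0, 0)
        assert b.mirrored() == DEFAULT_MAZE_A


class TestGuitar:
    def test_twelve_note_actions(self):
        task = make_guitar_task()
        assert task.n_actions == 12
        assert task.n_states == 1 + 3 * 7

    def test_optimal_return_is_zero(self):
        task = make_guitar_task()
        _, policy = value_iteration(task)
        traj = rollout(task, policy, 100, np.random.default_rng(0))
        assert traj.terminated
        assert traj.rewards.sum() == 0.0

    def test_octave_merging_partition_zero_loss(self):
        task = make_guitar_task()
        part = guitar_scale_partition(7)
        assert loss_predictive(task, part) < 1e-9

    def test_start_transition_uniform_over_octaves(self):
        task = make_guitar_task(("C", "D"))
        first = NOTES.index("C")
        starts = np.flatnonzero(task.transition[0, first] > 0)
        assert len(starts) == 3
        assert np.allclose(task.transition[0, first, starts], 1 / 3)

    def test_wrong_note_penalty(self):
        task = make_guitar_task()
        wrong = NOTES.index("G#")
        assert task.reward[0, wrong, 0] == -1.0

    def test_unknown_note_rejected(self):
        with pytest.raises(ValueError):
            make_guitar_task(("C", "H"))

    def test_fretboard_marks_all_positions_of_a_note(self):
        board = guitar_fretboard("C")
        assert board.shape == (6, 10)
        assert board.sum() >= 4                      # several playable positions
        # every marked position really sounds a C under standard tuning
        tuning = ("E", "A", "D", "G", "B", "E")
        for i, fret in zip(*np.nonzero(board)):
            base = NOTES.index(tuning[i])
            assert NOTES[(base + fret) % 12] == "C"


class TestValidityAndDeterminism:
    def test_every_generator_output_validates(self):
        # construction already validates; just touch one of each
        make_column_world()
        make_grid_task_family()
        make_random_inflated_set(2, seed=0)
        make_cycle_curriculum(n_tasks=3, seed=0)
        make_guitar_task()

    def test_curriculum_export_manifest(self, tmp_path):
        spec = make_random_inflated_set(2, seed=9)
        spec.export(tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "task_000.json").exists()
        from abstraxion.mdp_core import load_mdp_json

        assert load_mdp_json(tmp_path / "task_001.json") == spec.tasks[1]
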