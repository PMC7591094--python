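"""Configuration-driven drivers for the four experiment families.

* ``run_enumeration_transfer`` — enumerate the abstraction hypothesis space,
  score every partition on one evaluation task by empirical total reward and
  by reward-sequence prediction error, then re-evaluate the top 5% of each
  ranking on the remaining transfer tasks.
* ``run_oracle_crp`` — the oracle belief-update loop on the cycle
  curriculum: per task, exhaustively search all 9→3 partitions for the
  best-scoring candidate, update the CRP posterior, and evaluate the
  posterior-mixture policy for ten steps.
* ``run_online_crp`` — the online lifelong models on the maze curriculum.
* ``run_guitar`` — the scale-playing transfer comparison.

Every run is reproducible from its config and seed; raw per-episode /
per-abstraction tables are returned as DataFrames and written as CSV by the
CLI layer together with a manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abstraction import StatePartition, enumerate_partitions
from .agents import LifelongConfig, run_lifelong
from .crp_transfer import BeliefSet, posterior, select_and_update
from .mdp_core import Policy, TabularMDP, expected_rewards
from .scoring import (
    batch_abstract_greedy,
    batch_loss_maximizing,
    batch_loss_predictive,
    predictive_distance_matrix,
    _batch_compress,
)
from .task_suite import (
    CurriculumSpec,
    make_barrier_grid,
    make_column_world,
    make_cycle_curriculum,
    make_grid_task_family,
    make_guitar_task,
    make_maze_curriculum,
    make_random_inflated_set,
    guitar_scale_partition,
)

__all__ = [
    "ExperimentConfig",
    "run_enumeration_transfer",
    "run_oracle_crp",
    "run_online_crp",
    "run_guitar",
    "run_experiment",
    "EXPERIMENTS",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experiment configuration; unused fields are ignored per driver."""

    experiment: str = "enumeration_transfer"
    task_family: str = "random_inflated"        # enumeration: column | random_inflated | barrier_grid
    n_tasks: int = 20                            # tasks per generated set/curriculum
    k_restrict: int | None = None                # restrict H to k-cell partitions
    n_trials: int = 20                           # rollouts per total-reward score
    horizon: int = 10                            # steps per rollout / reward sequence
    top_fraction: float = 0.05
    repeats: int = 10
    alphas: tuple[float, ...] = (1.0,)
    betas: tuple[float, ...] = (math.inf,)
    loss_types: tuple[str, ...] = ("predictive", "maximizing")
    n_curricula: int = 10
    episodes_per_task: int = 200
    models: tuple[str, ...] = ("q_baseline", "crp_predictive", "crp_maximizing",
                               "sf_reset", "sf_transfer")
    scales: tuple[tuple[str, ...], ...] = (
        ("C", "D", "E", "F", "G", "A", "B"),
        ("A", "B", "C", "D", "E", "F", "G"),
    )
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        data = dict(data)
        for key in ("alphas", "betas"):
            if key in data:
                data[key] = tuple(math.inf if v in ("inf", "Infinity") else float(v) for v in data[key])
        for key in ("loss_types", "models"):
            if key in data:
                data[key] = tuple(data[key])
        if "scales" in data:
            data["scales"] = tuple(tuple(s) for s in data["scales"])
        return cls(**data)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["alphas"] = ["inf" if math.isinf(a) else a for a in self.alphas]
        payload["betas"] = ["inf" if math.isinf(b) else b for b in self.betas]
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Enumeration transfer (single-abstraction transfer)


def _enumeration_families(config: ExperimentConfig, rng) -> list[TabularMDP]:
    if config.task_family == "column":
        # three column-compressible variants: rewarded column and walls differ
        full_wall = [((r, 0), (r, 1)) for r in range(3)]
        return [
            make_column_world(),
            make_barrier_grid(goal_column=0),
            make_barrier_grid(goal_column=2, barriers=full_wall),
        ]
    if config.task_family == "barrier_grid":
        return list(make_grid_task_family())
    if config.task_family == "random_inflated":
        spec = make_random_inflated_set(
            config.n_tasks, rng=rng, seed=None
        )
        return list(spec.tasks)
    raise ValueError(f"unknown task family {config.task_family!r}")


def _batch_rollout_returns(
    mdp: TabularMDP,
    ground_actions: np.ndarray,
    n_trials: int,
    horizon: int,
    rng,
) -> np.ndarray:
    """Empirical mean total reward per partition from vectorized rollouts.

    ``ground_actions`` has shape (B, S): the deterministic lifted policy per
    partition.  All B policies are rolled out in parallel over n_trials.
    """
    B = ground_actions.shape[0]
    states = rng.choice(mdp.n_states, size=(B, n_trials), p=mdp.start_distribution)
    totals = np.zeros((B, n_trials))
    rows = np.arange(B)[:, None]
    for _ in range(horizon):
        acts = ground_actions[rows, states]
        probs = mdp.transition[states, acts]                  # (B, N, S)
        u = rng.random((B, n_trials, 1))
        nxt = (u > probs.cumsum(axis=2)).sum(axis=2)
        nxt = np.minimum(nxt, mdp.n_states - 1)
        totals += mdp.reward[states, acts, nxt]
        states = nxt
    return totals.mean(axis=1)


def _batch_rs_errors(
    mdp: TabularMDP,
    labels: np.ndarray,
    n_sequences: int,
    horizon: int,
    rng,
) -> np.ndarray:
    """Empirical reward-sequence error per partition over shared random
    (start, action-sequence) pairs, each evaluated by exact propagation."""
    B, S = labels.shape
    n_latent = int(labels.max()) + 1
    p_bar, r_bar_sa = _batch_compress(mdp, labels, n_latent)
    r_sa = expected_rewards(mdp)
    err = np.zeros(B)
    for _ in range(n_sequences):
        s0 = int(rng.integers(S))
        actions = rng.integers(mdp.n_actions, size=horizon)
        dist = np.zeros(S)
        dist[s0] = 1.0
        latent_dist = np.zeros((B, n_latent))
        latent_dist[np.arange(B), labels[:, s0]] = 1.0
        for a in actions:
            true_r = dist @ r_sa[:, a]
            pred_r = np.einsum("bx,bx->b", latent_dist, r_bar_sa[:, :, a])
            err += np.abs(true_r - pred_r)
            dist = dist @ mdp.transition[:, a, :]
            latent_dist = np.einsum("bx,bxy->by", latent_dist, p_bar[:, :, a, :])
    return err / n_sequences


def run_enumeration_transfer(config: ExperimentConfig, rng=None) -> dict:
    """Score every abstraction on one task, transfer the top 5% to the rest.

    Returns ``{"rows": per-abstraction DataFrame, "summary": DataFrame}``;
    the summary reports, per repeat, the mean transfer total reward of the
    abstractions selected by total reward versus by reward-sequence error.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    all_rows, summaries = [], []
    for repeat in range(config.repeats):
        tasks = _enumeration_families(config, rng)
        n_states = tasks[0].n_states
        labels = np.array(
            [p.array() for p in enumerate_partitions(n_states, k=config.k_restrict)]
        )
        eval_idx = int(rng.integers(len(tasks)))
        eval_task = tasks[eval_idx]
        transfer_tasks = [t for i, t in enumerate(tasks) if i != eval_idx]

        ground_actions = batch_abstract_greedy(eval_task, labels)
        r_total = _batch_rollout_returns(
            eval_task, ground_actions, config.n_trials, config.horizon, rng
        )
        rs_error = _batch_rs_errors(
            eval_task, labels, config.n_trials, config.horizon, rng
        )

        transfer_r = np.zeros(len(labels))
        for task in transfer_tasks:
            acts = batch_abstract_greedy(task, labels)
            transfer_r += _batch_rollout_returns(
                task, acts, config.n_trials, config.horizon, rng
            )
        transfer_r /= max(1, len(transfer_tasks))

        k_top = max(1, int(round(config.top_fraction * len(labels))))
        top_by_reward = np.argsort(-r_total, kind="stable")[:k_top]
        top_by_rs = np.argsort(rs_error, kind="stable")[:k_top]

        df = pd.DataFrame(
            {
                "repeat": repeat,
                "partition": [",".join(map(str, row)) for row in labels],
                "n_latent": labels.max(axis=1) + 1,
                "R_total_eval": r_total,
                "RS_error_eval": rs_error,
                "R_total_transfer": transfer_r,
                "top_by_R_total": False,
                "top_by_RS_error": False,
            }
        )
        df.loc[df.index[top_by_reward], "top_by_R_total"] = True
        df.loc[df.index[top_by_rs], "top_by_RS_error"] = True
        all_rows.append(df)
        summaries.append(
            {
                "repeat": repeat,
                "eval_task": eval_idx,
                "transfer_mean_top_R_total": float(transfer_r[top_by_reward].mean()),
                "transfer_mean_top_RS_error": float(transfer_r[top_by_rs].mean()),
            }
        )
    rows = pd.concat(all_rows, ignore_index=True)
    return {
        "rows": rows,
        "summary": pd.DataFrame(summaries),
        "histogram": _transfer_histograms(rows),
    }


def _transfer_histograms(rows: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Binned transfer-reward distributions of the two top-5% groups.

    Fixed-width bins over the observed range; purely cosmetic — the raw
    per-abstraction values in ``rows`` are authoritative.
    """
    lo, hi = rows.R_total_transfer.min(), rows.R_total_transfer.max()
    edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
    out = []
    for group in ("top_by_R_total", "top_by_RS_error"):
        counts, _ = np.histogram(rows.loc[rows[group], "R_total_transfer"], bins=edges)
        for b in range(n_bins):
            out.append(
                {
                    "group": group,
                    "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "count": int(counts[b]),
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Oracle CRP on the cycle curriculum


def _exact_return(mdp: TabularMDP, policy: Policy, horizon: int) -> float:
    """Exact expected undiscounted return of ``policy`` over ``horizon`` steps
    from the start distribution (distribution propagation, no sampling)."""
    P_pi = np.einsum("ij,ijk->ik", policy.probs, mdp.transition)
    r_pi = np.einsum("ij,ij->i", policy.probs, expected_rewards(mdp))
    dist = mdp.start_distribution.copy()
    total = 0.0
    for _ in range(horizon):
        total += float(dist @ r_pi)
        dist = dist @ P_pi
    return total


def run_oracle_crp(config: ExperimentConfig, rng=None) -> dict:
    """Oracle belief-update loop on cycle curricula for an (α, β) grid.

    The candidate abstraction per task is the exhaustive loss argmin over
    all 9→3 partitions not yet in the belief (the identity abstraction is
    excluded by construction).  The posterior-mixture policy is evaluated
    for ``horizon`` steps per task (exact expectation over starts).
    Returns per-curriculum rows and an (α, β, loss) summary.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not config.alphas or not config.betas:
        raise ValueError("empty (alpha, beta) grid")
    space = np.array([p.array() for p in enumerate_partitions(9, k=3)])
    index_of = {tuple(row): i for i, row in enumerate(space)}
    partitions = [StatePartition(tuple(row)) for row in space]
    rows = []
    for curriculum_idx in range(config.n_curricula):
        curr_seed = int(rng.integers(2**31 - 1))
        curriculum = make_cycle_curriculum(
            n_tasks=config.n_tasks, seed=curr_seed
        )
        # cache per-task loss vectors over the whole 9→3 space
        losses_cache: dict[tuple[int, str], np.ndarray] = {}
        for loss_type in config.loss_types:
            for t_idx, task in enumerate(curriculum.tasks):
                if loss_type == "predictive":
                    D, _ = predictive_distance_matrix(task)
                    losses_cache[(t_idx, loss_type)] = batch_loss_predictive(D, space)
                else:
                    losses_cache[(t_idx, loss_type)] = batch_loss_maximizing(task, space)
        for loss_type in config.loss_types:
            for alpha in config.alphas:
                for beta in config.betas:
                    run_rng = np.random.default_rng(curr_seed + 7)
                    belief = BeliefSet(alpha=alpha, beta=beta)
                    task_returns, chosen_list = [], []
                    for t_idx, task in enumerate(curriculum.tasks):
                        all_losses = losses_cache[(t_idx, loss_type)]
                        member_rows = [index_of[phi.assignment] for phi in belief.abstractions]
                        masked = all_losses.copy()
                        masked[member_rows] = np.inf
                        cand_row = int(np.argmin(masked))
                        candidate = partitions[cand_row]
                        losses = [float(all_losses[i]) for i in member_rows] + [
                            float(all_losses[cand_row])
                        ]
                        post = posterior(belief, candidate, losses)
                        components = [
                            Policy(_lifted_greedy(task, phi))
                            for phi in list(belief.abstractions) + [candidate]
                        ]
                        mix = Policy(
                            np.einsum("m,msa->sa", post, np.stack([c.probs for c in components]))
                        )
                        task_returns.append(_exact_return(task, mix, config.horizon))
                        chosen, belief = select_and_update(belief, post, candidate, run_rng)
                        chosen_list.append(chosen.to_string())
                    counts = np.array(belief.counts)
                    rows.append(
                        {
                            "curriculum": curriculum_idx,
                            "seed": curr_seed,
                            "loss": loss_type,
                            "alpha": alpha,
                            "beta": beta,
                            "belief_size": len(belief),
                            "max_count": int(counts.max()),
                            "max_count_share": float(counts.max() / counts.sum()),
                            "mean_task_return": float(np.mean(task_returns)),
                            "n_majority_tasks": int(
                                np.sum(curriculum.params["uses_majority"])
                            ),
                        }
                    )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["loss", "alpha", "beta"], sort=False)
        .agg(
            mean_belief_size=("belief_size", "mean"),
            mean_max_count_share=("max_count_share", "mean"),
            mean_task_return=("mean_task_return", "mean"),
            mean_majority_tasks=("n_majority_tasks", "mean"),
        )
        .reset_index()
    )
    return {"rows": df, "summary": summary}


def _lifted_greedy(task: TabularMDP, phi: StatePartition) -> np.ndarray:
    """Greedy ground policy from planning in the φ-compressed task."""
    actions = batch_abstract_greedy(task, phi.array()[None, :])[0]
    probs = np.zeros((task.n_states, task.n_actions))
    probs[np.arange(task.n_states), actions] = 1.0
    return probs


# ---------------------------------------------------------------------------
# Online lifelong learning


def run_online_crp(config: ExperimentConfig, rng=None) -> dict:
    """Run the online lifelong models on the maze curriculum.

    Each model in ``config.models`` is run ``config.repeats`` times with
    distinct seeds; per-episode rows are concatenated, and the summary
    aggregates mean episode length per (model, task) with standard errors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    curriculum = make_maze_curriculum()
    frames = []
    seeds = [int(rng.integers(2**31 - 1)) for _ in range(config.repeats)]
    for model in config.models:
        for seed in seeds:
            cfg = LifelongConfig(
                model=model,
                episodes_per_task=config.episodes_per_task,
                seed=seed,
            )
            df = run_lifelong(curriculum, cfg)
            df.insert(0, "model", model)
            frames.append(df)
    rows = pd.concat(frames, ignore_index=True)
    per_run = rows.groupby(["model", "task", "seed"])["steps"].mean().reset_index()
    summary = (
        per_run.groupby(["model", "task"])["steps"]
        .agg(mean_steps="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return {"rows": rows, "summary": summary}


# ---------------------------------------------------------------------------
# Guitar scales


def guitar_curriculum(config: ExperimentConfig) -> CurriculumSpec:
    tasks = tuple(make_guitar_task(scale) for scale in config.scales)
    hiddens = tuple(guitar_scale_partition(len(scale)) for scale in config.scales)
    return CurriculumSpec(name="guitar", tasks=tasks, hidden_partitions=hiddens,
                          params={"scales": [list(s) for s in config.scales]})


def run_guitar(config: ExperimentConfig, rng=None) -> dict:
    """Scale-playing transfer: each model learns scale 1 then scale 2.

    Greedy action selection on zero-initialized tables is used (rewards are
    ≤ 0, so zeros are optimistic).  The summary reports, per model and task,
    the mean return of the final ten episodes and the first episode whose
    return reaches the optimum (0), averaged over repeats.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    curriculum = guitar_curriculum(config)
    frames = []
    seeds = [int(rng.integers(2**31 - 1)) for _ in range(config.repeats)]
    for model in config.models:
        for seed in seeds:
            cfg = LifelongConfig(
                model=model,
                episodes_per_task=config.episodes_per_task,
                exploration="greedy",
                posterior_update_every=1,
                seed=seed,
            )
            df = run_lifelong(curriculum, cfg)
            df.insert(0, "model", model)
            frames.append(df)
    rows = pd.concat(frames, ignore_index=True)

    def first_optimal(group):
        hit = group.loc[group["return"] >= 0.0, "episode"]
        return int(hit.min()) if len(hit) else np.nan

    summary = (
        rows.groupby(["model", "task", "seed"])
        .apply(
            lambda g: pd.Series(
                {
                    "final_return": g.sort_values("episode")["return"].tail(10).mean(),
                    "episodes_to_optimal": first_optimal(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
        .groupby(["model", "task"])
        .agg(
            mean_final_return=("final_return", "mean"),
            mean_episodes_to_optimal=("episodes_to_optimal", "mean"),
            median_episodes_to_optimal=("episodes_to_optimal", "median"),
        )
        .reset_index()
    )
    return {"rows": rows, "summary": summary}


EXPERIMENTS = {
    "enumeration_transfer": run_enumeration_transfer,
    "oracle_crp": run_oracle_crp,
    "online_crp": run_online_crp,
    "guitar": run_guitar,
}


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Dispatch on ``config.experiment``; optionally write CSVs + manifest."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    result = EXPERIMENTS[config.experiment](config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in result.items():
            df.to_csv(out / f"{config.experiment}_{name}.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "experiment": config.experiment,
                    "config": json.loads(config.to_json()),
                    "outputs": [f"{config.experiment}_{name}.csv" for name in result],
                    "version": _version_stamp(),
                },
                indent=2,
            )
        )
    return result


def _version_stamp() -> str:
    from . import __version__

    return f"abstraxion-{__version__}"
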