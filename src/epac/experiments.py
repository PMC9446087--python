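"""Experiment harness: task presets, run metrics, multi-seed reports, logs.

Metrics follow the evaluation protocol of the study this package
implements: per run, the mean and the population standard deviation of
the reward over the last 25% of episodes (a stability measure), and the
mean softmax probability the actor assigned to its executed actions per
episode (a confidence measure); across seeds, the mean and standard
error of the per-run last-quartile means and the average of the per-run
last-quartile SDs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .actor import EPConfig
from .agent import AgentConfig, EpisodeLog, TrainingResult, run_training
from .learning import LearningRates


# Per-task hyperparameters: layer sizes, per-layer actor learning rates,
# nudging strength, critic Adam rate and the two phase durations, plus
# the per-episode step cap (1000 for cartpole/acrobot, 2000 for
# lunarlander).  The bandit row is this package's own fixture scale: a
# 1-16-2 actor with larger rates so the closed-form optimal arm is
# recoverable within a few hundred one-step episodes.
TASK_DEFAULTS = {
    "cartpole": dict(n_inputs=4, n_actions=2, n_hidden=256, critic_hidden=256,
                     alpha1=1e-4, alpha2=1e-4, beta=0.02, critic_alpha=1e-3,
                     iters_free=150, iters_clamped=25,
                     hidden_activation="hard_sigmoid_A", discount=0.99,
                     max_steps=1000, episodes=1000),
    "acrobot": dict(n_inputs=6, n_actions=3, n_hidden=256, critic_hidden=256,
                    alpha1=1e-3, alpha2=1e-3, beta=0.02, critic_alpha=1e-3,
                    iters_free=150, iters_clamped=25,
                    hidden_activation="hard_sigmoid_B", discount=0.99,
                    max_steps=1000, episodes=1000),
    "lunarlander": dict(n_inputs=8, n_actions=4, n_hidden=512,
                        critic_hidden=512,
                        alpha1=1e-4, alpha2=2e-3, beta=0.03, critic_alpha=3e-4,
                        iters_free=180, iters_clamped=25,
                        hidden_activation="hard_sigmoid_A", discount=0.99,
                        max_steps=2000, episodes=2000),
    "bandit": dict(n_inputs=1, n_actions=2, n_hidden=16, critic_hidden=16,
                   alpha1=0.05, alpha2=0.05, beta=0.02, critic_alpha=0.01,
                   iters_free=60, iters_clamped=15,
                   hidden_activation="hard_sigmoid_A",
                   max_steps=1, episodes=500),
}


def make_config(task: str, seed: int = 0, algo: str = "ep_bp",
                episodes: Optional[int] = None, **overrides) -> AgentConfig:
    """AgentConfig for a named task, with optional keyword overrides.

    Override keys mirror the hyperparameter table names (alpha1, alpha2,
    beta, critic_alpha, iters_free, iters_clamped, hidden_size, ...).
    """
    if task not in TASK_DEFAULTS:
        raise ValueError(f"unknown task {task!r}")
    d = dict(TASK_DEFAULTS[task])
    if "hidden_size" in overrides:
        d["n_hidden"] = d["critic_hidden"] = overrides.pop("hidden_size")
    d.update(overrides)
    ep = EPConfig(h=d.get("h", 0.5), beta=d["beta"],
                  gamma_fb=d.get("gamma_fb", 1.0),
                  iters_free=d["iters_free"],
                  iters_clamped=d["iters_clamped"],
                  hidden_activation=d["hidden_activation"],
                  convergence_tol=d.get("convergence_tol"))
    lr = LearningRates(d["alpha1"], d["alpha2"], d.get("rule", "single_phase"))
    return AgentConfig(
        task=task, n_inputs=d["n_inputs"], n_actions=d["n_actions"],
        n_hidden=d["n_hidden"], critic_hidden=d["critic_hidden"],
        lr=lr, critic_lr=d["critic_alpha"], ep=ep,
        replay_capacity=d.get("replay_capacity", 1000),
        batch_size=d.get("batch_size", 20),
        episodes=episodes if episodes is not None else d["episodes"],
        max_steps=d["max_steps"], seed=seed, algo=algo,
        discount=d.get("discount", 1.0),
        bp_actor_lr=d.get("bp_actor_lr", 1e-3),
        tie_feedback=d.get("tie_feedback", True),
    )


def last_quartile_stats(trace: Sequence[float]) -> tuple[float, float]:
    """Mean and population SD of the final floor(0.25 * n) episodes
    (at least one episode)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty reward trace")
    k = max(1, math.floor(0.25 * trace.size))
    tail = trace[-k:]
    return float(tail.mean()), float(tail.std(ddof=0))


@dataclass
class RunSummary:
    """Per-run metrics derived from one episode log."""

    seed: int
    rewards: np.ndarray
    mean_action_prob: np.ndarray   # per episode
    last_quartile_mean: float
    last_quartile_sd: float

    @classmethod
    def from_logs(cls, logs: List[EpisodeLog], seed: int = 0) -> "RunSummary":
        rewards = np.array([e.total_reward for e in logs])
        probs = np.array([e.mean_action_prob for e in logs])
        m, sd = last_quartile_stats(rewards)
        return cls(seed=seed, rewards=rewards, mean_action_prob=probs,
                   last_quartile_mean=m, last_quartile_sd=sd)


@dataclass
class ExperimentReport:
    """Cross-seed aggregate of run summaries."""

    n_runs: int
    last_quartile_means: List[float]
    mean_reward: float          # mean of per-run last-quartile means
    sem_reward: float           # standard error across runs
    mean_sd: float              # mean of per-run last-quartile SDs

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "last_quartile_means": self.last_quartile_means,
            "mean_reward": self.mean_reward,
            "sem_reward": self.sem_reward,
            "mean_sd": self.mean_sd,
        }


def aggregate_runs(runs: List[RunSummary]) -> ExperimentReport:
    """Cross-seed mean and SEM of last-quartile means, and the average
    of last-quartile SDs."""
    if not runs:
        raise ValueError("need at least one run")
    means = [r.last_quartile_mean for r in runs]
    n = len(means)
    sem = float(np.std(means, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ExperimentReport(
        n_runs=n,
        last_quartile_means=[float(m) for m in means],
        mean_reward=float(np.mean(means)),
        sem_reward=sem,
        mean_sd=float(np.mean([r.last_quartile_sd for r in runs])),
    )


def run_to_frame(logs: List[EpisodeLog]) -> pd.DataFrame:
    return pd.DataFrame({
        "episode": [e.episode for e in logs],
        "total_reward": [e.total_reward for e in logs],
        "mean_action_prob": [e.mean_action_prob for e in logs],
        "steps": [e.steps for e in logs],
    })


def write_run_csv(logs: List[EpisodeLog], path) -> None:
    run_to_frame(logs).to_csv(path, index=False)


def read_run_csv(path) -> RunSummary:
    df = pd.read_csv(path)
    m, sd = last_quartile_stats(df["total_reward"].to_numpy())
    return RunSummary(seed=-1, rewards=df["total_reward"].to_numpy(),
                      mean_action_prob=df["mean_action_prob"].to_numpy(),
                      last_quartile_mean=m, last_quartile_sd=sd)


def run_experiment(task: str, algo: str = "ep_bp", seeds: Sequence[int] = range(8),
                   episodes: Optional[int] = None, out_dir=None,
                   **overrides) -> ExperimentReport:
    """Train one algorithm on one task over several seeds (8 by default)
    and aggregate; optionally persist one CSV per run plus a JSON report."""
    out = Path(out_dir) if out_dir is not None else None
    summaries = []
    for seed in seeds:
        cfg = make_config(task, seed=seed, algo=algo, episodes=episodes,
                          **overrides)
        result = run_training(cfg)
        summaries.append(RunSummary.from_logs(result.episodes, seed=seed))
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            write_run_csv(result.episodes, out / f"{task}_{algo}_seed{seed}.csv")
    report = aggregate_runs(summaries)
    if out is not None:
        with open(out / f"{task}_{algo}_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return report


def compare_algorithms(task: str, seeds: Sequence[int] = range(8),
                       episodes: Optional[int] = None, out_dir=None,
                       **overrides) -> dict:
    """EP-BP vs BP-only reports over the *same* seed set.

    Returns ``{"ep_bp": ExperimentReport, "bp_only": ExperimentReport}``;
    both algorithms see identical seeds so the comparison is paired.
    """
    seeds = list(seeds)
    return {algo: run_experiment(task, algo=algo, seeds=seeds,
                                 episodes=episodes, out_dir=out_dir,
                                 **overrides)
            for algo in ("ep_bp", "bp_only")}
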