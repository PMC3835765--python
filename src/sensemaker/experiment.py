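"""End-to-end experiment runner.

A *subject* is one agent with fresh memory and a unique seed, run through
Tasks 1-6 in order with declarative memory persisting across tasks; the
default protocol runs 45 subjects so the stochastic retrieval noise plays
the role of individual differences.  Outputs are tidy per-response-point
DataFrames/CSVs, a JSON summary, and the averaged probability-adjustment
sweep (blended posterior vs. prior for the linear and ratio similarity
regimes, classically averaged over a thousand runs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import Agent, AgentConfig
from .metrics import response_frame, summarize
from .probadjust import adjust_probability, normative_posterior, seed_adjustment_memory
from .taskenv import TASK_SCHEDULE, NetworkConfig, TrialRecord, new_task_state, run_trial

__all__ = [
    "ExperimentConfig",
    "run_task",
    "run_subject",
    "run_experiment",
    "sweep_adjustment",
]

N_SUBJECTS_DEFAULT = 45


@dataclass
class ExperimentConfig:
    """Protocol parameters: which tasks, how many subjects, agent settings."""

    tasks: Sequence[int] = (1, 2, 3, 4, 5, 6)
    n_subjects: int = N_SUBJECTS_DEFAULT
    agent: AgentConfig = field(default_factory=AgentConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    humint_dispersion: float = 10.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "agent" in d and isinstance(d["agent"], dict):
            a = dict(d["agent"])
            if "path_weights" in a:
                a["path_weights"] = tuple(a["path_weights"])
            d["agent"] = AgentConfig(**a)
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig(**d["network"])
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)


def run_task(
    task_id: int,
    agent: Agent,
    rng: np.random.Generator,
    config: ExperimentConfig | None = None,
    n_trials: Optional[int] = None,
) -> list[TrialRecord]:
    """Run one task's full trial schedule for an existing agent."""
    config = config or ExperimentConfig()
    state = new_task_state(task_id, rng, config.network, config.humint_dispersion)
    records = []
    trials = n_trials if n_trials is not None else TASK_SCHEDULE[task_id]["trials"]
    for _ in range(trials):
        records.append(run_trial(task_id, agent, state, rng, config.network))
    return records


def run_subject(
    seed_seq: np.random.SeedSequence | int,
    config: ExperimentConfig | None = None,
) -> list[TrialRecord]:
    """One simulated subject: fresh agent, Tasks run in order, memory kept."""
    config = config or ExperimentConfig()
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    agent_ss, env_ss = seed_seq.spawn(2)
    agent = Agent(config.agent, np.random.default_rng(agent_ss))
    records: list[TrialRecord] = []
    for task_id, task_ss in zip(config.tasks, env_ss.spawn(len(config.tasks))):
        records.extend(run_task(task_id, agent, np.random.default_rng(task_ss), config))
    return records


def run_experiment(
    seed: int,
    config: ExperimentConfig | None = None,
    out_dir: Optional[Path | str] = None,
) -> pd.DataFrame:
    """Run all subjects; returns the tidy response frame (optionally
    writing trials.csv, summary.json and a config/seed manifest)."""
    config = config or ExperimentConfig()
    root = np.random.SeedSequence(seed)
    frames = []
    for subject, ss in enumerate(root.spawn(config.n_subjects)):
        records = run_subject(ss, config)
        frames.append(response_frame(records, subject=subject))
    frame = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "trials.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summarize(frame), fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"seed": seed, "config": config.to_dict()}, fh, indent=2)
    return frame


def sweep_adjustment(
    runs: int = 1000,
    factor: float = 2.0,
    similarities: Sequence[str] = ("linear", "ratio"),
    seed: int = 0,
    prior_grid: Sequence[float] | None = None,
    agent_config: AgentConfig | None = None,
) -> pd.DataFrame:
    """Averaged blended-adjustment curves (posterior vs. prior).

    For each prior on the grid and each similarity regime, the blended
    posterior is averaged over ``runs`` stochastic retrievals and reported
    next to the closed-form normative posterior.
    """
    cfg = agent_config or AgentConfig()
    params = cfg.activation_params()
    store = seed_adjustment_memory()
    priors = (
        np.asarray(prior_grid, dtype=float)
        if prior_grid is not None
        else np.round(np.arange(0.0, 1.0001, 0.05), 10)
    )
    rows = []
    for sim_idx, sim in enumerate(similarities):
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(len(similarities))[sim_idx])
        for p in priors:
            vals = [
                adjust_probability(float(p), factor, store, params, rng, sim)
                for _ in range(runs)
            ]
            rows.append(
                {
                    "similarity": sim,
                    "prior": float(p),
                    "factor": factor,
                    "blended_mean": float(np.mean(vals)),
                    "blended_sd": float(np.std(vals)),
                    "normative": normative_posterior(float(p), factor),
                    "runs": runs,
                }
            )
    return pd.DataFrame(rows)
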