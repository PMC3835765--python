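"""The integrated instance-based cognitive agent.

One agent instance carries all declarative stores across the six tasks —
event memories, the centroid history, the seeded probability-adjustment
triplets, allocation episodes, layer-selection episodes, and the
reinforcement-learned layer preferences — so experience in the early
tasks (e.g. zero-score forced choices) shapes behavior in the later ones.

Every self-generated probability is reported through the blended
adjustment memory (with the identity factor), so the regression-to-the-
mean of blending compresses extreme values; this is what flattens the
agent's distributions relative to the normative solver and produces the
trialwise anchoring signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .allocation import AllocationDecision, decide_allocation, learn_allocation
from .bayes import ProbDist
from .centroids import CentroidMemory, blend_centroid, centroid_of_centroids
from .layers import record_layer_experience, rl_feedback, select_layer
from .memory import ActivationParams, Chunk, ChunkStore, UtilityState
from .paths import plan_path
from .probadjust import adjust_probability, seed_adjustment_memory, update_distribution
from .taskenv import FeatureOutcome, SigactEvent

__all__ = ["AgentConfig", "Agent"]


@dataclass
class AgentConfig:
    """Tunable parameters of the agent.

    ``noise_s`` is the activation-noise scale / softmax temperature (0.25);
    ``similarity`` selects the linear or ratio probability-similarity
    regime used by the adjustment memory; ``humint_dispersion`` is the
    Gaussian scale (grid units) the agent assumes when mapping road
    distances to likelihoods in the feature-layer tasks.
    """

    mismatch_scale: float = 2.0
    assoc_strength: float = 4.0
    noise_s: float = 0.25
    noise_on: bool = True
    similarity: str = "linear"
    update_strategy: str = "positive"
    humint_dispersion: float = 10.0
    min_dispersion: float = 2.0
    rl_alpha: float = 0.2
    path_weights: tuple[float, float] = (1.0, 1.0)
    counterfactuals_on_forced: bool = True

    def activation_params(self) -> ActivationParams:
        return ActivationParams(
            mismatch_scale=self.mismatch_scale,
            assoc_strength=self.assoc_strength,
            noise_s=self.noise_s,
            noise_on=self.noise_on,
        )


class Agent:
    """Instance-based sensemaking agent with persistent declarative memory."""

    def __init__(self, config: AgentConfig | None = None, rng: np.random.Generator | None = None):
        self.config = config or AgentConfig()
        self.rng = rng or np.random.default_rng()
        self.params = self.config.activation_params()
        self.events: dict[str, list[Chunk]] = {}
        self.centroid_memory = CentroidMemory()
        self.adjustment_store: ChunkStore = seed_adjustment_memory()
        self.allocation_store = ChunkStore()
        self.layer_store = ChunkStore()
        self.rlstate = UtilityState(alpha=self.config.rl_alpha, noise_s=self.config.noise_s)

    # -- event memory -------------------------------------------------------

    def observe_events(self, events: Sequence[SigactEvent]) -> None:
        for ev in events:
            if ev.category is None:
                continue
            self.events.setdefault(ev.category, []).append(
                Chunk(slots={"location": ev.location, "category": ev.category})
            )

    def event_count(self, label: str) -> int:
        return len(self.events.get(label, []))

    # -- centroid estimation (Tasks 1-3) ------------------------------------

    def estimate_centroid(self, label: str, trial_index: int) -> tuple[float, float]:
        """Blend the category's events, then blend with past centroid
        estimates (centroid-of-centroids), storing the result."""
        evs = self.events.get(label)
        if not evs:
            raise ValueError(f"no events for category {label!r}")
        raw = blend_centroid(evs, self.params, self.rng)
        return centroid_of_centroids(
            label, raw, self.centroid_memory, trial_index, self.params, self.rng
        )

    def estimate_dispersion(self, label: str, centroid: tuple[float, float]) -> float:
        pts = np.array([c.slots["location"] for c in self.events.get(label, [])], dtype=float)
        if len(pts) < 2:
            return self.config.humint_dispersion
        sq = np.sum((pts - np.asarray(centroid)) ** 2)
        return max(self.config.min_dispersion, math.sqrt(sq / (2.0 * len(pts))))

    # -- probability generation and revision --------------------------------

    def report_probability(self, value: float) -> float:
        """Report a self-generated probability through the blended
        adjustment memory (identity factor): the instance-based map that
        regresses extreme values toward the seeded consensus."""
        return adjust_probability(
            float(value), 1.0, self.adjustment_store, self.params, self.rng,
            self.config.similarity,
        )

    def report_distribution(self, raw: ProbDist) -> ProbDist:
        mapped = [self.report_probability(p) for p in raw.probs]
        return ProbDist(np.array(mapped), raw.labels)

    def distribution_from_events(
        self,
        probe: tuple[float, float],
        labels: Sequence[str],
        trial_index: int,
        network=None,
    ) -> ProbDist:
        """Tasks 1-3 response: centroid-of-centroids per category, a
        Gaussian likelihood in (possibly cognitive road) distance with the
        estimated dispersion, and *no frequency term* (base-rate neglect),
        reported through the adjustment map."""
        likes = []
        for lbl in labels:
            c = self.estimate_centroid(lbl, trial_index)
            sigma = self.estimate_dispersion(lbl, c)
            if network is not None:
                d = plan_path(
                    c, probe, network, self.params, self.rng, self.config.path_weights
                ).cognitive_distance
                ndim = 1
            else:
                d = math.dist(c, probe)
                ndim = 2
            likes.append(math.exp(-(d**2) / (2.0 * sigma**2)) / sigma**ndim)
        raw = ProbDist(np.array(likes), tuple(labels))
        return self.report_distribution(raw)

    def humint_distribution(
        self,
        centroids: dict[str, tuple[float, float]],
        probe: tuple[float, float],
        network,
    ) -> ProbDist:
        """Initial distribution from given centroids over a road network,
        using greedily planned paths and distorted distance percepts."""
        sigma = self.config.humint_dispersion
        likes, labels = [], []
        for lbl, c in centroids.items():
            d = plan_path(
                c, probe, network, self.params, self.rng, self.config.path_weights
            ).cognitive_distance
            likes.append(math.exp(-(d**2) / (2.0 * sigma**2)) / sigma)
            labels.append(lbl)
        return self.report_distribution(ProbDist(np.array(likes), tuple(labels)))

    def update(self, dist: ProbDist, outcome: FeatureOutcome) -> ProbDist:
        return update_distribution(
            dist, outcome, self.adjustment_store, self.params, self.rng,
            self.config.similarity, self.config.update_strategy,
        )

    # -- resource allocation -------------------------------------------------

    def allocate(self, dist: ProbDist, forced_choice: bool = False) -> AllocationDecision:
        return decide_allocation(
            dist, self.allocation_store, self.params, self.rng, forced_choice
        )

    def learn_outcome(
        self, dist: ProbDist, decision: AllocationDecision, truth: str,
        forced_choice: bool = False,
    ) -> float:
        if forced_choice and not self.config.counterfactuals_on_forced:
            labels = dist.labels
            outcome = float(decision.allocation[labels.index(truth)])
            self.allocation_store.add(
                {"lead_prob": float(dist.probs[labels.index(decision.leader)]),
                 "allocated": 100.0, "outcome": outcome, "kind": "actual"}
            )
            return outcome
        return learn_allocation(dist, decision, truth, self.allocation_store)

    # -- layer selection ------------------------------------------------------

    def choose_layer(self, dist: ProbDist, available: Sequence[str]):
        return select_layer(
            dist, available, self.layer_store, self.rlstate, self.params, self.rng
        )

    def experience_layer(self, situation: ProbDist, action: str, posterior: ProbDist) -> None:
        """After a layer's update: store the episode and apply RL feedback."""
        record_layer_experience(situation, action, posterior, self.layer_store)
        rl_feedback(situation, posterior, action, self.rlstate)

    # -- checkpointing --------------------------------------------------------

    def checkpoint(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.allocation_store.to_jsonl(d / "allocation.jsonl")
        self.layer_store.to_jsonl(d / "layers.jsonl")
        self.adjustment_store.to_jsonl(d / "adjustment.jsonl")
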