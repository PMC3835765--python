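"""Intelligence-layer selection for the choose-your-evidence task.

Selection is instance based: situation-action-outcome-utility chunks from
past layer choices (and from the fixed-order tasks that precede the free
choice) are partially matched on the current situation — the leading
category's probability and a bucketed entropy — and the blended utility
of each available layer is compared.  Utility is the weighted distance

    d = sum_i p_i (1 - p_i)

of the post-update distribution (0 at certainty, 0.75 at a uniform
four-hypothesis state); lower is better.  When no episode is available
for a layer, the agent performs a depth-one difference-reduction
look-ahead: it mentally simulates each outcome of the candidate layer
with the rule-implied predictive probabilities, scores the expected d
(with some simulation noise standing in for inaccuracy), and commits the
simulated episode to memory.  A reinforcement-learned preference order
over layers (rewarded by entropy reduction) breaks ties and orients the
first pick of a trial.  SIGINT always inspects the current leading
category — the confirmation-prone default strategy.
"""

from __future__ import annotations

from functools import partial
from typing import Sequence

import numpy as np

from .bayes import ProbDist, apply_rule
from .memory import (
    ActivationParams,
    BlendRequest,
    ChunkStore,
    RetrievalFailure,
    UtilityState,
    blend,
    similarity_linear,
    utility_update,
)
from .taskenv import (
    FeatureOutcome,
    IMINT_MOVINT_P_FAVORED,
    SIGINT_P_CHATTER_OTHER,
    SIGINT_P_CHATTER_TRUE,
    SOCINT_P_TRUE_REGION,
)

__all__ = [
    "ALL_LAYERS",
    "DEFAULT_LAYER_PREFERENCE",
    "weighted_distance",
    "entropy_bucket",
    "outcome_space",
    "expected_layer_utility",
    "select_layer",
    "record_layer_experience",
    "rl_feedback",
]

ALL_LAYERS = ("SOCINT", "IMINT", "MOVINT", "SIGINT")
# Canonical tie-break order by best-single-outcome diagnosticity (7 > 4 = 4 > 2).
DEFAULT_LAYER_PREFERENCE = ("SIGINT", "IMINT", "MOVINT", "SOCINT")

ENTROPY_BUCKET_WIDTH = 0.25
_UTILITY_GRID = tuple(np.round(np.arange(0.0, 0.7501, 0.01), 10))
_sim_prob = partial(similarity_linear, scale=1.0)
_sim_bucket = partial(similarity_linear, scale=8.0)
_sim_util = partial(similarity_linear, scale=0.75)
PUNISHMENT_FLOOR = 0.05


def weighted_distance(dist: ProbDist) -> float:
    """Certainty deficit ``d = sum p_i (1 - p_i)``; zero is the optimum."""
    p = np.asarray(dist.probs)
    return float(np.sum(p * (1.0 - p)))


def entropy_bucket(dist: ProbDist) -> int:
    """Entropy bucket index (0.25-bit-wide bins)."""
    return int(dist.entropy() / ENTROPY_BUCKET_WIDTH)


def outcome_space(layer: str, dist: ProbDist, inspected: str | None = None):
    """All outcomes of a layer with their predictive probabilities under
    the current belief and the generative rule model."""
    labels = dist.labels
    if layer == "IMINT":
        p = IMINT_MOVINT_P_FAVORED
        p_gov = sum(
            dist[lbl] * (p if lbl in ("A", "B") else 1 - p) for lbl in labels
        )
        return [
            (FeatureOutcome("IMINT", "government"), p_gov),
            (FeatureOutcome("IMINT", "military"), 1.0 - p_gov),
        ]
    if layer == "MOVINT":
        p = IMINT_MOVINT_P_FAVORED
        p_dense = sum(
            dist[lbl] * (p if lbl in ("A", "C") else 1 - p) for lbl in labels
        )
        return [
            (FeatureOutcome("MOVINT", "dense"), p_dense),
            (FeatureOutcome("MOVINT", "sparse"), 1.0 - p_dense),
        ]
    if layer == "SIGINT":
        c = inspected or dist.leader()
        p_chat = dist[c] * SIGINT_P_CHATTER_TRUE + (1.0 - dist[c]) * SIGINT_P_CHATTER_OTHER
        return [
            (FeatureOutcome("SIGINT", "chatter", c), p_chat),
            (FeatureOutcome("SIGINT", "silence", c), 1.0 - p_chat),
        ]
    if layer == "SOCINT":
        p_true, n = SOCINT_P_TRUE_REGION, len(labels)
        out = []
        for r in labels:
            p_r = dist[r] * p_true + (1.0 - dist[r]) * (1.0 - p_true) / (n - 1)
            out.append((FeatureOutcome("SOCINT", r), p_r))
        return out
    raise ValueError(f"unknown layer {layer!r}")


def expected_layer_utility(layer: str, dist: ProbDist, inspected: str | None = None) -> float:
    """Exact expected post-update d of one layer (depth-one enumeration)."""
    return sum(
        p * weighted_distance(apply_rule(dist, outcome))
        for outcome, p in outcome_space(layer, dist, inspected)
    )


def _preference_rank(rlstate: UtilityState | None) -> dict[str, int]:
    base = {lyr: i for i, lyr in enumerate(DEFAULT_LAYER_PREFERENCE)}
    if rlstate is None or not rlstate.utilities:
        return base
    ordered = sorted(ALL_LAYERS, key=lambda l: (-rlstate.utilities.get(l, 0.0), base[l]))
    return {lyr: i for i, lyr in enumerate(ordered)}


def select_layer(
    dist: ProbDist,
    available: Sequence[str],
    store: ChunkStore,
    rlstate: UtilityState | None,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
) -> tuple[str, str | None]:
    """Pick the next layer; returns ``(layer, inspected_category)``.

    Blends stored utilities per available layer when episodes exist;
    otherwise look-ahead simulates the layer, stores the simulated
    episode, and uses its (possibly noise-perturbed) expected utility.
    The minimum-d layer wins; exact ties fall to the RL preference order.
    """
    if not available:
        raise ValueError("no layers available")
    leader = dist.leader()
    lead_prob = dist[leader]
    bucket = entropy_bucket(dist)
    rank = _preference_rank(rlstate)

    scored: list[tuple[float, int, str]] = []
    for layer in available:
        inspected = leader if layer == "SIGINT" else None
        chunks = store.filter(action=layer)
        if chunks:
            try:
                util = blend(
                    chunks,
                    BlendRequest(
                        constraints={
                            "leader_prob": (lead_prob, _sim_prob),
                            "entropy_bucket": (float(bucket), _sim_bucket),
                        },
                        value_slot="utility",
                        value_similarity=_sim_util,
                        candidate_grid=_UTILITY_GRID,
                    ),
                    params,
                    rng,
                )
            except RetrievalFailure:  # pragma: no cover - filter guarantees a match
                chunks = []
        if not chunks:
            util = expected_layer_utility(layer, dist, inspected)
            if params.noise_on and params.noise_s > 0:
                if rng is None:
                    raise ValueError("stochastic look-ahead requires an rng")
                util = float(np.clip(util + rng.logistic(0.0, params.noise_s / 4.0), 0.0, 0.75))
            store.add(
                {"leader_prob": lead_prob, "entropy_bucket": float(bucket),
                 "action": layer, "utility": float(util), "simulated": True},
                merge=False,
            )
        scored.append((float(util), rank[layer], layer))
    # Utilities agreeing to 9 decimals are exact ties (float-noise guard).
    scored.sort(key=lambda t: (round(t[0], 9), t[1]))
    choice = scored[0][2]
    return choice, (leader if choice == "SIGINT" else None)


def record_layer_experience(
    situation: ProbDist,
    action: str,
    posterior: ProbDist,
    store: ChunkStore,
) -> float:
    """Store the realized situation-action-outcome-utility episode.

    The utility slot holds the post-update weighted distance d.
    """
    d = weighted_distance(posterior)
    store.add(
        {"leader_prob": situation[situation.leader()],
         "entropy_bucket": float(entropy_bucket(situation)),
         "action": action, "utility": float(d), "simulated": False},
        merge=False,
    )
    return d


def rl_feedback(
    prior: ProbDist,
    posterior: ProbDist,
    action: str,
    rlstate: UtilityState,
) -> UtilityState:
    """Reward a layer by its entropy reduction; punish a no-gain update.

    The reward is the entropy drop in bits; an update that leaves entropy
    unchanged or raises it is a punishment (floored at -0.05).
    """
    gain = prior.entropy() - posterior.entropy()
    reward = gain if gain > 1e-12 else min(gain, -PUNISHMENT_FLOOR)
    return utility_update(rlstate, action, reward)
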