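"""Instance-based resource allocation with counterfactual learning.

Allocation decisions are driven by episodes of past decisions, each an
(lead-probability, allocated-share, outcome) chunk, via two blended
retrievals: first an *expected outcome* is blended from past episodes
cued on the leading category's probability; then the *allocated share* is
blended from episodes cued on both the probability and that expected
outcome.  The remainder is split among the other categories in proportion
to their probabilities.  After feedback, the actual episode is stored
together with up to two counterfactuals — what a winner-take-all (WTA)
choice and a pure probability-matching (PM) choice would have scored —
bracketing the strategy space so any intermediate policy can emerge from
blending.  Early zero-outcome WTA feedback (forced choices) is what later
pulls allocations away from WTA toward matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import partial
from typing import Optional

import numpy as np

from .bayes import ProbDist
from .memory import (
    ActivationParams,
    BlendRequest,
    ChunkStore,
    RetrievalFailure,
    blend,
    similarity_linear,
)

__all__ = ["AllocationDecision", "decide_allocation", "learn_allocation", "round_to_percent"]

_OUTCOME_GRID = tuple(float(x) for x in range(0, 101))
_SHARE_GRID = tuple(float(x) for x in range(25, 101))

_sim_prob = partial(similarity_linear, scale=1.0)
_sim_pct = partial(similarity_linear, scale=100.0)


@dataclass
class AllocationDecision:
    allocation: np.ndarray  # integer percents summing to 100
    leader: str
    leader_share: float  # pre-rounding blended share for the leader
    expected_outcome: Optional[float] = None
    fallback: Optional[str] = None  # "matching" when the store was empty


def round_to_percent(shares: np.ndarray) -> np.ndarray:
    """Round nonnegative shares summing to 100 to integers summing to 100
    (largest-remainder correction)."""
    shares = np.maximum(np.asarray(shares, dtype=float), 0.0)
    total = shares.sum()
    if total <= 1e-9:  # degenerate/denormal mass: fall back to an even split
        shares = np.full(len(shares), 100.0 / len(shares))
    else:
        shares = shares * (100.0 / total)
    floors = np.floor(shares).astype(int)
    short = 100 - floors.sum()
    order = np.argsort(-(shares - floors))
    for i in range(short):
        floors[order[i % len(floors)]] += 1
    return floors


def _distribute_remainder(dist: ProbDist, leader_idx: int, leader_share: float) -> np.ndarray:
    shares = np.zeros(len(dist.probs))
    shares[leader_idx] = leader_share
    rest = np.delete(np.arange(len(dist.probs)), leader_idx)
    rest_p = dist.probs[rest]
    if rest_p.sum() > 0:
        shares[rest] = (100.0 - leader_share) * rest_p / rest_p.sum()
    else:
        shares[rest] = (100.0 - leader_share) / len(rest)
    return shares


def decide_allocation(
    dist: ProbDist,
    store: ChunkStore,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
    forced_choice: bool = False,
) -> AllocationDecision:
    """Choose an allocation vector for the current distribution.

    Forced-choice trials put 100% on the leading category.  Otherwise the
    two-step blended retrieval sets the leader's share; with no stored
    episodes yet the decision falls back to pure probability matching.
    """
    leader = dist.leader()
    leader_idx = dist.labels.index(leader)
    lead_prob = float(dist.probs[leader_idx])

    if forced_choice:
        shares = np.zeros(len(dist.probs))
        shares[leader_idx] = 100.0
        return AllocationDecision(round_to_percent(shares), leader, 100.0)

    try:
        expected = blend(
            store,
            BlendRequest(
                constraints={"lead_prob": (lead_prob, _sim_prob)},
                value_slot="outcome",
                value_similarity=_sim_pct,
                candidate_grid=_OUTCOME_GRID,
            ),
            params,
            rng,
        )
        share = blend(
            store,
            BlendRequest(
                constraints={
                    "lead_prob": (lead_prob, _sim_prob),
                    "outcome": (expected, _sim_pct),
                },
                value_slot="allocated",
                value_similarity=_sim_pct,
                candidate_grid=_SHARE_GRID,
            ),
            params,
            rng,
        )
    except RetrievalFailure:
        shares = dist.probs * 100.0
        return AllocationDecision(
            round_to_percent(shares), leader, float(shares[leader_idx]), fallback="matching"
        )
    share = float(min(100.0, max(0.0, share)))
    shares = _distribute_remainder(dist, leader_idx, share)
    return AllocationDecision(round_to_percent(shares), leader, share, expected_outcome=expected)


def learn_allocation(
    dist: ProbDist,
    decision: AllocationDecision,
    truth: str,
    store: ChunkStore,
) -> float:
    """Commit the trial's episode and counterfactuals to memory.

    Returns the actual outcome (the share allocated to the ground truth).
    Counterfactual episodes: WTA (100 to the leader — 100 if the leader
    was correct, else 0) and PM (allocation = probabilities — outcome is
    100 * p_truth).  A counterfactual identical to the actual decision is
    skipped.
    """
    labels = dist.labels
    truth_idx = labels.index(truth)
    leader_idx = labels.index(decision.leader)
    lead_prob = float(dist.probs[leader_idx])
    actual_share = float(decision.allocation[leader_idx])
    outcome = float(decision.allocation[truth_idx])

    store.add({"lead_prob": lead_prob, "allocated": actual_share,
               "outcome": outcome, "kind": "actual"})

    wta_outcome = 100.0 if leader_idx == truth_idx else 0.0
    if actual_share != 100.0:
        store.add({"lead_prob": lead_prob, "allocated": 100.0,
                   "outcome": wta_outcome, "kind": "counterfactual-WTA"})

    pm_share = 100.0 * lead_prob
    pm_outcome = 100.0 * float(dist.probs[truth_idx])
    if abs(pm_share - actual_share) > 0.5:
        store.add({"lead_prob": lead_prob, "allocated": pm_share,
                   "outcome": pm_outcome, "kind": "counterfactual-PM"})
    return outcome
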