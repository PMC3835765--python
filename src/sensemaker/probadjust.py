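"""Instance-based probability adjustment.

Memory is seeded with (prior, factor, posterior) triplets over a grid of
initial probabilities and the task's rule factors, where the posterior is
the normalized product assuming the remaining mass is unaffected:

    posterior = p*f / (p*f + (1 - p)).

Estimating an adjusted probability is then a blended retrieval cueing on
the prior (partial match, mismatch 2*|Mk - Mj|) and the factor (exact
match): the returned posterior is the blended consensus of the seeded
chunks.  The consensus regresses toward the local mean of the seeded
posteriors, which *underestimates* adjustments over most of the prior
range and *overestimates* them at the low end (where the value domain is
truncated at zero) — the mechanistic source of anchoring and of low-end
confirmation.  A ratio (magnitude-sensitive) similarity sharpens matching
near zero and shrinks the low-end overestimate.
"""

from __future__ import annotations

from functools import partial
from typing import Sequence

import numpy as np

from .bayes import ProbDist, RULE_FACTORS
from .memory import (
    ActivationParams,
    BlendRequest,
    ChunkStore,
    RetrievalFailure,
    blend,
    similarity_linear,
    similarity_ratio,
)

__all__ = [
    "DEFAULT_PRIOR_GRID",
    "DEFAULT_FACTORS",
    "normative_posterior",
    "seed_adjustment_memory",
    "adjust_probability",
    "update_distribution",
    "rule_targets",
]

DEFAULT_PRIOR_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))
# All rule factors and their inverses, plus the identity factor.
DEFAULT_FACTORS = (1.0 / 7.0, 1.0 / 4.0, 1.0 / 3.0, 1.0 / 2.0, 1.0, 2.0, 3.0, 4.0, 7.0)

_VALUE_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 10))


def normative_posterior(prior: float, factor: float) -> float:
    """Closed-form normalized product ``p*f / (p*f + (1-p))``."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    num = prior * factor
    return num / (num + (1.0 - prior)) if (num + (1.0 - prior)) > 0 else 0.0


def seed_adjustment_memory(
    prior_grid: Sequence[float] = DEFAULT_PRIOR_GRID,
    factors: Sequence[float] = DEFAULT_FACTORS,
) -> ChunkStore:
    """One chunk per (prior, factor) pair with its normalized posterior."""
    if not prior_grid:
        raise ValueError("empty prior grid")
    store = ChunkStore()
    for f in factors:
        if f <= 0:
            raise ValueError("factor must be positive")
        for p in prior_grid:
            store.add(
                {"prior": float(p), "factor": float(f),
                 "posterior": normative_posterior(float(p), float(f))},
                merge=False,
            )
    return store


def _similarity_fn(name: str):
    if name == "linear":
        return partial(similarity_linear, scale=1.0)
    if name == "ratio":
        return similarity_ratio
    raise ValueError(f"unknown similarity {name!r}")


def adjust_probability(
    prior: float,
    factor: float,
    store: ChunkStore,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
    similarity: str = "linear",
) -> float:
    """Blended posterior for (prior, factor), clipped to [0, 1].

    The factor slot is matched exactly; the prior slot is partially
    matched with the configured similarity.  An unseeded factor falls
    back to the closed-form normalized product.
    """
    sim = _similarity_fn(similarity)
    req = BlendRequest(
        constraints={"factor": (float(factor), None), "prior": (float(prior), sim)},
        value_slot="posterior",
        value_similarity=sim,
        candidate_grid=_VALUE_GRID,
    )
    try:
        value = blend(store, req, params, rng)
    except RetrievalFailure:
        return normative_posterior(prior, factor)
    return float(min(1.0, max(0.0, value)))


def rule_targets(outcome) -> list[tuple[str, float]]:
    """Categories named by a feature outcome with their update factors.

    These are the categories the positive-only strategy adjusts; the
    factors are the likelihood weights of the rule (e.g. the inspected
    category gets 7 on chatter, 1/3 on silence; other categories are
    left to the interface normalization).
    """
    return [(lbl, float(w)) for lbl, w in RULE_FACTORS(outcome).items() if w != 1.0]


def update_distribution(
    dist: ProbDist,
    outcome,
    store: ChunkStore,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
    similarity: str = "linear",
    strategy: str = "positive",
) -> ProbDist:
    """Revise a distribution after one feature outcome.

    ``positive`` (default): only the categories favored/named by the rule
    are re-estimated through the blended adjustment; the rest keep their
    prior value and a single renormalization (the interface's) closes the
    books.  ``full-bayes``: every category is multiplied by its exact rule
    weight (reference strategy, no blending).
    """
    if strategy == "full-bayes":
        return dist.scaled(RULE_FACTORS(outcome))
    if strategy != "positive":
        raise ValueError(f"unknown update strategy {strategy!r}")
    new = np.array(dist.probs, dtype=float)
    for label, factor in rule_targets(outcome):
        i = dist.labels.index(label)
        new[i] = adjust_probability(float(dist.probs[i]), factor, store, params, rng, similarity)
    return ProbDist(new, dist.labels)
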