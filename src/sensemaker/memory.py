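"""Subsymbolic declarative-memory kernel: activation, partial matching,
probabilistic retrieval, blended retrieval, and utility learning.

The kernel follows the standard ACT-R subsymbolic equations.  A chunk's
activation is

    A_i = B_i + S_i + P_i + eps_i

where ``B_i = ln(n_i)`` is base-level activation (decay and the constant
offset are disabled in this model, leaving only the frequency term),
``S_i`` is spreading activation from source chunks (off by default),
``P_i`` is the partial-matching penalty (mismatch scale times the summed
slot similarities, each in [-1, 0]), and ``eps_i`` is transient logistic
noise with scale ``s``.  Retrieval is a Boltzmann (softmax) draw over
``exp(A_i / s)``; blended retrieval returns the compromise value ``v``
minimizing ``sum_i P_i (1 - Sim(v, v_i))^2`` over a candidate grid.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Chunk",
    "ChunkStore",
    "ActivationParams",
    "BlendRequest",
    "UtilityState",
    "similarity_linear",
    "similarity_ratio",
    "activation",
    "retrieval_probabilities",
    "retrieve",
    "blend",
    "utility_update",
    "utility_select",
    "RetrievalFailure",
]

_chunk_counter = itertools.count()


class RetrievalFailure(Exception):
    """Raised when no chunk matches the hard constraints of a request."""


@dataclass
class Chunk:
    """A declarative memory record: named slots plus a presentation history.

    ``n`` is the number of presentations (merging an identical chunk into a
    store re-presents it and increments ``n``); with decay disabled the
    base-level activation is ``ln(n)``.
    """

    slots: dict[str, Any]
    n: int = 1
    id: int = field(default_factory=lambda: next(_chunk_counter))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a chunk needs at least one presentation")


@dataclass
class ActivationParams:
    """Architectural parameters of the declarative module.

    mismatch_scale
        Weight of the partial-matching penalty (match scale, default 2).
    assoc_strength
        Maximum associative strength S for spreading activation (default 4).
    noise_s
        Scale of the transient logistic activation noise, also the softmax
        temperature of retrieval (default 0.25).
    noise_on
        Master switch for the stochastic component; with noise off the
        kernel is fully deterministic (useful for limit checks).
    """

    mismatch_scale: float = 2.0
    assoc_strength: float = 4.0
    noise_s: float = 0.25
    noise_on: bool = True

    def deterministic(self) -> "ActivationParams":
        return replace(self, noise_on=False)


@dataclass
class BlendRequest:
    """Specification of a blended retrieval.

    ``constraints`` maps slot names to (target value, similarity function)
    pairs used for partial matching; a similarity of ``None`` makes the slot
    a hard (exact-match) constraint filtering the candidate chunks.
    ``value_slot`` names the slot whose value is blended, searched over
    ``candidate_grid`` unioned with all stored values, with ties broken
    toward the smallest candidate.
    """

    constraints: dict[str, tuple[Any, Callable[[Any, Any], float] | None]]
    value_slot: str
    value_similarity: Callable[[Any, Any], float]
    candidate_grid: Sequence[float] = ()


def similarity_linear(a: float, b: float, scale: float = 1.0) -> float:
    """Linear similarity ``-|a - b| / scale``, in [-1, 0] over the domain.

    ``scale`` is the width of the value domain (1 for probabilities, 100
    for grid coordinates or percentages).
    """
    return -abs(a - b) / scale


def similarity_ratio(a: float, b: float) -> float:
    """Ratio similarity ``-(1 - min/max)``, in [-1, 0].

    Magnitude-sensitive: mismatch grows sharply for values near zero
    (0.01 vs 0.02 is -0.5, where the linear mismatch is only -0.01).
    The 0/0 case is defined as a perfect match.
    """
    if a < 0 or b < 0:
        raise ValueError("ratio similarity is defined for nonnegative values")
    if a == b:
        return 0.0
    lo, hi = (a, b) if a < b else (b, a)
    return -(1.0 - lo / hi)


def _matches_hard(chunk: Chunk, req: BlendRequest) -> bool:
    for slot, (target, sim) in req.constraints.items():
        if sim is None and chunk.slots.get(slot) != target:
            return False
    return True


def activation(
    chunk: Chunk,
    req: BlendRequest | None,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
    sources: Sequence[tuple[float, int]] | None = None,
) -> float:
    """Total activation ``A_i = B_i + S_i + P_i + eps_i`` of one chunk.

    ``sources`` optionally lists ``(W_kj, fan_ji)`` pairs for spreading
    activation ``sum W_kj (S - ln fan_ji)``; the integrated model leaves
    it off by default.
    """
    a = math.log(chunk.n)
    if sources:
        a += sum(w * (params.assoc_strength - math.log(fan)) for w, fan in sources)
    if req is not None:
        for slot, (target, sim) in req.constraints.items():
            if sim is None:
                continue
            a += params.mismatch_scale * sim(target, chunk.slots[slot])
    if params.noise_on and params.noise_s > 0:
        if rng is None:
            raise ValueError("stochastic activation requires an rng")
        a += rng.logistic(0.0, params.noise_s)
    return a


def retrieval_probabilities(activations: Sequence[float], s: float) -> np.ndarray:
    """Boltzmann retrieval distribution ``exp(A_i/s) / sum_j exp(A_j/s)``.

    In the ``s -> 0`` limit the argmax chunk is retrieved with certainty.
    """
    a = np.asarray(activations, dtype=float)
    if s <= 0:
        p = np.zeros_like(a)
        p[np.flatnonzero(a == a.max())] = 1.0
        return p / p.sum()
    z = a / s
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def retrieve(
    candidates: Sequence[Chunk],
    params: ActivationParams,
    rng: np.random.Generator,
    req: BlendRequest | None = None,
) -> Chunk:
    """Sample one chunk with Boltzmann probability over activations.

    The sampling distribution is the softmax of the noise-free activations
    at temperature ``s`` (the printed retrieval-probability equation); with
    ``noise_on`` off the argmax chunk is returned deterministically.
    """
    if not candidates:
        raise RetrievalFailure("empty candidate set")
    quiet = params.deterministic()
    acts = [activation(c, req, quiet) for c in candidates]
    if not params.noise_on:
        return candidates[int(np.argmax(acts))]
    probs = retrieval_probabilities(acts, params.noise_s)
    return candidates[int(rng.choice(len(candidates), p=probs))]


def blend(
    store: Iterable[Chunk],
    req: BlendRequest,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Blended retrieval: the consensus value of all matching chunks.

    Returns the candidate ``v`` minimizing ``sum_i P_i (1 - Sim(v, v_i))^2``
    where ``P_i`` are the Boltzmann retrieval probabilities of the chunks
    matching the hard constraints.  Candidates are the request grid unioned
    with the stored values; exact ties go to the smallest candidate.
    """
    matching = [c for c in store if _matches_hard(c, req)]
    if not matching:
        raise RetrievalFailure("no chunk matches the blend constraints")
    acts = [activation(c, req, params, rng) for c in matching]
    probs = retrieval_probabilities(acts, params.noise_s)
    values = np.array([float(c.slots[req.value_slot]) for c in matching])
    candidates = np.unique(np.concatenate([np.asarray(req.candidate_grid, dtype=float), values]))
    sim = req.value_similarity
    # Kernel similarities live in [-1, 0] with 0 = identical; on the
    # 1 = identical convention of the compromise objective this makes
    # (1 - Sim)^2 the squared dissimilarity sim(v, v_i)^2.
    cost = np.array(
        [sum(p * sim(v, vi) ** 2 for p, vi in zip(probs, values)) for v in candidates]
    )
    return float(candidates[int(np.argmin(cost))])


@dataclass
class UtilityState:
    """Delta-rule action utilities with softmax selection.

    ``U_i(n) = U_i(n-1) + alpha * (R_i(n) - U_i(n-1))``.
    """

    utilities: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.2
    noise_s: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


def utility_update(state: UtilityState, action: str, reward: float) -> UtilityState:
    """Apply one delta-rule update for ``action``; returns the state."""
    u = state.utilities.get(action, 0.0)
    state.utilities[action] = u + state.alpha * (reward - u)
    return state


def utility_select(
    state: UtilityState,
    actions: Sequence[str],
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
) -> str:
    """Softmax action selection over utilities (unseen actions start at 0).

    Deterministic mode takes the argmax, first listed action on ties.
    """
    us = [state.utilities.get(a, 0.0) for a in actions]
    if not stochastic or state.noise_s <= 0:
        return actions[int(np.argmax(us))]
    if rng is None:
        raise ValueError("stochastic selection requires an rng")
    probs = retrieval_probabilities(us, state.noise_s)
    return actions[int(rng.choice(len(actions), p=probs))]


class ChunkStore:
    """A set of chunks with identical-slot merging and JSONL checkpointing.

    Re-adding a chunk whose slots match an existing one exactly re-presents
    that chunk (``n += 1``) rather than duplicating it, which is how
    frequency enters base-level activation.
    """

    def __init__(self, chunks: Iterable[Chunk] = ()) -> None:
        self.chunks: list[Chunk] = list(chunks)

    def __iter__(self):
        return iter(self.chunks)

    def __len__(self) -> int:
        return len(self.chunks)

    def add(self, slots: dict[str, Any], merge: bool = True) -> Chunk:
        if merge:
            for c in self.chunks:
                if c.slots == slots:
                    c.n += 1
                    return c
        c = Chunk(slots=dict(slots))
        self.chunks.append(c)
        return c

    def filter(self, **exact: Any) -> list[Chunk]:
        return [c for c in self.chunks if all(c.slots.get(k) == v for k, v in exact.items())]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chunks:
                fh.write(json.dumps({"slots": c.slots, "n": c.n}) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ChunkStore":
        store = cls()
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    store.chunks.append(Chunk(slots=rec["slots"], n=rec["n"]))
        return store
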