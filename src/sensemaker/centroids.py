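"""Category centroid estimation by blended retrieval over events.

A centroid estimate is the blended consensus of the event locations in
memory: the compromise point minimizing the retrieval-probability-weighted
squared dissimilarity, where the mismatch between two locations is a
linear difference scaled by the display size,

    P_i = 2 * |d1 - d2| / max_range,    max_range = 100.

Because the squared-dissimilarity objective is separable, the 2-D blend
is performed per coordinate with shared retrieval probabilities, which is
equivalent to minimizing squared Euclidean dissimilarity.

To damp the disproportionate influence of recent events, the final
response blends over the *history of past centroid estimates* (one stored
per category per trial): a centroid-of-centroids.  Each new estimate is
therefore a compromise between the previous ones and the new evidence —
an anchoring-and-adjustment process arising purely from the blending
mechanism.  Since every category contributes exactly one centroid chunk
per trial, probabilities later computed from centroids carry no trace of
category base rates (base-rate neglect by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .memory import ActivationParams, Chunk, retrieval_probabilities

__all__ = ["CentroidChunk", "CentroidMemory", "blend_centroid", "centroid_of_centroids"]

MAX_RANGE = 100.0


@dataclass
class CentroidChunk:
    """One per category per trial: the blended centroid at that trial."""

    category: str
    location: tuple[float, float]
    generation: int


def _location_blend(
    points: np.ndarray,
    counts: np.ndarray,
    params: ActivationParams,
    rng: np.random.Generator | None,
) -> tuple[float, float]:
    """Blend 2-D locations: retrieval-probability-weighted mean.

    Activations are base level ``ln(n)`` plus transient noise; with the
    linear location mismatch the squared-dissimilarity minimum is the
    probability-weighted mean of the stored points (grid-free closed
    form, exact because the objective is quadratic in the candidate).
    """
    acts = np.log(counts).astype(float)
    if params.noise_on and params.noise_s > 0:
        if rng is None:
            raise ValueError("stochastic blending requires an rng")
        acts = acts + rng.logistic(0.0, params.noise_s, size=len(acts))
    probs = retrieval_probabilities(acts, params.noise_s)
    xy = probs @ points
    return (float(xy[0]), float(xy[1]))


def blend_centroid(
    events,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Blended location over the event chunks of one category.

    ``events`` may be ``SigactEvent``s, memory ``Chunk``s with a
    ``location`` slot, or bare points; repeated presentations (chunk
    ``n``) raise base-level activation and pull the blend toward
    frequently re-presented locations.
    """
    pts, counts = [], []
    for ev in events:
        if isinstance(ev, Chunk):
            pts.append(ev.slots["location"])
            counts.append(ev.n)
        else:
            pts.append(getattr(ev, "location", ev))
            counts.append(getattr(ev, "n", 1))
    if not pts:
        raise ValueError("no events for category")
    return _location_blend(np.asarray(pts, dtype=float), np.asarray(counts), params, rng)


@dataclass
class CentroidMemory:
    """Per-category history of centroid chunks across trials."""

    history: dict[str, list[CentroidChunk]] = field(default_factory=dict)

    def for_category(self, label: str) -> list[CentroidChunk]:
        return self.history.get(label, [])

    def append(self, chunk: CentroidChunk) -> None:
        self.history.setdefault(chunk.category, []).append(chunk)

    def to_records(self) -> list[dict]:
        return [
            {"category": c.category, "location": list(c.location), "generation": c.generation}
            for chunks in self.history.values()
            for c in chunks
        ]


def centroid_of_centroids(
    category: str,
    raw_centroid: tuple[float, float],
    memory: CentroidMemory,
    trial_index: int,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Blend the trial's raw centroid with all previously stored centroids.

    The blended location is stored as the trial's new ``CentroidChunk``
    and returned as the response estimate.  On the first trial this is
    exactly the raw blended centroid.
    """
    prior = memory.for_category(category)
    pts = np.asarray([c.location for c in prior] + [raw_centroid], dtype=float)
    counts = np.ones(len(pts))
    est = _location_blend(pts, counts, params, rng)
    memory.append(CentroidChunk(category, est, trial_index))
    return est
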