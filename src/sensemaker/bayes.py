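"""Normative Bayesian reference solver.

Produces the gold-standard probability distribution over category
hypotheses at every response point: a location posterior from the
generative event model, and exact likelihood-rule updates for the
intelligence feature layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbDist", "posterior_from_events", "apply_rule", "RULE_FACTORS"]

FOUR_LABELS = ("A", "B", "C", "D")
TWO_LABELS = ("A", "B")


@dataclass
class ProbDist:
    """A normalized distribution over 2 or 4 category hypotheses."""

    probs: np.ndarray
    labels: tuple[str, ...] = field(default=FOUR_LABELS)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = tuple(self.labels)
        if len(self.probs) != len(self.labels):
            raise ValueError("probs and labels disagree in length")
        if np.any(self.probs < 0):
            raise ValueError("negative probability")
        total = self.probs.sum()
        if not math.isfinite(total) or total <= 0:
            raise ValueError("distribution not normalizable")
        self.probs = self.probs / total

    @classmethod
    def uniform(cls, labels: tuple[str, ...] = FOUR_LABELS) -> "ProbDist":
        n = len(labels)
        return cls(np.full(n, 1.0 / n), labels)

    def __getitem__(self, label: str) -> float:
        return float(self.probs[self.labels.index(label)])

    def entropy(self) -> float:
        """Shannon entropy in bits, with 0*log(0) = 0."""
        p = self.probs[self.probs > 0]
        return float(-(p * np.log2(p)).sum())

    def leader(self) -> str:
        """Most probable label; ties go to canonical (listed) order."""
        return self.labels[int(np.argmax(self.probs))]

    def scaled(self, weights: dict[str, float]) -> "ProbDist":
        w = np.array([weights.get(lbl, 1.0) for lbl in self.labels])
        return ProbDist(self.probs * w, self.labels)

    def as_dict(self) -> dict[str, float]:
        return {lbl: float(p) for lbl, p in zip(self.labels, self.probs)}


def _gauss_likelihood(dist: float, sigma: float, ndim: int) -> float:
    if sigma <= 0:
        raise ValueError("degenerate dispersion")
    return math.exp(-(dist**2) / (2.0 * sigma**2)) / sigma**ndim


def posterior_from_events(
    probe_xy,
    categories,
    mode: str = "euclidean",
    network=None,
    use_frequency: bool = True,
) -> ProbDist:
    """Posterior category membership of a probe location.

    ``P(cat | probe) ∝ frequency · Gaussian(distance; dispersion)`` with
    Euclidean distance on the open grid or shortest-path road distance when
    ``mode == "road"`` (road distances are treated as one-dimensional
    displacements, matching the generative snap-to-road model).
    """
    probs, labels = [], []
    for cat in categories:
        if mode == "road":
            if network is None:
                raise ValueError("road mode requires a network")
            d = network.road_distance(cat.centroid, probe_xy)
            ndim = 1
        elif mode == "euclidean":
            d = math.dist(cat.centroid, probe_xy)
            ndim = 2
        else:
            raise ValueError(f"unknown distance mode {mode!r}")
        like = _gauss_likelihood(d, cat.dispersion, ndim)
        if use_frequency:
            like *= cat.frequency
        probs.append(like)
        labels.append(cat.label)
    return ProbDist(np.array(probs), tuple(labels))


def RULE_FACTORS(outcome) -> dict[str, float]:
    """Likelihood weight per hypothesis implied by a feature outcome.

    IMINT government favors A,B 4:1 (military favors C,D); MOVINT dense
    favors A,C 4:1 (sparse favors B,D); SIGINT chatter on X weighs X by 7,
    silence on X weighs X by 1/3; SOCINT weighs the probe's region 2:1.
    """
    layer, value = outcome.layer, outcome.value
    if layer == "IMINT":
        return {"A": 4, "B": 4, "C": 1, "D": 1} if value == "government" else {"A": 1, "B": 1, "C": 4, "D": 4}
    if layer == "MOVINT":
        return {"A": 4, "B": 1, "C": 4, "D": 1} if value == "dense" else {"A": 1, "B": 4, "C": 1, "D": 4}
    if layer == "SIGINT":
        cat = outcome.category
        if cat is None:
            raise ValueError("SIGINT outcome must carry the inspected category")
        return {cat: 7.0} if value == "chatter" else {cat: 1.0 / 3.0}
    if layer == "SOCINT":
        return {value: 2.0}
    raise ValueError(f"no likelihood rule for layer {layer!r}")


def apply_rule(dist: ProbDist, outcome) -> ProbDist:
    """Exact Bayes update of ``dist`` for one feature outcome.

    Multiplies each hypothesis by its likelihood weight and renormalizes;
    independent layers may be applied in any order.
    """
    return dist.scaled(RULE_FACTORS(outcome))
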