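"""Road parsing, hill-climbing path planning, and distorted distance percepts.

The agent does not compute shortest paths.  It splits the road network
into segments between intersections, then greedily appends contiguous
segments from the start toward the probe, preferring at each intersection
the adjoining segment whose far end is nearest the probe (a
difference-reduction heuristic).  Each traversed segment contributes a
*cognitive* distance estimate given by a Stevens power law on curve
complexity,

    D = (1.02 * (cow_walk / crow_flies) + crow_flies) ** 0.82,

which underestimates long and curvy roads: the exponent below unity
compresses large magnitudes, and the compression grows with the
cow-walk/crow-flies ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .memory import ActivationParams, retrieval_probabilities

__all__ = [
    "SegmentPercept",
    "PlannedPath",
    "parse_roads",
    "estimate_distance",
    "plan_path",
    "cognitive_road_distance",
    "STRAIGHT_FACTOR",
    "COMPRESSION_EXPONENT",
]

STRAIGHT_FACTOR = 1.02
COMPRESSION_EXPONENT = 0.82


@dataclass
class SegmentPercept:
    """Perceived geometry of one road segment.

    ``cow_walk`` is the veridical polyline length, ``crow_flies`` the
    straight distance between its endpoint intersections.
    """

    u: tuple[float, float]
    v: tuple[float, float]
    cow_walk: float
    crow_flies: float
    segment_id: int = 0

    def __post_init__(self) -> None:
        if self.crow_flies > self.cow_walk + 1e-6:
            raise ValueError("crow_flies cannot exceed cow_walk")
        self.crow_flies = min(self.crow_flies, self.cow_walk)


def parse_roads(net) -> list[SegmentPercept]:
    """Split a road network into two-intersection segments."""
    segs = [
        SegmentPercept(u, v, data["cow_walk"], data["crow_flies"], data["segment_id"])
        for u, v, data in net.graph.edges(data=True)
    ]
    return sorted(segs, key=lambda s: s.segment_id)


def estimate_distance(
    seg: SegmentPercept,
    exponent: float = COMPRESSION_EXPONENT,
    factor: float = STRAIGHT_FACTOR,
) -> float:
    """Cognitive distance of one segment by the power-law percept."""
    if seg.crow_flies <= 0:
        return 0.0
    complexity = seg.cow_walk / seg.crow_flies
    return (factor * complexity + seg.crow_flies) ** exponent


@dataclass
class PlannedPath:
    """Ordered traversal of segments with its total cognitive distance."""

    nodes: list[tuple[float, float]]
    segments: list[SegmentPercept]
    cognitive_distance: float
    veridical_distance: float
    fell_back: bool = False


def plan_path(
    start,
    probe,
    net,
    params: ActivationParams | None = None,
    rng: np.random.Generator | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    exponent: float = COMPRESSION_EXPONENT,
    factor: float = STRAIGHT_FACTOR,
) -> PlannedPath:
    """Greedy hill-climb along road segments from ``start`` to ``probe``.

    At each intersection the adjoining unvisited segments are scored by
    partial matching over two cues — segment length and the remaining
    straight-line distance from the far intersection to the probe — and
    the best-scoring (lowest summed mismatch) segment is appended.  With
    noise on, the choice is a Boltzmann draw over the cue scores.  Dead
    ends trigger one-step backtracking; if the search exhausts, the true
    shortest path is used as a fallback (flagged on the result).
    """
    params = params or ActivationParams(noise_on=False)
    graph, (s_node, p_node) = net.graph_with_points([start, probe])
    if s_node == p_node:
        return PlannedPath([s_node], [], 0.0, 0.0)

    w_len, w_rem = weights
    span = 100.0 * math.sqrt(2.0)
    visited = {s_node}
    path_nodes = [s_node]
    path_edges: list[tuple] = []

    def edge_percept(u, v):
        data = graph.get_edge_data(u, v)
        return SegmentPercept(u, v, data["cow_walk"], data["crow_flies"], data["segment_id"])

    while path_nodes[-1] != p_node:
        current = path_nodes[-1]
        options = []
        for nbr in graph.neighbors(current):
            if nbr in visited:
                continue
            data = graph.get_edge_data(current, nbr)
            # Mismatch cues, each scaled to [0, 1] over the display span.
            remaining = math.dist(nbr, p_node)
            score = -(w_len * data["cow_walk"] / span + w_rem * remaining / span)
            options.append((nbr, score, data["segment_id"]))
        if not options:
            # Dead end: backtrack one step; exhausted -> shortest-path fallback.
            if len(path_nodes) > 1:
                path_nodes.pop()
                path_edges.pop()
                continue
            return _fallback_path(graph, s_node, p_node, exponent, factor)
        # Deterministic: best score, ties to the lower segment id.
        if params.noise_on and params.noise_s > 0:
            if rng is None:
                raise ValueError("stochastic path planning requires an rng")
            probs = retrieval_probabilities([o[1] for o in options], params.noise_s)
            pick = options[int(rng.choice(len(options), p=probs))]
        else:
            pick = max(options, key=lambda o: (o[1], -o[2]))
        visited.add(pick[0])
        path_edges.append((current, pick[0]))
        path_nodes.append(pick[0])

    segments = [edge_percept(u, v) for u, v in path_edges]
    cog = sum(estimate_distance(s, exponent, factor) for s in segments)
    ver = sum(s.cow_walk for s in segments)
    return PlannedPath(path_nodes, segments, cog, ver)


def _fallback_path(graph, s_node, p_node, exponent, factor) -> PlannedPath:
    nodes = nx.shortest_path(graph, s_node, p_node, weight="cow_walk")
    segments = []
    for u, v in zip(nodes[:-1], nodes[1:]):
        data = graph.get_edge_data(u, v)
        segments.append(SegmentPercept(u, v, data["cow_walk"], data["crow_flies"], data["segment_id"]))
    cog = sum(estimate_distance(s, exponent, factor) for s in segments)
    return PlannedPath(list(nodes), segments, cog, sum(s.cow_walk for s in segments), fell_back=True)


def cognitive_road_distance(
    start,
    probe,
    net,
    params: ActivationParams | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Total cognitive distance of the greedily planned path."""
    return plan_path(start, probe, net, params, rng).cognitive_distance
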