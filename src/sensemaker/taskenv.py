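"""Generative simulator of the six geospatial sensemaking tasks.

The task environment lives on a 100 x 100 grid (continuous Cartesian
coordinates, origin bottom-left).  Events ("SIGACTs") are sampled from an
isotropic Gaussian window around each category's centroid; Tasks 3-6 place
events and probes on a randomly generated road network, and Tasks 4-6
reveal intelligence feature layers (SOCINT / IMINT / MOVINT / SIGINT)
whose outcomes are sampled with the odds implied by the task's likelihood
rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import substring as shapely_substring

from .bayes import FOUR_LABELS, ProbDist, apply_rule, posterior_from_events

__all__ = [
    "GRID_SIZE",
    "Category",
    "SigactEvent",
    "FeatureOutcome",
    "ResponsePoint",
    "TrialRecord",
    "RoadNetwork",
    "NetworkConfig",
    "sample_events",
    "generate_road_network",
    "emit_feature_outcome",
    "random_categories",
    "SIGINT_P_CHATTER_TRUE",
    "SIGINT_P_CHATTER_OTHER",
    "SOCINT_P_TRUE_REGION",
]

GRID_SIZE = 100.0

# Generative constants chosen so the sampled outcome frequencies reproduce
# the likelihood ratios of the feature rules exactly (7:1 for chatter,
# 1/3 for silence, 2:1 for region membership, 4:1 for IMINT/MOVINT).
SIGINT_P_CHATTER_TRUE = 0.7
SIGINT_P_CHATTER_OTHER = 0.1
SOCINT_P_TRUE_REGION = 0.4
IMINT_MOVINT_P_FAVORED = 0.8


@dataclass
class Category:
    """An event-generating category: centroid, dispersion, relative rate."""

    label: str
    centroid: tuple[float, float]
    dispersion: float
    frequency: float = 1.0

    def __post_init__(self) -> None:
        x, y = self.centroid
        if not (0 <= x <= GRID_SIZE and 0 <= y <= GRID_SIZE):
            raise ValueError("centroid outside the grid")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass
class SigactEvent:
    """One displayed event; probe events have ``category=None``."""

    location: tuple[float, float]
    category: Optional[str]
    trial_index: int = 0
    order_index: int = 0


@dataclass
class FeatureOutcome:
    """Outcome of revealing one intelligence layer.

    ``value`` is layer-specific (IMINT: government|military, MOVINT:
    dense|sparse, SIGINT: chatter|silence, SOCINT: region label);
    SIGINT additionally carries the inspected ``category``.
    """

    layer: str
    value: Any
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.layer == "SIGINT" and self.category is None:
            raise ValueError("SIGINT outcome must carry the inspected category")


@dataclass
class ResponsePoint:
    """A single probability response: the stage label plus both dists."""

    stage: str
    agent: ProbDist
    normative: ProbDist


@dataclass
class TrialRecord:
    task_id: int
    trial_index: int
    ground_truth: str
    responses: list[ResponsePoint] = field(default_factory=list)
    allocation: Optional[np.ndarray] = None
    labels: tuple[str, ...] = FOUR_LABELS
    score: Optional[float] = None
    layer_sequence: list[str] = field(default_factory=list)

    def final_agent(self) -> ProbDist:
        return self.responses[-1].agent

    def final_normative(self) -> ProbDist:
        return self.responses[-1].normative


def sample_events(
    cat: Category,
    n: int,
    rng: np.random.Generator,
    network: "RoadNetwork | None" = None,
    trial_index: int = 0,
) -> list[SigactEvent]:
    """Sample ``n`` events in a Gaussian window around the centroid.

    Samples falling outside the grid are rejection-resampled; with a road
    network each sample is snapped to the nearest on-road point.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    events = []
    for k in range(n):
        while True:
            xy = rng.normal(cat.centroid, cat.dispersion, size=2)
            if 0 <= xy[0] <= GRID_SIZE and 0 <= xy[1] <= GRID_SIZE:
                break
        loc = (float(xy[0]), float(xy[1]))
        if network is not None:
            loc = network.snap(loc)
        events.append(SigactEvent(loc, cat.label, trial_index, k))
    return events


def emit_feature_outcome(
    layer: str,
    ground_truth: str,
    rng: np.random.Generator,
    inspected: Optional[str] = None,
    labels: Sequence[str] = FOUR_LABELS,
) -> FeatureOutcome:
    """Sample one feature outcome given the ground-truth category.

    The generative direction of the likelihood rules: e.g. a government
    building is 4x more likely under categories A/B, so
    P(government | truth in {A,B}) = 4/5.  HUMINT has no sampled outcome
    (its evidence is the distance geometry itself).
    """
    p = IMINT_MOVINT_P_FAVORED
    if layer == "IMINT":
        p_gov = p if ground_truth in ("A", "B") else 1 - p
        return FeatureOutcome("IMINT", "government" if rng.random() < p_gov else "military")
    if layer == "MOVINT":
        p_dense = p if ground_truth in ("A", "C") else 1 - p
        return FeatureOutcome("MOVINT", "dense" if rng.random() < p_dense else "sparse")
    if layer == "SIGINT":
        if inspected is None:
            raise ValueError("SIGINT requires an inspected category")
        p_chat = SIGINT_P_CHATTER_TRUE if inspected == ground_truth else SIGINT_P_CHATTER_OTHER
        return FeatureOutcome("SIGINT", "chatter" if rng.random() < p_chat else "silence", inspected)
    if layer == "SOCINT":
        if rng.random() < SOCINT_P_TRUE_REGION:
            region = ground_truth
        else:
            others = [lbl for lbl in labels if lbl != ground_truth]
            region = others[int(rng.integers(len(others)))]
        return FeatureOutcome("SOCINT", region)
    raise ValueError(f"unknown layer {layer!r}")


# ---------------------------------------------------------------------------
# Road networks
# ---------------------------------------------------------------------------

_COORD_DECIMALS = 6


def _node(pt: Sequence[float]) -> tuple[float, float]:
    return (round(float(pt[0]), _COORD_DECIMALS), round(float(pt[1]), _COORD_DECIMALS))


@dataclass
class NetworkConfig:
    """Parameters of the perturbed-grid road generator."""

    n_horizontal: int = 3
    n_vertical: int = 3
    waypoint_spacing: float = 25.0
    jitter: float = 5.0

    def __post_init__(self) -> None:
        if self.n_horizontal + self.n_vertical < 2:
            raise ValueError("at least two roads are required")


class RoadNetwork:
    """Polyline roads spanning the grid, parsed into an intersection graph.

    Nodes are intersections and road endpoints; each edge is a road segment
    between two adjacent nodes carrying its polyline geometry, veridical
    curve length (``cow_walk``) and straight endpoint distance
    (``crow_flies``).
    """

    def __init__(self, roads: Sequence[LineString | Sequence[tuple[float, float]]]):
        self.roads: list[LineString] = [
            r if isinstance(r, LineString) else LineString(r) for r in roads
        ]
        if len(self.roads) < 2:
            raise ValueError("a network needs at least two roads")
        self.graph = self._build_graph()

    def _build_graph(self) -> nx.Graph:
        # Split each road at every point where another road crosses it.
        cuts: list[list[float]] = [[0.0, r.length] for r in self.roads]
        for i, ri in enumerate(self.roads):
            for j in range(i + 1, len(self.roads)):
                inter = ri.intersection(self.roads[j])
                if inter.is_empty:
                    continue
                pts = []
                if inter.geom_type == "Point":
                    pts = [inter]
                elif inter.geom_type == "MultiPoint":
                    pts = list(inter.geoms)
                else:  # collinear overlap: use boundary points
                    pts = [Point(c) for c in inter.coords] if hasattr(inter, "coords") else []
                for p in pts:
                    cuts[i].append(ri.project(p))
                    cuts[j].append(self.roads[j].project(p))
        g = nx.Graph()
        seg_id = 0
        for road_idx, road in enumerate(self.roads):
            offsets = sorted(set(round(c, _COORD_DECIMALS) for c in cuts[road_idx]))
            for a, b in zip(offsets[:-1], offsets[1:]):
                geom = _substring(road, a, b)
                u = _node(geom.coords[0])
                v = _node(geom.coords[-1])
                if u == v:
                    continue
                crow = min(math.dist(u, v), geom.length)
                g.add_edge(
                    u,
                    v,
                    geometry=geom,
                    cow_walk=geom.length,
                    crow_flies=crow,
                    segment_id=seg_id,
                    road=road_idx,
                )
                seg_id += 1
        return g

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def snap(self, xy: Sequence[float]) -> tuple[float, float]:
        """Nearest on-road point to ``xy``."""
        p = Point(xy)
        best, best_d = None, math.inf
        for road in self.roads:
            q = road.interpolate(road.project(p))
            d = p.distance(q)
            if d < best_d:
                best, best_d = q, d
        return (float(best.x), float(best.y))

    def graph_with_points(self, points: Sequence[Sequence[float]]):
        """Copy of the graph with each (snapped) point inserted as a node.

        Returns ``(graph, node_ids)``; a point already coinciding with a
        node reuses it, otherwise its segment is split in two.
        """
        g = self.graph.copy()
        ids = []
        for xy in points:
            snapped = Point(self.snap(xy))
            nid = _node((snapped.x, snapped.y))
            if nid in g:
                ids.append(nid)
                continue
            # Find the edge whose geometry contains the snapped point.
            best = None
            best_d = math.inf
            for u, v, data in g.edges(data=True):
                d = data["geometry"].distance(snapped)
                if d < best_d:
                    best, best_d = (u, v, data), d
            u, v, data = best
            geom = data["geometry"]
            off = geom.project(snapped)
            g.remove_edge(u, v)
            for (a, b, sub) in (
                (u, nid, _substring(geom, 0.0, off)),
                (nid, v, _substring(geom, off, geom.length)),
            ):
                if a == b:
                    continue
                g.add_edge(
                    a,
                    b,
                    geometry=sub,
                    cow_walk=sub.length,
                    crow_flies=min(math.dist(a, b), sub.length),
                    segment_id=data["segment_id"],
                    road=data["road"],
                )
            ids.append(nid)
        return g, ids

    def road_distance(self, p: Sequence[float], q: Sequence[float]) -> float:
        """Veridical shortest-path distance along roads between two points."""
        g, (u, v) = self.graph_with_points([p, q])
        return float(nx.shortest_path_length(g, u, v, weight="cow_walk"))


def _substring(line: LineString, start: float, end: float) -> LineString:
    """Portion of ``line`` between two arc-length offsets."""
    if end < start:
        start, end = end, start
    return shapely_substring(line, start, end)


def generate_road_network(
    config: NetworkConfig,
    rng: np.random.Generator,
    max_tries: int = 20,
) -> RoadNetwork:
    """Random perturbed grid of polyline roads spanning the display.

    Horizontal and vertical roads with jittered waypoints; every pair of
    cross roads intersects generically, and a disconnected draw is
    regenerated internally, never returned.
    """
    for _ in range(max_tries):
        roads = []
        n_h, n_v = config.n_horizontal, config.n_vertical
        h_levels = np.sort(rng.uniform(5, GRID_SIZE - 5, size=n_h))
        v_levels = np.sort(rng.uniform(5, GRID_SIZE - 5, size=n_v))
        xs = np.arange(0, GRID_SIZE + 1e-9, config.waypoint_spacing)
        for y0 in h_levels:
            ys = np.clip(y0 + rng.normal(0, config.jitter, size=len(xs)), 0, GRID_SIZE)
            roads.append(LineString(list(zip(xs, ys))))
        for x0 in v_levels:
            xv = np.clip(x0 + rng.normal(0, config.jitter, size=len(xs)), 0, GRID_SIZE)
            roads.append(LineString(list(zip(xv, xs))))
        net = RoadNetwork(roads)
        if net.is_connected:
            return net
    raise RuntimeError("failed to generate a connected road network")


# ---------------------------------------------------------------------------
# Trial flow
# ---------------------------------------------------------------------------

_LAYER_MENU = ("SOCINT", "IMINT", "MOVINT", "SIGINT")
TASK_SCHEDULE = {
    1: {"trials": 10, "events": 9, "labels": ("A", "B")},
    2: {"trials": 5, "events": 19, "labels": FOUR_LABELS},
    3: {"trials": 5, "events": 19, "labels": FOUR_LABELS},
    4: {"trials": 10, "labels": FOUR_LABELS},
    5: {"trials": 10, "labels": FOUR_LABELS},
    6: {"trials": 10, "labels": FOUR_LABELS},
}


@dataclass
class TaskState:
    """Mutable per-task environment state (categories persist across the
    trials of Tasks 1-3; Tasks 4-6 redraw everything each trial)."""

    task_id: int
    labels: tuple[str, ...]
    categories: list[Category] = field(default_factory=list)
    network: Optional["RoadNetwork"] = None
    events: list[SigactEvent] = field(default_factory=list)
    trial: int = 0
    humint_dispersion: float = 10.0


def new_task_state(
    task_id: int,
    rng: np.random.Generator,
    network_config: NetworkConfig | None = None,
    humint_dispersion: float = 10.0,
) -> TaskState:
    """Draw the stimulus parameters for one task run."""
    sched = TASK_SCHEDULE[task_id]
    labels = sched["labels"]
    state = TaskState(task_id, labels, humint_dispersion=humint_dispersion)
    if task_id <= 3:
        state.categories = random_categories(rng, labels)
        if task_id == 3:
            state.network = generate_road_network(network_config or NetworkConfig(), rng)
    return state


def _frequency_weights(categories: Sequence[Category]) -> np.ndarray:
    w = np.array([c.frequency for c in categories], dtype=float)
    return w / w.sum()


def run_trial(
    task_id: int,
    agent,
    state: TaskState,
    rng: np.random.Generator,
    network_config: NetworkConfig | None = None,
) -> TrialRecord:
    """Run one trial: stimuli, agent and normative responses, feedback.

    Tasks 1-3: a batch of labeled events plus an unlabeled probe; the
    agent responds with a category distribution (one response point) and
    a forced-choice allocation.  Tasks 4-6: a fresh road network with
    given centroids, a HUMINT response, then feature layers (fixed,
    random-order, or agent-chosen), and a free resource allocation.
    Feedback is the resource-allocation score only.
    """
    if task_id <= 3:
        return _run_events_trial(task_id, agent, state, rng)
    return _run_layers_trial(task_id, agent, state, rng, network_config)


def _run_events_trial(task_id, agent, state, rng) -> TrialRecord:
    sched = TASK_SCHEDULE[task_id]
    cats = state.categories
    freqs = _frequency_weights(cats)
    counts = rng.multinomial(sched["events"], freqs)
    if state.trial == 0:
        # First trial: every category is shown at least once so a centroid
        # can be formed for each.
        counts = np.ones(len(cats), dtype=int) + rng.multinomial(
            sched["events"] - len(cats), freqs
        )
    new_events = []
    for cat, k in zip(cats, counts):
        new_events.extend(sample_events(cat, int(k), rng, state.network, state.trial))
    agent.observe_events(new_events)
    state.events.extend(new_events)

    truth_cat = cats[int(rng.choice(len(cats), p=freqs))]
    probe_loc = sample_events(truth_cat, 1, rng, state.network, state.trial)[0].location
    state.events.append(SigactEvent(probe_loc, None, state.trial, sched["events"]))

    agent_dist = agent.distribution_from_events(
        probe_loc, state.labels, state.trial, state.network
    )
    mode = "road" if state.network is not None else "euclidean"
    normative = posterior_from_events(probe_loc, cats, mode, state.network)

    decision = agent.allocate(agent_dist, forced_choice=True)
    score = agent.learn_outcome(agent_dist, decision, truth_cat.label, forced_choice=True)

    rec = TrialRecord(
        task_id, state.trial, truth_cat.label,
        responses=[ResponsePoint("events", agent_dist, normative)],
        allocation=decision.allocation, labels=state.labels, score=score,
    )
    state.trial += 1
    return rec


def _run_layers_trial(task_id, agent, state, rng, network_config) -> TrialRecord:
    labels = state.labels
    network = generate_road_network(network_config or NetworkConfig(), rng)
    sigma = state.humint_dispersion
    centroids: dict[str, tuple[float, float]] = {}
    cats = []
    for lbl in labels:
        raw = rng.uniform(10.0, GRID_SIZE - 10.0, size=2)
        c = network.snap(raw)
        centroids[lbl] = c
        cats.append(Category(lbl, c, sigma, 1.0))
    truth = labels[int(rng.integers(len(labels)))]
    probe = network.snap(np.asarray(centroids[truth]) + rng.normal(0.0, sigma, size=2))

    normative = posterior_from_events(probe, cats, "road", network)
    rec = TrialRecord(task_id, state.trial, truth, labels=labels)

    if task_id == 4:
        agent_dist = agent.humint_distribution(centroids, probe, network)
        layer_plan = ["SOCINT"]
    else:
        # The correct HUMINT distribution is provided to the agent.
        agent_dist = ProbDist(np.array(normative.probs), labels)
        if task_id == 5:
            layer_plan = list(rng.permutation(_LAYER_MENU))
        else:
            layer_plan = None  # agent chooses 3 of 4
    rec.responses.append(ResponsePoint("HUMINT", agent_dist, normative))

    if task_id in (4, 5):
        for layer in layer_plan:
            inspected = labels[int(rng.integers(len(labels)))] if layer == "SIGINT" else None
            outcome = emit_feature_outcome(layer, truth, rng, inspected, labels)
            situation = agent_dist
            agent_dist = agent.update(agent_dist, outcome)
            normative = apply_rule(normative, outcome)
            rec.responses.append(ResponsePoint(layer, agent_dist, normative))
            agent.experience_layer(situation, layer, agent_dist)
            rec.layer_sequence.append(layer)
    else:
        available = list(_LAYER_MENU)
        for _ in range(3):
            layer, inspected = agent.choose_layer(agent_dist, available)
            outcome = emit_feature_outcome(layer, truth, rng, inspected, labels)
            situation = agent_dist
            agent_dist = agent.update(agent_dist, outcome)
            normative = apply_rule(normative, outcome)
            rec.responses.append(ResponsePoint(layer, agent_dist, normative))
            agent.experience_layer(situation, layer, agent_dist)
            rec.layer_sequence.append(layer)
            available.remove(layer)

    decision = agent.allocate(agent_dist)
    score = agent.learn_outcome(agent_dist, decision, truth)
    rec.allocation = decision.allocation
    rec.score = score
    state.trial += 1
    return rec


def random_categories(
    rng: np.random.Generator,
    labels: Sequence[str] = FOUR_LABELS,
    margin: float = 15.0,
    dispersion_range: tuple[float, float] = (5.0, 15.0),
    frequency_choices: Sequence[float] = (1.0, 2.0),
) -> list[Category]:
    """Draw category parameters for one task run.

    Centroids uniform inside the grid margin, dispersions uniform in
    [5, 15] grid units, frequencies drawn from small-integer ratios so the
    frequency/distance trade-off of the stimuli is present.
    """
    cats = []
    for lbl in labels:
        centroid = tuple(rng.uniform(margin, GRID_SIZE - margin, size=2))
        disp = float(rng.uniform(*dispersion_range))
        freq = float(frequency_choices[int(rng.integers(len(frequency_choices)))])
        cats.append(Category(lbl, centroid, disp, freq))
    return cats
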