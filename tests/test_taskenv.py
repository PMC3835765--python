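"""Tests of the stimulus generators and trial flow."""

import math

import numpy as np
import pytest

from sensemaker.agent import Agent, AgentConfig
from sensemaker.taskenv import (
    Category,
    NetworkConfig,
    SIGINT_P_CHATTER_TRUE,
    emit_feature_outcome,
    generate_road_network,
    new_task_state,
    run_trial,
    sample_events,
)


class TestSampleEvents:
    def test_degenerate_dispersion_collapses_to_centroid(self, rng):
        cat = Category("A", (30.0, 70.0), 1e-9)
        evs = sample_events(cat, 5, rng)
        for ev in evs:
            assert ev.location == pytest.approx((30.0, 70.0), abs=1e-6)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            Category("A", (50.0, 50.0), 0.0)

    def test_sample_mean_matches_centroid(self, rng):
        cat = Category("A", (50.0, 50.0), 10.0)
        locs = np.array([e.location for e in sample_events(cat, 10000, rng)])
        # CLT bound: the mean of 10k draws sits within 0.5 of the centroid.
        assert np.allclose(locs.mean(axis=0), (50.0, 50.0), atol=0.5)

    def test_events_stay_on_grid(self, rng):
        cat = Category("A", (2.0, 2.0), 20.0)
        locs = np.array([e.location for e in sample_events(cat, 500, rng)])
        assert (locs >= 0).all() and (locs <= 100).all()

    def test_road_variant_snaps_to_roads(self, rng, cross_roads):
        cat = Category("A", (40.0, 60.0), 15.0)
        for ev in sample_events(cat, 50, rng, network=cross_roads):
            x, y = ev.location
            assert min(abs(y - 50.0), abs(x - 50.0)) < 1e-6


class TestRoadNetwork:
    def test_cross_roads_structure(self, cross_roads):
        g = cross_roads.graph
        assert g.degree[(50.0, 50.0)] == 4
        assert g.number_of_edges() == 4

    def test_l_road_polyline_length(self, l_network):
        assert l_network.roads[0].length == pytest.approx(100.0)

    def test_generated_networks_connected(self, rng):
        for _ in range(5):
            net = generate_road_network(NetworkConfig(), rng)
            assert net.is_connected

    def test_road_distance_cross(self, cross_roads):
        # (10,50) -> (50,90): 40 along each arm through the intersection.
        assert cross_roads.road_distance((10.0, 50.0), (50.0, 90.0)) == pytest.approx(80.0)


class TestFeatureOutcomes:
    N = 30000

    @pytest.mark.parametrize(
        "layer,truth,value,expected",
        [
            ("IMINT", "A", "government", 0.8),
            ("MOVINT", "D", "sparse", 0.8),
            ("SOCINT", "B", "B", 0.4),
        ],
    )
    def test_generative_frequencies(self, rng, layer, truth, value, expected):
        hits = sum(
            emit_feature_outcome(layer, truth, rng).value == value for _ in range(self.N)
        )
        tol = 3 * math.sqrt(self.N * expected * (1 - expected))
        assert abs(hits - expected * self.N) < tol

    def test_sigint_chatter_rate_on_truth(self, rng):
        hits = sum(
            emit_feature_outcome("SIGINT", "A", rng, inspected="A").value == "chatter"
            for _ in range(self.N)
        )
        p = SIGINT_P_CHATTER_TRUE
        assert abs(hits - p * self.N) < 3 * math.sqrt(self.N * p * (1 - p))

    def test_sigint_requires_inspected(self, rng):
        with pytest.raises(ValueError):
            emit_feature_outcome("SIGINT", "A", rng)

    def test_unknown_layer(self, rng):
        with pytest.raises(ValueError):
            emit_feature_outcome("HUMINT", "A", rng)


def _agent(rng_seed=0, **kw):
    return Agent(AgentConfig(**kw), np.random.default_rng(rng_seed))


class TestTrialFlow:
    def test_task1_accumulates_100_events(self, rng):
        agent = _agent()
        state = new_task_state(1, rng)
        for _ in range(10):
            run_trial(1, agent, state, rng)
        # 10 trials x (9 labeled + probe) on the display at the end.
        assert len(state.events) == 100
        assert agent.event_count("A") + agent.event_count("B") == 90

    def test_event_accumulation_is_monotone(self, rng):
        agent = _agent()
        state = new_task_state(1, rng)
        sizes = []
        for _ in range(4):
            run_trial(1, agent, state, rng)
            sizes.append(len(state.events))
        assert sizes == sorted(sizes)

    def test_forced_choice_scores_all_or_nothing(self, rng):
        agent = _agent()
        state = new_task_state(1, rng)
        recs = [run_trial(1, agent, state, rng) for _ in range(10)]
        for rec in recs:
            truth_idx = rec.labels.index(rec.ground_truth)
            assert sorted(rec.allocation) == [0, 100]
            assert rec.score == rec.allocation[truth_idx]
            assert rec.score in (0.0, 100.0)

    def test_responses_are_normalized(self, rng):
        agent = _agent()
        state = new_task_state(2, rng)
        rec = run_trial(2, agent, state, rng)
        for rp in rec.responses:
            assert rp.agent.probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert rp.normative.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_task5_has_four_post_humint_updates(self, rng):
        agent = _agent()
        state = new_task_state(5, rng)
        rec = run_trial(5, agent, state, rng)
        assert len(rec.responses) == 5  # HUMINT + 4 feature updates
        assert rec.responses[0].stage == "HUMINT"
        assert sorted(rec.layer_sequence) == ["IMINT", "MOVINT", "SIGINT", "SOCINT"]

    def test_task6_chooses_exactly_three_layers(self, rng):
        agent = _agent()
        state = new_task_state(6, rng)
        rec = run_trial(6, agent, state, rng)
        assert len(rec.layer_sequence) == 3
        assert len(set(rec.layer_sequence)) == 3
        assert len(rec.responses) == 4

    def test_allocation_sums_to_100(self, rng):
        agent = _agent()
        state = new_task_state(4, rng)
        for _ in range(5):
            rec = run_trial(4, agent, state, rng)
            assert rec.allocation.sum() == 100
            assert (rec.allocation >= 0).all()
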