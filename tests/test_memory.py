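"""Unit and property tests of the declarative-memory kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensemaker.memory import (
    ActivationParams,
    BlendRequest,
    Chunk,
    RetrievalFailure,
    UtilityState,
    activation,
    blend,
    retrieval_probabilities,
    retrieve,
    similarity_linear,
    similarity_ratio,
    utility_update,
)

GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 10))


def _req(target, grid=GRID):
    return BlendRequest(
        constraints={"value": (target, similarity_linear)},
        value_slot="value",
        value_similarity=similarity_linear,
        candidate_grid=grid,
    )


class TestActivation:
    def test_perfect_match_with_one_source(self, quiet):
        # ln(1) + (S - ln 1) + 0 = 4 with a single full-weight source.
        c = Chunk({"value": 0.5})
        req = BlendRequest({"value": (0.5, similarity_linear)}, "value", similarity_linear)
        a = activation(c, req, quiet, sources=[(1.0, 1)])
        assert a == pytest.approx(4.0)

    def test_one_mismatching_slot(self, quiet):
        # P * M = 2 * (-0.2) with no spreading and a single presentation.
        c = Chunk({"value": 0.7})
        req = BlendRequest({"value": (0.5, similarity_linear)}, "value", similarity_linear)
        assert activation(c, req, quiet) == pytest.approx(2.0 * -0.2)

    def test_base_level_is_log_presentations(self, quiet):
        c = Chunk({"value": 0.0}, n=math.e)
        assert activation(c, None, quiet) == pytest.approx(1.0)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError):
            activation(Chunk({"v": 1}), None, ActivationParams())


class TestRetrieve:
    def test_equal_activation_split(self, rng):
        chunks = [Chunk({"v": 0}), Chunk({"v": 1})]
        params = ActivationParams(noise_s=1.0)
        picks = sum(retrieve(chunks, params, rng).slots["v"] for _ in range(4000))
        # Symmetric case: each chunk retrieved with prob 1/2 (3 sigma band).
        assert abs(picks - 2000) < 3 * math.sqrt(4000 * 0.25)

    def test_softmax_closed_form(self, rng):
        # Activations {0, ln 3} at s=1 give probabilities {0.25, 0.75}.
        chunks = [Chunk({"v": 0}, n=1), Chunk({"v": 1}, n=3)]
        params = ActivationParams(noise_s=1.0)
        n = 20000
        picks = sum(retrieve(chunks, params, rng).slots["v"] for _ in range(n))
        assert abs(picks - 0.75 * n) < 3 * math.sqrt(n * 0.75 * 0.25)

    def test_zero_temperature_argmax(self, rng):
        chunks = [Chunk({"v": 0}, n=1), Chunk({"v": 1}, n=3)]
        params = ActivationParams(noise_on=False)
        assert all(retrieve(chunks, params, rng).slots["v"] == 1 for _ in range(10))

    def test_empty_candidates_fail(self, rng):
        with pytest.raises(RetrievalFailure):
            retrieve([], ActivationParams(), rng)


class TestBlend:
    def test_single_chunk_identity(self, quiet):
        assert blend([Chunk({"value": 0.6})], _req(0.6), quiet) == pytest.approx(0.6)

    def test_equal_probability_mean(self, quiet):
        # Minimizing sum (v - v_i)^2 with equal weights gives the midpoint.
        chunks = [Chunk({"value": 0.2}), Chunk({"value": 0.4})]
        req = BlendRequest({}, "value", similarity_linear, GRID)
        assert blend(chunks, req, quiet) == pytest.approx(0.3)

    def test_weighted_mean(self, quiet):
        # Retrieval odds 3:1 (base level ln 3 vs 0 at s=0.25 would be 81:1;
        # use s=1 to hit exactly {0.75, 0.25}) -> 0.75*0.2 + 0.25*0.4.
        params = ActivationParams(noise_on=False, noise_s=1.0)
        chunks = [Chunk({"value": 0.2}, n=3), Chunk({"value": 0.4}, n=1)]
        req = BlendRequest({}, "value", similarity_linear, GRID)
        assert blend(chunks, req, params) == pytest.approx(0.25)

    def test_no_match_raises(self, quiet):
        req = BlendRequest({"kind": ("x", None)}, "value", similarity_linear, GRID)
        with pytest.raises(RetrievalFailure):
            blend([Chunk({"kind": "y", "value": 1.0})], req, quiet)

    @settings(deadline=None, max_examples=40)
    @given(values=st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_blend_in_convex_hull(self, values):
        params = ActivationParams(noise_on=False)
        chunks = [Chunk({"value": round(v, 6)}) for v in values]
        req = BlendRequest({}, "value", similarity_linear, GRID)
        out = blend(chunks, req, params)
        assert min(c.slots["value"] for c in chunks) - 1e-9 <= out
        assert out <= max(c.slots["value"] for c in chunks) + 1e-9

    @settings(deadline=None, max_examples=40)
    @given(ns=st.lists(st.integers(1, 9), min_size=1, max_size=6))
    def test_retrieval_probabilities_normalize(self, ns):
        probs = retrieval_probabilities([math.log(n) for n in ns], 0.25)
        assert probs.sum() == pytest.approx(1.0)
        assert (probs >= 0).all()


class TestSimilarity:
    @pytest.mark.parametrize("sim", [similarity_linear, similarity_ratio])
    def test_identity(self, sim):
        assert sim(0.3, 0.3) == 0.0

    def test_linear_extremes(self):
        assert similarity_linear(0.0, 1.0) == -1.0

    def test_ratio_magnifies_near_zero(self):
        # Ratio mismatch dwarfs linear mismatch for small magnitudes.
        assert similarity_ratio(0.01, 0.02) == pytest.approx(-0.5)
        assert similarity_linear(0.01, 0.02) == pytest.approx(-0.01)
        assert similarity_ratio(0.01, 0.02) < similarity_linear(0.01, 0.02)

    def test_ratio_rejects_negatives(self):
        with pytest.raises(ValueError):
            similarity_ratio(-0.1, 0.2)


class TestUtility:
    def test_delta_rule_step(self):
        s = utility_update(UtilityState(alpha=0.2), "go", 1.0)
        assert s.utilities["go"] == pytest.approx(0.2)

    def test_fixed_point(self):
        s = UtilityState(alpha=0.2, utilities={"go": 0.7})
        utility_update(s, "go", 0.7)
        assert s.utilities["go"] == pytest.approx(0.7)

    def test_geometric_convergence(self):
        # After 20 updates toward R=10: U = 10 * (1 - 0.8^20).
        s = UtilityState(alpha=0.2)
        for _ in range(20):
            utility_update(s, "go", 10.0)
        assert s.utilities["go"] == pytest.approx(10.0 * (1 - 0.8**20))
        assert abs(s.utilities["go"] - 10.0) < 0.2

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            UtilityState(alpha=0.0)


class TestChunkStore:
    def test_identical_slots_merge_as_presentations(self):
        from sensemaker.memory import ChunkStore

        store = ChunkStore()
        store.add({"a": 1.0})
        store.add({"a": 1.0})
        store.add({"a": 2.0})
        assert len(store) == 2
        assert store.filter(a=1.0)[0].n == 2

    def test_jsonl_round_trip(self, tmp_path):
        from sensemaker.memory import ChunkStore

        store = ChunkStore()
        store.add({"prior": 0.25, "factor": 2.0, "posterior": 0.4})
        store.add({"prior": 0.25, "factor": 2.0, "posterior": 0.4})
        path = tmp_path / "chunks.jsonl"
        store.to_jsonl(path)
        again = ChunkStore.from_jsonl(path)
        assert len(again) == len(store)
        assert again.chunks[0].slots == store.chunks[0].slots
        assert again.chunks[0].n == 2
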