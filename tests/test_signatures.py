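"""signatures: median-split schema construction and signature extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoemd import (
    BinningSchema,
    EventMatrix,
    Signature,
    apply_schema,
    build_schema,
    compute_signature,
)
from cytoemd.errors import DegenerateInputError, NormalizationError, SchemaError
from cytoemd.signatures import assign_bins


class TestBuildSchema:
    def test_splits_on_max_variance_dimension(self, small_events):
        # variances: dim 0 is constant (0), dim 1 has sample variance 500/3
        schema = build_schema(small_events, stop_threshold=2)
        assert schema.root.split_dim == 1
        assert schema.n_leaves == 2
        # lower-median convention: sorted dim-1 values [0,10,20,30] -> 10
        assert schema.root.split_value == 10.0
        counts = apply_schema(small_events, schema)
        np.testing.assert_array_equal(counts, [2, 2])

    def test_zero_variance_sample_is_single_leaf(self):
        events = EventMatrix(np.full((8, 1), 3.0), ("x",))
        schema = build_schema(events, stop_threshold=2)
        assert schema.n_leaves == 1
        assert schema.degenerate

    def test_single_event_errors(self):
        with pytest.raises(DegenerateInputError):
            build_schema(EventMatrix(np.zeros((1, 1)), ("x",)), 2)

    def test_auto_threshold_enforces_min_occupancy(self, rng):
        n = 1000
        events = EventMatrix(rng.normal(size=(n, 2)), ("a", "b"))
        schema = build_schema(events, "auto")
        assert schema.stop_threshold == pytest.approx(2 * math.log(n))
        counts = apply_schema(events, schema)
        assert counts.min() >= math.ceil(2 * math.log(n))  # = 14

    def test_variance_tie_prefers_lowest_dimension(self):
        values = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        schema = build_schema(EventMatrix(values, ("a", "b")), 2)
        assert schema.root.split_dim == 0

    def test_bad_threshold(self, small_events):
        with pytest.raises(DegenerateInputError):
            build_schema(small_events, stop_threshold=-1)


class TestApplySchema:
    def test_counts_sum_to_n(self, rng):
        build = EventMatrix(rng.normal(size=(512, 3)), ("a", "b", "c"))
        other = EventMatrix(rng.normal(0.5, 1.2, size=(777, 3)), ("a", "b", "c"))
        schema = build_schema(build, 16)
        assert apply_schema(other, schema).sum() == 777

    def test_single_event_hits_one_leaf(self, rng):
        build = EventMatrix(rng.normal(size=(256, 2)), ("a", "b"))
        schema = build_schema(build, 16)
        counts = apply_schema(EventMatrix(np.zeros((1, 2)), ("a", "b")), schema)
        assert counts.sum() == 1
        assert (counts > 0).sum() == 1

    def test_shifted_sample_unbalances_counts(self, rng):
        build = EventMatrix(rng.normal(size=(1024, 1)), ("x",))
        schema = build_schema(build, 64)
        shifted = EventMatrix(build.values + 1.5, ("x",))
        counts = apply_schema(shifted, schema)
        equal = 1024 / schema.n_leaves
        assert counts.max() > 2 * equal

    def test_routing_matches_bruteforce_path_following(self, rng):
        build = EventMatrix(rng.normal(size=(128, 2)), ("a", "b"))
        schema = build_schema(build, 8)
        probe = EventMatrix(rng.normal(size=(64, 2)), ("a", "b"))
        labels = assign_bins(probe, schema)

        def walk(row):
            node = schema.root
            while not node.is_leaf:
                node = node.left if row[node.split_dim] <= node.split_value else node.right
            return node.leaf_id

        expected = [walk(row) for row in probe.values]
        np.testing.assert_array_equal(labels, expected)

    def test_dimension_mismatch(self, rng):
        build = EventMatrix(rng.normal(size=(64, 2)), ("a", "b"))
        schema = build_schema(build, 8)
        with pytest.raises(SchemaError):
            apply_schema(EventMatrix(np.zeros((5, 1)), ("a",)), schema)

    def test_equal_occupancy_within_depth(self, rng):
        """Leaf counts on the building sample differ by <= 1 per split level."""
        events = EventMatrix(rng.normal(size=(1000, 2)), ("a", "b"))
        schema = build_schema(events, "auto")
        counts = apply_schema(events, schema)
        max_depth = schema.leaf_depths().max()
        assert counts.max() - counts.min() <= max_depth


class TestComputeSignature:
    def test_two_point_masses(self):
        events = EventMatrix(np.array([[0.0], [0.0], [10.0], [10.0]]), ("x",))
        sig = compute_signature(events, "auto", stop_threshold=2)
        np.testing.assert_allclose(sorted(sig.centroids.ravel()), [0.0, 10.0])
        np.testing.assert_allclose(sig.weights, [0.5, 0.5])

    def test_single_leaf_grand_mean(self):
        events = EventMatrix(np.full((8, 2), 2.5), ("a", "b"))
        sig = compute_signature(events, "auto")
        assert sig.n_bins == 1
        np.testing.assert_allclose(sig.centroids, [[2.5, 2.5]])
        np.testing.assert_allclose(sig.weights, [1.0])

    def test_weights_normalized_and_empty_leaves_dropped(self, rng):
        build = EventMatrix(rng.normal(size=(512, 1)), ("x",))
        schema = build_schema(build, 16)
        # far-shifted sample occupies only a few control bins
        probe = EventMatrix(build.values + 10.0, ("x",))
        sig = compute_signature(probe, schema)
        assert sig.n_bins < schema.n_leaves
        assert sig.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(sig.weights > 0)

    def test_permutation_invariance(self, rng):
        values = rng.normal(size=(400, 2))
        a = compute_signature(EventMatrix(values, ("a", "b")), "auto")
        perm = rng.permutation(400)
        b = compute_signature(EventMatrix(values[perm], ("a", "b")), "auto")
        order_a = np.lexsort(a.centroids.T)
        order_b = np.lexsort(b.centroids.T)
        np.testing.assert_allclose(a.centroids[order_a], b.centroids[order_b])
        np.testing.assert_allclose(a.weights[order_a], b.weights[order_b])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_refinement_keeps_centroids_inside_parent_box(self, seed):
        """Halving the stop threshold refines bins without moving mass outside."""
        rng = np.random.default_rng(seed)
        events = EventMatrix(rng.normal(size=(256, 2)), ("a", "b"))
        coarse = compute_signature(events, "auto", stop_threshold=64)
        fine = compute_signature(events, "auto", stop_threshold=32)
        assert coarse.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert fine.weights.sum() == pytest.approx(1.0, abs=1e-12)
        lo, hi = events.values.min(axis=0), events.values.max(axis=0)
        for sig in (coarse, fine):
            assert np.all(sig.centroids >= lo) and np.all(sig.centroids <= hi)


class TestSerialization:
    def test_schema_json_roundtrip_preserves_routing(self, rng):
        events = EventMatrix(rng.normal(size=(300, 2)), ("a", "b"))
        schema = build_schema(events, 16)
        back = BinningSchema.from_json(schema.to_json())
        np.testing.assert_array_equal(
            apply_schema(events, schema), apply_schema(events, back)
        )

    def test_signature_json_roundtrip(self, rng):
        events = EventMatrix(rng.normal(size=(200, 2)), ("a", "b"))
        sig = compute_signature(events, "auto")
        back = Signature.from_json(sig.to_json())
        np.testing.assert_allclose(back.centroids, sig.centroids)
        np.testing.assert_allclose(back.weights, sig.weights)

    def test_signature_validation(self):
        with pytest.raises(NormalizationError):
            Signature(np.zeros((2, 1)), np.array([0.7, 0.7]))
        with pytest.raises(NormalizationError):
            Signature(np.zeros((2, 1)), np.array([1.5, -0.5]))
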