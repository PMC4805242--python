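"""flow_io: parsing, transforms, gating."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoemd import (
    EventMatrix,
    LogicleParams,
    RectGate,
    gate,
    read_events,
    transform,
    write_events,
)
from cytoemd.errors import (
    ChannelMismatchError,
    DegenerateInputError,
    ParameterError,
)
from cytoemd.flow_io import asinh_transform, logicle_inverse, logicle_transform

from conftest import write_fcs


class TestEventMatrix:
    def test_rejects_duplicate_channels(self):
        with pytest.raises(ParameterError, match="unique"):
            EventMatrix(np.zeros((2, 2)), ("CD63", "CD63"))

    def test_rejects_empty(self):
        with pytest.raises(DegenerateInputError):
            EventMatrix(np.empty((0, 2)), ("a", "b"))

    def test_rejects_nan(self):
        with pytest.raises(ParameterError, match="non-finite"):
            EventMatrix(np.array([[np.nan, 0.0]]), ("a", "b"))

    def test_missing_channel_lookup(self, small_events):
        with pytest.raises(ChannelMismatchError):
            small_events.column("CD123")


class TestReadEvents:
    def test_csv_roundtrip_header_and_shape(self, tmp_path):
        path = tmp_path / "events.csv"
        path.write_text("CD63,CD203c\n1.5,2.0\n3.25,4.0\n0.0,-1.0\n")
        events = read_events(path, format="delimited")
        assert events.n_events == 3
        assert events.channels == ("CD63", "CD203c")
        assert events.transform_tag == "none"
        np.testing.assert_allclose(events.values[1], [3.25, 4.0])

    def test_write_read_roundtrip(self, tmp_path, gaussian_events):
        path = tmp_path / "out.csv"
        write_events(gaussian_events, path)
        back = read_events(path)
        assert back.channels == gaussian_events.channels
        np.testing.assert_allclose(back.values, gaussian_events.values, rtol=1e-12)

    def test_tab_delimited(self, tmp_path):
        path = tmp_path / "events.tsv"
        path.write_text("a\tb\n1\t2\n")
        events = read_events(path)
        assert events.channels == ("a", "b")

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(DegenerateInputError):
            read_events(path)

    def test_header_only_errors(self, tmp_path):
        path = tmp_path / "hdr.csv"
        path.write_text("a,b\n")
        with pytest.raises(DegenerateInputError):
            read_events(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            read_events(tmp_path / "nope.csv")

    @pytest.mark.parametrize(
        "datatype,little", [("F", True), ("F", False), ("D", True), ("I", True)]
    )
    def test_fcs_roundtrip(self, tmp_path, rng, datatype, little):
        values = rng.uniform(0, 1000, size=(500, 3))
        if datatype == "I":
            values = np.floor(values)
        path = write_fcs(
            tmp_path / "sample.fcs",
            values,
            ["FSC-A", "CD63", "CD203c"],
            datatype=datatype,
            little_endian=little,
        )
        events = read_events(path)
        assert events.n_events == 500
        assert events.channels == ("FSC-A", "CD63", "CD203c")
        rtol = 1e-6 if datatype == "F" else 1e-12
        np.testing.assert_allclose(events.values, values, rtol=rtol)

    def test_fcs_known_event_count(self, tmp_path, rng):
        values = rng.normal(size=(10_000, 8))
        path = write_fcs(tmp_path / "big.fcs", values, [f"P{i}" for i in range(8)])
        events = read_events(path)
        assert (events.n_events, events.n_channels) == (10_000, 8)


class TestTransforms:
    def test_asinh_closed_forms(self):
        assert asinh_transform(np.array(0.0), cofactor=1.0) == 0.0
        np.testing.assert_allclose(
            asinh_transform(np.array(150.0), cofactor=150.0), np.arcsinh(1.0)
        )

    def test_asinh_bad_cofactor(self, small_events):
        with pytest.raises(ParameterError):
            transform(small_events, "asinh", cofactor=0.0)

    def test_logicle_top_of_scale_maps_to_decades(self):
        params = LogicleParams(T=262144, W=0.5, M=4.5, A=0.0)
        np.testing.assert_allclose(
            logicle_transform(np.array([262144.0]), params), [4.5], rtol=1e-9
        )

    def test_logicle_inverts_biexponential(self):
        params = LogicleParams()
        decades = np.linspace(0.0, params.M, 12)
        data = logicle_inverse(decades, params)
        np.testing.assert_allclose(
            logicle_transform(data, params), decades, atol=1e-8
        )

    def test_logicle_negative_width_rejected(self):
        with pytest.raises(ParameterError):
            LogicleParams(W=-0.1)

    def test_no_transform_stacking(self, small_events):
        once = transform(small_events, "asinh")
        with pytest.raises(ParameterError, match="already transformed"):
            transform(once, "asinh")

    def test_transform_selected_channels_only(self, small_events):
        out = transform(small_events, "asinh", channels=["CD203c"], cofactor=1.0)
        np.testing.assert_array_equal(out.column("CD63"), small_events.column("CD63"))
        np.testing.assert_allclose(
            out.column("CD203c"), np.arcsinh(small_events.column("CD203c"))
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e5), min_size=2, max_size=30
        )
    )
    def test_transforms_are_strictly_monotone(self, raw):
        x = np.unique(np.asarray(raw))
        # drop near-duplicates below the numeric inversion's resolution
        x = x[np.concatenate([[True], np.diff(x) > 1e-6])]
        if x.size < 2:
            return
        for y in (
            asinh_transform(x, cofactor=150.0),
            logicle_transform(x, LogicleParams()),
        ):
            assert np.all(np.diff(y) > 0)


class TestGate:
    def test_1d_interval(self):
        events = EventMatrix(np.array([[1.0], [5.0], [9.0]]), ("x",))
        out = gate(events, RectGate({"x": (4, 10)}))
        np.testing.assert_array_equal(out.values.ravel(), [5.0, 9.0])

    def test_whole_range_is_identity(self, gaussian_events):
        g = RectGate({"CD203c": (-100, 100), "CD63": (-100, 100)})
        out = gate(gaussian_events, g)
        np.testing.assert_array_equal(out.values, gaussian_events.values)

    def test_boundary_inclusive(self):
        events = EventMatrix(np.array([[4.0], [10.0]]), ("x",))
        out = gate(events, RectGate({"x": (4, 10)}))
        assert out.n_events == 2

    def test_partial_channel_gate_matches_bruteforce(self, rng):
        events = EventMatrix(rng.normal(size=(300, 2)), ("a", "b"))
        g = RectGate({"a": (-0.5, 0.8)})
        out = gate(events, g)
        expected = events.values[
            (events.values[:, 0] >= -0.5) & (events.values[:, 0] <= 0.8)
        ]
        np.testing.assert_array_equal(out.values, expected)

    def test_idempotent(self, gaussian_events):
        g = RectGate({"CD203c": (-1, 1)})
        once = gate(gaussian_events, g)
        twice = gate(once, g)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_empty_gate_errors(self, small_events):
        with pytest.raises(DegenerateInputError, match="0 of 4"):
            gate(small_events, RectGate({"CD63": (100, 200)}))

    def test_invalid_interval(self):
        with pytest.raises(ParameterError):
            RectGate({"x": (5, 1)})

    def test_gate_json_roundtrip(self):
        g = RectGate({"CD63": (0.0, 2.5), "CD203c": (-1.0, 1.0)})
        assert RectGate.from_json(g.to_json()) == g
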