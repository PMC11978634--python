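"""Convolution engine: reference vs pipelined dataflow, pooling, shapes."""

import heapq

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epihybrid import (
    CNNModel,
    ConfigError,
    ConvLayerSpec,
    ShapeError,
    conv2d_direct,
    conv2d_pipelined,
    extract_features,
    maxpool_two_stage,
)
from epihybrid.cnn import CycleReport, conv_cycles, load_cnn_bundle, pool_cycles, save_cnn_bundle


def conv_oracle(x, w, bias, relu):
    """Naive triple-loop valid cross-correlation in double precision."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    k = w.shape[0]
    ho, wo = x.shape[0] - k + 1, x.shape[1] - k + 1
    out = np.zeros((ho, wo))
    for i in range(ho):
        for j in range(wo):
            acc = bias
            for u in range(k):
                for v in range(k):
                    acc += x[i + u, j + v] * w[u, v]
            out[i, j] = acc
    return np.maximum(out, 0.0) if relu else out


def simulate_pipeline(k: int, h_out: int, w_out: int) -> dict:
    """Independent discrete-event simulation of the PE pipeline.

    Columns stream one per cycle (cycle 1 = first column in); the row
    partial for the window starting at column j leaves the last PE of its
    chain at cycle j + k, and the cross-row adder emits the summed output
    the following cycle. Output positions drain row-major, one per cycle.
    """
    events = []
    for idx in range(h_out * w_out):
        j = idx % w_out
        heapq.heappush(events, j + k + 1)  # row partial j+k, adder +1
    first_partial = k  # window j = 0: k columns through the PE chain
    clock = 0
    last = 0
    while events:
        ready = heapq.heappop(events)
        clock = max(clock + 1, ready)  # one result per cycle, not before ready
        last = clock
    return {"first_row_partial": first_partial, "total": last}


def random_layer(rng, k, relu=True):
    return ConvLayerSpec(
        weights=rng.normal(0, 1, (k, k)).astype(np.float32),
        bias=np.float32(rng.normal()),
        activation="relu" if relu else "none",
    )


def simple_model(rng=None, scale=0.1):
    rng = rng or np.random.default_rng(0)
    return CNNModel(
        layers=(
            ConvLayerSpec(weights=rng.normal(0, scale, (5, 5)).astype(np.float32)),
            ConvLayerSpec(weights=rng.normal(0, scale, (3, 3)).astype(np.float32)),
            ConvLayerSpec(weights=rng.normal(0, scale, (1, 1)).astype(np.float32)),
        )
    )


class TestConvDirect:
    def test_1x1_doubling(self, rng):
        x = rng.normal(0, 1, (6, 9)).astype(np.float32)
        layer = ConvLayerSpec(weights=[[2.0]], bias=0.0, activation="none")
        assert np.array_equal(conv2d_direct(x, layer), (x * np.float32(2)).astype(np.float32))

    def test_output_shape_20x256_5x5(self, rng):
        x = rng.normal(0, 1, (20, 256)).astype(np.float32)
        out = conv2d_direct(x, random_layer(rng, 5))
        assert out.shape == (16, 252)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_triple_loop_oracle(self, rng, k):
        x = rng.normal(0, 1, (8, 8)).astype(np.float32)
        layer = random_layer(rng, k, relu=False)
        got = conv2d_direct(x, layer).astype(np.float64)
        ref = conv_oracle(x, layer.weights, float(layer.bias), relu=False)
        assert np.max(np.abs(got - ref)) <= 1e-5 * max(np.max(np.abs(ref)), 1.0)

    def test_input_smaller_than_kernel_raises(self, rng):
        with pytest.raises(ShapeError):
            conv2d_direct(np.zeros((2, 2), dtype=np.float32), random_layer(rng, 3))

    def test_relu_idempotent(self, rng):
        x = rng.normal(0, 1, (10, 10)).astype(np.float32)
        out = conv2d_direct(x, random_layer(rng, 3))
        assert np.array_equal(np.maximum(out, np.float32(0)), out)


class TestConvPipelined:
    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(
        st.integers(0, 2**32 - 1),
        st.sampled_from([1, 3, 5]),
        st.integers(0, 7),
        st.integers(0, 7),
    )
    def test_bit_identical_to_direct(self, seed, k, dh, dw):
        """The dataflow emulation and the reference path perform the same
        float32 operations, so outputs must agree bit for bit."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 10, (k + dh, k + dw + 1)).astype(np.float32)
        layer = random_layer(rng, k)
        direct = conv2d_direct(x, layer)
        piped, _ = conv2d_pipelined(x, layer)
        assert np.array_equal(direct, piped)

    def test_first_row_partial_ready_at_cycle_three_for_3x3(self):
        """The third operation unit of a 3x3 row chain completes its window's
        partial sum in the third clock cycle."""
        assert simulate_pipeline(3, 1, 1)["first_row_partial"] == 3

    @pytest.mark.parametrize(
        "k,h,w",
        [(5, 20, 256), (3, 8, 126), (1, 6, 62), (3, 10, 10)],
    )
    def test_cycle_count_matches_event_simulation(self, rng, k, h, w):
        x = rng.normal(0, 1, (h, w)).astype(np.float32)
        _, cycles = conv2d_pipelined(x, random_layer(rng, k))
        ho, wo = h - k + 1, w - k + 1
        assert cycles == simulate_pipeline(k, ho, wo)["total"]
        assert cycles == conv_cycles(k, ho, wo)


class TestMaxPool:
    def test_single_window(self):
        assert maxpool_two_stage(np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32)) == 4.0

    def test_3x62_gives_1x31(self, rng):
        out = maxpool_two_stage(rng.normal(0, 1, (3, 62)).astype(np.float32))
        assert out.shape == (1, 31)

    def test_matches_brute_force(self, rng):
        x = rng.normal(0, 1, (10, 10)).astype(np.float32)
        got = maxpool_two_stage(x)
        for i in range(5):
            for j in range(5):
                assert got[i, j] == x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max()

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 11), st.integers(2, 11))
    def test_output_is_member_of_window(self, seed, h, w):
        x = np.random.default_rng(seed).normal(0, 1, (h, w)).astype(np.float32)
        out = maxpool_two_stage(x)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                window = x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                assert out[i, j] in window

    def test_empty_input_raises(self):
        with pytest.raises(ShapeError):
            maxpool_two_stage(np.zeros((0, 4), dtype=np.float32))

    def test_cycle_model_two_per_window(self):
        assert pool_cycles(8, 126) == 2 * 8 * 126


class TestExtractFeatures:
    def test_zero_input_zero_features(self):
        model = simple_model()
        zero_model = CNNModel(
            layers=tuple(
                ConvLayerSpec(weights=l.weights, bias=0.0) for l in model.layers
            )
        )
        fv, _ = extract_features(np.zeros((20, 256), dtype=np.float32), zero_model)
        assert np.all(fv.values == 0)

    def test_length_31_and_stage_shapes(self, rng):
        """The conv/pool chain runs 20x256 -> 16x252 -> 8x126 -> 6x124 ->
        3x62 -> 3x62 -> 1x31; checked via the per-stage cycle counts, which
        encode the output geometry."""
        x = rng.normal(0, 1, (20, 256)).astype(np.float32)
        fv, report = extract_features(x, simple_model(rng))
        assert fv.values.shape == (31,)
        expected = {
            "conv1": conv_cycles(5, 16, 252),
            "pool1": pool_cycles(8, 126),
            "conv2": conv_cycles(3, 6, 124),
            "pool2": pool_cycles(3, 62),
            "conv3": conv_cycles(1, 3, 62),
            "pool3": pool_cycles(1, 31),
        }
        assert report.stage_cycles == expected

    def test_pipelined_path_same_features(self, rng):
        x = rng.normal(0, 1, (20, 256)).astype(np.float32)
        model = simple_model(rng)
        direct, _ = extract_features(x, model)
        piped, rep = extract_features(x, model, use_pipelined=True)
        assert np.array_equal(direct.values, piped.values)

    def test_wrong_input_shape_raises(self):
        with pytest.raises(ShapeError):
            extract_features(np.zeros((20, 255), dtype=np.float32), simple_model())


class TestBundleIO:
    def test_roundtrip_preserves_weights_exactly(self, tmp_path, rng):
        model = simple_model(rng)
        path = tmp_path / "cnn.json"
        save_cnn_bundle(model, path)
        back = load_cnn_bundle(path)
        for la, lb in zip(model.layers, back.layers):
            assert np.array_equal(la.weights, lb.weights)
            assert la.bias == lb.bias

    def test_model_validates_layer_order(self, rng):
        with pytest.raises(ConfigError):
            CNNModel(
                layers=(
                    ConvLayerSpec(weights=np.zeros((3, 3))),
                    ConvLayerSpec(weights=np.zeros((5, 5))),
                    ConvLayerSpec(weights=np.zeros((1, 1))),
                )
            )

    def test_cycle_report_totals(self):
        rep = CycleReport(stage_cycles={"conv1": 100, "svm": 50}, clock_hz=1e7)
        assert rep.total_cycles == 150
        assert rep.latency_s == pytest.approx(1.5e-5)
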