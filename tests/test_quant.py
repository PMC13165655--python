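"""INT8 quantization engine: qparams, calibration, integer execution."""

import numpy as np
import pytest

from edgebp.graph import ArchitectureSpec, LayerSpec
from edgebp.nn import FloatModel, forward_batch, init_weights, predict
from edgebp.quant import (
    QMAX,
    QMIN,
    QuantError,
    calibrate,
    compute_qparams,
    dequantize_tensor,
    forward_int8,
    forward_int8_batch,
    predict_int8,
    quantize_model,
    quantize_tensor,
    requantize,
)


class TestQParams:
    def test_unsigned_range_example(self):
        qp = compute_qparams(0.0, 2.55)
        assert qp.scale == pytest.approx(0.01)
        assert qp.zero_point == -128

    def test_symmetric_example(self):
        qp = compute_qparams(-1.27, 1.27, symmetric=True)
        assert qp.scale == pytest.approx(0.01)
        assert qp.zero_point == 0

    def test_zero_exactly_representable(self):
        qp = compute_qparams(-1.0, 3.0)
        grid = (np.arange(QMIN, QMAX + 1) - qp.zero_point) * qp.scale
        assert np.abs(grid).min() == 0.0

    def test_zero_range_uses_epsilon_scale(self):
        qp = compute_qparams(0.0, 0.0)
        assert qp.scale > 0

    def test_invalid_range(self):
        with pytest.raises(QuantError):
            compute_qparams(1.0, 0.5)


class TestQuantizeTensor:
    def test_hand_value(self):
        qp = compute_qparams(0.0, 2.55)
        assert quantize_tensor(np.array([1.0]), qp)[0] == -28  # 100 - 128

    def test_saturation(self):
        qp = compute_qparams(0.0, 2.55)
        assert quantize_tensor(np.array([99.0]), qp)[0] == 127
        assert quantize_tensor(np.array([-99.0]), qp)[0] == -128

    def test_round_trip_within_half_scale(self, rng):
        qp = compute_qparams(-2.0, 3.0)
        x = rng.uniform(-2, 3, 1000)
        err = np.abs(dequantize_tensor(quantize_tensor(x, qp), qp) - x)
        assert err.max() <= qp.scale / 2 + 1e-12

    def test_non_finite_rejected(self):
        with pytest.raises(QuantError):
            quantize_tensor(np.array([np.inf]), compute_qparams(0, 1))


def _toy_spec(L=64):
    return ArchitectureSpec(
        "toyq",
        [
            LayerSpec("c1", "conv1d", ("input",), kernel=3, filters=8),
            LayerSpec("r1", "relu", ("c1",)),
            LayerSpec("p1", "maxpool1d", ("r1",), kernel=2),
            LayerSpec("c2", "conv1d", ("p1",), kernel=3, filters=8),
            LayerSpec("r2", "relu", ("c2",)),
            LayerSpec("g", "gap1d", ("r2",)),
            LayerSpec("out", "dense", ("g",), filters=2),
        ],
        input_shape=(L, 1),
    )


class TestCalibration:
    def test_single_sample_min_equals_max(self, rng):
        model = init_weights(_toy_spec(), seed=0)
        x = np.full((1, 64), 0.25)
        stats = calibrate(model, x)
        for edge, (lo, hi) in stats.ranges.items():
            if edge != "input":
                pass
            # constant input through a deterministic net: per-edge extrema
            # come from one activation map; min <= max always, and for the
            # scalar-valued edges they coincide
        lo, hi = stats.ranges["input"]
        assert lo == hi == 0.25

    def test_two_sample_lattice_property(self, rng):
        model = init_weights(_toy_spec(), seed=0)
        a = rng.uniform(0, 1, (1, 64))
        b = rng.uniform(0, 1, (1, 64))
        sa, sb = calibrate(model, a), calibrate(model, b)
        sab = calibrate(model, np.vstack([a, b]))
        for edge in sab.ranges:
            lo, hi = sab.ranges[edge]
            assert lo == min(sa.ranges[edge][0], sb.ranges[edge][0])
            assert hi == max(sa.ranges[edge][1], sb.ranges[edge][1])

    def test_calibration_deterministic(self, rng):
        model = init_weights(_toy_spec(), seed=0)
        X = rng.uniform(0, 1, (32, 64))
        assert calibrate(model, X).ranges == calibrate(model, X).ranges


class TestRequantize:
    def test_hand_values(self):
        assert requantize(np.array([100]), 0.25, 0)[0] == 25
        assert requantize(np.array([0]), 0.37, 5)[0] == 5

    def test_fixed_point_matches_float_mode_within_one_lsb(self, rng):
        acc = rng.integers(-(2**30), 2**30, 1_000_000)
        for M in np.exp(rng.uniform(np.log(1e-7), np.log(4.0), 10)):
            a = requantize(acc, M, 0, mode="fixed_point").astype(np.int64)
            b = requantize(acc, M, 0, mode="float").astype(np.int64)
            assert np.abs(a - b).max() <= 1

    def test_invalid_multiplier(self):
        with pytest.raises(QuantError):
            requantize(np.array([1]), -0.5, 0)


class TestQuantizeModel:
    def test_all_zero_weights_quantize_to_zero(self, rng):
        model = init_weights(_toy_spec(), seed=0)
        for wb in model.weights.values():
            wb["w"][:] = 0.0
            wb["b"][:] = rng.normal(0, 0.1, wb["b"].shape)
        stats = calibrate(model, rng.uniform(0, 1, (16, 64)))
        qm = quantize_model(model, stats)
        for lq in qm.layers.values():
            assert np.all(lq.w_q == 0)

    def test_weights_avoid_negative_128(self, rng):
        model = init_weights(_toy_spec(), seed=1)
        stats = calibrate(model, rng.uniform(0, 1, (16, 64)))
        qm = quantize_model(model, stats)
        for lq in qm.layers.values():
            assert lq.w_q.min() >= -127

    def test_weight_round_trip_within_half_scale(self, rng):
        model = init_weights(_toy_spec(), seed=1)
        stats = calibrate(model, rng.uniform(0, 1, (16, 64)))
        qm = quantize_model(model, stats)
        for name, lq in qm.layers.items():
            w = model.weights[name]["w"]
            scales = lq.w_scales if lq.w_scales.size > 1 else np.full(w.shape[-1], lq.w_scales[0])
            w_dq = lq.w_q.astype(float) * scales
            assert np.all(np.abs(w_dq - w) <= scales / 2 + 1e-12)

    def test_bias_scale_identity(self, rng):
        model = init_weights(_toy_spec(), seed=1)
        stats = calibrate(model, rng.uniform(0, 1, (16, 64)))
        qm = quantize_model(model, stats)
        lq = qm.layers["c1"]
        s_in = float(np.asarray(qm.edge_qp["input"].scale))
        b_dq = lq.bias_q * (s_in * lq.w_scales)
        assert np.all(np.abs(b_dq - model.weights["c1"]["b"]) <= s_in * lq.w_scales / 2 + 1e-12)

    def test_quantization_is_deterministic(self, rng):
        model = init_weights(_toy_spec(), seed=1)
        X = rng.uniform(0, 1, (16, 64))
        qa = quantize_model(model, calibrate(model, X))
        qb = quantize_model(model, calibrate(model, X))
        for name in qa.layers:
            assert np.array_equal(qa.layers[name].w_q, qb.layers[name].w_q)
            assert np.array_equal(qa.layers[name].bias_q, qb.layers[name].bias_q)


class TestIntegerForward:
    def test_identity_one_tap_conv(self):
        """Weight dequantizing to exactly 1.0 with matched scales passes
        integer values through unchanged."""
        spec = ArchitectureSpec(
            "ident",
            [LayerSpec("c", "conv1d", ("input",), kernel=1, filters=1)],
            input_shape=(16, 1),
        )
        model = FloatModel(
            spec=spec, weights={"c": {"w": np.ones((1, 1, 1)), "b": np.zeros(1)}}
        )
        X = np.linspace(0, 1, 16)[None, :]
        stats = calibrate(model, X)
        qm = quantize_model(model, stats)
        xq = quantize_tensor(X, qm.input_qp)[:, :, None]
        out = forward_int8_batch(qm, xq)
        assert np.array_equal(out[:, :, 0], xq[:, :, 0])

    def test_all_zero_input_yields_zero_points(self, rng):
        model = init_weights(_toy_spec(), seed=2)
        for wb in model.weights.values():
            wb["b"][:] = 0.0
        stats = calibrate(model, rng.uniform(-0.5, 0.5, (16, 64)))
        qm = quantize_model(model, stats)
        zp_in = qm.input_qp.zero_point
        xq = np.full((1, 64, 1), zp_in, dtype=np.int8)
        out = forward_int8_batch(qm, xq)
        assert np.all(out == qm.output_qp.zero_point)

    def test_toy_net_within_propagated_error_bound(self, rng):
        from quant_bound import propagated_error_bound

        model = init_weights(_toy_spec(), seed=3)
        X = rng.uniform(0, 1, (64, 64))
        stats = calibrate(model, X)
        qm = quantize_model(model, stats)
        pf = forward_batch(model, X[:16])[0]
        pq_raw = forward_int8_batch(qm, quantize_tensor(X[:16], qm.input_qp))
        pq = dequantize_tensor(pq_raw, qm.output_qp)
        err = np.abs(pq - pf).max()
        assert err <= propagated_error_bound(qm, stats)
        # and the bound is not vacuous at this depth
        assert err <= 5.0 * max(float(np.asarray(qm.output_qp.scale)), 1e-3)

    def test_fixed_point_and_float_modes_agree_closely(self, rng):
        model = init_weights(_toy_spec(), seed=3)
        X = rng.uniform(0, 1, (32, 64))
        qm = quantize_model(model, calibrate(model, X))
        xq = quantize_tensor(X, qm.input_qp)
        a = forward_int8_batch(qm, xq, mode="fixed_point").astype(int)
        b = forward_int8_batch(qm, xq, mode="float").astype(int)
        assert np.abs(a - b).max() <= 1

    def test_integer_purity_under_scale_jitter(self, rng):
        """Perturbing every float scale field in its last ulp leaves the
        integer outputs bitwise unchanged in fixed-point mode."""
        import copy

        model = init_weights(_toy_spec(), seed=4)
        X = rng.uniform(0, 1, (32, 64))
        qm = quantize_model(model, calibrate(model, X))
        xq = quantize_tensor(X, qm.input_qp)
        base = forward_int8_batch(qm, xq, mode="fixed_point")

        jittered = copy.deepcopy(qm)
        for lq in jittered.layers.values():
            lq.w_scales = np.nextafter(lq.w_scales, np.inf)
            lq.M = np.nextafter(lq.M, np.inf)
        out = forward_int8_batch(jittered, xq, mode="fixed_point")
        assert np.array_equal(base, out)

    def test_single_window_wrapper_dequantizes(self, rng):
        model = init_weights(_toy_spec(), seed=5)
        X = rng.uniform(0, 1, (16, 64))
        qm = quantize_model(model, calibrate(model, X))
        xq = quantize_tensor(X[0], qm.input_qp)
        sbp, dbp, raw = forward_int8(qm, xq)
        s = float(np.asarray(qm.output_qp.scale))
        zp = qm.output_qp.zero_point
        assert sbp == pytest.approx((int(raw[0]) - zp) * s)
        assert dbp == pytest.approx((int(raw[1]) - zp) * s)

    def test_residual_add_path(self, rng):
        spec = ArchitectureSpec(
            "res",
            [
                LayerSpec("c1", "conv1d", ("input",), kernel=3, filters=4),
                LayerSpec("r1", "relu", ("c1",)),
                LayerSpec("c2", "conv1d", ("r1",), kernel=3, filters=4),
                LayerSpec("a", "add", ("c2", "r1")),
                LayerSpec("r2", "relu", ("a",)),
                LayerSpec("g", "gap1d", ("r2",)),
                LayerSpec("out", "dense", ("g",), filters=2),
            ],
            input_shape=(32, 1),
        )
        from quant_bound import propagated_error_bound

        model = init_weights(spec, seed=6)
        X = rng.uniform(0, 1, (64, 32))
        stats = calibrate(model, X)
        qm = quantize_model(model, stats)
        pf = forward_batch(model, X[:8])[0]
        pq = predict_int8(qm, X[:8])
        assert np.abs(pq - pf).max() <= propagated_error_bound(qm, stats)
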