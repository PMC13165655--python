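"""Self-contained full-integer INT8 post-training quantization.

Scheme (the de-facto full-integer PTQ convention): per-channel symmetric
INT8 weights (scale = max|w|/127 per output channel, zero-point 0, -128
never used), per-tensor asymmetric INT8 activations calibrated by plain
min/max over a representative sample of training windows, INT32 biases at
scale s_in * s_w, INT8 input and output tensors, no retraining.

ReLU is fused into the producing layer: calibration records post-activation
ranges, so requantizing a conv/dense/add output to its post-ReLU edge and
clamping at the zero point realizes the nonlinearity with no separate
integer op. Max-pooling operates directly on the integer tensor (no
requantization); global average pooling is an integer sum followed by a
rounded division at unchanged scale; residual adds requantize both addends
to the output edge's scale before a saturating add.

Requantization uses a 31-bit fixed-point mantissa with a rounding right
shift (round half away from zero everywhere); a float-multiplier mode is
retained for debugging only. Integer matrix accumulations are evaluated in
float64, which is exact for these magnitudes (|products| << 2^53), and
then handed to the int64 fixed-point path; no floating-point *value* can
influence any integer tensor, which the scale-jitter purity test asserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from edgebp.graph import CONV_KINDS, INPUT, WEIGHTED, ArchitectureSpec
from edgebp.nn import FloatModel, forward_batch, pad_amounts

log = logging.getLogger(__name__)

QMIN, QMAX = -128, 127
_EPS_SCALE = 1e-8  # minimal positive scale for degenerate (zero-range) edges


class QuantError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Quantization parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantParams:
    scale: float | np.ndarray
    zero_point: int = 0
    granularity: str = "per_tensor"  # {per_tensor, per_channel}
    symmetric: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.scale)
        if not (s > 0).all():
            raise QuantError("scale must be positive")
        if self.symmetric and self.zero_point != 0:
            raise QuantError("symmetric quantization requires zero_point == 0")
        if not (QMIN <= self.zero_point <= QMAX):
            raise QuantError("zero_point outside [-128, 127]")


def compute_qparams(min_val: float, max_val: float, symmetric: bool = False, bits: int = 8) -> QuantParams:
    """Affine quantization parameters from an observed real range.

    The range is widened to include 0 so that real zero is exactly
    representable (zero-nudging); a zero-width range falls back to a
    documented minimal positive scale.
    """
    if bits != 8:
        raise QuantError("only 8-bit quantization is supported")
    if not np.isfinite([min_val, max_val]).all() or max_val < min_val:
        raise QuantError(f"invalid range ({min_val}, {max_val})")
    lo = min(min_val, 0.0)
    hi = max(max_val, 0.0)
    if symmetric:
        bound = max(abs(lo), abs(hi))
        scale = bound / 127.0 if bound > 0 else _EPS_SCALE
        return QuantParams(scale=scale, zero_point=0, symmetric=True)
    if hi == lo:
        return QuantParams(scale=_EPS_SCALE, zero_point=0)
    scale = (hi - lo) / 255.0
    zp = int(np.clip(_round_half_away(np.array(QMIN - lo / scale)), QMIN, QMAX))
    return QuantParams(scale=scale, zero_point=zp)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_tensor(x: np.ndarray, qp: QuantParams, channel_axis: int = -1) -> np.ndarray:
    """q = clamp(round(x/scale) + zero_point, -128, 127), half away from zero.

    With per_channel granularity, ``qp.scale`` is a vector applied along
    ``channel_axis``.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise QuantError("non-finite input to quantize_tensor")
    scale = np.asarray(qp.scale, dtype=np.float64)
    if qp.granularity == "per_channel":
        shape = [1] * x.ndim
        shape[channel_axis] = -1
        scale = scale.reshape(shape)
    q = _round_half_away(x / scale) + qp.zero_point
    return np.clip(q, QMIN, QMAX).astype(np.int8)


def dequantize_tensor(q: np.ndarray, qp: QuantParams, channel_axis: int = -1) -> np.ndarray:
    scale = np.asarray(qp.scale, dtype=np.float64)
    if qp.granularity == "per_channel":
        shape = [1] * q.ndim
        shape[channel_axis] = -1
        scale = scale.reshape(shape)
    return (q.astype(np.float64) - qp.zero_point) * scale


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationStats:
    """Per-activation-edge running (min, max) over the representative set."""

    ranges: dict[str, tuple[float, float]]
    n_samples: int

    def __post_init__(self) -> None:
        for edge, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise QuantError(f"edge {edge}: min > max")


def calibrate(model: FloatModel, representative: np.ndarray, batch_size: int = 128) -> CalibrationStats:
    """Track global min/max of every activation edge over the representative
    windows (drawn from the training split; 512 is the reference size)."""
    X = np.atleast_2d(np.asarray(representative, dtype=np.float64))
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    for i in range(0, X.shape[0], batch_size):
        _, acts = forward_batch(model, X[i : i + batch_size], want_cache=True)
        for edge, a in acts.items():
            lo, hi = float(a.min()), float(a.max())
            mins[edge] = min(mins.get(edge, np.inf), lo)
            maxs[edge] = max(maxs.get(edge, -np.inf), hi)
    expected = {INPUT} | {l.name for l in model.spec.layers}
    if set(mins) != expected:  # pragma: no cover - executor bug guard
        raise QuantError(f"uncovered edges: {expected - set(mins)}")
    return CalibrationStats(
        ranges={e: (mins[e], maxs[e]) for e in mins}, n_samples=int(X.shape[0])
    )


# ---------------------------------------------------------------------------
# Fixed-point requantization
# ---------------------------------------------------------------------------


def _fixed_point_multiplier(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose M = mant * 2^-shift with a 31-bit integer mantissa."""
    M = np.atleast_1d(np.asarray(M, dtype=np.float64))
    if (M <= 0).any():
        raise QuantError("multiplier must be positive")
    mant, exp = np.frexp(M)  # M = mant * 2^exp, mant in [0.5, 1)
    qmant = np.round(mant * (1 << 31)).astype(np.int64)
    over = qmant == (1 << 31)
    qmant[over] >>= 1
    exp = exp.astype(np.int64)
    exp[over] += 1
    return qmant, 31 - exp  # right-shift amounts (can be <= 0 for M >= 1)


def _rounding_rshift(v: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Arithmetic right shift with round half away from zero, elementwise."""
    v = np.asarray(v, dtype=np.int64)
    n = np.broadcast_to(np.asarray(n, dtype=np.int64), v.shape)
    pos_shift = np.maximum(n, 1)
    offset = np.int64(1) << (pos_shift - 1)
    mag = np.abs(v)
    shifted = (mag + offset) >> pos_shift
    out = np.where(v >= 0, shifted, -shifted)
    left = n <= 0
    if left.any():
        out = np.where(left, v << np.maximum(-n, 0), out)
    return out


def requantize(
    acc: np.ndarray,
    M: float | np.ndarray,
    zero_point_out: int = 0,
    mode: str = "fixed_point",
) -> np.ndarray:
    """Rescale an INT32 accumulator to INT8: round(M*acc) + zp, saturated.

    ``mode="fixed_point"`` decomposes M into a 31-bit mantissa and a
    rounding right shift (64-bit intermediates, overflow-free for INT32
    accumulators); ``mode="float"`` is the debug path. The two agree within
    1 LSB.
    """
    acc = np.asarray(acc)
    if mode == "float":
        out = _round_half_away(np.asarray(M, dtype=np.float64) * acc.astype(np.float64)) + zero_point_out
        return np.clip(out, QMIN, QMAX).astype(np.int8)
    qmant, shift = _fixed_point_multiplier(M)
    if qmant.size == 1:
        qmant, shift = qmant[0], shift[0]
    prod = acc.astype(np.int64) * qmant
    out = _rounding_rshift(prod, shift) + zero_point_out
    return np.clip(out, QMIN, QMAX).astype(np.int8)


# ---------------------------------------------------------------------------
# Quantized model
# ---------------------------------------------------------------------------


@dataclass
class LayerQuant:
    """Quantized payload of one weighted layer."""

    w_q: np.ndarray  # INT8 kernel, per-channel symmetric
    w_scales: np.ndarray  # per output channel
    bias_q: np.ndarray  # INT32 at scale s_in * s_w
    mant: np.ndarray  # fixed-point mantissas of M = s_in*s_w/s_out
    shift: np.ndarray
    M: np.ndarray  # float multipliers (debug path)
    zp_in: int
    zp_out: int
    fused_relu: bool


@dataclass
class AddQuant:
    """Requantization parameters of a residual add (one set per addend)."""

    mant: tuple
    shift: tuple
    M: tuple
    zp_in: tuple
    zp_out: int
    fused_relu: bool


@dataclass
class QuantizedModel:
    spec: ArchitectureSpec
    layers: dict  # weighted layer name -> LayerQuant
    adds: dict  # add layer name -> AddQuant
    edge_qp: dict  # edge name -> QuantParams (per-tensor, activations)
    weight_qp: dict  # weighted layer name -> QuantParams (per-channel)
    fused_relus: frozenset

    @property
    def input_qp(self) -> QuantParams:
        return self.edge_qp[INPUT]

    @property
    def output_qp(self) -> QuantParams:
        return self.edge_qp[self.spec.output_layer]


def _channel_axis(kind: str) -> int:
    return 1 if kind == "depthwise_conv1d" else -1


def quantize_model(model: FloatModel, stats: CalibrationStats) -> QuantizedModel:
    """Full-integer INT8 conversion of a trained float model (no retraining).

    Weights are quantized per-channel symmetric along the output-channel
    axis; activations per-tensor asymmetric from the calibration ranges;
    biases to INT32 at scale s_in * s_w. ReLU layers are fused into their
    producer's output range. Degenerate zero-range edges get a minimal
    positive scale and are logged.
    """
    spec = model.spec
    consumers: dict[str, list] = {}
    for l in spec.layers:
        for src in l.inputs:
            consumers.setdefault(src, []).append(l)

    def sole_relu_consumer(name: str):
        cs = consumers.get(name, [])
        if len(cs) == 1 and cs[0].kind == "relu":
            return cs[0].name
        return None

    # Assign per-edge activation qparams in topological order.
    edge_qp: dict[str, QuantParams] = {}
    fused: set[str] = set()

    def qp_from_stats(edge: str) -> QuantParams:
        lo, hi = stats.ranges[edge]
        if hi == lo:
            log.info("degenerate zero-range edge %s; using epsilon scale", edge)
        return compute_qparams(lo, hi, symmetric=False)

    edge_qp[INPUT] = qp_from_stats(INPUT)
    for l in spec.layers:
        if l.name in edge_qp:
            continue
        if l.kind in WEIGHTED or l.kind == "add":
            relu = sole_relu_consumer(l.name)
            if relu is not None:
                qp = qp_from_stats(relu)
                edge_qp[l.name] = qp
                edge_qp[relu] = qp
                fused.add(relu)
            else:
                edge_qp[l.name] = qp_from_stats(l.name)
        elif l.kind in ("maxpool1d", "flatten", "gap1d"):
            edge_qp[l.name] = edge_qp[l.inputs[0]]
        elif l.kind == "relu":
            edge_qp[l.name] = qp_from_stats(l.name)

    layers: dict[str, LayerQuant] = {}
    weight_qp: dict[str, QuantParams] = {}
    adds: dict[str, AddQuant] = {}
    for l in spec.layers:
        if l.kind in WEIGHTED:
            w = model.weights[l.name]["w"]
            b = model.weights[l.name]["b"]
            if l.kind == "dense":
                # Fully-connected kernels are quantized per-tensor, matching
                # the reference full-integer converters (per-channel applies
                # to convolutions only).
                bound = np.abs(w).max()
                w_scales = np.array([bound / 127.0 if bound > 0 else _EPS_SCALE])
                wqp = QuantParams(scale=float(w_scales[0]), symmetric=True)
                w_q = quantize_tensor(w, wqp)
            else:
                axis = _channel_axis(l.kind)
                red = tuple(i for i in range(w.ndim) if i != (axis % w.ndim))
                bound = np.abs(w).max(axis=red)
                w_scales = np.where(bound > 0, bound / 127.0, _EPS_SCALE)
                wqp = QuantParams(scale=w_scales, granularity="per_channel", symmetric=True)
                w_q = quantize_tensor(w, wqp, channel_axis=axis)
            s_in = float(np.asarray(edge_qp[l.inputs[0]].scale))
            s_out = float(np.asarray(edge_qp[l.name].scale))
            bias_scale = s_in * w_scales
            bias_q = np.clip(
                _round_half_away(b / bias_scale), -(2**31), 2**31 - 1
            ).astype(np.int64)
            M = s_in * w_scales / s_out
            mant, shift = _fixed_point_multiplier(M)
            layers[l.name] = LayerQuant(
                w_q=w_q,
                w_scales=w_scales,
                bias_q=bias_q,
                mant=mant,
                shift=shift,
                M=M,
                zp_in=edge_qp[l.inputs[0]].zero_point,
                zp_out=edge_qp[l.name].zero_point,
                fused_relu=sole_relu_consumer(l.name) is not None,
            )
            weight_qp[l.name] = wqp
        elif l.kind == "add":
            s_out = float(np.asarray(edge_qp[l.name].scale))
            Ms, mants, shifts, zps = [], [], [], []
            for src in l.inputs:
                s_i = float(np.asarray(edge_qp[src].scale))
                M = np.array([s_i / s_out])
                mant, shift = _fixed_point_multiplier(M)
                Ms.append(float(M[0]))
                mants.append(int(mant[0]))
                shifts.append(int(shift[0]))
                zps.append(edge_qp[src].zero_point)
            adds[l.name] = AddQuant(
                mant=tuple(mants),
                shift=tuple(shifts),
                M=tuple(Ms),
                zp_in=tuple(zps),
                zp_out=edge_qp[l.name].zero_point,
                fused_relu=sole_relu_consumer(l.name) is not None,
            )
    return QuantizedModel(
        spec=spec,
        layers=layers,
        adds=adds,
        edge_qp=edge_qp,
        weight_qp=weight_qp,
        fused_relus=frozenset(fused),
    )


# ---------------------------------------------------------------------------
# Integer-only forward pass
# ---------------------------------------------------------------------------


def _exact_int_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Integer matmul through float64 BLAS; exact while |values| << 2^53."""
    return a.astype(np.float64) @ b.astype(np.float64)


def _rounded_div(v: np.ndarray, d: int) -> np.ndarray:
    mag = np.abs(v)
    out = (mag + d // 2) // d
    return np.where(v >= 0, out, -out)


def _int_conv(x_q: np.ndarray, lq: LayerQuant, l, depthwise: bool, mode: str) -> np.ndarray:
    B, L, C = x_q.shape
    k = lq.w_q.shape[0]
    pad = "causal" if l.kind == "dilated_causal_conv1d" else l.padding
    pl, pr, Lout = pad_amounts(L, k, l.stride, l.dilation, pad)
    # Pad with the input zero-point (= real zero), then remove the offset.
    xp = np.pad(x_q.astype(np.int64), ((0, 0), (pl, pr), (0, 0)), constant_values=lq.zp_in)
    xc = xp - lq.zp_in
    span = l.stride * (Lout - 1) + 1
    cout = lq.w_q.shape[-1] if not depthwise else C
    acc = np.zeros((B, Lout, cout), dtype=np.float64)
    for j in range(k):
        sl = xc[:, j * l.dilation : j * l.dilation + span : l.stride, :]
        if depthwise:
            acc += sl * lq.w_q[j].astype(np.float64)
        else:
            acc += _exact_int_matmul(sl, lq.w_q[j])
    acc = acc.astype(np.int64) + lq.bias_q
    if mode == "float":
        out = _round_half_away(lq.M * acc.astype(np.float64)) + lq.zp_out
    else:
        prod = acc * lq.mant
        out = _rounding_rshift(prod, lq.shift) + lq.zp_out
    out = np.clip(out, QMIN, QMAX)
    if lq.fused_relu:
        out = np.maximum(out, lq.zp_out)
    return out.astype(np.int8)


def _int_dense(x_q: np.ndarray, lq: LayerQuant, mode: str) -> np.ndarray:
    xc = x_q.astype(np.int64) - lq.zp_in
    acc = _exact_int_matmul(xc, lq.w_q).astype(np.int64) + lq.bias_q
    if mode == "float":
        out = _round_half_away(lq.M * acc.astype(np.float64)) + lq.zp_out
    else:
        out = _rounding_rshift(acc * lq.mant, lq.shift) + lq.zp_out
    out = np.clip(out, QMIN, QMAX)
    if lq.fused_relu:
        out = np.maximum(out, lq.zp_out)
    return out.astype(np.int8)


def forward_int8_batch(qmodel: QuantizedModel, x_q: np.ndarray, mode: str = "fixed_point") -> np.ndarray:
    """Integer-only evaluation of a batch of quantized windows.

    x_q: (B, 1024) or (B, 1024, 1) INT8, quantized with the model's input
    QuantParams. Returns the raw INT8 outputs, shape (B, 2).
    """
    if x_q.dtype != np.int8:
        raise QuantError("input must be quantized to int8 with the model's input qparams")
    if x_q.ndim == 2:
        x_q = x_q[:, :, None]
    acts: dict[str, np.ndarray] = {INPUT: x_q}
    for l in qmodel.spec.layers:
        a = acts[l.inputs[0]]
        if l.kind in CONV_KINDS:
            out = _int_conv(a, qmodel.layers[l.name], l, l.kind == "depthwise_conv1d", mode)
        elif l.kind == "dense":
            out = _int_dense(a, qmodel.layers[l.name], mode)
        elif l.kind == "relu":
            if l.name in qmodel.fused_relus:
                out = a  # realized by the producer's clamp
            else:
                out = np.maximum(a, qmodel.edge_qp[l.name].zero_point).astype(np.int8)
        elif l.kind == "maxpool1d":
            B, L, C = a.shape
            Lo = L // l.kernel
            out = a[:, : Lo * l.kernel, :].reshape(B, Lo, l.kernel, C).max(axis=2)
        elif l.kind == "gap1d":
            zp = qmodel.edge_qp[l.inputs[0]].zero_point
            s = (a.astype(np.int64) - zp).sum(axis=1)
            out = np.clip(_rounded_div(s, a.shape[1]) + zp, QMIN, QMAX).astype(np.int8)
        elif l.kind == "flatten":
            out = a.reshape(a.shape[0], -1)
        elif l.kind == "add":
            aq = qmodel.adds[l.name]
            b = acts[l.inputs[1]]
            total = np.zeros(a.shape, dtype=np.int64)
            for i, t in enumerate((a, b)):
                v = t.astype(np.int64) - aq.zp_in[i]
                if mode == "float":
                    total += _round_half_away(aq.M[i] * v.astype(np.float64)).astype(np.int64)
                else:
                    total += _rounding_rshift(v * aq.mant[i], aq.shift[i])
            out = np.clip(total + aq.zp_out, QMIN, QMAX)
            if aq.fused_relu:
                out = np.maximum(out, aq.zp_out)
            out = out.astype(np.int8)
        acts[l.name] = out
    return acts[qmodel.spec.output_layer]


def forward_int8(
    qmodel: QuantizedModel, window_int8: np.ndarray, mode: str = "fixed_point"
) -> tuple[float, float, np.ndarray]:
    """Integer-only evaluation of one window.

    Returns (sbp_est, dbp_est, raw_int8_outputs); the estimates are the raw
    INT8 outputs dequantized to mmHg with the model's output QuantParams.
    """
    raw = forward_int8_batch(qmodel, np.asarray(window_int8, dtype=np.int8)[None, :], mode=mode)[0]
    sbp, dbp = dequantize_tensor(raw, qmodel.output_qp)
    return float(sbp), float(dbp), raw


def predict_int8(
    qmodel: QuantizedModel,
    windows: np.ndarray,
    mode: str = "fixed_point",
    batch_size: int = 256,
) -> np.ndarray:
    """Quantize float windows, run the integer path, dequantize to mmHg."""
    X = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    outs = []
    for i in range(0, X.shape[0], batch_size):
        xq = quantize_tensor(X[i : i + batch_size], qmodel.input_qp)
        raw = forward_int8_batch(qmodel, xq, mode=mode)
        outs.append(dequantize_tensor(raw, qmodel.output_qp))
    return np.vstack(outs) if outs else np.empty((0, 2))
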