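"""Worst-case error propagation bound for the integer engine.

Walks a quantized model edge by edge and accumulates a rigorous bound on
|dequantized INT8 activation - float activation| under worst-case rounding:
requantization contributes half an output LSB (plus one LSB of fixed-point
slack), weight rounding contributes 0.5 * s_w per kernel element times the
input magnitude, bias rounding half a bias LSB, and input errors propagate
through the layer's absolute-weight sums. Max-pool and fused ReLU preserve
the bound; GAP adds half an LSB for the rounded division; residual adds sum
their addends' bounds plus their own requantization rounding.
"""

from __future__ import annotations

import numpy as np

from edgebp.graph import CONV_KINDS, INPUT
from edgebp.quant import CalibrationStats, QuantizedModel


def propagated_error_bound(qmodel: QuantizedModel, stats: CalibrationStats) -> float:
    """Upper bound on the end-to-end |dequant(int8 out) - float out|."""
    bounds: dict[str, float] = {}
    s_in0 = float(np.asarray(qmodel.edge_qp[INPUT].scale))
    bounds[INPUT] = 0.5 * s_in0

    def edge_amp(edge: str) -> float:
        lo, hi = stats.ranges[edge]
        return max(abs(lo), abs(hi))

    for l in qmodel.spec.layers:
        src = l.inputs[0]
        e_in = bounds[src]
        if l.kind in CONV_KINDS or l.kind == "dense":
            lq = qmodel.layers[l.name]
            s_out = float(np.asarray(qmodel.edge_qp[l.name].scale))
            s_in = float(np.asarray(qmodel.edge_qp[src].scale))
            w_dq = lq.w_q.astype(np.float64)
            if l.kind == "depthwise_conv1d":
                scales = lq.w_scales  # (C,)
                l1 = float((np.abs(w_dq) * scales).sum(axis=0).max())
                n_taps = lq.w_q.shape[0]
            elif l.kind == "dense":
                s = float(lq.w_scales[0] if lq.w_scales.size else lq.w_scales)
                l1 = float(np.abs(w_dq * s).sum(axis=0).max())
                n_taps = lq.w_q.shape[0]
                scales = np.full(lq.w_q.shape[-1], s)
            else:
                scales = lq.w_scales  # per out channel
                l1 = float((np.abs(w_dq) * scales).sum(axis=(0, 1)).max())
                n_taps = lq.w_q.shape[0] * lq.w_q.shape[1]
            s_w_max = float(np.max(scales))
            amp = edge_amp(src) + e_in
            bound = (
                1.5 * s_out  # requant rounding + fixed-point slack
                + l1 * e_in  # propagated input error
                + 0.5 * s_w_max * n_taps * amp  # weight rounding
                + 0.5 * s_in * s_w_max  # bias rounding
            )
            bounds[l.name] = bound
        elif l.kind == "relu":
            bounds[l.name] = e_in
        elif l.kind == "maxpool1d":
            bounds[l.name] = e_in
        elif l.kind == "gap1d":
            s = float(np.asarray(qmodel.edge_qp[l.name].scale))
            bounds[l.name] = e_in + 0.5 * s
        elif l.kind == "flatten":
            bounds[l.name] = e_in
        elif l.kind == "add":
            s_out = float(np.asarray(qmodel.edge_qp[l.name].scale))
            bounds[l.name] = bounds[l.inputs[0]] + bounds[l.inputs[1]] + 1.5 * s_out
    return bounds[qmodel.spec.output_layer]
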