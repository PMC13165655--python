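"""Deployment-feasibility arithmetic: memory footprint and duty cycle.

These are analytic estimates from the model description, not on-device
measurements: the weight payload follows this package's documented
serialization layout, and the activation peak comes from a liveness
analysis over the graph's fixed topological schedule. Real toolchains use
their own schedulers and runtime overheads, so their figures will differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from edgebp.graph import INPUT, ArchitectureSpec, infer_shapes
from edgebp.quant import QuantizedModel

# Documented qparams-table layout: per weighted layer, one float32 scale per
# output channel plus one INT8 zero-point byte; per activation edge, one
# float32 scale plus one INT8 zero-point.
_SCALE_BYTES = 4
_ZP_BYTES = 1


def duty_cycle(latency_ms: float, window_s: float = 8.192) -> float:
    """Inference-to-acquisition ratio in percent (full precision).

    The acquisition window is 8.192 s (1024 samples at 125 Hz) by default;
    report alongside a one-decimal rounding for readability.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if latency_ms < 0:
        raise ValueError("latency_ms must be non-negative")
    return 100.0 * latency_ms / (1000.0 * window_s)


def weights_bytes(qmodel: QuantizedModel) -> int:
    """Serialized payload: INT8 kernel bytes + INT32 bias bytes + qparams table."""
    total = 0
    for name, lq in qmodel.layers.items():
        total += lq.w_q.size  # 1 byte per INT8 kernel element
        total += 4 * lq.bias_q.size  # 4 bytes per INT32 bias
        total += _SCALE_BYTES * np.asarray(lq.w_scales).size + _ZP_BYTES
    total += len(qmodel.edge_qp) * (_SCALE_BYTES + _ZP_BYTES)
    return int(total)


def activation_peak_bytes(spec: ArchitectureSpec) -> int:
    """Peak INT8 activation memory under the graph's topological schedule.

    A tensor is live from the step that produces it until its last consumer
    has executed; the peak is the maximum over steps of the summed byte
    sizes (1 byte per element) of simultaneously live tensors, including
    the model input.
    """
    shapes = infer_shapes(spec)
    sizes = {name: int(np.prod(shape)) for name, shape in shapes.items()}
    last_use = {INPUT: -1}
    for i, l in enumerate(spec.layers):
        last_use[l.name] = i  # keep sinks live through their own step
        for src in l.inputs:
            last_use[src] = i
    peak = 0
    for i, l in enumerate(spec.layers):
        live = sizes[l.name]
        live += sizes[INPUT] if last_use[INPUT] >= i else 0
        for j, prev in enumerate(spec.layers[:i]):
            if last_use[prev.name] >= i:
                live += sizes[prev.name]
        peak = max(peak, live)
    return int(peak)


@dataclass(frozen=True)
class FootprintReport:
    weights_bytes: int
    activation_peak_bytes: int
    latency_ms: float
    window_s: float
    duty_cycle_pct: float
    duty_cycle_rounded: float

    @staticmethod
    def build(qmodel: QuantizedModel, latency_ms: float, window_s: float = 8.192) -> "FootprintReport":
        dc = duty_cycle(latency_ms, window_s)
        return FootprintReport(
            weights_bytes=weights_bytes(qmodel),
            activation_peak_bytes=activation_peak_bytes(qmodel.spec),
            latency_ms=latency_ms,
            window_s=window_s,
            duty_cycle_pct=dc,
            duty_cycle_rounded=round(dc, 1),
        )
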