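"""Declarative 1D layer graphs: shape inference and parameter counting.

An architecture is an ordered DAG of layers over a single (1024, 1) input
and a single (2,) regression output (SBP, DBP). Layers reference their
predecessors by name; the reserved name "input" denotes the model input.
The list order must be a topological order.

Shapes are (length, channels) for temporal tensors and (n,) after
flatten/GAP/dense. Temporal length transforms:

  same-padding conv, stride s  -> ceil(L / s)
  causal dilated conv          -> L (stride 1, left pad (k-1)*dilation)
  valid conv                   -> floor((L - (k-1)*dilation - 1)/s) + 1
  maxpool(p)                   -> floor(L / p)
  flatten                      -> (L*C,)
  global average pool          -> (C,)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

INPUT = "input"

LAYER_KINDS = {
    "conv1d",
    "depthwise_conv1d",
    "pointwise_conv1d",
    "dilated_causal_conv1d",
    "dense",
    "relu",
    "maxpool1d",
    "gap1d",
    "flatten",
    "add",
}

WEIGHTED = {"conv1d", "depthwise_conv1d", "pointwise_conv1d", "dilated_causal_conv1d", "dense"}
CONV_KINDS = {"conv1d", "depthwise_conv1d", "pointwise_conv1d", "dilated_causal_conv1d"}


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str
    inputs: tuple[str, ...] = (INPUT,)
    kernel: int = 1  # kernel size; pool size for maxpool1d
    filters: int = 0  # output channels (conv/pointwise) or units (dense)
    stride: int = 1
    dilation: int = 1
    padding: str = "same"  # {same, causal, valid}

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise GraphError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1 or self.dilation < 1 or self.kernel < 1:
            raise GraphError("kernel, stride and dilation must be >= 1")
        if self.kind == "add" and len(self.inputs) != 2:
            raise GraphError("add takes exactly two inputs")
        if self.kind != "add" and len(self.inputs) != 1:
            raise GraphError(f"{self.kind} takes exactly one input")
        if self.padding not in ("same", "causal", "valid"):
            raise GraphError(f"unknown padding {self.padding!r}")
        if self.kind == "dilated_causal_conv1d" and self.stride != 1:
            raise GraphError("causal convolutions are stride 1")


@dataclass
class ArchitectureSpec:
    name: str
    layers: list[LayerSpec]
    declared_param_count: Optional[int] = None
    input_shape: tuple[int, int] = (1024, 1)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise GraphError("duplicate layer names")
        seen = {INPUT}
        for l in self.layers:
            for src in l.inputs:
                if src not in seen:
                    raise GraphError(f"layer {l.name!r} references {src!r} before definition")
            seen.add(l.name)

    @property
    def output_layer(self) -> str:
        consumed = {src for l in self.layers for src in l.inputs}
        sinks = [l.name for l in self.layers if l.name not in consumed]
        if len(sinks) != 1:
            raise GraphError(f"graph must have exactly one sink, found {sinks}")
        return sinks[0]

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Shape inference
# ---------------------------------------------------------------------------


def _conv_out_len(L: int, k: int, stride: int, dilation: int, padding: str) -> int:
    if padding == "same":
        return math.ceil(L / stride)
    if padding == "causal":
        return L
    eff = (k - 1) * dilation + 1
    out = (L - eff) // stride + 1
    if out < 1:
        raise GraphError("valid convolution produces non-positive length")
    return out


def infer_shapes(spec: ArchitectureSpec) -> dict[str, tuple[int, ...]]:
    """Propagate shapes through the DAG; returns {layer name: shape}.

    The input shape is included under the key "input".
    """
    shapes: dict[str, tuple[int, ...]] = {INPUT: spec.input_shape}
    for l in spec.layers:
        ins = [shapes[s] for s in l.inputs]
        if l.kind in CONV_KINDS:
            (L, C) = ins[0]
            pad = "causal" if l.kind == "dilated_causal_conv1d" else l.padding
            Lo = _conv_out_len(L, l.kernel, l.stride, l.dilation, pad)
            Co = C if l.kind == "depthwise_conv1d" else l.filters
            if Co < 1:
                raise GraphError(f"{l.name}: filters must be >= 1")
            shapes[l.name] = (Lo, Co)
        elif l.kind == "dense":
            (n,) = ins[0] if len(ins[0]) == 1 else (None,)
            if n is None:
                raise GraphError(f"{l.name}: dense requires a flat input")
            shapes[l.name] = (l.filters,)
        elif l.kind == "relu":
            shapes[l.name] = ins[0]
        elif l.kind == "maxpool1d":
            (L, C) = ins[0]
            Lo = L // l.kernel
            if Lo < 1:
                raise GraphError(f"{l.name}: pooled length vanished")
            shapes[l.name] = (Lo, C)
        elif l.kind == "gap1d":
            (L, C) = ins[0]
            shapes[l.name] = (C,)
        elif l.kind == "flatten":
            (L, C) = ins[0]
            shapes[l.name] = (L * C,)
        elif l.kind == "add":
            if ins[0] != ins[1]:
                raise GraphError(f"{l.name}: add with mismatched shapes {ins[0]} vs {ins[1]}")
            shapes[l.name] = ins[0]
    return shapes


# ---------------------------------------------------------------------------
# Parameter counting
# ---------------------------------------------------------------------------


def layer_param_count(l: LayerSpec, in_shape: tuple[int, ...]) -> int:
    if l.kind in ("conv1d", "pointwise_conv1d", "dilated_causal_conv1d"):
        k = 1 if l.kind == "pointwise_conv1d" else l.kernel
        c_in = in_shape[1]
        return k * c_in * l.filters + l.filters
    if l.kind == "depthwise_conv1d":
        c_in = in_shape[1]
        return l.kernel * c_in + c_in
    if l.kind == "dense":
        return in_shape[0] * l.filters + l.filters
    return 0


def count_params(spec: ArchitectureSpec) -> int:
    """Total trainable parameters: kernels + biases over all weighted layers."""
    shapes = infer_shapes(spec)
    return sum(layer_param_count(l, shapes[l.inputs[0]]) for l in spec.layers)


def validate_spec(spec: ArchitectureSpec) -> None:
    """Structural contract: single source/sink, (2,) output, declared count."""
    shapes = infer_shapes(spec)
    out = shapes[spec.output_layer]
    if out != (2,):
        raise GraphError(f"sink shape must be (2,), got {out}")
    if spec.declared_param_count is not None:
        got = count_params(spec)
        if got != spec.declared_param_count:
            raise GraphError(
                f"{spec.name}: parameter count {got} != declared {spec.declared_param_count}"
            )


def receptive_field(spec: ArchitectureSpec) -> dict[str, int]:
    """Receptive field (in input samples) of each layer output.

    Tracks (rf, jump): rf grows by (k-1)*dilation*jump per conv tap span,
    jump multiplies by stride / pool size.
    """
    state: dict[str, tuple[int, int]] = {INPUT: (1, 1)}
    for l in spec.layers:
        rf, jump = state[l.inputs[0]]
        if l.kind in CONV_KINDS:
            k = 1 if l.kind == "pointwise_conv1d" else l.kernel
            rf = rf + (k - 1) * l.dilation * jump
            jump *= l.stride
        elif l.kind == "maxpool1d":
            rf = rf + (l.kernel - 1) * jump
            jump *= l.kernel
        elif l.kind == "add":
            rf2, jump2 = state[l.inputs[1]]
            rf, jump = max(rf, rf2), max(jump, jump2)
        state[l.name] = (rf, jump)
    return {name: rf for name, (rf, jump) in state.items() if name != INPUT}
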