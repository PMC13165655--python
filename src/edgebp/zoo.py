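"""Reference architectures at frozen configurations.

Five 1D-CNN families over a (1024, 1) PPG window with a two-element
(SBP, DBP) regression head:

* ``baseline_cnn`` — four stacked convolutions with increasing filter
  counts, max-pool downsampling, flatten + two dense layers.
* ``residual_cnn`` — four residual stages (two convolutions per block with
  identity shortcuts, 1x1 projection at channel changes), flatten head.
* ``residual_cnn_slim`` — the residual layout with reduced filters per
  stage and a global-average-pooling head.
* ``mobilenet_1d`` — depthwise-separable stages (strided depthwise temporal
  convolution + pointwise channel mixing).
* ``micro_tcn`` — dilated causal convolutions with exponentially increasing
  dilation arranged in residual blocks, strided stem for downsampling.

The exact layer widths/kernels were fixed once by a constrained search so
that each family's trainable-parameter total matches its published
reference count; the chosen knobs live in ``edgebp/configs/*.yaml`` and are
treated as frozen.
"""

from __future__ import annotations

from importlib import resources

import yaml

from edgebp.graph import INPUT, ArchitectureSpec, LayerSpec, validate_spec

ARCHITECTURE_NAMES = (
    "baseline_cnn",
    "residual_cnn",
    "residual_cnn_slim",
    "mobilenet_1d",
    "micro_tcn",
)


def load_config(name: str) -> dict:
    if name not in ARCHITECTURE_NAMES:
        raise KeyError(f"unknown architecture {name!r}; choose from {ARCHITECTURE_NAMES}")
    with resources.files("edgebp.configs").joinpath(f"{name}.yaml").open() as fh:
        return yaml.safe_load(fh)


def _residual_stage(layers, prev, stage_idx, c_in, c_out, kernel):
    """One residual block: conv-relu-conv, shortcut (1x1 projection on
    channel change), add, relu."""
    p = f"stage{stage_idx}"
    layers.append(LayerSpec(f"{p}_conv1", "conv1d", (prev,), kernel=kernel, filters=c_out))
    layers.append(LayerSpec(f"{p}_relu1", "relu", (f"{p}_conv1",)))
    layers.append(LayerSpec(f"{p}_conv2", "conv1d", (f"{p}_relu1",), kernel=kernel, filters=c_out))
    shortcut = prev
    if c_in != c_out:
        layers.append(LayerSpec(f"{p}_proj", "pointwise_conv1d", (prev,), filters=c_out))
        shortcut = f"{p}_proj"
    layers.append(LayerSpec(f"{p}_add", "add", (f"{p}_conv2", shortcut)))
    layers.append(LayerSpec(f"{p}_relu2", "relu", (f"{p}_add",)))
    return f"{p}_relu2"


def _build_baseline(cfg: dict) -> list[LayerSpec]:
    layers: list[LayerSpec] = []
    prev = INPUT
    for i, f in enumerate(cfg["filters"], 1):
        layers.append(LayerSpec(f"conv{i}", "conv1d", (prev,), kernel=cfg["kernel"], filters=f))
        layers.append(LayerSpec(f"relu{i}", "relu", (f"conv{i}",)))
        layers.append(LayerSpec(f"pool{i}", "maxpool1d", (f"relu{i}",), kernel=cfg["pool"]))
        prev = f"pool{i}"
    layers.append(LayerSpec("flatten", "flatten", (prev,)))
    layers.append(LayerSpec("fc1", "dense", ("flatten",), filters=cfg["dense_width"]))
    layers.append(LayerSpec("fc1_relu", "relu", ("fc1",)))
    layers.append(LayerSpec("head", "dense", ("fc1_relu",), filters=2))
    return layers


def _build_residual(cfg: dict) -> list[LayerSpec]:
    k = cfg["kernel"]
    layers: list[LayerSpec] = [
        LayerSpec("stem_conv", "conv1d", (INPUT,), kernel=k, filters=cfg["stem_filters"]),
        LayerSpec("stem_relu", "relu", ("stem_conv",)),
        LayerSpec("stem_pool", "maxpool1d", ("stem_relu",), kernel=cfg["pool"]),
    ]
    prev = "stem_pool"
    c_in = cfg["stem_filters"]
    n_stages = len(cfg["stage_filters"])
    for i, c in enumerate(cfg["stage_filters"], 1):
        prev = _residual_stage(layers, prev, i, c_in, c, k)
        c_in = c
        if i < n_stages:  # downsample between stages
            layers.append(LayerSpec(f"pool{i}", "maxpool1d", (prev,), kernel=cfg["pool"]))
            prev = f"pool{i}"
    if cfg["head"] == "gap":
        layers.append(LayerSpec("gap", "gap1d", (prev,)))
        prev = "gap"
    else:
        layers.append(LayerSpec("flatten", "flatten", (prev,)))
        prev = "flatten"
    layers.append(LayerSpec("head", "dense", (prev,), filters=2))
    return layers


def _build_mobilenet(cfg: dict) -> list[LayerSpec]:
    layers: list[LayerSpec] = [
        LayerSpec(
            "stem_conv", "conv1d", (INPUT,), kernel=cfg["kernel"], filters=cfg["stem_filters"], stride=cfg["stem_stride"]
        ),
        LayerSpec("stem_relu", "relu", ("stem_conv",)),
    ]
    prev = "stem_relu"
    for i, c in enumerate(cfg["stage_filters"], 1):
        layers.append(
            LayerSpec(f"dw{i}", "depthwise_conv1d", (prev,), kernel=cfg["kernel"], stride=cfg["stage_stride"])
        )
        layers.append(LayerSpec(f"dw{i}_relu", "relu", (f"dw{i}",)))
        layers.append(LayerSpec(f"pw{i}", "pointwise_conv1d", (f"dw{i}_relu",), filters=c))
        layers.append(LayerSpec(f"pw{i}_relu", "relu", (f"pw{i}",)))
        prev = f"pw{i}_relu"
    layers.append(LayerSpec("gap", "gap1d", (prev,)))
    layers.append(LayerSpec("head", "dense", ("gap",), filters=2))
    return layers


def _build_tcn(cfg: dict) -> list[LayerSpec]:
    c = cfg["channels"]
    k = cfg["kernel"]
    layers: list[LayerSpec] = [
        LayerSpec(
            "stem_conv", "conv1d", (INPUT,), kernel=cfg["stem_kernel"], filters=cfg["stem_filters"], stride=cfg["stem_stride"]
        ),
        LayerSpec("stem_relu", "relu", ("stem_conv",)),
    ]
    prev = "stem_relu"
    c_in = cfg["stem_filters"]
    for i in range(cfg["n_blocks"]):
        d = 2**i
        p = f"block{i + 1}"
        layers.append(
            LayerSpec(f"{p}_conv1", "dilated_causal_conv1d", (prev,), kernel=k, filters=c, dilation=d, padding="causal")
        )
        layers.append(LayerSpec(f"{p}_relu1", "relu", (f"{p}_conv1",)))
        layers.append(
            LayerSpec(f"{p}_conv2", "dilated_causal_conv1d", (f"{p}_relu1",), kernel=k, filters=c, dilation=d, padding="causal")
        )
        shortcut = prev
        if c_in != c:
            layers.append(LayerSpec(f"{p}_proj", "pointwise_conv1d", (prev,), filters=c))
            shortcut = f"{p}_proj"
        layers.append(LayerSpec(f"{p}_add", "add", (f"{p}_conv2", shortcut)))
        layers.append(LayerSpec(f"{p}_relu2", "relu", (f"{p}_add",)))
        prev = f"{p}_relu2"
        c_in = c
    layers.append(LayerSpec("gap", "gap1d", (prev,)))
    layers.append(LayerSpec("head", "dense", ("gap",), filters=2))
    return layers


_BUILDERS = {
    "baseline_cnn": _build_baseline,
    "residual_cnn": _build_residual,
    "residual_cnn_slim": _build_residual,
    "mobilenet_1d": _build_mobilenet,
    "micro_tcn": _build_tcn,
}


def reference_architecture(name: str) -> ArchitectureSpec:
    """Instantiate a frozen reference architecture by name.

    The returned spec is validated: single (1024, 1) source, (2,) sink, and
    a trainable-parameter total equal to the declared reference count.
    """
    cfg = load_config(name)
    spec = ArchitectureSpec(
        name=name,
        layers=_BUILDERS[name](cfg),
        declared_param_count=cfg["declared_param_count"],
    )
    validate_spec(spec)
    return spec
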