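"""Neutral numpy executor for the layer graphs, with batched backprop.

Two independent execution paths are provided on purpose:

* :func:`forward_float` — a deliberately plain single-window reference
  executor (per-layer loops over kernel taps). It is the parity oracle for
  both the batched training path and the integer engine.
* :func:`forward_batch` / :func:`backward_batch` — vectorized batched
  forward and backward passes used by the trainer, written around BLAS
  matmuls.

Weights layout: conv kernels are (k, c_in, c_out), depthwise kernels
(k, c), dense kernels (n_in, n_out); every weighted layer has a bias of
length c_out (or n_out).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from edgebp.graph import (
    CONV_KINDS,
    INPUT,
    WEIGHTED,
    ArchitectureSpec,
    GraphError,
    LayerSpec,
    infer_shapes,
)


class ExecutionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class FloatModel:
    spec: ArchitectureSpec
    weights: dict  # layer name -> {"w": ndarray, "b": ndarray}

    def __post_init__(self) -> None:
        shapes = infer_shapes(self.spec)
        for l in self.spec.layers:
            if l.kind not in WEIGHTED:
                continue
            if l.name not in self.weights:
                raise ExecutionError(f"missing weights for {l.name}")
            w = self.weights[l.name]["w"]
            b = self.weights[l.name]["b"]
            exp = _weight_shape(l, shapes[l.inputs[0]])
            if tuple(w.shape) != exp:
                raise ExecutionError(f"{l.name}: weight shape {w.shape} != expected {exp}")
            if b.shape != (exp[-1],):
                raise ExecutionError(f"{l.name}: bias shape {b.shape} != ({exp[-1]},)")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ExecutionError(f"{l.name}: non-finite weights")


def _weight_shape(l: LayerSpec, in_shape: tuple[int, ...]) -> tuple[int, ...]:
    if l.kind == "depthwise_conv1d":
        return (l.kernel, in_shape[1])
    if l.kind in ("conv1d", "dilated_causal_conv1d"):
        return (l.kernel, in_shape[1], l.filters)
    if l.kind == "pointwise_conv1d":
        return (1, in_shape[1], l.filters)
    if l.kind == "dense":
        return (in_shape[0], l.filters)
    raise GraphError(l.kind)


def init_weights(spec: ArchitectureSpec, seed: int = 42, dtype=np.float64) -> FloatModel:
    """He-normal initialization (ReLU-appropriate), zero biases, seeded."""
    rng = np.random.default_rng(seed)
    shapes = infer_shapes(spec)
    weights = {}
    for l in spec.layers:
        if l.kind not in WEIGHTED:
            continue
        shape = _weight_shape(l, shapes[l.inputs[0]])
        fan_in = int(np.prod(shape[:-1])) if l.kind != "depthwise_conv1d" else shape[0]
        w = rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape).astype(dtype)
        b = np.zeros(shape[-1], dtype=dtype)
        weights[l.name] = {"w": w, "b": b}
    return FloatModel(spec=spec, weights=weights)


# ---------------------------------------------------------------------------
# Padding arithmetic (TF-style "same"; "causal" pads left only)
# ---------------------------------------------------------------------------


def pad_amounts(L: int, k: int, stride: int, dilation: int, padding: str) -> tuple[int, int, int]:
    eff = (k - 1) * dilation + 1
    if padding == "same":
        Lout = -(-L // stride)
        total = max((Lout - 1) * stride + eff - L, 0)
        return total // 2, total - total // 2, Lout
    if padding == "causal":
        return (k - 1) * dilation, 0, L
    Lout = (L - eff) // stride + 1
    return 0, 0, Lout


def _conv_padding(l: LayerSpec) -> str:
    return "causal" if l.kind == "dilated_causal_conv1d" else l.padding


# ---------------------------------------------------------------------------
# Batched forward / backward
# ---------------------------------------------------------------------------


def forward_batch(model: FloatModel, x: np.ndarray, want_cache: bool = False):
    """Evaluate the DAG on a batch.

    x: (B, 1024) or (B, 1024, 1). Returns (out, cache) where out is (B, 2)
    and cache maps layer name -> activation (present when requested; the
    input is cached under "input").
    """
    if x.ndim == 2:
        x = x[:, :, None]
    acts: dict[str, np.ndarray] = {INPUT: x}
    aux: dict[str, np.ndarray] = {}
    for l in model.spec.layers:
        a = acts[l.inputs[0]]
        if l.kind in CONV_KINDS:
            w, b = model.weights[l.name]["w"], model.weights[l.name]["b"]
            out = _conv_fwd(a, w, b, l, depthwise=(l.kind == "depthwise_conv1d"))
        elif l.kind == "dense":
            w, b = model.weights[l.name]["w"], model.weights[l.name]["b"]
            out = a @ w + b
        elif l.kind == "relu":
            out = np.maximum(a, 0.0)
        elif l.kind == "maxpool1d":
            out, idx = _maxpool_fwd(a, l.kernel)
            aux[l.name] = idx
        elif l.kind == "gap1d":
            out = a.mean(axis=1)
        elif l.kind == "flatten":
            out = a.reshape(a.shape[0], -1)
        elif l.kind == "add":
            out = a + acts[l.inputs[1]]
        acts[l.name] = out
    final = acts[model.spec.output_layer]
    if not np.isfinite(final).all():
        raise ExecutionError("non-finite activations in forward pass")
    return (final, acts if want_cache else None)


def backward_batch(model: FloatModel, acts: dict, grad_out: np.ndarray) -> dict:
    """Backpropagate d(loss)/d(output) through the cached forward pass.

    Returns {layer name: {"w": grad, "b": grad}} for weighted layers.
    """
    grads: dict[str, dict] = {}
    gacts: dict[str, np.ndarray] = {model.spec.output_layer: grad_out}
    for l in reversed(model.spec.layers):
        g = gacts.pop(l.name, None)
        if g is None:
            continue
        a = acts[l.inputs[0]]
        if l.kind in CONV_KINDS:
            w = model.weights[l.name]["w"]
            gw, gb, gx = _conv_bwd(a, w, g, l, depthwise=(l.kind == "depthwise_conv1d"))
            grads[l.name] = {"w": gw, "b": gb}
            _acc(gacts, l.inputs[0], gx)
        elif l.kind == "dense":
            w = model.weights[l.name]["w"]
            grads[l.name] = {"w": a.T @ g, "b": g.sum(axis=0)}
            _acc(gacts, l.inputs[0], g @ w.T)
        elif l.kind == "relu":
            _acc(gacts, l.inputs[0], g * (acts[l.name] > 0))
        elif l.kind == "maxpool1d":
            _acc(gacts, l.inputs[0], _maxpool_bwd(a, acts[l.name], g, l.kernel))
        elif l.kind == "gap1d":
            L = a.shape[1]
            _acc(gacts, l.inputs[0], np.repeat(g[:, None, :] / L, L, axis=1))
        elif l.kind == "flatten":
            _acc(gacts, l.inputs[0], g.reshape(a.shape))
        elif l.kind == "add":
            _acc(gacts, l.inputs[0], g)
            _acc(gacts, l.inputs[1], g)
    return grads


def _acc(store: dict, key: str, val: np.ndarray) -> None:
    if key in store:
        store[key] = store[key] + val
    else:
        store[key] = val


def _conv_fwd(x, w, b, l: LayerSpec, depthwise: bool):
    B, L, C = x.shape
    k = w.shape[0]
    pl, pr, Lout = pad_amounts(L, k, l.stride, l.dilation, _conv_padding(l))
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))) if (pl or pr) else x
    span = l.stride * (Lout - 1) + 1
    if depthwise:
        out = np.empty((B, Lout, C), dtype=x.dtype)
        out[:] = b
        for j in range(k):
            out += xp[:, j * l.dilation : j * l.dilation + span : l.stride, :] * w[j]
    else:
        out = np.empty((B, Lout, w.shape[2]), dtype=x.dtype)
        out[:] = b
        for j in range(k):
            out += xp[:, j * l.dilation : j * l.dilation + span : l.stride, :] @ w[j]
    return out


def _conv_bwd(x, w, g, l: LayerSpec, depthwise: bool):
    B, L, C = x.shape
    k = w.shape[0]
    pl, pr, Lout = pad_amounts(L, k, l.stride, l.dilation, _conv_padding(l))
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))) if (pl or pr) else x
    span = l.stride * (Lout - 1) + 1
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    for j in range(k):
        sl = slice(j * l.dilation, j * l.dilation + span, l.stride)
        piece = xp[:, sl, :]
        if depthwise:
            gw[j] = (piece * g).sum(axis=(0, 1))
            gxp[:, sl, :] += g * w[j]
        else:
            gw[j] = np.einsum("blc,blo->co", piece, g, optimize=True)
            gxp[:, sl, :] += g @ w[j].T
    gb = g.sum(axis=(0, 1))
    gx = gxp[:, pl : pl + L, :] if (pl or pr) else gxp
    return gw, gb, gx


def _maxpool_fwd(x, p: int):
    B, L, C = x.shape
    Lo = L // p
    xr = x[:, : Lo * p, :].reshape(B, Lo, p, C)
    idx = xr.argmax(axis=2)
    out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, idx


def _maxpool_bwd(x, out, g, p: int):
    B, L, C = x.shape
    Lo = L // p
    xr_shape = (B, Lo, p, C)
    idx = x[:, : Lo * p, :].reshape(xr_shape).argmax(axis=2)
    gx = np.zeros(xr_shape, dtype=g.dtype)
    np.put_along_axis(gx, idx[:, :, None, :], g[:, :, None, :], axis=2)
    gx = gx.reshape(B, Lo * p, C)
    if Lo * p < L:
        gx = np.pad(gx, ((0, 0), (0, L - Lo * p), (0, 0)))
    return gx


# ---------------------------------------------------------------------------
# Single-window reference executor
# ---------------------------------------------------------------------------


def forward_float(model: FloatModel, window: np.ndarray) -> tuple[float, float]:
    """Reference evaluation of one 1024-sample window -> (sbp, dbp) in mmHg.

    Deterministic topological evaluation with simple per-tap loops; kept
    independent of the batched path so the two can cross-check each other.
    """
    x = np.asarray(window, dtype=np.float64).reshape(-1, 1)
    if x.shape[0] != model.spec.input_shape[0]:
        raise ExecutionError(f"window must have {model.spec.input_shape[0]} samples")
    acts: dict[str, np.ndarray] = {INPUT: x}
    for l in model.spec.layers:
        a = acts[l.inputs[0]]
        if l.kind in CONV_KINDS:
            w = model.weights[l.name]["w"]
            b = model.weights[l.name]["b"]
            k = w.shape[0]
            pl, pr, Lout = pad_amounts(a.shape[0], k, l.stride, l.dilation, _conv_padding(l))
            ap = np.pad(a, ((pl, pr), (0, 0)))
            if l.kind == "depthwise_conv1d":
                out = np.empty((Lout, a.shape[1]))
                for t in range(Lout):
                    seg = ap[t * l.stride : t * l.stride + (k - 1) * l.dilation + 1 : l.dilation, :]
                    out[t] = (seg * w).sum(axis=0) + b
            else:
                cout = w.shape[2]
                out = np.empty((Lout, cout))
                for t in range(Lout):
                    seg = ap[t * l.stride : t * l.stride + (k - 1) * l.dilation + 1 : l.dilation, :]
                    out[t] = np.tensordot(seg, w, axes=([0, 1], [0, 1])) + b
        elif l.kind == "dense":
            out = acts[l.inputs[0]] @ model.weights[l.name]["w"] + model.weights[l.name]["b"]
        elif l.kind == "relu":
            out = np.maximum(a, 0.0)
        elif l.kind == "maxpool1d":
            Lo = a.shape[0] // l.kernel
            out = a[: Lo * l.kernel].reshape(Lo, l.kernel, -1).max(axis=1)
        elif l.kind == "gap1d":
            out = a.mean(axis=0)
        elif l.kind == "flatten":
            out = a.reshape(-1)
        elif l.kind == "add":
            out = a + acts[l.inputs[1]]
        if not np.isfinite(out).all():
            raise ExecutionError(f"non-finite intermediate at {l.name}")
        acts[l.name] = out
    sbp, dbp = acts[model.spec.output_layer]
    return float(sbp), float(dbp)


def cast_model(model: FloatModel, dtype) -> FloatModel:
    return FloatModel(
        spec=model.spec,
        weights={
            name: {"w": wb["w"].astype(dtype), "b": wb["b"].astype(dtype)}
            for name, wb in model.weights.items()
        },
    )


def predict(model: FloatModel, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Batched float predictions, (n, 2) mmHg (SBP, DBP)."""
    outs = []
    X = np.asarray(windows, dtype=np.float64)
    for i in range(0, X.shape[0], batch_size):
        out, _ = forward_batch(model, X[i : i + batch_size])
        outs.append(out)
    return np.vstack(outs) if outs else np.empty((0, 2))
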