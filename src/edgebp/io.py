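"""Serialization: records, window sets, float models, quantized models.

Records travel as one file per record in either a plain CSV dialect
(metadata in ``# key=value`` comment lines, two aligned ``ppg,abp``
columns, optional per-beat ground-truth lines) or a compressed ``.npz``
container with the identical schema. Window sets and models use ``.npz``
with named arrays; model containers embed the architecture graph as JSON
plus a content hash, and loaders validate shapes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from edgebp.cohort import FS, Record
from edgebp.graph import ArchitectureSpec, LayerSpec
from edgebp.nn import FloatModel
from edgebp.preprocess import SplitDataset, WindowSet

# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


def save_record_csv(record: Record, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# record_id={record.record_id}\n")
        fh.write(f"# fs={record.fs}\n")
        if record.ground_truth is not None:
            for t, s, d in record.ground_truth:
                fh.write(f"# beat={t:.6f},{s:.6f},{d:.6f}\n")
        fh.write("ppg,abp\n")
        for p, a in zip(record.ppg, record.abp):
            fh.write(f"{p:.9g},{a:.9g}\n")


def load_record_csv(path: str | Path) -> Record:
    meta: dict[str, str] = {}
    beats = []
    ppg, abp = [], []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# beat="):
                beats.append([float(v) for v in line[len("# beat=") :].split(",")])
            elif line.startswith("#"):
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            elif line and line != "ppg,abp":
                p, a = line.split(",")
                ppg.append(float(p))
                abp.append(float(a))
    return Record(
        record_id=meta["record_id"],
        fs=int(meta.get("fs", FS)),
        ppg=np.array(ppg),
        abp=np.array(abp),
        ground_truth=np.array(beats) if beats else None,
    )


def save_record_npz(record: Record, path: str | Path) -> None:
    payload = {
        "record_id": np.array(record.record_id),
        "fs": np.array(record.fs),
        "ppg": record.ppg,
        "abp": record.abp,
    }
    if record.ground_truth is not None:
        payload["ground_truth"] = record.ground_truth
    np.savez_compressed(path, **payload)


def load_record_npz(path: str | Path) -> Record:
    with np.load(path, allow_pickle=False) as z:
        return Record(
            record_id=str(z["record_id"]),
            fs=int(z["fs"]),
            ppg=z["ppg"],
            abp=z["abp"],
            ground_truth=z["ground_truth"] if "ground_truth" in z else None,
        )


# ---------------------------------------------------------------------------
# Window sets / splits
# ---------------------------------------------------------------------------


def save_windows(ws: WindowSet, path: str | Path) -> None:
    np.savez_compressed(
        path,
        values=ws.values,
        sbp=ws.sbp,
        dbp=ws.dbp,
        record_id=ws.record_id.astype(str),
        start=ws.start,
    )


def load_windows(path: str | Path) -> WindowSet:
    with np.load(path, allow_pickle=False) as z:
        return WindowSet(
            values=z["values"],
            sbp=z["sbp"],
            dbp=z["dbp"],
            record_id=z["record_id"].astype(object),
            start=z["start"],
        )


def save_split(split: SplitDataset, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for part in ("train", "val", "test"):
        save_windows(getattr(split, part), d / f"{part}.npz")
    (d / "split_config.json").write_text(json.dumps(split.split_config, indent=2))


def load_split(directory: str | Path) -> SplitDataset:
    d = Path(directory)
    return SplitDataset(
        train=load_windows(d / "train.npz"),
        val=load_windows(d / "val.npz"),
        test=load_windows(d / "test.npz"),
        split_config=json.loads((d / "split_config.json").read_text()),
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


def spec_to_json(spec: ArchitectureSpec) -> str:
    return json.dumps(
        {
            "name": spec.name,
            "declared_param_count": spec.declared_param_count,
            "input_shape": list(spec.input_shape),
            "layers": [asdict(l) for l in spec.layers],
        },
        sort_keys=True,
    )


def spec_from_json(blob: str) -> ArchitectureSpec:
    d = json.loads(blob)
    layers = [
        LayerSpec(
            name=l["name"],
            kind=l["kind"],
            inputs=tuple(l["inputs"]),
            kernel=l["kernel"],
            filters=l["filters"],
            stride=l["stride"],
            dilation=l["dilation"],
            padding=l["padding"],
        )
        for l in d["layers"]
    ]
    return ArchitectureSpec(
        name=d["name"],
        layers=layers,
        declared_param_count=d["declared_param_count"],
        input_shape=tuple(d["input_shape"]),
    )


def spec_hash(spec: ArchitectureSpec) -> str:
    return hashlib.sha256(spec_to_json(spec).encode()).hexdigest()[:16]


def save_float_model(model: FloatModel, path: str | Path) -> None:
    payload = {"__spec__": np.array(spec_to_json(model.spec)), "__hash__": np.array(spec_hash(model.spec))}
    for name, wb in model.weights.items():
        payload[f"{name}__w"] = wb["w"]
        payload[f"{name}__b"] = wb["b"]
    np.savez_compressed(path, **payload)


def load_float_model(path: str | Path) -> FloatModel:
    with np.load(path, allow_pickle=False) as z:
        spec = spec_from_json(str(z["__spec__"]))
        if str(z["__hash__"]) != spec_hash(spec):  # pragma: no cover
            raise ValueError("model container hash mismatch")
        weights = {}
        for key in z.files:
            if key.endswith("__w"):
                name = key[: -len("__w")]
                weights[name] = {"w": z[key], "b": z[f"{name}__b"]}
    return FloatModel(spec=spec, weights=weights)  # validates shapes


# ---------------------------------------------------------------------------
# Quantized models
# ---------------------------------------------------------------------------


def save_quantized_model(qmodel, path: str | Path) -> None:
    from edgebp.quant import QuantizedModel  # local import avoids cycle

    assert isinstance(qmodel, QuantizedModel)
    meta = {
        "edges": {
            name: {"scale": float(np.asarray(qp.scale)), "zero_point": qp.zero_point}
            for name, qp in qmodel.edge_qp.items()
        },
        "fused_relus": sorted(qmodel.fused_relus),
        "layers": {
            name: {"zp_in": lq.zp_in, "zp_out": lq.zp_out, "fused_relu": lq.fused_relu}
            for name, lq in qmodel.layers.items()
        },
        "adds": {
            name: {
                "mant": list(aq.mant),
                "shift": list(aq.shift),
                "M": list(aq.M),
                "zp_in": list(aq.zp_in),
                "zp_out": aq.zp_out,
                "fused_relu": aq.fused_relu,
            }
            for name, aq in qmodel.adds.items()
        },
    }
    payload = {"__spec__": np.array(spec_to_json(qmodel.spec)), "__meta__": np.array(json.dumps(meta))}
    for name, lq in qmodel.layers.items():
        payload[f"{name}__wq"] = lq.w_q
        payload[f"{name}__bias"] = lq.bias_q
        payload[f"{name}__wscales"] = lq.w_scales
        payload[f"{name}__mant"] = lq.mant
        payload[f"{name}__shift"] = lq.shift
        payload[f"{name}__M"] = lq.M
    np.savez_compressed(path, **payload)


def load_quantized_model(path: str | Path):
    from edgebp.quant import AddQuant, LayerQuant, QuantizedModel, QuantParams

    with np.load(path, allow_pickle=False) as z:
        spec = spec_from_json(str(z["__spec__"]))
        meta = json.loads(str(z["__meta__"]))
        layers = {}
        weight_qp = {}
        for name, lm in meta["layers"].items():
            layers[name] = LayerQuant(
                w_q=z[f"{name}__wq"],
                w_scales=z[f"{name}__wscales"],
                bias_q=z[f"{name}__bias"],
                mant=z[f"{name}__mant"],
                shift=z[f"{name}__shift"],
                M=z[f"{name}__M"],
                zp_in=lm["zp_in"],
                zp_out=lm["zp_out"],
                fused_relu=lm["fused_relu"],
            )
            weight_qp[name] = QuantParams(
                scale=z[f"{name}__wscales"], granularity="per_channel", symmetric=True
            )
        adds = {
            name: AddQuant(
                mant=tuple(am["mant"]),
                shift=tuple(am["shift"]),
                M=tuple(am["M"]),
                zp_in=tuple(am["zp_in"]),
                zp_out=am["zp_out"],
                fused_relu=am["fused_relu"],
            )
            for name, am in meta["adds"].items()
        }
        edge_qp = {
            name: QuantParams(scale=e["scale"], zero_point=e["zero_point"])
            for name, e in meta["edges"].items()
        }
    return QuantizedModel(
        spec=spec,
        layers=layers,
        adds=adds,
        edge_qp=edge_qp,
        weight_qp=weight_qp,
        fused_relus=frozenset(meta["fused_relus"]),
    )


def save_windows_csv(ws: WindowSet, path: str | Path) -> None:
    """Plain-text export for small fixtures: label/provenance columns
    followed by the 1024 sample columns."""
    import pandas as pd

    cols = {
        "record_id": ws.record_id.astype(str),
        "start": ws.start,
        "sbp": ws.sbp,
        "dbp": ws.dbp,
    }
    df = pd.DataFrame(cols)
    vals = pd.DataFrame(ws.values, columns=[f"v{i}" for i in range(ws.values.shape[1])])
    pd.concat([df, vals], axis=1).to_csv(path, index=False)


def load_windows_csv(path: str | Path) -> WindowSet:
    import pandas as pd

    df = pd.read_csv(path)
    vcols = [c for c in df.columns if c.startswith("v")]
    return WindowSet(
        values=df[vcols].to_numpy(dtype=np.float64),
        sbp=df["sbp"].to_numpy(),
        dbp=df["dbp"].to_numpy(),
        record_id=df["record_id"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
    )
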