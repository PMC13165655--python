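"""End-to-end benchmark orchestration.

Three stages, mirroring a quantization-aware model-selection methodology:

1. float comparison — synthesize the cohort, preprocess, train every listed
   architecture, evaluate floating-point error statistics on the test split;
2. quantization robustness — full-integer INT8 conversion of the selected
   candidates (representative calibration from the training split),
   INT8 evaluation, FP32-vs-INT8 consistency and drift;
3. deployment feasibility — analytic footprint plus duty-cycle arithmetic
   for a user-supplied inference latency (latency is an *input*, not a
   measurement).

Every artifact is written under a run directory with a manifest carrying
the config hash and seeds, so a run is fully determined by (config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from edgebp import io as eio
from edgebp.cohort import CohortSpec, generate_cohort
from edgebp.footprint import FootprintReport
from edgebp.metrics import (
    AAMI_DISCLAIMER,
    aami_reference_check,
    drift_report,
    error_stats,
    physiological_check,
    signed_errors,
)
from edgebp.nn import predict
from edgebp.preprocess import assemble_splits, preprocess_records
from edgebp.quant import calibrate, predict_int8, quantize_model
from edgebp.training import TrainConfig, default_config, fast_profile, train_model
from edgebp.zoo import reference_architecture

log = logging.getLogger(__name__)

DEFAULT_QUANT_CANDIDATES = ("baseline_cnn", "residual_cnn_slim")


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    architectures: Sequence[str] = DEFAULT_QUANT_CANDIDATES
    quantize_architectures: Sequence[str] = DEFAULT_QUANT_CANDIDATES
    train_overrides: dict = field(default_factory=dict)  # name -> TrainConfig
    profile: str = "default"  # {default, fast}
    calibration_size: int = 512
    min_samples: Optional[int] = None  # None -> the 8-minute default
    latency_ms: float = 165.8  # documented example value for feasibility
    split_seed: int = 0
    output_dir: str = "runs/bench"

    def train_config(self, name: str) -> TrainConfig:
        if name in self.train_overrides:
            return self.train_overrides[name]
        return fast_profile(name) if self.profile == "fast" else default_config(name)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def evaluate_predictions(ref_sbp, ref_dbp, preds) -> dict:
    """Per-target error statistics + reference flags for one model/precision."""
    out = {}
    for i, target in enumerate(("SBP", "DBP")):
        ref = ref_sbp if target == "SBP" else ref_dbp
        st = error_stats(signed_errors(ref, preds[:, i]), target=target)
        me_pass, sd_pass = aami_reference_check(st)
        out[target] = {"stats": st, "me_pass": me_pass, "sd_pass": sd_pass}
    out["constraint_violations"] = physiological_check(preds)
    return out


def _stats_row(model_name, precision, ev, n):
    rows = []
    for target in ("SBP", "DBP"):
        st = ev[target]["stats"]
        rows.append(
            {
                "model": model_name,
                "precision": precision,
                "target": target,
                "n": n,
                "me_mmHg": st.me,
                "sd_mmHg": st.sd,
                "mae_mmHg": st.mae,
                "me_within_5": ev[target]["me_pass"],
                "sd_below_8": ev[target]["sd_pass"],
                "constraint_violations": ev["constraint_violations"],
            }
        )
    return rows


def _histogram_table(name: str, values: np.ndarray, bins: int = 40) -> pd.DataFrame:
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame(
        {"series": name, "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def run_benchmark(config: RunConfig) -> dict:
    """Execute the three-stage benchmark; returns the report dictionary.

    Artifacts (metric tables, histogram data, manifest) are written under
    ``config.output_dir``. Any stage failure aborts with the stage name;
    artifacts produced so far stay on disk.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "cohort_seed": config.cohort.seed,
        "split_seed": config.split_seed,
        "profile": config.profile,
        "stages": [],
    }
    report: dict = {"models": {}}
    stage = "synthesize"
    try:
        t0 = time.time()
        records = generate_cohort(config.cohort)
        min_samples = (
            config.min_samples
            if config.min_samples is not None
            else 60_000
        )
        stage = "preprocess"
        windows = preprocess_records(records, min_samples=min_samples)
        split = assemble_splits(windows, split_seed=config.split_seed)
        manifest["n_windows"] = {
            "train": len(split.train),
            "val": len(split.val),
            "test": len(split.test),
        }
        manifest["stages"].append({"name": "preprocess", "seconds": round(time.time() - t0, 2)})

        ref_sbp, ref_dbp = split.test.sbp, split.test.dbp
        float_rows, int8_rows, drift_rows, consistency_rows, foot_rows = [], [], [], [], []

        for name in config.architectures:
            stage = f"train:{name}"
            t0 = time.time()
            spec = reference_architecture(name)
            result = train_model(spec, split, config.train_config(name))
            preds_f = predict(result.model, split.test.values)
            ev_f = evaluate_predictions(ref_sbp, ref_dbp, preds_f)
            float_rows += _stats_row(name, "fp32", ev_f, len(split.test))
            report["models"][name] = {
                "float": ev_f,
                "float_preds": preds_f,
                "model": result.model,
                "stopped_epoch": result.stopped_epoch,
            }
            eio.save_float_model(result.model, out_dir / f"{name}_fp32.npz")
            pd.DataFrame(result.history).to_csv(out_dir / f"{name}_history.csv", index=False)
            manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 2)})

        stage = "quantize"
        rng_cal = np.random.default_rng(config.cohort.seed + 1)
        cal_size = min(config.calibration_size, len(split.train))
        cal_idx = rng_cal.choice(len(split.train), size=cal_size, replace=False)
        for name in config.quantize_architectures:
            if name not in report["models"]:
                raise RuntimeError(f"{name} selected for quantization but not trained")
            t0 = time.time()
            entry = report["models"][name]
            stats = calibrate(entry["model"], split.train.values[cal_idx])
            qmodel = quantize_model(entry["model"], stats)
            preds_q = predict_int8(qmodel, split.test.values)
            ev_q = evaluate_predictions(ref_sbp, ref_dbp, preds_q)
            int8_rows += _stats_row(name, "int8", ev_q, len(split.test))
            drift = drift_report(
                {t: entry["float"][t]["stats"] for t in ("SBP", "DBP")},
                {t: ev_q[t]["stats"] for t in ("SBP", "DBP")},
                entry["float_preds"],
                preds_q,
            )
            entry.update({"int8": ev_q, "int8_preds": preds_q, "drift": drift, "qmodel": qmodel})
            eio.save_quantized_model(qmodel, out_dir / f"{name}_int8.npz")
            for t in ("SBP", "DBP"):
                drift_rows.append(
                    {"model": name, "target": t, **{f"d_{k}": v for k, v in drift["deltas"][t].items()}}
                )
            c = drift["consistency"]
            consistency_rows.append(
                {
                    "model": name,
                    "pearson_sbp": c.pearson_sbp,
                    "pearson_dbp": c.pearson_dbp,
                    "max_abs_delta_mmHg": c.max_abs_delta,
                }
            )
            foot = FootprintReport.build(qmodel, config.latency_ms)
            entry["footprint"] = foot
            foot_rows.append({"model": name, **asdict(foot)})
            manifest["stages"].append({"name": f"quantize:{name}", "seconds": round(time.time() - t0, 2)})

        stage = "report"
        pd.DataFrame(float_rows).to_csv(out_dir / "float_metrics.csv", index=False)
        if int8_rows:
            pd.DataFrame(int8_rows).to_csv(out_dir / "int8_metrics.csv", index=False)
            pd.DataFrame(drift_rows).to_csv(out_dir / "drift.csv", index=False)
            pd.DataFrame(consistency_rows).to_csv(out_dir / "consistency.csv", index=False)
            pd.DataFrame(foot_rows).to_csv(out_dir / "footprint.csv", index=False)

        # Underlying data of the distribution figures: true vs predicted and
        # error histograms for each trained model.
        hist_parts = [
            _histogram_table("true_sbp", ref_sbp),
            _histogram_table("true_dbp", ref_dbp),
        ]
        for name, entry in report["models"].items():
            hist_parts.append(_histogram_table(f"{name}_pred_sbp", entry["float_preds"][:, 0]))
            hist_parts.append(_histogram_table(f"{name}_pred_dbp", entry["float_preds"][:, 1]))
            hist_parts.append(
                _histogram_table(f"{name}_err_sbp", ref_sbp - entry["float_preds"][:, 0])
            )
            hist_parts.append(
                _histogram_table(f"{name}_err_dbp", ref_dbp - entry["float_preds"][:, 1])
            )
        pd.concat(hist_parts).to_csv(out_dir / "histograms.csv", index=False)
        manifest["disclaimer"] = AAMI_DISCLAIMER
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"benchmark failed in stage {stage!r}: {exc}") from exc

    report["manifest"] = manifest
    report["split"] = split
    return report
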