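"""Error statistics, consistency analysis and reference checks.

Sign convention: the signed error is reference minus estimate,
e_i = P_i^ref - P_i^est. ME is the mean signed error (bias), SD the sample
standard deviation of the signed errors (n-1 denominator), MAE the mean
absolute error; all in mmHg.

|ME| <= 5 mmHg and SD < 8 mmHg are commonly adopted *reference benchmarks*
for retrospective, window-level comparison in the cuffless-BP literature.
They are advisory labels here, not clinical validation: the formal
AAMI/ESH/ISO protocol is subject-level and prospective, which this package
does not simulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

AAMI_DISCLAIMER = (
    "Reference benchmarks (|ME| <= 5 mmHg, SD < 8 mmHg) for retrospective "
    "comparison only; not evidence of clinical validation or AAMI/ESH/ISO "
    "compliance."
)


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorStats:
    target: str  # "SBP" or "DBP"
    n: int
    me: float
    sd: float
    mae: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise MetricError("error statistics need n >= 2")
        if self.sd < 0:
            raise MetricError("sd must be non-negative")
        if self.mae + 1e-12 < abs(self.me):
            raise MetricError("mae >= |me| violated")


@dataclass(frozen=True)
class ConsistencyReport:
    pearson_sbp: float
    pearson_dbp: float
    max_abs_delta: float
    deltas: np.ndarray = field(repr=False, default=None)


def signed_errors(ref: Sequence[float], est: Sequence[float]) -> np.ndarray:
    """e_i = ref_i - est_i (reference minus estimate)."""
    r = np.asarray(ref, dtype=np.float64)
    e = np.asarray(est, dtype=np.float64)
    if r.shape != e.shape or r.size < 1:
        raise MetricError("ref and est must have equal, non-zero length")
    return r - e


def error_stats(e: Sequence[float], target: str = "SBP") -> ErrorStats:
    """ME / SD / MAE of a signed-error sample (SD uses n-1)."""
    e = np.asarray(e, dtype=np.float64)
    if e.size < 2:
        raise MetricError("need at least two errors")
    return ErrorStats(
        target=target,
        n=int(e.size),
        me=float(e.mean()),
        sd=float(e.std(ddof=1)),
        mae=float(np.abs(e).mean()),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient between two prediction series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise MetricError("pearson needs two equal-length series, n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    if den == 0:
        raise MetricError("pearson undefined for constant input")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def aami_reference_check(stats: ErrorStats) -> tuple[bool, bool]:
    """(me_pass, sd_pass): |ME| <= 5 mmHg (inclusive), SD < 8 mmHg (strict)."""
    return (abs(stats.me) <= 5.0, stats.sd < 8.0)


def physiological_check(predictions: np.ndarray) -> int:
    """Count (sbp_est, dbp_est) pairs violating DBP <= SBP."""
    p = np.atleast_2d(np.asarray(predictions, dtype=np.float64))
    if p.shape[1] != 2:
        raise MetricError("predictions must be (n, 2) pairs (sbp, dbp)")
    return int((p[:, 1] > p[:, 0]).sum())


def drift_report(
    float_stats: dict[str, ErrorStats],
    int8_stats: dict[str, ErrorStats],
    float_preds: np.ndarray,
    int8_preds: np.ndarray,
) -> dict:
    """Quantization-drift fragment: INT8-minus-float deltas + consistency.

    ``float_stats``/``int8_stats`` map target name ("SBP"/"DBP") to
    ErrorStats computed on the *same* evaluation windows; ``*_preds`` are
    the matching (n, 2) prediction arrays.
    """
    fp = np.asarray(float_preds, dtype=np.float64)
    qp = np.asarray(int8_preds, dtype=np.float64)
    if fp.shape != qp.shape:
        raise MetricError("window-set mismatch between float and INT8 predictions")
    for t in ("SBP", "DBP"):
        if float_stats[t].n != int8_stats[t].n:
            raise MetricError("window-set mismatch between float and INT8 stats")
    deltas = {
        t: {
            "me": int8_stats[t].me - float_stats[t].me,
            "sd": int8_stats[t].sd - float_stats[t].sd,
            "mae": int8_stats[t].mae - float_stats[t].mae,
        }
        for t in ("SBP", "DBP")
    }
    diff = qp - fp
    consistency = ConsistencyReport(
        pearson_sbp=pearson(fp[:, 0], qp[:, 0]),
        pearson_dbp=pearson(fp[:, 1], qp[:, 1]),
        max_abs_delta=float(np.abs(diff).max()) if diff.size else 0.0,
        deltas=diff,
    )
    return {"deltas": deltas, "consistency": consistency, "disclaimer": AAMI_DISCLAIMER}
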