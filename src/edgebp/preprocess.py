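"""Signal conditioning, windowing and split protocol.

Pipeline: record selection (duration / pressure-excursion / channel
validity), per-record linear detrend of the PPG, per-record min-max
normalization to [0, 1], segmentation into 1024-sample (8.192 s at 125 Hz)
windows with 75% overlap (hop 256), per-window SBP/DBP labels taken as the
ABP maximum/minimum over the window, then a window-level random 70/30
train/test partition, removal of test windows whose PPG vectors are
value-identical to a training-pool window, and an 80/20 train/val split with
a fixed shuffle seed of 42.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from edgebp.cohort import FS, Record

log = logging.getLogger(__name__)

WINDOW_SAMPLES = 1024
HOP = 256  # 25% of the window: 75% overlap
MIN_SAMPLES = 8 * 60 * FS  # eight-minute retention boundary: 60,000 samples
ABP_MAX_MMHG = 200.0


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """Columnar container of labeled PPG windows.

    values: (n, 1024) float array, each row min-max normalized per record;
    sbp/dbp: labels in mmHg; record_id and start document provenance
    (0-based start index, half-open [start, start+1024) slice).
    """

    values: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    record_id: np.ndarray
    start: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        n = self.values.shape[0]
        for name in ("sbp", "dbp", "record_id", "start"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise PreprocessError(f"{name} misaligned with values")
            setattr(self, name, arr)
        if n and self.values.shape[1] != WINDOW_SAMPLES:
            raise PreprocessError(f"windows must have {WINDOW_SAMPLES} samples")
        if n and np.any(self.dbp > self.sbp):
            raise PreprocessError("dbp label above sbp label")

    def __len__(self) -> int:
        return self.values.shape[0]

    def take(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.values[idx], self.sbp[idx], self.dbp[idx], self.record_id[idx], self.start[idx]
        )

    @staticmethod
    def concatenate(parts: Sequence["WindowSet"]) -> "WindowSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return empty_window_set()
        return WindowSet(
            np.vstack([p.values for p in parts]),
            np.concatenate([p.sbp for p in parts]),
            np.concatenate([p.dbp for p in parts]),
            np.concatenate([p.record_id for p in parts]),
            np.concatenate([p.start for p in parts]),
        )


def empty_window_set() -> WindowSet:
    return WindowSet(
        np.empty((0, WINDOW_SAMPLES)),
        np.empty(0),
        np.empty(0),
        np.empty(0, dtype=object),
        np.empty(0, dtype=np.int64),
    )


@dataclass
class SplitDataset:
    train: WindowSet
    val: WindowSet
    test: WindowSet
    split_config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Record selection
# ---------------------------------------------------------------------------


def select_records(
    records: Iterable[Record],
    min_samples: int = MIN_SAMPLES,
    abp_max: float = ABP_MAX_MMHG,
) -> tuple[list[Record], list[tuple[Record, str]]]:
    """Apply the retention rules; returns (kept, rejected_with_reasons).

    A record is kept iff it is at least ``min_samples`` long, its ABP never
    exceeds ``abp_max`` mmHg (strictly), and both channels are finite and
    non-constant ("valid channel").
    """
    kept: list[Record] = []
    rejected: list[tuple[Record, str]] = []
    for rec in records:
        if len(rec) < min_samples:
            rejected.append((rec, f"too short ({len(rec)} < {min_samples} samples)"))
        elif not (np.isfinite(rec.ppg).all() and np.isfinite(rec.abp).all()):
            rejected.append((rec, "non-finite samples"))
        elif rec.ppg.max() == rec.ppg.min() or rec.abp.max() == rec.abp.min():
            rejected.append((rec, "constant channel"))
        elif rec.abp.max() > abp_max:
            rejected.append((rec, f"ABP peak {rec.abp.max():.2f} above {abp_max:g} mmHg"))
        else:
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------


def detrend_ppg(ppg: np.ndarray, method: str = "linear", window_s: float = 2.0) -> np.ndarray:
    """Remove baseline trend from the PPG over the full record.

    Default is least-squares removal of the best-fit line. A moving-average
    high-pass alternative is available as ``method="moving_average"``.
    """
    x = np.asarray(ppg, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise PreprocessError("detrend requires a 1-D series with >= 2 samples")
    if not np.isfinite(x).all():
        raise PreprocessError("non-finite samples")
    if x.max() == x.min():
        raise PreprocessError("constant channel cannot be detrended")
    if method == "linear":
        t = np.arange(x.size, dtype=np.float64)
        # Least-squares line fit via centered closed form (numerically stable).
        tc = t - t.mean()
        slope = float(tc @ (x - x.mean())) / float(tc @ tc)
        return x - (x.mean() + slope * tc)
    if method == "moving_average":
        w = max(int(round(window_s * FS)), 3)
        pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
        baseline = np.convolve(pad, np.ones(w) / w, mode="valid")
        return x - baseline
    raise PreprocessError(f"unknown detrend method {method!r}")


def normalize_minmax(ppg: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; constant input is a degenerate record."""
    x = np.asarray(ppg, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if not np.isfinite([lo, hi]).all() or hi == lo:
        raise PreprocessError("degenerate record: constant or non-finite PPG")
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_record(record: Record, ppg_conditioned: np.ndarray | None = None) -> WindowSet:
    """Cut a (conditioned) record into labeled 1024-sample windows.

    Start indices run 0, 256, 512, ... while start + 1024 <= N, giving
    floor((N - 1024)/256) + 1 windows; each window is labeled with the ABP
    max (SBP) and min (DBP) over its half-open slice. Records shorter than
    one window yield an empty set (logged).
    """
    ppg = ppg_conditioned if ppg_conditioned is not None else record.ppg
    ppg = np.asarray(ppg, dtype=np.float64)
    n = ppg.size
    if n != len(record):
        raise PreprocessError("conditioned PPG misaligned with record")
    if n < WINDOW_SAMPLES:
        log.info("record %s shorter than one window (%d samples); skipped", record.record_id, n)
        return empty_window_set()
    n_win = (n - WINDOW_SAMPLES) // HOP + 1
    idx = np.arange(n_win) * HOP
    wins = np.lib.stride_tricks.sliding_window_view(ppg, WINDOW_SAMPLES)[idx]
    abp_wins = np.lib.stride_tricks.sliding_window_view(record.abp, WINDOW_SAMPLES)[idx]
    return WindowSet(
        values=wins.copy(),
        sbp=abp_wins.max(axis=1),
        dbp=abp_wins.min(axis=1),
        record_id=np.full(n_win, record.record_id, dtype=object),
        start=idx.astype(np.int64),
    )


def preprocess_records(
    records: Sequence[Record],
    detrend_method: str = "linear",
    min_samples: int = MIN_SAMPLES,
    abp_max: float = ABP_MAX_MMHG,
) -> WindowSet:
    """Full conditioning chain: select, detrend, normalize, segment."""
    kept, rejected = select_records(records, min_samples=min_samples, abp_max=abp_max)
    for rec, reason in rejected:
        log.info("rejected %s: %s", rec.record_id, reason)
    parts = []
    for rec in kept:
        cond = normalize_minmax(detrend_ppg(rec.ppg, method=detrend_method))
        parts.append(segment_record(rec, cond))
    return WindowSet.concatenate(parts)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _dedup_against(test: WindowSet, pool: WindowSet) -> tuple[WindowSet, int]:
    """Drop test windows whose value vectors appear bitwise in the pool."""
    pool_keys = {row.tobytes() for row in np.ascontiguousarray(pool.values)}
    keep = np.array(
        [row.tobytes() not in pool_keys for row in np.ascontiguousarray(test.values)], dtype=bool
    )
    return test.take(keep), int((~keep).sum())


def assemble_splits(
    windows: WindowSet,
    test_fraction: float = 0.30,
    val_fraction: float = 0.20,
    split_seed: int = 0,
    val_seed: int = 42,
    subject_wise: bool = False,
) -> SplitDataset:
    """Window-level random 70/30 partition, cross-split dedup, 80/20 val.

    Counts use round-half-up on fraction * n (ties round up), matching the
    documented rounding rule. Duplicated windows are removed from the *test*
    side only, preserving training-set size semantics. The default split is
    window-level random (the leakage-prone protocol of the emulated study);
    ``subject_wise=True`` instead assigns whole records to sides.
    """
    if not (0 < test_fraction < 1 and 0 < val_fraction < 1):
        raise PreprocessError("fractions must lie in (0, 1)")
    n = len(windows)
    if n < 10:
        raise PreprocessError("need at least 10 windows to split")

    rng = np.random.default_rng(split_seed)
    if subject_wise:
        recs = np.unique(windows.record_id.astype(str))
        rng.shuffle(recs)
        n_test_rec = max(_round_half_up(test_fraction * recs.size), 1)
        test_recs = set(recs[:n_test_rec])
        in_test = np.array([r in test_recs for r in windows.record_id.astype(str)])
        test = windows.take(np.where(in_test)[0])
        pool = windows.take(np.where(~in_test)[0])
    else:
        order = rng.permutation(n)
        n_test = _round_half_up(test_fraction * n)
        test = windows.take(order[:n_test])
        pool = windows.take(order[n_test:])

    test, n_removed = _dedup_against(test, pool)

    vrng = np.random.default_rng(val_seed)
    vorder = vrng.permutation(len(pool))
    n_val = _round_half_up(val_fraction * len(pool))
    val = pool.take(vorder[:n_val])
    train = pool.take(vorder[n_val:])

    return SplitDataset(
        train=train,
        val=val,
        test=test,
        split_config={
            "test_fraction": test_fraction,
            "val_fraction": val_fraction,
            "split_seed": split_seed,
            "val_seed": val_seed,
            "subject_wise": subject_wise,
            "n_dedup_removed": n_removed,
        },
    )
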