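"""Conditioning pipeline: selection boundaries, detrend, windowing, splits."""

import numpy as np
import pytest
from edgebp.cohort import Record
from edgebp.preprocess import (
    HOP,
    WINDOW_SAMPLES,
    PreprocessError,
    WindowSet,
    assemble_splits,
    detrend_ppg,
    normalize_minmax,
    preprocess_records,
    segment_record,
    select_records,
)


def _record(n, rid="r0", abp_level=100.0, abp_peak=None):
    rng = np.random.default_rng(3)
    ppg = rng.uniform(0, 1, n)
    abp = np.full(n, abp_level) + rng.uniform(-1, 1, n)
    if abp_peak is not None:
        abp[n // 2] = abp_peak
    return Record(record_id=rid, ppg=ppg, abp=abp)


class TestSelection:
    def test_duration_boundary_is_60000_samples(self):
        kept, rejected = select_records([_record(59_999), _record(60_000, "r1")])
        assert [r.record_id for r in kept] == ["r1"]
        assert "too short" in rejected[0][1]

    def test_abp_exclusion_is_strict_above_200(self):
        ok = _record(60_000, "ok", abp_peak=200.0)
        bad = _record(60_000, "bad", abp_peak=200.01)
        kept, rejected = select_records([ok, bad])
        assert [r.record_id for r in kept] == ["ok"]
        assert "200" in rejected[0][1]

    def test_constant_channel_rejected(self):
        r = _record(60_000)
        r.ppg = np.zeros(60_000)
        kept, rejected = select_records([r])
        assert not kept and "constant" in rejected[0][1]

    def test_empty_input_yields_empty_output(self):
        assert select_records([]) == ([], [])


class TestDetrend:
    def test_pure_line_removed_to_zero(self):
        t = np.arange(500, dtype=float)
        assert np.abs(detrend_ppg(3.0 + 0.25 * t)).max() < 1e-9

    def test_zero_trend_sinusoid_unchanged(self):
        # whole periods, even-symmetric about the midpoint: exactly
        # orthogonal to both the constant and the linear term
        t = np.arange(1000)
        x = np.cos(2 * np.pi * (t - 499.5) / 125.0)
        assert np.abs(detrend_ppg(x) - x).max() < 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        t = np.arange(2000, dtype=float)
        x = np.sin(2 * np.pi * t / 90.0) + 0.01 * t + rng.normal(0, 0.1, t.size)
        # independent least-squares residual via the normal equations
        A = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(A.T @ A, A.T @ x)
        assert np.allclose(detrend_ppg(x), x - A @ beta, atol=1e-9)

    def test_constant_input_errors(self):
        with pytest.raises(PreprocessError):
            detrend_ppg(np.full(100, 2.0))


class TestNormalize:
    def test_hand_example(self):
        assert np.allclose(normalize_minmax(np.array([-1.0, 0.0, 1.0])), [0, 0.5, 1])

    def test_idempotent_iff_endpoints_attained(self, rng):
        x = rng.uniform(0, 1, 100)
        x[0], x[1] = 0.0, 1.0
        assert np.array_equal(normalize_minmax(x), x)

    def test_endpoints_exact(self, rng):
        y = normalize_minmax(rng.normal(0, 5, 1000))
        assert y.min() == 0.0 and y.max() == 1.0


class TestSegmentation:
    @pytest.mark.parametrize(
        "n,expected_starts",
        [
            (1024, [0]),
            (2048, [0, 256, 512, 768, 1024]),
            (1023, []),
            (1300, [0, 256]),
        ],
    )
    def test_window_starts(self, n, expected_starts):
        ws = segment_record(_record(n))
        assert list(ws.start) == expected_starts
        assert len(ws) == max((n - WINDOW_SAMPLES) // HOP + 1, 0) if n >= 1024 else len(ws) == 0

    def test_constant_abp_labels(self):
        r = _record(2048)
        r.abp = np.full(2048, 100.0)
        ws = segment_record(r)
        assert np.all(ws.sbp == 100.0) and np.all(ws.dbp == 100.0)

    def test_labels_are_slice_extrema(self):
        r = _record(4096)
        ws = segment_record(r)
        for i in range(len(ws)):
            s = slice(ws.start[i], ws.start[i] + WINDOW_SAMPLES)
            assert ws.sbp[i] == r.abp[s].max()
            assert ws.dbp[i] == r.abp[s].min()

    def test_conservation_over_cohort(self, small_cohort, small_windows):
        spec, records = small_cohort
        expected = sum((len(r) - WINDOW_SAMPLES) // HOP + 1 for r in records)
        assert len(small_windows) == expected


class TestSplits:
    def _windows(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return WindowSet(
            values=rng.uniform(0, 1, (n, WINDOW_SAMPLES)),
            sbp=rng.uniform(100, 180, n),
            dbp=rng.uniform(50, 90, n),
            record_id=np.array([f"r{i}" for i in range(n)], dtype=object),
            start=np.zeros(n, dtype=np.int64),
        )

    def test_ten_windows_documented_rounding(self):
        split = assemble_splits(self._windows(10), split_seed=1)
        assert len(split.test) == 3  # round(3.0)
        assert len(split.val) == 1  # round(1.4) -> 1, nearest with ties up
        assert len(split.train) == 6

    def test_duplicate_removed_from_test_side(self):
        ws = self._windows(20)
        ws.values[0] = ws.values[1]  # identical vector pair
        seen_removal = False
        for seed in range(20):
            split = assemble_splits(ws, split_seed=seed)
            # postcondition: no test vector has a bitwise twin in train+val
            pool_keys = {
                row.tobytes() for row in np.vstack([split.train.values, split.val.values])
            }
            assert all(row.tobytes() not in pool_keys for row in split.test.values)
            # the training side is never shrunk by dedup
            assert len(split.train) + len(split.val) + len(split.test) + split.split_config[
                "n_dedup_removed"
            ] == len(ws)
            seen_removal |= split.split_config["n_dedup_removed"] > 0
        assert seen_removal  # some split separated the twins and removed one

    def test_split_membership_is_deterministic(self):
        ws = self._windows(57)
        a = assemble_splits(ws, split_seed=9)
        b = assemble_splits(ws, split_seed=9)
        for part in ("train", "val", "test"):
            assert np.array_equal(getattr(a, part).values, getattr(b, part).values)

    def test_sets_are_disjoint(self):
        split = assemble_splits(self._windows(60), split_seed=2)
        keys = [
            {row.tobytes() for row in getattr(split, p).values} for p in ("train", "val", "test")
        ]
        assert not (keys[0] & keys[1]) and not (keys[0] & keys[2]) and not (keys[1] & keys[2])

    def test_val_ratio_near_20_percent(self):
        split = assemble_splits(self._windows(200), split_seed=3)
        ratio = len(split.val) / (len(split.train) + len(split.val))
        assert abs(ratio - 0.20) < 0.01

    def test_bad_fractions_rejected(self):
        with pytest.raises(PreprocessError):
            assemble_splits(self._windows(20), test_fraction=1.5)


class TestZeroNoiseLabelExactness:
    def test_window_labels_equal_generator_ground_truth(self):
        from edgebp.cohort import CohortSpec, Distribution, generate_cohort

        spec = CohortSpec(
            n_records=2,
            duration_s=60.0,
            sbp_distribution=Distribution(kind="point", loc=140.0),
            dbp_distribution=Distribution(kind="point", loc=70.0),
            noise_sd=0.0,
            wander_amplitude=0.0,
            drift_amplitude_mmHg=0.0,
            seed=2,
        )
        windows = preprocess_records(generate_cohort(spec), min_samples=int(60 * 125))
        assert np.all(windows.sbp == 140.0)
        assert np.all(windows.dbp == 70.0)
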