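"""Synthetic paired PPG + arterial-pressure cohort generation.

Each record holds two aligned channels sampled at 125 Hz: an arterial blood
pressure (ABP) waveform in mmHg and a photoplethysmogram (PPG) in arbitrary
units. Beats are built from a two-lobe additive pulse shape (systolic lobe
plus dicrotic lobe) rescaled per beat so that the ABP minimum and maximum
equal the diastolic and systolic targets *exactly*; downstream window labels
therefore have known ground truth by construction, independent of how
realistic the morphology is.

Because the downstream pipeline min-max normalizes the PPG per record,
absolute PPG amplitude carries no information. The generator instead couples
beat *morphology* (systolic upstroke width, dicrotic-wave amplitude and
delay, heart rate) deterministically to the per-beat pressure targets, so
that a waveform-to-pressure regression task is well posed on the synthetic
data. This coupling is a stated modeling assumption, not a physiological
inference; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

FS = 125  # Hz, fixed sampling rate of both channels

# Population support and median targets (mmHg) the cohort emulates.
SBP_LOW, SBP_HIGH, SBP_MEDIAN = 78.25, 199.87, 139.01
DBP_LOW, DBP_HIGH, DBP_MEDIAN = 50.00, 158.02, 61.49

_MAX_REJECTION_ROUNDS = 1000


class CohortError(ValueError):
    """Invalid cohort specification or unsatisfiable sampling constraints."""


# ---------------------------------------------------------------------------
# Population distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Distribution:
    """Truncated location-scale law for population pressure targets.

    kind:
      - "truncnorm": normal(loc, scale) truncated to [low, high]
      - "shifted_lognormal": low + LogNormal(mu, sigma), truncated to
        [low, high]; right-skewed by construction
      - "point": degenerate point mass at ``loc``
    """

    kind: str
    loc: float = 0.0
    scale: float = 1.0
    mu: float = 0.0
    sigma: float = 1.0
    low: float = -np.inf
    high: float = np.inf

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, float(self.loc))
        if self.kind == "truncnorm":
            a = (self.low - self.loc) / self.scale
            b = (self.high - self.loc) / self.scale
            return np.asarray(
                spstats.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale, size=n, random_state=rng)
            )
        if self.kind == "shifted_lognormal":
            out = np.empty(n)
            filled = 0
            for _ in range(_MAX_REJECTION_ROUNDS):
                need = n - filled
                if need == 0:
                    break
                draw = self.low + rng.lognormal(self.mu, self.sigma, size=2 * need)
                draw = draw[(draw >= self.low) & (draw <= self.high)][:need]
                out[filled : filled + draw.size] = draw
                filled += draw.size
            else:  # pragma: no cover - pathological truncation
                raise CohortError("lognormal truncation rejection cap exceeded")
            return out
        raise CohortError(f"unknown distribution kind {self.kind!r}")


def default_sbp_distribution() -> Distribution:
    """Truncated normal on [78.25, 199.87] mmHg centred on the median target."""
    return Distribution(kind="truncnorm", loc=SBP_MEDIAN, scale=24.0, low=SBP_LOW, high=SBP_HIGH)


def default_dbp_distribution() -> Distribution:
    """Shifted log-normal on [50.00, 158.02] mmHg, median ~61.5, right-skewed.

    50 + LogNormal(mu, sigma) has median 50 + e^mu; mu = ln(61.49 - 50)
    puts the untruncated median on target, and the upper truncation at
    158.02 barely moves it. sigma chosen once for a heavy 55-70 mmHg bulk
    with a long right tail.
    """
    return Distribution(
        kind="shifted_lognormal", mu=float(np.log(DBP_MEDIAN - DBP_LOW)), sigma=0.52, low=DBP_LOW, high=DBP_HIGH
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeatParams:
    """Parameters of one synthetic cardiac beat."""

    heart_rate_bpm: float
    sbp_target: float
    dbp_target: float
    systolic_width: float = 0.30  # s, FWHM of the systolic lobe
    dicrotic_amplitude: float = 0.25  # fraction of pulse pressure, in [0, 0.5]
    dicrotic_delay: float = 0.25  # s after the systolic peak
    ppg_lag: int = 25  # samples (0.2 s at 125 Hz)
    lowpass_cutoff: float = 8.0  # Hz, PPG smoothing cutoff

    def validate(self) -> None:
        vals = [
            self.heart_rate_bpm,
            self.sbp_target,
            self.dbp_target,
            self.systolic_width,
            self.dicrotic_amplitude,
            self.dicrotic_delay,
            self.lowpass_cutoff,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise CohortError("non-finite beat parameter")
        if not (40.0 <= self.heart_rate_bpm <= 180.0):
            raise CohortError(f"heart rate {self.heart_rate_bpm} outside [40, 180] bpm")
        if self.dbp_target >= self.sbp_target:
            raise CohortError("dbp_target must be < sbp_target")
        if not (0.0 <= self.dicrotic_amplitude <= 0.5):
            raise CohortError("dicrotic_amplitude outside [0, 0.5]")
        period = 60.0 / self.heart_rate_bpm
        if not (0 < self.systolic_width < period and 0 < self.dicrotic_delay < period):
            raise CohortError("beat widths/delays must be positive and shorter than one period")
        if self.ppg_lag < 0:
            raise CohortError("ppg_lag must be >= 0")


@dataclass
class Record:
    """One aligned PPG/ABP recording with optional per-beat ground truth.

    ``ground_truth`` rows are (beat peak time in s, realized SBP, realized
    DBP); the realized values are attained exactly by the noise-free ABP
    channel.
    """

    record_id: str
    ppg: np.ndarray
    abp: np.ndarray
    fs: int = FS
    ground_truth: Optional[np.ndarray] = None  # shape (n_beats, 3)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=np.float64)
        self.abp = np.asarray(self.abp, dtype=np.float64)
        if self.ppg.shape != self.abp.shape or self.ppg.ndim != 1:
            raise CohortError("ppg and abp must be aligned 1-D series")
        if self.fs != FS:
            raise CohortError(f"fs must be {FS} Hz")

    def __len__(self) -> int:
        return self.ppg.size


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_records: int = 100
    duration_s: float = 480.0
    sbp_distribution: Distribution = field(default_factory=default_sbp_distribution)
    dbp_distribution: Distribution = field(default_factory=default_dbp_distribution)
    noise_sd: float = 0.02  # white noise SD on the (unit-amplitude) PPG
    wander_amplitude: float = 0.05  # baseline wander amplitude on the PPG
    wander_freq_hz: float = 0.25
    drift_amplitude_mmHg: float = 5.0  # slow within-record SBP/DBP drift
    fraction_short: float = 0.0
    fraction_high_abp: float = 0.0
    seed: int = 42

    def validate(self) -> None:
        if self.n_records < 1 or self.duration_s <= 0:
            raise CohortError("n_records must be >= 1 and duration_s > 0")
        if not (0 <= self.fraction_short <= 1 and 0 <= self.fraction_high_abp <= 1):
            raise CohortError("fractions must lie in [0, 1]")
        if self.fraction_short + self.fraction_high_abp > 1:
            raise CohortError("fraction_short + fraction_high_abp must be <= 1")


# ---------------------------------------------------------------------------
# Target sampling
# ---------------------------------------------------------------------------


def sample_population_targets(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample per-record (SBP, DBP) targets under the population laws.

    Pairs violating DBP <= SBP - 10 mmHg are rejected and redrawn; a
    documented cap on rejection rounds guards against unsatisfiable specs.

    Returns an array of shape (n_records, 2).
    """
    spec.validate()
    n = spec.n_records
    sbp = spec.sbp_distribution.sample(n, rng)
    dbp = spec.dbp_distribution.sample(n, rng)
    bad = dbp > sbp - 10.0
    for _ in range(_MAX_REJECTION_ROUNDS):
        if not bad.any():
            break
        m = int(bad.sum())
        sbp[bad] = spec.sbp_distribution.sample(m, rng)
        dbp[bad] = spec.dbp_distribution.sample(m, rng)
        bad = dbp > sbp - 10.0
    else:
        raise CohortError("rejection cap exceeded: SBP/DBP laws incompatible with DBP <= SBP - 10")
    return np.column_stack([sbp, dbp])


# ---------------------------------------------------------------------------
# Beat synthesis
# ---------------------------------------------------------------------------


def _morphology_from_targets(sbp: float, dbp: float) -> dict:
    """Deterministic pressure -> morphology coupling (documented assumption).

    Higher systolic pressure gives a faster heart rate, a narrower systolic
    upstroke and a weaker dicrotic wave; the dicrotic delay encodes
    diastolic pressure. All knobs stay inside BeatParams' validity ranges.
    """
    hr = float(np.clip(55.0 + 0.28 * (sbp - SBP_LOW) + 0.18 * (dbp - DBP_LOW), 42.0, 175.0))
    width = float(np.clip(0.40 - 0.0013 * (sbp - SBP_LOW), 0.14, 0.45))
    dic_amp = float(np.clip(0.45 - 0.0030 * (sbp - SBP_LOW), 0.05, 0.5))
    dic_delay = float(np.clip(0.16 + 0.0012 * (dbp - DBP_LOW), 0.10, 0.30))
    return {
        "heart_rate_bpm": hr,
        "systolic_width": width,
        "dicrotic_amplitude": dic_amp,
        "dicrotic_delay": dic_delay,
    }


def synthesize_beat(params: BeatParams) -> tuple[np.ndarray, np.ndarray]:
    """Build one beat of ABP (mmHg) and PPG (unit amplitude).

    The ABP shape is g(t) = systolic Gaussian lobe + dicrotic Gaussian lobe,
    rescaled so min(g) = 0 and max(g) = 1; the beat then attains the
    diastolic and systolic targets exactly. The PPG is a low-pass-filtered
    (periodic extension, zero-phase), lag-shifted, [0, 1]-normalized copy.
    """
    params.validate()
    period = 60.0 / params.heart_rate_bpm
    n = max(int(round(period * FS)), 8)
    t = np.arange(n) / FS

    sd_main = params.systolic_width / 2.355  # FWHM -> Gaussian SD
    sd_dic = 1.2 * sd_main
    t_sys = 0.28 * period
    g = np.exp(-0.5 * ((t - t_sys) / sd_main) ** 2)
    if params.dicrotic_amplitude > 0:
        g = g + params.dicrotic_amplitude * np.exp(-0.5 * ((t - t_sys - params.dicrotic_delay) / sd_dic) ** 2)
    g = (g - g.min()) / (g.max() - g.min())
    abp = params.dbp_target + (params.sbp_target - params.dbp_target) * g

    # PPG: smooth the pulse shape, delay it, normalize the amplitude away.
    b, a = sps.butter(2, params.lowpass_cutoff / (FS / 2.0), btype="low")
    tiled = np.tile(g, 3)
    smooth = sps.filtfilt(b, a, tiled)[n : 2 * n]
    smooth = np.roll(smooth, params.ppg_lag % n)
    rng_amp = smooth.max() - smooth.min()
    ppg = (smooth - smooth.min()) / rng_amp if rng_amp > 0 else np.zeros_like(smooth)
    return abp, ppg


# ---------------------------------------------------------------------------
# Record and cohort generation
# ---------------------------------------------------------------------------


def generate_record(
    spec: CohortSpec,
    targets: tuple[float, float],
    duration_s: float,
    rng: np.random.Generator,
    record_id: str = "rec",
    high_abp_beat: bool = False,
) -> Record:
    """Generate one record around (sbp, dbp) targets.

    Beat-to-beat heart-rate jitter and a slow sinusoidal pressure drift are
    applied around the targets; baseline wander and white noise corrupt the
    PPG channel only, so the ABP channel (and hence the labels) stays exact.
    With ``high_abp_beat`` one mid-record beat's systolic target is raised
    above 200 mmHg to exercise the downstream exclusion rule.
    """
    if duration_s <= 0:
        raise CohortError("duration_s must be > 0")
    sbp0, dbp0 = float(targets[0]), float(targets[1])
    n_total = int(round(duration_s * FS))

    drift_freq = 0.01  # Hz; slow respiratory/vasomotor-scale modulation
    drift_phase = rng.uniform(0, 2 * np.pi)

    abp_parts: list[np.ndarray] = []
    ppg_parts: list[np.ndarray] = []
    gt_rows: list[tuple[float, float, float]] = []
    pos = 0
    beat_idx = 0
    gt_rows_high = False
    n_beats_est = max(int(duration_s * 3) + 4, 8)
    hr_jitter = rng.normal(0.0, 0.03, size=n_beats_est)
    while pos < n_total:
        t_now = pos / FS
        drift = spec.drift_amplitude_mmHg * np.sin(2 * np.pi * drift_freq * t_now + drift_phase)
        sbp_i = sbp0 + drift
        dbp_i = dbp0 + 0.5 * drift
        if dbp_i > sbp_i - 5.0:
            dbp_i = sbp_i - 5.0
        if high_abp_beat and pos >= n_total // 2 and not gt_rows_high:
            sbp_i = max(sbp_i, 205.0 + rng.uniform(0, 10))
            gt_rows_high = True
        morph = _morphology_from_targets(sbp_i, dbp_i)
        jit = hr_jitter[beat_idx % n_beats_est]
        hr_i = float(np.clip(morph["heart_rate_bpm"] * (1.0 + jit), 40.0, 180.0))
        params = BeatParams(
            heart_rate_bpm=hr_i,
            sbp_target=sbp_i,
            dbp_target=dbp_i,
            systolic_width=morph["systolic_width"],
            dicrotic_amplitude=morph["dicrotic_amplitude"],
            dicrotic_delay=morph["dicrotic_delay"],
        )
        abp_b, ppg_b = synthesize_beat(params)
        peak_t = (pos + int(np.argmax(abp_b))) / FS
        abp_parts.append(abp_b)
        ppg_parts.append(ppg_b)
        gt_rows.append((peak_t, sbp_i, dbp_i))
        pos += abp_b.size
        beat_idx += 1

    abp = np.concatenate(abp_parts)[:n_total]
    ppg = np.concatenate(ppg_parts)[:n_total]
    t = np.arange(n_total) / FS
    if spec.wander_amplitude > 0:
        ppg = ppg + spec.wander_amplitude * np.sin(2 * np.pi * spec.wander_freq_hz * t + rng.uniform(0, 2 * np.pi))
    if spec.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, spec.noise_sd, size=n_total)

    gt = np.array(gt_rows, dtype=np.float64)
    gt = gt[gt[:, 0] < duration_s]  # keep beats whose peak lies in the record
    return Record(record_id=record_id, ppg=ppg, abp=abp, ground_truth=gt)


def generate_cohort(spec: CohortSpec) -> list[Record]:
    """Generate a full cohort under ``spec``.

    Exactly round(fraction_short * n) records are shorter than the 8-minute
    retention boundary (60,000 samples) and exactly
    round(fraction_high_abp * n) records contain an ABP excursion above
    200 mmHg; injection is deterministic in count (rounding, not Bernoulli)
    so filter tests can assert exact counts. The remaining records pass the
    downstream selection rules.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_short = int(round(spec.fraction_short * n))
    n_high = int(round(spec.fraction_high_abp * n))
    if n_short + n_high > n:
        raise CohortError("rounded invalid-record counts exceed n_records")
    targets = sample_population_targets(spec, rng)

    records = []
    for i in range(n):
        short = i < n_short
        high = n_short <= i < n_short + n_high
        dur = min(spec.duration_s / 2.0, 240.0) if short else spec.duration_s
        if short and dur * FS >= 60_000:
            dur = 59_000 / FS
        # Keep normal records' own peaks under the 200 mmHg exclusion line.
        sbp_i, dbp_i = targets[i]
        if not high:
            sbp_cap = 199.0 - spec.drift_amplitude_mmHg
            if sbp_i > sbp_cap:
                sbp_i = sbp_cap
        rec = generate_record(
            spec,
            (sbp_i, dbp_i),
            dur,
            rng,
            record_id=f"synth-{i:04d}",
            high_abp_beat=high,
        )
        records.append(rec)
    return records
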