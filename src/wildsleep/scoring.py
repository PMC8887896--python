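"""Sleep-period detection and per-epoch sleep/wake classification.

The scoring unit is a noon-to-noon local day (1440 one-minute epochs), which
guarantees exactly one nocturnal sleep period per unit. Within a unit:

1. The classification threshold is the 10th percentile of the day's non-missing
   log VeDBA multiplied by 1.125.
2. A 9-minute centred rolling median smooths the log-VeDBA series; maximal runs
   of >=30 min below the threshold are sleep blocks; blocks separated by <=45
   min are merged; the longest merged period is the sleep period (SPT window),
   its ends giving sleep onset and awakening.
3. Independently, every epoch (inside and outside the SPT window) is labelled
   sleep when it sits in a run of >=3 consecutive epochs with raw log VeDBA
   below the threshold, otherwise wake.

Night metrics: total sleep time (sleep epochs within the SPT window), sleep
efficiency (TST / SPT duration), sleep fragmentation (wake bouts >=2 min,
separated by >=3 sleep epochs, per hour of sleep), and napping (sleep epochs
07:30-17:30). Days missing >=120 bursts are unusable for all metrics; days
with >=20 consecutive missing bursts lose SPT-derived metrics but keep
napping.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solar import TwilightTimes

SLEEP, WAKE, MISSING = 0, 1, -1

EPOCHS_PER_DAY = 1440


@dataclass(frozen=True)
class ScoringParams:
    """All tunable constants of the scoring algorithm."""

    percentile: float = 10.0
    threshold_multiplier: float = 1.125
    median_window_min: int = 9
    min_block_min: int = 30
    merge_gap_min: int = 45
    min_sleep_run: int = 3
    min_wake_bout_min: int = 2
    bout_separation_sleep_epochs: int = 3
    nap_start: dt.time = dt.time(7, 30)
    nap_end: dt.time = dt.time(17, 30)
    max_missing_per_day: int = 120
    max_consecutive_missing: int = 20
    min_valid_epochs: int = EPOCHS_PER_DAY - 120
    # When True, missing epochs break below-threshold runs in SPT detection.
    # Default bridges short gaps (the dedicated >=20-consecutive-missing QC rule
    # exists because only long gaps corrupt the window determination).
    spt_break_at_missing: bool = False


@dataclass(frozen=True)
class SptWindow:
    """One night's sleep period: onset to awakening."""

    onset: pd.Timestamp
    awakening: pd.Timestamp
    onset_idx: int
    end_idx: int  # exclusive epoch index within the noon-to-noon day

    @property
    def duration_min(self) -> int:
        return self.end_idx - self.onset_idx


def compute_threshold(
    log_vedba: np.ndarray, params: ScoringParams = ScoringParams()
) -> float | None:
    """Day-level classification threshold, or None when the day is unscorable.

    Linear-interpolation percentile over the non-missing epochs; the
    multiplier is applied literally (for a negative percentile it lowers the
    threshold — see docs).
    """
    vals = np.asarray(log_vedba, dtype=float)
    valid = vals[~np.isnan(vals)]
    if len(valid) < params.min_valid_epochs:
        return None
    q = float(np.percentile(valid, params.percentile))  # linear interpolation
    return q * params.threshold_multiplier


def rolling_median(x: np.ndarray, window: int = 9, mask_missing: bool = True) -> np.ndarray:
    """Centred rolling median; at the edges the window shrinks symmetrically.

    Missing (NaN) epochs are excluded from each window; with ``mask_missing``
    (default) the output is missing exactly where the input is, otherwise
    missing positions receive the median of their available neighbours.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    out = np.full(n, np.nan)
    if n == 0:
        return out
    if n >= window:
        interior = np.lib.stride_tricks.sliding_window_view(x, window)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            med = np.nanmedian(interior, axis=1)
        out[half : n - half] = med
    for i in range(min(half, n)):
        r = min(half, i, n - 1 - i)
        lo, hi = i - r, i + r + 1
        w = x[max(lo, 0) : hi]
        out[i] = np.nanmedian(w) if np.any(~np.isnan(w)) else np.nan
    for i in range(max(n - half, 0), n):
        r = min(half, i, n - 1 - i)
        w = x[i - r : i + r + 1]
        out[i] = np.nanmedian(w) if np.any(~np.isnan(w)) else np.nan
    if mask_missing:
        out[np.isnan(x)] = np.nan
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end_exclusive)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


def merge_blocks(blocks: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge time-sorted blocks whose gaps are <= max_gap (idempotent)."""
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def detect_spt_window(
    smoothed: np.ndarray,
    threshold: float,
    index: pd.DatetimeIndex | None = None,
    params: ScoringParams = ScoringParams(),
) -> SptWindow | None:
    """Locate the sleep period within one noon-to-noon day.

    Missing epochs break below-threshold runs. Returns None when no block of
    ``min_block_min`` qualifies; ties on merged length go to the earliest.
    """
    with np.errstate(invalid="ignore"):
        below = np.asarray(smoothed) < threshold  # NaN compares False
    blocks = [(s, e) for s, e in _runs(below) if e - s >= params.min_block_min]
    if not blocks:
        return None
    merged = merge_blocks(blocks, params.merge_gap_min)
    lengths = [e - s for s, e in merged]
    best = int(np.argmax(lengths))  # argmax returns the first (earliest) maximum
    s, e = merged[best]
    if index is not None:
        onset, awakening = index[s], index[s] + pd.Timedelta(minutes=e - s)
    else:
        onset = awakening = pd.NaT
    return SptWindow(onset=onset, awakening=awakening, onset_idx=s, end_idx=e)


def classify_epochs(
    log_vedba: np.ndarray, threshold: float, params: ScoringParams = ScoringParams()
) -> np.ndarray:
    """Per-epoch labels over the whole day: SLEEP / WAKE / MISSING.

    Sleep requires a run of >= min_sleep_run consecutive epochs strictly below
    the threshold; missing epochs break runs.
    """
    x = np.asarray(log_vedba, dtype=float)
    labels = np.full(len(x), WAKE, dtype=np.int8)
    labels[np.isnan(x)] = MISSING
    with np.errstate(invalid="ignore"):
        below = x < threshold
    for s, e in _runs(below):
        if e - s >= params.min_sleep_run:
            labels[s:e] = SLEEP
    return labels


def count_wake_bouts(
    labels: np.ndarray, params: ScoringParams = ScoringParams()
) -> int:
    """Qualifying wake bouts within a label window.

    Wake runs separated by fewer than ``bout_separation_sleep_epochs`` sleep
    epochs belong to the same bout (wake minutes summed); a bout counts when
    its total wake length is >= min_wake_bout_min. Missing epochs neither add
    wake time nor separate bouts.
    """
    lab = np.asarray(labels)
    wake_runs = _runs(lab == WAKE)
    if not wake_runs:
        return 0
    bouts: list[int] = []
    cur = wake_runs[0][1] - wake_runs[0][0]
    for (s0, e0), (s1, e1) in zip(wake_runs, wake_runs[1:]):
        sleep_between = int(np.sum(lab[e0:s1] == SLEEP))
        if sleep_between < params.bout_separation_sleep_epochs:
            cur += e1 - s1
        else:
            bouts.append(cur)
            cur = e1 - s1
    bouts.append(cur)
    return sum(1 for b in bouts if b >= params.min_wake_bout_min)


@dataclass
class NightMetrics:
    individual_id: str
    night_id: dt.date
    spt: SptWindow | None
    total_sleep_time: float | None = None
    sleep_period_duration: float | None = None
    sleep_efficiency: float | None = None
    sleep_fragmentation: float | None = None
    nap_minutes: float | None = None
    onset_rel_twilight_min: float | None = None
    awakening_rel_twilight_min: float | None = None
    qc: dict = field(default_factory=dict)


def compute_night_metrics(
    spt: SptWindow,
    labels: np.ndarray,
    twilight_evening: TwilightTimes | None = None,
    twilight_morning: TwilightTimes | None = None,
    params: ScoringParams = ScoringParams(),
) -> dict:
    """Night-level sleep metrics from an SPT window and the day's labels."""
    window = labels[spt.onset_idx : spt.end_idx]
    tst = int(np.sum(window == SLEEP))
    duration = spt.duration_min
    efficiency = tst / duration if duration else np.nan
    bouts = count_wake_bouts(window, params)
    fragmentation = bouts / (tst / 60.0) if tst > 0 else np.nan
    out = {
        "total_sleep_time": tst,
        "sleep_period_duration": duration,
        "sleep_efficiency": efficiency,
        "n_wake_bouts": bouts,
        "sleep_fragmentation": fragmentation,
    }
    if twilight_evening is not None and spt.onset is not pd.NaT:
        out["onset_rel_twilight_min"] = (
            spt.onset - twilight_evening.evening_astro_end
        ).total_seconds() / 60.0
    if twilight_morning is not None and spt.awakening is not pd.NaT:
        out["awakening_rel_twilight_min"] = (
            spt.awakening - twilight_morning.morning_astro_start
        ).total_seconds() / 60.0
    return out


def compute_nap_minutes(
    labels: pd.Series, day: dt.date, params: ScoringParams = ScoringParams()
) -> int:
    """Sleep epochs within the fixed daytime window on a calendar date.

    ``labels`` is a label series indexed by epoch timestamps (may span many
    days); the nap window is [nap_start, nap_end) local time on ``day``.
    """
    ts = labels.index
    sel = labels[
        (ts.date == day) & (ts.time >= params.nap_start) & (ts.time < params.nap_end)
    ]
    return int((sel == SLEEP).sum())


def apply_qc_filters(
    missing_mask: np.ndarray, params: ScoringParams = ScoringParams()
) -> dict:
    """QC flags for one noon-to-noon day from its per-epoch missingness."""
    m = np.asarray(missing_mask, dtype=bool)
    n_missing = int(m.sum())
    max_run = max((e - s for s, e in _runs(m)), default=0)
    return {
        "n_missing": n_missing,
        "max_consecutive_missing": max_run,
        "missing_ge_120": n_missing >= params.max_missing_per_day,
        "consecutive_ge_20": max_run >= params.max_consecutive_missing,
    }


@dataclass
class DayScore:
    """Scoring result for one individual and one noon-to-noon day."""

    individual_id: str
    day: dt.date
    threshold: float | None
    spt: SptWindow | None
    labels: np.ndarray  # 1440 labels
    index: pd.DatetimeIndex
    qc: dict
    metrics: dict


def score_day(
    series: pd.Series,
    individual_id: str,
    day: dt.date,
    params: ScoringParams = ScoringParams(),
    twilight_evening: TwilightTimes | None = None,
    twilight_morning: TwilightTimes | None = None,
) -> DayScore:
    """Score one noon-to-noon day of a per-minute log-VeDBA series.

    ``series`` must be minute-indexed (tz-aware) and cover the window
    [day 12:00, day+1 12:00); gaps are treated as missing.
    """
    tz = series.index.tz
    start = pd.Timestamp(dt.datetime.combine(day, dt.time(12, 0)), tz=tz)
    idx = pd.date_range(start, periods=EPOCHS_PER_DAY, freq="min")
    x = series.reindex(idx).to_numpy(dtype=float)
    qc = apply_qc_filters(np.isnan(x), params)
    threshold = compute_threshold(x, params)
    spt = None
    labels = np.full(EPOCHS_PER_DAY, MISSING, dtype=np.int8)
    metrics: dict = {}
    if threshold is not None:
        labels = classify_epochs(x, threshold, params)
        smoothed = rolling_median(
            x, params.median_window_min, mask_missing=params.spt_break_at_missing
        )
        spt = detect_spt_window(smoothed, threshold, index=idx, params=params)
        if spt is not None:
            metrics = compute_night_metrics(
                spt, labels, twilight_evening, twilight_morning, params
            )
    if qc["missing_ge_120"]:
        spt, metrics = None, {}
    elif qc["consecutive_ge_20"]:
        spt, metrics = None, {}  # napping survives; SPT metrics do not
    return DayScore(
        individual_id=individual_id,
        day=day,
        threshold=threshold,
        spt=spt,
        labels=labels,
        index=idx,
        qc=qc,
        metrics=metrics,
    )
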