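"""Accelerometry ingest: bursts, VeDBA, and the per-minute log-VeDBA series.

VeDBA (vectorial dynamic body acceleration) is the Euclidean norm of the
dynamic components of triaxial acceleration, with the static (gravitational)
component per axis estimated by a centred running mean. One accelerometer
burst per minute epoch gives the per-minute mean VeDBA, and its natural log
(with a small offset against all-still bursts) is the series every downstream
sleep analysis consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOG_EPS = 1e-6  # offset inside the log, in acceleration units

DEFAULT_SCHEMA = {
    "individual_id": "individual_id",
    "timestamp": "timestamp",
    "sample_index": "sample_index",
    "acc_x": "acc_x",
    "acc_y": "acc_y",
    "acc_z": "acc_z",
}


def read_accel_records(path, schema: dict | None = None, tz=None, dialect: str = "long") -> pd.DataFrame:
    """Read burst records in either Movebank-style dialect.

    ``dialect="long"``: one row per sample (individual_id, timestamp,
    sample_index, acc_x/y/z). ``dialect="packed"``: one row per burst with a
    whitespace-separated ``accelerations`` column of x y z triplets; the
    schema entry ``accelerations`` can rename it. Rows are sorted by
    individual, burst epoch and sample index; duplicate (individual, epoch,
    sample_index) rows raise, naming the offender.
    """
    cols = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path)
    df = df.rename(columns={v: k for k, v in cols.items()})
    if dialect == "packed":
        acc_col = cols.get("accelerations", "accelerations")
        if acc_col not in df.columns:
            raise ValueError(f"packed dialect needs an {acc_col!r} column")
        records = []
        for _, row in df.iterrows():
            vals = np.array(str(row[acc_col]).split(), dtype=float)
            if len(vals) % 3:
                raise ValueError(
                    f"packed burst for {row['individual_id']} at {row['timestamp']} "
                    f"has {len(vals)} values (not a multiple of 3)"
                )
            triples = vals.reshape(-1, 3)
            records.append(
                pd.DataFrame(
                    {
                        "individual_id": row["individual_id"],
                        "timestamp": row["timestamp"],
                        "sample_index": np.arange(len(triples)),
                        "acc_x": triples[:, 0],
                        "acc_y": triples[:, 1],
                        "acc_z": triples[:, 2],
                    }
                )
            )
        df = pd.concat(records, ignore_index=True)
    elif dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = {"individual_id", "timestamp", "acc_x", "acc_y", "acc_z"} - set(df.columns)
    if missing:
        raise ValueError(f"accelerometry file lacks columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    if tz is not None and df["timestamp"].dt.tz is None:
        df["timestamp"] = df["timestamp"].dt.tz_localize(tz)
    if "sample_index" not in df.columns:
        df["sample_index"] = df.groupby(["individual_id", "timestamp"]).cumcount()
    dup = df.duplicated(["individual_id", "timestamp", "sample_index"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate burst sample for individual {row['individual_id']} "
            f"at epoch {row['timestamp']}"
        )
    return df.sort_values(["individual_id", "timestamp", "sample_index"]).reset_index(drop=True)


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean, window truncated at the edges."""
    n = len(x)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    lo = np.maximum(np.arange(n) - half_lo, 0)
    hi = np.minimum(np.arange(n) + half_hi + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def compute_vedba(
    samples: np.ndarray, rate_hz: float, smoothing_window_s: float = 0.7
) -> tuple[np.ndarray, float]:
    """Per-sample VeDBA and its burst mean.

    ``samples`` is (n, 3). The static component per axis is the centred
    running mean over ``smoothing_window_s``; the dynamic component is the
    residual, and VeDBA its Euclidean norm.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be (n, 3)")
    n = samples.shape[0]
    window = max(int(round(smoothing_window_s * rate_hz)), 1)
    if n < window:
        raise ValueError(
            f"burst of {n} samples shorter than the {window}-sample smoothing window"
        )
    dyn = np.column_stack([samples[:, k] - running_mean(samples[:, k], window) for k in range(3)])
    vedba = np.sqrt((dyn**2).sum(axis=1))
    return vedba, float(vedba.mean())


def harmonize_daytime(
    continuous: pd.DataFrame,
    target_rate_hz: float = 10.0,
    burst_duration_s: float = 2.5,
) -> pd.DataFrame:
    """Resample a continuous stream onto the nocturnal burst schedule.

    For each minute covered by the stream, the first ``burst_duration_s`` are
    linearly interpolated onto ``target_rate_hz`` sample times, producing
    burst rows identical in shape to the native night bursts. Minutes whose
    window is not fully covered by continuous samples are omitted (missing).
    """
    if continuous.empty:
        raise ValueError("empty continuous accelerometry stream")
    n_samp = int(round(burst_duration_s * target_rate_hz))
    offsets = np.arange(n_samp) / target_rate_hz
    out = []
    for ind, grp in continuous.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp")
        ts = pd.DatetimeIndex(grp["timestamp"])
        tsec = ((ts - ts[0]).total_seconds()).to_numpy()
        axes = grp[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
        minutes = ts.floor("min").unique()
        for m in minutes:
            t0 = (m - ts[0]).total_seconds()
            targets = t0 + offsets
            if targets[0] < tsec[0] - 1e-9 or targets[-1] > tsec[-1] + 1e-9:
                continue  # window not fully covered -> minute stays missing
            interp = np.column_stack(
                [np.interp(targets, tsec, axes[:, k]) for k in range(3)]
            )
            burst = pd.DataFrame(
                {
                    "individual_id": ind,
                    "timestamp": m,
                    "sample_index": np.arange(n_samp),
                    "acc_x": interp[:, 0],
                    "acc_y": interp[:, 1],
                    "acc_z": interp[:, 2],
                }
            )
            out.append(burst)
    if not out:
        return pd.DataFrame(
            columns=["individual_id", "timestamp", "sample_index", "acc_x", "acc_y", "acc_z"]
        )
    return pd.concat(out, ignore_index=True)


def burst_mean_vedba(
    records: pd.DataFrame, rate_hz: float = 10.0, smoothing_window_s: float = 0.7
) -> pd.DataFrame:
    """Mean VeDBA per (individual, minute epoch) from long-format burst rows."""
    rows = []
    for (ind, epoch), grp in records.groupby(["individual_id", "timestamp"], sort=True):
        samp = grp.sort_values("sample_index")[["acc_x", "acc_y", "acc_z"]].to_numpy()
        _, mean_v = compute_vedba(samp, rate_hz, smoothing_window_s)
        rows.append({"individual_id": ind, "timestamp": epoch, "mean_vedba": mean_v})
    return pd.DataFrame(rows)


def assemble_minute_series(mean_vedba: pd.DataFrame, eps: float = LOG_EPS) -> pd.DataFrame:
    """Per-minute log-VeDBA frame: rows = minute epochs, columns = individuals.

    log_vedba = ln(mean VeDBA + eps). Epochs without a burst are NaN (missing,
    never interpolated). The index spans first to last observed epoch at 1-min
    spacing.
    """
    if (mean_vedba["mean_vedba"] < 0).any():
        bad = mean_vedba.loc[mean_vedba["mean_vedba"] < 0].iloc[0]
        raise ValueError(f"negative mean VeDBA for {bad['individual_id']} at {bad['timestamp']}")
    df = mean_vedba.copy()
    df["log_vedba"] = np.log(df["mean_vedba"] + eps)
    wide = df.pivot_table(
        index="timestamp", columns="individual_id", values="log_vedba", aggfunc="first"
    )
    full = pd.date_range(wide.index.min(), wide.index.max(), freq="min")
    return wide.reindex(full)


def cumulative_daytime_vedba(
    continuous: pd.DataFrame,
    day,
    start=(6, 0),
    end=(18, 0),
    smoothing_window_s: float = 0.5,
) -> tuple[float, int, int]:
    """Cumulative daytime activity: per-minute mean VeDBA summed over the day.

    Uses the continuous stream between ``start`` and ``end`` local time with a
    0.5-s static-estimation window. Returns (total, minutes_covered,
    minutes_missing); missing minutes contribute nothing.
    """
    ts = continuous["timestamp"]
    sel = continuous.loc[
        (ts.dt.date == day)
        & (ts.dt.time >= pd.Timestamp(2000, 1, 1, *start).time())
        & (ts.dt.time < pd.Timestamp(2000, 1, 1, *end).time())
    ].sort_values("timestamp")
    n_expected = ((end[0] * 60 + end[1]) - (start[0] * 60 + start[1]))
    if sel.empty:
        return 0.0, 0, n_expected
    # infer the stream rate from the median sample spacing
    dt_s = np.median(np.diff(sel["timestamp"].to_numpy()) / np.timedelta64(1, "s"))
    rate = 1.0 / float(dt_s)
    total = 0.0
    covered = 0
    for _, grp in sel.groupby(pd.DatetimeIndex(sel["timestamp"]).floor("min")):
        samp = grp[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
        window = max(int(round(smoothing_window_s * rate)), 1)
        if len(samp) < window:
            continue
        _, mean_v = compute_vedba(samp, rate, smoothing_window_s)
        total += mean_v
        covered += 1
    return total, covered, n_expected - covered
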