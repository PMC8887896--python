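"""VeDBA computation, burst ingest, daytime harmonization."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wildsleep import accel, simulate as sim
from wildsleep.accel import (
    assemble_minute_series,
    compute_vedba,
    cumulative_daytime_vedba,
    harmonize_daytime,
    read_accel_records,
    running_mean,
)

TZ = dt.timezone(dt.timedelta(hours=3))


def brute_force_vedba(samples, window):
    """Independent oracle: truncated centred running mean per axis."""
    n = len(samples)
    half_lo, half_hi = (window - 1) // 2, window // 2
    ved = []
    for i in range(n):
        lo, hi = max(0, i - half_lo), min(n, i + half_hi + 1)
        sq = 0.0
        for k in range(3):
            static = sum(s[k] for s in samples[lo:hi]) / (hi - lo)
            sq += (samples[i][k] - static) ** 2
        ved.append(sq**0.5)
    return ved


class TestVedba:
    def test_constant_burst_has_zero_vedba(self):
        samples = np.tile([0.0, 0.0, 1.0], (25, 1))
        per_sample, mean = compute_vedba(samples, 10.0)
        assert np.allclose(per_sample, 0.0) and mean == 0.0

    def test_impulse_matches_brute_force(self):
        x = [0, 0, 0, 1.0, 0, 0, 0]
        samples = np.column_stack([x, np.zeros(7), np.zeros(7)])
        per_sample, mean = compute_vedba(samples, 10.0, 0.7)
        want = brute_force_vedba([tuple(s) for s in samples], 7)
        assert np.allclose(per_sample, want, atol=1e-12)
        assert mean == pytest.approx(float(np.mean(want)), abs=1e-12)

    def test_random_bursts_match_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(7, 40))
            samples = rng.normal(0, 1, (n, 3))
            per_sample, _ = compute_vedba(samples, 10.0, 0.7)
            assert np.allclose(per_sample, brute_force_vedba([tuple(s) for s in samples], 7))

    def test_homogeneity_under_axis_scaling(self, rng):
        samples = rng.normal(0, 1, (25, 3))
        _, m1 = compute_vedba(samples, 10.0)
        _, m2 = compute_vedba(2.0 * samples, 10.0)
        assert m2 == pytest.approx(2.0 * m1)

    def test_burst_shorter_than_window_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_vedba(np.zeros((5, 3)), 10.0, 0.7)

    def test_running_mean_matches_pandas(self, rng):
        x = rng.normal(size=100)
        want = pd.Series(x).rolling(7, center=True, min_periods=1).mean().to_numpy()
        assert np.allclose(running_mean(x, 7), want)


class TestHarmonize:
    def _continuous(self, fn, seconds=180, rate=12.0):
        t0 = pd.Timestamp("2012-08-01 08:00", tz=TZ)
        n = int(seconds * rate)
        ts = t0 + pd.to_timedelta(np.arange(n) / rate, unit="s")
        tsec = np.arange(n) / rate
        return pd.DataFrame(
            {
                "individual_id": "a",
                "timestamp": ts,
                "acc_x": fn(tsec),
                "acc_y": 0.0,
                "acc_z": 1.0,
            }
        )

    def test_constant_signal_resamples_to_constant(self):
        cont = self._continuous(lambda t: np.full_like(t, 0.37))
        out = harmonize_daytime(cont)
        assert np.allclose(out["acc_x"], 0.37)
        assert (out.groupby("timestamp").size() == 25).all()

    def test_linear_ramp_is_exactly_interpolated(self):
        cont = self._continuous(lambda t: 0.01 * t)
        out = harmonize_daytime(cont)
        t0 = cont["timestamp"].iloc[0]
        tsec = (out["timestamp"] + pd.to_timedelta(out["sample_index"] / 10.0, unit="s") - t0).dt.total_seconds()
        # exact up to nanosecond timestamp rounding of the 12 Hz sample times
        assert np.max(np.abs(out["acc_x"] - 0.01 * tsec)) < 1e-9

    def test_sinusoid_matches_closed_form(self):
        amp, freq = 0.5, 0.5
        cont = self._continuous(lambda t: amp * np.sin(2 * np.pi * freq * t))
        out = harmonize_daytime(cont)
        t0 = cont["timestamp"].iloc[0]
        tsec = (out["timestamp"] + pd.to_timedelta(out["sample_index"] / 10.0, unit="s") - t0).dt.total_seconds()
        want = amp * np.sin(2 * np.pi * freq * tsec)
        # linear-interpolation error bound at 12 Hz: amp*(2*pi*f/rate)^2/8 ~ 0.86% amp
        assert np.max(np.abs(out["acc_x"] - want)) < 0.01 * amp

    def test_uncovered_minutes_are_missing(self):
        cont = self._continuous(lambda t: t * 0 + 1.0, seconds=61)  # second minute partial
        out = harmonize_daytime(cont)
        assert out["timestamp"].nunique() == 1


class TestMinuteSeries:
    def test_log_of_unit_vedba_is_near_zero(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a"],
                "timestamp": [pd.Timestamp("2012-08-01 19:00", tz=TZ)],
                "mean_vedba": [1.0],
            }
        )
        out = assemble_minute_series(df)
        assert out.iloc[0, 0] == pytest.approx(0.0, abs=1e-5)

    def test_zero_vedba_floors_at_log_eps(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a"],
                "timestamp": [pd.Timestamp("2012-08-01 19:00", tz=TZ)],
                "mean_vedba": [0.0],
            }
        )
        out = assemble_minute_series(df)
        assert out.iloc[0, 0] == pytest.approx(np.log(accel.LOG_EPS))

    def test_negative_mean_vedba_raises(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a"],
                "timestamp": [pd.Timestamp("2012-08-01 19:00", tz=TZ)],
                "mean_vedba": [-0.1],
            }
        )
        with pytest.raises(ValueError, match="negative"):
            assemble_minute_series(df)

    def test_gaps_become_missing_epochs(self):
        t0 = pd.Timestamp("2012-08-01 19:00", tz=TZ)
        df = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "timestamp": [t0, t0 + pd.Timedelta(minutes=3)],
                "mean_vedba": [1.0, 1.0],
            }
        )
        out = assemble_minute_series(df)
        assert len(out) == 4 and out["a"].isna().sum() == 2


class TestReadRecords:
    def test_shuffled_rows_are_sorted_and_duplicates_rejected(self, tmp_path, rng):
        t0 = pd.Timestamp("2012-08-01 19:00", tz=TZ)
        rows = []
        for m in range(3):
            for k in range(5):
                rows.append(
                    {
                        "individual_id": "a",
                        "timestamp": (t0 + pd.Timedelta(minutes=m)).isoformat(),
                        "sample_index": k,
                        "acc_x": 0.0,
                        "acc_y": 0.0,
                        "acc_z": 1.0,
                    }
                )
        df = pd.DataFrame(rows).sample(frac=1, random_state=1)
        path = tmp_path / "acc.csv"
        df.to_csv(path, index=False)
        out = read_accel_records(path)
        assert out["timestamp"].is_monotonic_increasing
        assert out.groupby("timestamp").size().tolist() == [5, 5, 5]

        pd.concat([df, df.head(1)]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_accel_records(path)

    def test_packed_dialect_round_trips(self, tmp_path, rng):
        t0 = pd.Timestamp("2012-08-01 19:00", tz=TZ)
        vals = rng.normal(0, 1, (2, 25, 3))
        packed = pd.DataFrame(
            {
                "individual_id": "a",
                "timestamp": [(t0 + pd.Timedelta(minutes=m)).isoformat() for m in range(2)],
                "accelerations": [" ".join(f"{v:.6f}" for v in burst.ravel()) for burst in vals],
            }
        )
        path = tmp_path / "packed.csv"
        packed.to_csv(path, index=False)
        out = read_accel_records(path, dialect="packed")
        assert len(out) == 50
        got = out[out["timestamp"] == t0][["acc_x", "acc_y", "acc_z"]].to_numpy()
        assert np.allclose(got, vals[0], atol=1e-6)


class TestRoundTrip:
    def test_rendered_bursts_reproduce_emission_logvedba(self, small_truth):
        # deterministic emissions: every sleep burst yields the exact state mean
        cfg = small_truth.config.replace(
            sleep_logvedba_sd=0.0, day_logvedba_sd=0.0, restingwake_logvedba_sd=0.0
        )
        truth = sim.generate_group_truth(cfg)
        night_slice = slice(440, 470)  # within the first sleep window
        recs = sim.render_accel_bursts(truth, cfg, individuals=["ind01"], epoch_slice=night_slice)
        means = accel.burst_mean_vedba(recs)
        series = assemble_minute_series(means)
        states = truth.states[0, night_slice]
        want = np.where(states == sim.STATE_SLEEP, cfg.sleep_logvedba_mean, cfg.day_logvedba_mean)
        assert np.allclose(series["ind01"].to_numpy(), want, atol=1e-6)

    def test_sample_mean_of_noisy_sleep_bursts(self, small_truth):
        cfg = small_truth.config
        truth = small_truth
        night_slice = slice(470, 590)
        recs = sim.render_accel_bursts(truth, cfg, individuals=["ind02"], epoch_slice=night_slice)
        means = accel.burst_mean_vedba(recs)
        series = assemble_minute_series(means)["ind02"]
        states = truth.states[1, night_slice]
        vals = series.to_numpy()[states == sim.STATE_SLEEP]
        se = cfg.sleep_logvedba_sd / np.sqrt(len(vals))
        assert abs(vals.mean() - cfg.sleep_logvedba_mean) < 3 * se

    def test_rendering_twice_is_identical(self, small_truth):
        a = sim.render_accel_bursts(small_truth, individuals=["ind01"], epoch_slice=slice(0, 50))
        b = sim.render_accel_bursts(small_truth, individuals=["ind01"], epoch_slice=slice(0, 50))
        pd.testing.assert_frame_equal(a, b)


class TestCumulativeDaytime:
    def _stream(self, scale, day=dt.date(2012, 8, 1), minutes=30):
        t0 = pd.Timestamp(dt.datetime.combine(day, dt.time(8, 0)), tz=TZ)
        n = int(minutes * 60 * 12)
        ts = t0 + pd.to_timedelta(np.arange(n) / 12.0, unit="s")
        x = scale * np.sin(2 * np.pi * 2.0 * np.arange(n) / 12.0)
        return pd.DataFrame(
            {"individual_id": "a", "timestamp": ts, "acc_x": x, "acc_y": 0.0, "acc_z": 1.0}
        )

    def test_constant_signal_accumulates_zero(self):
        df = self._stream(0.0)
        total, covered, missing = cumulative_daytime_vedba(df, dt.date(2012, 8, 1))
        assert total == pytest.approx(0.0)
        assert covered == 30 and missing == 690

    def test_more_movement_accumulates_more(self):
        quiet = cumulative_daytime_vedba(self._stream(0.05), dt.date(2012, 8, 1))[0]
        active = cumulative_daytime_vedba(self._stream(0.5), dt.date(2012, 8, 1))[0]
        assert active > quiet > 0
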