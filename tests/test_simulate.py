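"""Generator: latent process structure, emissions, missingness, determinism."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wildsleep import simulate as sim
from wildsleep.simulate import STATE_ACTIVE_WAKE, STATE_REST_WAKE, STATE_SLEEP, SimConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"coupling_prob": 1.2},
            {"missing_burst_prob": -0.1},
            {"n_individuals": 0},
            {"n_trees": 0},
            {"sleep_logvedba_mean": 7.0},
            {"epoch_length_s": 7},
            {"wake_bout_mean_min": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestTruthProcess:
    def test_sleep_window_conservation(self, small_truth):
        """Sleep plus wake epochs partition each night's window exactly."""
        cfg = small_truth.config
        for i in range(cfg.n_individuals):
            for n in range(cfg.n_nights):
                o, f = small_truth.onset_idx[i, n], small_truth.offset_idx[i, n]
                win = small_truth.states[i, o:f]
                n_sleep = (win == STATE_SLEEP).sum()
                n_wake = (win != STATE_SLEEP).sum()
                assert n_sleep + n_wake == f - o

    def test_no_bouts_means_uninterrupted_sleep(self):
        cfg = SimConfig(n_individuals=3, n_nights=3, seed=1, wake_bout_rate_per_h=0.0)
        truth = sim.generate_group_truth(cfg)
        for i in range(3):
            for n in range(3):
                o, f = truth.onset_idx[i, n], truth.offset_idx[i, n]
                assert (truth.states[i, o:f] == STATE_SLEEP).all()

    def test_degenerate_preference_uses_single_tree(self):
        cfg = SimConfig(
            n_individuals=4, n_nights=10, seed=2, tree_preference_concentration=np.inf
        )
        truth = sim.generate_group_truth(cfg)
        assert all(len(set(truth.trees[i])) == 1 for i in range(4))

    def test_uncoupled_wake_onsets_are_independent(self):
        """With coupling off, one individual's wake onset at t-1 does not
        change the other's probability of waking at t (chi-square over many
        nights in a shared tree)."""
        cfg = SimConfig(
            n_individuals=2,
            n_nights=100,
            seed=5,
            coupling_prob=0.0,
            n_trees=1,
            wake_bout_rate_per_h=2.0,
        )
        truth = sim.generate_group_truth(cfg)
        a = (truth.states[0] != STATE_SLEEP).astype(int)
        b = (truth.states[1] != STATE_SLEEP).astype(int)
        # restrict to epochs where both are inside their sleep windows
        inside = np.zeros(truth.states.shape[1], dtype=bool)
        for n in range(cfg.n_nights):
            lo = max(truth.onset_idx[0, n], truth.onset_idx[1, n]) + 1
            hi = min(truth.offset_idx[0, n], truth.offset_idx[1, n])
            inside[lo:hi] = True
        onset_a = (a[1:] == 1) & (a[:-1] == 0)
        woke_b = (b[1:] == 1) & (b[:-1] == 0)
        # lag 1: does a's onset at t-1 predict b's onset at t? Restrict both
        # epochs to the common window (heterogeneous pooling would fabricate
        # an association between independent processes)
        mask = inside[1:-1] & inside[2:]
        table = pd.crosstab(onset_a[:-1][mask], woke_b[1:][mask])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_coupling_produces_logged_events(self):
        cfg = SimConfig(n_individuals=6, n_nights=5, seed=3, coupling_prob=0.5, n_trees=2)
        truth = sim.generate_group_truth(cfg)
        assert len(truth.coupling_events) > 0
        for ev in truth.coupling_events:
            i = truth.individuals.index(ev["individual"])
            assert truth.states[i, ev["epoch"]] != STATE_SLEEP
            assert truth.trees[i, ev["night"]] == ev["tree"]

    def test_seeded_determinism_all_stages(self, tree_map):
        cfg = SimConfig(n_individuals=3, n_nights=2, seed=7, n_trees=6)
        t1, t2 = sim.generate_group_truth(cfg), sim.generate_group_truth(cfg)
        assert np.array_equal(t1.states, t2.states)
        assert np.array_equal(t1.trees, t2.trees)
        f1, f2 = sim.render_minute_logvedba(t1), sim.render_minute_logvedba(t2)
        pd.testing.assert_frame_equal(f1, f2)
        g1 = sim.render_gps_fixes(t1, tree_map)
        g2 = sim.render_gps_fixes(t2, tree_map)
        pd.testing.assert_frame_equal(g1, g2)


class TestEmissions:
    def test_zero_sd_gives_piecewise_constant_series(self):
        cfg = SimConfig(
            n_individuals=2,
            n_nights=2,
            seed=4,
            sleep_logvedba_sd=0.0,
            day_logvedba_sd=0.0,
            restingwake_logvedba_sd=0.0,
        )
        truth = sim.generate_group_truth(cfg)
        frame = sim.render_minute_logvedba(truth)
        lookup = {
            STATE_SLEEP: cfg.sleep_logvedba_mean,
            STATE_REST_WAKE: cfg.restingwake_logvedba_mean,
            STATE_ACTIVE_WAKE: cfg.day_logvedba_mean,
        }
        for i, ind in enumerate(truth.individuals):
            want = np.array([lookup[s] for s in truth.states[i]])
            assert np.allclose(frame[ind].to_numpy(), want)

    def test_sample_mean_within_three_se(self, small_truth, small_frame):
        cfg = small_truth.config
        sleep_vals = small_frame.to_numpy().T[small_truth.states == STATE_SLEEP]
        se = cfg.sleep_logvedba_sd / np.sqrt(len(sleep_vals))
        assert abs(sleep_vals.mean() - cfg.sleep_logvedba_mean) < 3 * se

    def test_resting_wake_emitted_at_sleep_like_level(self):
        cfg = SimConfig(n_individuals=2, n_nights=3, seed=8, resting_wake_prob=1.0)
        truth = sim.generate_group_truth(cfg)
        frame = sim.render_minute_logvedba(truth)
        rest = frame.to_numpy().T[truth.states == STATE_REST_WAKE]
        assert len(rest) > 0
        assert abs(rest.mean() - cfg.restingwake_logvedba_mean) < 0.1


class TestGps:
    def test_zero_jitter_puts_sleep_location_at_centroid(self, tree_map):
        cfg = SimConfig(n_individuals=2, n_nights=2, seed=6, gps_jitter_m=0.0, n_trees=6)
        truth = sim.generate_group_truth(cfg, tree_map)
        gps = sim.render_gps_fixes(truth, tree_map, include_day_track=False)
        from wildsleep.sites import infer_sleep_location, to_local_xy

        ind = truth.individuals[0]
        morning = truth.night_dates()[0] + dt.timedelta(days=1)
        loc, reason = infer_sleep_location(gps[gps["individual_id"] == ind], morning)
        assert reason is None
        c = tree_map.projected(int(truth.trees[0, 0])).centroid
        x, y = to_local_xy(loc[0], loc[1], tree_map.site_center)
        assert float(np.hypot(x - c.x, y - c.y)) < 0.01

    def test_at_least_ten_fixes_before_cutoff(self, tree_map):
        cfg = SimConfig(n_individuals=1, n_nights=2, seed=6, n_trees=6)
        truth = sim.generate_group_truth(cfg, tree_map)
        gps = sim.render_gps_fixes(truth, tree_map, include_day_track=False)
        ts = gps["timestamp"]
        for night in truth.night_dates():
            morning = night + dt.timedelta(days=1)
            early = gps[(ts.dt.date == morning) & (ts.dt.time < dt.time(6, 15))]
            assert len(early) >= 10


class TestMissingness:
    def _records(self, n_epochs=50):
        t0 = pd.Timestamp("2012-08-01 19:00", tz=dt.timezone(dt.timedelta(hours=3)))
        rows = []
        for m in range(n_epochs):
            for k in range(3):
                rows.append(("a", t0 + pd.Timedelta(minutes=m), k, 0.0, 0.0, 1.0))
        return pd.DataFrame(
            rows, columns=["individual_id", "timestamp", "sample_index", "acc_x", "acc_y", "acc_z"]
        )

    def test_zero_probability_is_identity(self):
        recs = self._records()
        out, dropped = sim.inject_missingness(recs, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, recs)
        assert dropped.empty

    def test_binomial_mean_missing_count(self):
        frame = pd.DataFrame(
            np.zeros((1440, 1)),
            index=pd.date_range("2012-08-01 12:00", periods=1440, freq="min"),
            columns=["a"],
        )
        counts = [
            sim.inject_missingness_minutes(frame, 0.083, seed=s)["a"].isna().sum()
            for s in range(30)
        ]
        # binomial mean 119.5, sd ~10.5; mean of 30 replicates within 4 se
        assert abs(np.mean(counts) - 1440 * 0.083) < 4 * 10.5 / np.sqrt(30)

    def test_inserted_gap_triggers_consecutive_qc_flag(self):
        from wildsleep.scoring import apply_qc_filters, score_day

        cfg = SimConfig(n_individuals=1, n_nights=1, seed=2, missing_burst_prob=0.0)
        truth = sim.generate_group_truth(cfg)
        frame = sim.render_minute_logvedba(truth)
        start = frame.index[600]
        frame = sim.inject_missingness_minutes(
            frame, 0.0, seed=0, consecutive_runs=[("ind01", start, 25)]
        )
        ds = score_day(frame["ind01"], "ind01", cfg.start_date)
        assert ds.qc["consecutive_ge_20"]
        assert ds.spt is None

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sim.inject_missingness(self._records(), 1.5)

    def test_missingness_conserved_through_ingest(self):
        """Epochs dropped from burst records come back as missing epochs."""
        from wildsleep import accel

        cfg = SimConfig(n_individuals=1, n_nights=1, seed=12)
        truth = sim.generate_group_truth(cfg)
        recs = sim.render_accel_bursts(truth, individuals=["ind01"], epoch_slice=slice(400, 460))
        out, dropped = sim.inject_missingness(recs, 0.15, seed=3)
        series = accel.assemble_minute_series(accel.burst_mean_vedba(out))
        n_missing = series["ind01"].isna().sum()
        # dropped epochs interior to the span stay NaN; edge drops shrink the span
        span = pd.date_range(out["timestamp"].min(), out["timestamp"].max(), freq="min")
        dropped_interior = dropped["timestamp"].isin(span).sum()
        assert n_missing == dropped_interior
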