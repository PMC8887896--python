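"""Simulation experiments: recovery, null-model calibration, power.

These drive the package's own validation: each experiment regenerates
synthetic groups from scratch, runs the relevant pipeline stages, and reports
rates. Group sizes default to the first-14-days analysis scale (15 tracked
individuals over 14 nights); calibration and power runs operate on the
generator's truth labels directly, which is what the null machinery consumes
— rendering and re-scoring the accelerometry signal in between would test
nothing additional about the resampling tests themselves.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from . import arousal, fidelity, simulate as sim, sync
from .scoring import SLEEP, WAKE, score_day
from .simulate import STATE_SLEEP, SimConfig

NIGHT_START_EPOCH = 540  # 21:00, minutes after local noon
NIGHT_EPOCHS = 480


def truth_epoch_matrix(truth: sim.GroundTruth) -> np.ndarray:
    """(nights, individuals, 480) binary matrix from generator truth states."""
    n_ind, _ = truth.states.shape
    n_nights = truth.config.n_nights
    mats = []
    for n in range(n_nights):
        lo = n * 1440 + NIGHT_START_EPOCH
        block = truth.states[:, lo : lo + NIGHT_EPOCHS]
        mats.append(np.where(block == STATE_SLEEP, SLEEP, WAKE).astype(np.int8))
    return np.stack(mats)


def truth_assignments(truth: sim.GroundTruth) -> pd.DataFrame:
    rows = []
    for i, ind in enumerate(truth.individuals):
        for n, night in enumerate(truth.night_dates()):
            rows.append(
                {"individual_id": ind, "night_id": night, "tree_id": int(truth.trees[i, n])}
            )
    return pd.DataFrame(rows)


def recovery_experiment(
    n_individuals: int = 26,
    n_nights: int = 10,
    seed: int = 0,
    noise: bool = True,
) -> dict:
    """Score rendered synthetic data and compare to truth.

    ``noise=False`` switches off every stochastic perturbation (emission noise,
    missing bursts and spontaneous wake bouts), isolating window detection;
    under those conditions onset/awakening recovery is exact up to the rolling
    median's edge behaviour.
    """
    cfg = SimConfig(n_individuals=n_individuals, n_nights=n_nights, seed=seed)
    if not noise:
        cfg = cfg.replace(
            sleep_logvedba_sd=0.0,
            day_logvedba_sd=0.0,
            restingwake_logvedba_sd=0.0,
            missing_burst_prob=0.0,
            wake_bout_rate_per_h=0.0,
        )
    truth = sim.generate_group_truth(cfg)
    frame = sim.render_minute_logvedba(truth)
    if cfg.missing_burst_prob > 0:
        frame = sim.inject_missingness_minutes(frame, cfg.missing_burst_prob, seed=cfg.seed)

    onset_errs, awake_errs, accs, tst_rel_errs = [], [], [], []
    nights = truth.night_dates()
    for i, ind in enumerate(truth.individuals):
        for n, day in enumerate(nights):
            ds = score_day(frame[ind], ind, day)
            sl = truth.states[i, n * 1440 : (n + 1) * 1440]
            true_labels = np.where(sl == STATE_SLEEP, SLEEP, WAKE)
            observed = ds.labels != -1
            accs.append(float((ds.labels[observed] == true_labels[observed]).mean()))
            if ds.spt is None:
                continue
            true_onset = truth.index[truth.onset_idx[i, n]]
            true_awake = truth.index[0] + pd.Timedelta(minutes=int(truth.offset_idx[i, n]))
            onset_errs.append((ds.spt.onset - true_onset).total_seconds() / 60.0)
            awake_errs.append((ds.spt.awakening - true_awake).total_seconds() / 60.0)
            o, f = truth.onset_idx[i, n] - n * 1440, truth.offset_idx[i, n] - n * 1440
            tst_true = int((sl[o:f] == STATE_SLEEP).sum())
            tst_det = int((ds.labels[ds.spt.onset_idx : ds.spt.end_idx] == SLEEP).sum())
            tst_rel_errs.append(abs(tst_det - tst_true) / tst_true)
    return {
        "n_nights_scored": len(onset_errs),
        "onset_max_abs_err_min": float(np.max(np.abs(onset_errs))),
        "awakening_max_abs_err_min": float(np.max(np.abs(awake_errs))),
        "epoch_accuracy": float(np.mean(accs)),
        "epoch_accuracy_min": float(np.min(accs)),
        "tst_mean_rel_err": float(np.mean(tst_rel_errs)),
    }


def _calibration_config(seed: int, n_individuals: int, n_nights: int) -> SimConfig:
    return SimConfig(
        n_individuals=n_individuals,
        n_nights=n_nights,
        seed=seed,
        coupling_prob=0.0,
        tree_preference_concentration=0.0,  # uniform random tree choice
        missing_burst_prob=0.0,
    )


def type_i_error_experiment(
    n_datasets: int = 400,
    n_iter: int = 100,
    n_individuals: int = 15,
    n_nights: int = 14,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the fidelity KS test and the time-shift sync test.

    Every dataset is generated under the null: no wake contagion and uniform
    random nightly tree choice.
    """
    fid_reject = 0
    sync_reject = 0
    fid_ps, sync_ps = [], []
    for k in range(n_datasets):
        cfg = _calibration_config(seed * 1_000_003 % (2**31 - 1) + k, n_individuals, n_nights)
        truth = sim.generate_group_truth(cfg)
        rep = fidelity.fidelity_analysis(
            truth_assignments(truth), n_perm=n_iter, seed=cfg.seed, first_n_nights=14
        )
        fid_ps.append(rep.p_value)
        fid_reject += rep.p_value < alpha
        mat = truth_epoch_matrix(truth)
        reports = sync.time_shift_null(mat, n_iter=n_iter, seed=cfg.seed)
        p = reports["mean_prop_synchronized"].p_value
        sync_ps.append(p)
        sync_reject += p < alpha
    return {
        "n_datasets": n_datasets,
        "fidelity_type_i": fid_reject / n_datasets,
        "timeshift_sync_type_i": sync_reject / n_datasets,
    }


def power_experiment(
    n_datasets: int = 100,
    coupling_prob: float = 0.3,
    n_iter: int = 100,
    n_individuals: int = 15,
    n_nights: int = 14,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Power of the collective-sleep analyses under wake contagion.

    Checks the expected sign pattern — the proportion of epochs with anyone
    awake falls *below* its time-shift null while synchronization rises
    *above* it — and whether the logistic stand-in recovers a positive
    group-mate-awake effect.
    """
    sign_ok = 0
    logit_ok = 0
    fit_attempted = 0
    for k in range(n_datasets):
        cfg = SimConfig(
            n_individuals=n_individuals,
            n_nights=n_nights,
            seed=seed * 999_983 % (2**31 - 1) + k,
            coupling_prob=coupling_prob,
            missing_burst_prob=0.0,
        )
        truth = sim.generate_group_truth(cfg)
        mat = truth_epoch_matrix(truth)
        reports = sync.time_shift_null(mat, n_iter=n_iter, seed=cfg.seed)
        r_any, r_sync = reports["prop_any_awake"], reports["mean_prop_synchronized"]
        below = r_any.empirical < np.mean(r_any.nulls) and r_any.p_value < alpha
        above = r_sync.empirical > np.mean(r_sync.nulls) and r_sync.p_value < alpha
        if below and above:
            sign_ok += 1
        table = arousal.build_arousal_table(
            mat, truth.individuals, truth.night_dates(), truth_assignments(truth)
        )
        fit_attempted += 1
        try:
            fit = arousal.fit_response_standin(table, include_interactions=False)
            row = fit.loc["groupmate_awake_prev"]
            if row["coef"] > 0 and row["p"] < 0.05:
                logit_ok += 1
        except ValueError:
            pass
    return {
        "n_datasets": n_datasets,
        "sign_pattern_rate": sign_ok / n_datasets,
        "logit_positive_rate": logit_ok / fit_attempted,
    }


def conservation_checks(seed: int = 0, n_iter: int = 50) -> dict:
    """Exact conservation invariants of both resampling schemes.

    Returns maximum absolute violations (all should be exactly zero).
    """
    cfg = SimConfig(
        n_individuals=10, n_nights=8, seed=seed, coupling_prob=0.2, missing_burst_prob=0.0
    )
    truth = sim.generate_group_truth(cfg)
    mat = truth_epoch_matrix(truth)
    wake_totals = (mat == WAKE).sum(axis=2)
    rng = np.random.default_rng(seed)
    max_shift_violation = 0
    for _ in range(n_iter):
        shifts = rng.integers(1, mat.shape[2], size=mat.shape[:2])
        shifted = sync._shifted(mat, shifts)
        max_shift_violation = max(
            max_shift_violation,
            int(np.abs((shifted == WAKE).sum(axis=2) - wake_totals).max()),
        )
    assignments = truth_assignments(truth)
    perms = fidelity.permute_night_assignments(assignments, n_perm=n_iter, seed=seed)
    obs = assignments.groupby(["night_id", "tree_id"]).size()
    max_occ_violation = 0
    for p in range(perms.shape[0]):
        perm_counts = (
            assignments.assign(tree_id=perms[p]).groupby(["night_id", "tree_id"]).size()
        )
        diff = obs.subtract(perm_counts, fill_value=0).abs().max()
        max_occ_violation = max(max_occ_violation, int(diff))
    rep = fidelity.fidelity_analysis(assignments, n_perm=n_iter, seed=seed, first_n_nights=None)
    index_sum = float(rep.fidelity_indices.sum(axis=1).abs().max())
    return {
        "timeshift_wake_total_violation": max_shift_violation,
        "occupancy_violation": max_occ_violation,
        "fidelity_index_max_abs_row_sum": index_sum,
    }
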