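"""End-to-end orchestration: ingest -> score -> sites -> fidelity -> sync -> arousal.

Every stage writes tabular outputs plus a machine-readable run manifest
(config hash, seeds, stage list), and re-running with the same configuration
and inputs reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accel, arousal, fidelity, sites, solar, sync
from .scoring import ScoringParams, score_day, compute_nap_minutes
from .sites import TreeMap

log = logging.getLogger("wildsleep")


@dataclass
class PipelineConfig:
    """Paths, site geometry and every stage parameter, with study defaults."""

    data_dir: str = "."
    out_dir: str = "out"
    accel_file: str = "accel.csv"
    minutes_file: str = "minute_logvedba.csv"
    continuous_file: str = "accel_continuous.csv"
    gps_file: str = "gps.csv"
    trees_file: str = "trees.geojson"
    site_lon: float = 36.90
    site_lat: float = 0.29
    tz_offset_hours: float = 3.0
    scoring: ScoringParams = field(default_factory=ScoringParams)
    vedba_window_s: float = 0.7
    day_vedba_window_s: float = 0.5
    location_cutoff: str = "06:15"
    location_n_fixes: int = 10
    tree_max_distance_m: float = 10.0
    travel_resolution_m: float = 5.0
    night_window_start_hour: int = 21
    n_perm: int = 1000
    n_iter: int = 1000
    first_n_nights: int = 14
    min_nights_fidelity: int = 4
    seed: int = 0

    @property
    def tz(self) -> dt.tzinfo:
        return dt.timezone(dt.timedelta(hours=self.tz_offset_hours))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scoring"] = {
            k: (v.isoformat() if isinstance(v, dt.time) else v)
            for k, v in dataclasses.asdict(self.scoring).items()
        }
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sc = raw.pop("scoring", {})
        for k in ("nap_start", "nap_end"):
            if k in sc and isinstance(sc[k], str):
                sc[k] = dt.time.fromisoformat(sc[k])
        cfg = cls(**raw)
        if sc:
            cfg.scoring = dataclasses.replace(ScoringParams(), **sc)
        return cfg


def load_minute_frame(config: PipelineConfig) -> pd.DataFrame:
    """Minute log-VeDBA frame from whichever input level is on disk.

    Prefers a precomputed per-minute file; otherwise ingests burst records
    (and, when present, a continuous daytime stream harmonized onto the burst
    schedule).
    """
    data = Path(config.data_dir)
    minutes = data / config.minutes_file
    if minutes.exists():
        df = pd.read_csv(minutes)
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
        wide = df.pivot_table(
            index="timestamp", columns="individual_id", values="log_vedba", aggfunc="first"
        )
        full = pd.date_range(wide.index.min(), wide.index.max(), freq="min")
        return wide.reindex(full)
    records = accel.read_accel_records(data / config.accel_file, tz=config.tz)
    cont_path = data / config.continuous_file
    if cont_path.exists():
        cont = pd.read_csv(cont_path)
        cont["timestamp"] = pd.to_datetime(cont["timestamp"], format="ISO8601")
        if cont["timestamp"].dt.tz is None:
            cont["timestamp"] = cont["timestamp"].dt.tz_localize(config.tz)
        records = pd.concat(
            [records, accel.harmonize_daytime(cont)], ignore_index=True
        ).drop_duplicates(["individual_id", "timestamp", "sample_index"], keep="first")
    means = accel.burst_mean_vedba(records, smoothing_window_s=config.vedba_window_s)
    return accel.assemble_minute_series(means)


def score_stage(
    frame: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every individual-day; returns (night_metrics, label_frame)."""
    first, last = frame.index[0], frame.index[-1]
    day0 = (first - pd.Timedelta(hours=12)).date()
    n_days = ((last - pd.Timedelta(hours=12)).date() - day0).days + 1
    days = [day0 + dt.timedelta(days=k) for k in range(n_days)]

    twilights: dict[dt.date, solar.TwilightTimes] = {}

    def twilight(d: dt.date) -> solar.TwilightTimes:
        if d not in twilights:
            twilights[d] = solar.compute_twilight(d, config.site_lat, config.site_lon, config.tz)
        return twilights[d]

    metric_rows = []
    label_cols = {}
    for ind in frame.columns:
        series = frame[ind]
        labels_parts = []
        idx_parts = []
        day_flags = {}
        for day in days:
            ds = score_day(
                series,
                ind,
                day,
                params=config.scoring,
                twilight_evening=twilight(day),
                twilight_morning=twilight(day + dt.timedelta(days=1)),
            )
            labels_parts.append(ds.labels)
            idx_parts.append(ds.index)
            day_flags[day] = ds.qc
            row = {
                "individual_id": ind,
                "night_id": day,
                "threshold": ds.threshold,
                "spt_onset": ds.spt.onset if ds.spt else pd.NaT,
                "spt_awakening": ds.spt.awakening if ds.spt else pd.NaT,
                "missing_ge_120": ds.qc["missing_ge_120"],
                "consecutive_ge_20": ds.qc["consecutive_ge_20"],
            }
            row.update(ds.metrics)
            metric_rows.append(row)
        lab = pd.Series(
            np.concatenate(labels_parts), index=idx_parts[0].append(idx_parts[1:])
        )
        label_cols[ind] = lab
        # napping per calendar day; invalid when a contributing day misses >=120 bursts
        for day in days:
            nap = compute_nap_minutes(lab, day, config.scoring)
            prior = day - dt.timedelta(days=1)
            invalid = day_flags.get(day, {}).get("missing_ge_120", False) or day_flags.get(
                prior, {}
            ).get("missing_ge_120", False)
            for r in metric_rows:
                if r["individual_id"] == ind and r["night_id"] == day:
                    r["nap_minutes"] = np.nan if invalid else nap
    metrics = pd.DataFrame(metric_rows)
    label_frame = pd.DataFrame(label_cols)
    return metrics, label_frame


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute every stage; returns the in-memory results and writes outputs."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stages: list[str] = []

    frame = load_minute_frame(config)
    results["minute_frame"] = frame
    stages.append("ingest")

    metrics, label_frame = score_stage(frame, config)
    results["night_metrics"] = metrics
    results["label_frame"] = label_frame
    stages.append("score")
    if write:
        metrics.to_csv(out / "night_metrics.csv", index=False)
        label_frame.to_csv(out / "epoch_labels.csv")

    data = Path(config.data_dir)
    nights = sorted(metrics["night_id"].unique())
    assignments = None
    if (data / config.gps_file).exists() and (data / config.trees_file).exists():
        gps = pd.read_csv(data / config.gps_file)
        gps["timestamp"] = pd.to_datetime(gps["timestamp"], format="ISO8601")
        if gps["timestamp"].dt.tz is None:
            gps["timestamp"] = gps["timestamp"].dt.tz_localize(config.tz)
        tree_map = TreeMap.from_geojson(data / config.trees_file)
        assignments = sites.assign_all_nights(
            gps,
            tree_map,
            nights,
            cutoff=dt.time.fromisoformat(config.location_cutoff),
            n_fixes=config.location_n_fixes,
            max_distance_m=config.tree_max_distance_m,
        )
        travel = []
        for ind, grp in gps.groupby("individual_id"):
            for day in nights:
                d, reason = sites.discretized_travel_distance(
                    grp, day, (config.site_lon, config.site_lat), config.travel_resolution_m
                )
                travel.append(
                    {"individual_id": ind, "day": day, "travel_m": d, "exclusion_reason": reason}
                )
        results["assignments"] = assignments
        results["travel"] = pd.DataFrame(travel)
        stages.append("sites")
        if write:
            assignments.to_csv(out / "sleep_assignments.csv", index=False)
            results["travel"].to_csv(out / "travel_distance.csv", index=False)

        try:
            rep = fidelity.fidelity_analysis(
                assignments,
                n_perm=config.n_perm,
                seed=config.seed,
                min_nights=config.min_nights_fidelity,
                first_n_nights=config.first_n_nights,
            )
            results["fidelity"] = rep
            stages.append("fidelity")
            if write:
                rep.fidelity_indices.to_csv(out / "fidelity_indices.csv")
                with open(out / "fidelity.json", "w") as fh:
                    json.dump(
                        {
                            "ks_statistic": rep.ks_statistic,
                            "p_value": rep.p_value,
                            "n_perm": rep.n_perm,
                            "seed": rep.seed,
                            "empirical_entropies": rep.empirical_entropies.to_dict(),
                        },
                        fh,
                        indent=2,
                    )
        except ValueError as exc:
            log.warning("fidelity stage skipped: %s", exc)

    if label_frame.shape[1] < 2:
        log.warning("fewer than 2 individuals: skipping group synchronization stage")
    else:
        matrix = sync.build_epoch_matrix(
            label_frame, nights, window_start_hour=config.night_window_start_hour
        )
        reports = {
            f"time_shift__{k}": v
            for k, v in sync.time_shift_null(
                matrix, n_iter=config.n_iter, seed=config.seed
            ).items()
        }
        if matrix.shape[0] >= 2:
            reports.update(
                {
                    f"night_permutation__{k}": v
                    for k, v in sync.night_permutation_null(
                        matrix, n_iter=config.n_iter, seed=config.seed + 1
                    ).items()
                }
            )
        dyads = sync.dyad_sync_scores(matrix, list(label_frame.columns), nights, assignments)
        results["sync_reports"] = reports
        results["dyads"] = dyads
        stages.append("sync")
        if write:
            dyads.to_csv(out / "dyad_sync.csv", index=False)
            with open(out / "sync_nulls.json", "w") as fh:
                json.dump(
                    {
                        name: {
                            "statistic": r.statistic,
                            "empirical": r.empirical,
                            "p_value": r.p_value,
                            "p_display": r.p_display,
                            "direction": r.direction,
                            "method": r.method,
                            "n_iter": len(r.nulls),
                            "null_mean": float(np.mean(r.nulls)),
                            "null_sd": float(np.std(r.nulls)),
                            "seed": r.seed,
                        }
                        for name, r in reports.items()
                    },
                    fh,
                    indent=2,
                )

        if assignments is not None:
            table = arousal.build_arousal_table(
                matrix,
                list(label_frame.columns),
                nights,
                assignments,
                night_metrics=metrics,
                first_n_nights=config.first_n_nights,
            )
            results["arousal_table"] = table
            stages.append("arousal")
            if write:
                table.to_csv(out / "arousal_table.csv", index=False)
                try:
                    fit = arousal.fit_response_standin(table)
                    results["arousal_fit"] = fit
                    fit.to_csv(out / "arousal_fit.csv")
                except ValueError as exc:
                    log.warning("arousal stand-in fit skipped: %s", exc)

    manifest = {
        "stages": stages,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_individuals": int(frame.shape[1]),
    }
    results["manifest"] = manifest
    if write:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results


def simulate_command(sim_config, out_dir, level: str = "minutes") -> Path:
    """Write a synthetic dataset consumable by :func:`run_pipeline`."""
    from . import simulate as sim

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree_map = sim.make_tree_map(
        sim_config.n_trees, (sim_config.site_lon, sim_config.site_lat), sim_config.seed
    )
    truth = sim.generate_group_truth(sim_config, tree_map)
    tree_map.to_geojson(out / "trees.geojson")
    gps = sim.render_gps_fixes(truth, tree_map)
    gps.to_csv(out / "gps.csv", index=False)
    truth.night_table().to_csv(out / "truth_nights.csv", index=False)
    truth.epoch_table().to_csv(out / "truth_epochs.csv", index=False)
    if level == "minutes":
        frame = sim.render_minute_logvedba(truth)
        frame = sim.inject_missingness_minutes(
            frame, sim_config.missing_burst_prob, seed=sim_config.seed
        )
        long = frame.stack().rename("log_vedba").reset_index()
        long.columns = ["timestamp", "individual_id", "log_vedba"]
        long[["individual_id", "timestamp", "log_vedba"]].to_csv(
            out / "minute_logvedba.csv", index=False
        )
    elif level == "bursts":
        records = sim.render_accel_bursts(truth)
        records, dropped = sim.inject_missingness(
            records, sim_config.missing_burst_prob, seed=sim_config.seed
        )
        records.to_csv(out / "accel.csv", index=False)
        dropped.to_csv(out / "dropped_bursts.csv", index=False)
    else:
        raise ValueError(f"unknown output level {level!r}")
    return out
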