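"""Synthetic biologger data with known ground truth.

Simulates a group of collared animals sharing a wooded sleep site: each
individual has a consolidated nocturnal sleep period (sampled onset/offset
clock times), Poisson-seeded wake bouts with geometric durations, optional
wake contagion between tree-mates (an individual asleep at epoch t wakes with
``coupling_prob`` when any same-tree group-mate transitioned to wake at t-1),
and a fixed per-individual sleep-tree preference from which a tree is drawn
each night.

Three latent states are tracked — sleep, resting wake and active wake — even
though scoring is binary: resting wake is emitted at sleep-like VeDBA, so the
known actigraphy failure mode (quiet wakefulness scored as sleep) can be
quantified against truth.

Emission model: the log of a minute's mean VeDBA is Gaussian around the
state's emission mean. Acceleration is rendered on a milli-g scale (gravity =
1000 units) so resting log VeDBA is positive; the multiplicative percentile
threshold used in scoring requires a positive log scale to separate sleep
from wake (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from . import accel
from .scoring import EPOCHS_PER_DAY
from .sites import TreeMap, from_local_xy

STATE_SLEEP, STATE_REST_WAKE, STATE_ACTIVE_WAKE = 0, 1, 2
STATE_NAMES = {STATE_SLEEP: "sleep", STATE_REST_WAKE: "resting-wake", STATE_ACTIVE_WAKE: "active-wake"}

GRAVITY = 1000.0  # milli-g scale


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated group.

    Clock-time parameters are local (the site timezone is a fixed UTC offset).
    Emission means/sds are in log VeDBA units (natural log, milli-g scale).
    """

    n_individuals: int = 26
    n_nights: int = 35
    epoch_length_s: int = 60
    # sleep window clock times (minutes after local noon)
    night_sleep_start_mean_min: float = 450.0  # 19:30
    night_sleep_start_sd_min: float = 20.0
    night_sleep_end_mean_min: float = 1065.0  # 05:45 next day
    night_sleep_end_sd_min: float = 20.0
    wake_bout_rate_per_h: float = 1.5
    wake_bout_mean_min: float = 2.0
    resting_wake_prob: float = 0.0  # fraction of night wake bouts that are quiet
    coupling_prob: float = 0.0
    n_trees: int = 10
    tree_preference_concentration: float = 2.0
    day_logvedba_mean: float = 6.0
    day_logvedba_sd: float = 0.5
    sleep_logvedba_mean: float = 3.5
    sleep_logvedba_sd: float = 0.12
    restingwake_logvedba_mean: float = 3.8
    restingwake_logvedba_sd: float = 0.12
    missing_burst_prob: float = 0.01
    gps_jitter_m: float = 2.0
    day_track_length_m: float = 3000.0
    # spacing chosen so consecutive track fixes sit ~10 m apart: comfortably
    # above the 5-m discretization and large against GPS jitter
    day_track_fix_interval_s: float = 120.0
    site_lon: float = 36.90
    site_lat: float = 0.29
    tz_offset_hours: float = 3.0
    start_date: dt.date = dt.date(2012, 8, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coupling_prob", "missing_burst_prob", "resting_wake_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_individuals < 1 or self.n_nights < 1 or self.n_trees < 1:
            raise ValueError("n_individuals, n_nights and n_trees must be positive")
        if self.sleep_logvedba_mean >= self.day_logvedba_mean:
            raise ValueError("sleep emission mean must be below day emission mean")
        if 86400 % self.epoch_length_s:
            raise ValueError("epoch_length_s must divide one day")
        if self.tree_preference_concentration < 0:
            raise ValueError("tree_preference_concentration must be >= 0")
        if self.wake_bout_rate_per_h < 0 or self.wake_bout_mean_min <= 0:
            raise ValueError("wake bout rate must be >= 0 and mean duration > 0")

    @property
    def tz(self) -> dt.tzinfo:
        return dt.timezone(dt.timedelta(hours=self.tz_offset_hours))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Latent truth for a simulated group."""

    config: SimConfig
    individuals: list[str]
    index: pd.DatetimeIndex  # minute epochs, noon day 0 to noon after last night
    states: np.ndarray  # (n_individuals, n_epochs) int8 state codes
    onset_idx: np.ndarray  # (n_individuals, n_nights) absolute epoch index
    offset_idx: np.ndarray
    trees: np.ndarray  # (n_individuals, n_nights) tree ids
    preferences: np.ndarray  # (n_individuals, n_trees)
    coupling_events: list = field(default_factory=list)

    @property
    def sleep_mask(self) -> np.ndarray:
        return self.states == STATE_SLEEP

    def night_dates(self) -> list[dt.date]:
        d0 = self.config.start_date
        return [d0 + dt.timedelta(days=n) for n in range(self.config.n_nights)]

    def epoch_table(self) -> pd.DataFrame:
        """Long truth table: individual_id, timestamp, state name."""
        frames = []
        for i, ind in enumerate(self.individuals):
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ind,
                        "timestamp": self.index,
                        "state": [STATE_NAMES[s] for s in self.states[i]],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def night_table(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.individuals):
            for n, night in enumerate(self.night_dates()):
                rows.append(
                    {
                        "individual_id": ind,
                        "night_id": night,
                        "onset": self.index[self.onset_idx[i, n]],
                        "awakening": self.index[0]
                        + pd.Timedelta(minutes=int(self.offset_idx[i, n])),
                        "tree_id": int(self.trees[i, n]),
                    }
                )
        return pd.DataFrame(rows)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def make_tree_map(
    n_trees: int, site_center: tuple[float, float], seed: int = 0
) -> TreeMap:
    """Non-overlapping convex crown polygons (5-15 m diameter) near a site.

    Crown centres sit on a jittered grid with 30-m spacing, which guarantees
    pairwise disjoint crowns at the maximum 7.5-m radius.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 900]))
    side = int(np.ceil(np.sqrt(n_trees)))
    spacing = 30.0
    crowns = {}
    cells = [(r, c) for r in range(side) for c in range(side)][:n_trees]
    offset = (side - 1) * spacing / 2.0
    for tid, (r, c) in enumerate(cells):
        cx = c * spacing - offset + rng.uniform(-5, 5)
        cy = r * spacing - offset + rng.uniform(-5, 5)
        radius = rng.uniform(2.5, 7.5)
        angles = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(8, 13)))
        radii = radius * rng.uniform(0.8, 1.0, len(angles))
        pts = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
        hull = MultiPoint(list(map(tuple, pts))).convex_hull
        xs, ys = np.asarray(hull.exterior.coords).T
        lon, lat = from_local_xy(xs, ys, site_center)
        crowns[tid] = Polygon(np.column_stack([lon, lat]))
    return TreeMap(site_center=site_center, crowns=crowns)


def generate_group_truth(config: SimConfig, tree_map: TreeMap | None = None) -> GroundTruth:
    """Sample the latent group process: sleep windows, wake bouts, contagion, trees."""
    if tree_map is None:
        tree_map = make_tree_map(config.n_trees, (config.site_lon, config.site_lat), config.seed)
    elif len(tree_map.tree_ids) != config.n_trees:
        raise ValueError(
            f"tree map has {len(tree_map.tree_ids)} trees but config.n_trees={config.n_trees}"
        )
    rng = _rng(config, 1)
    n_ind, n_nights = config.n_individuals, config.n_nights
    n_epochs = n_nights * EPOCHS_PER_DAY
    individuals = [f"ind{i:02d}" for i in range(1, n_ind + 1)]
    t0 = pd.Timestamp(
        dt.datetime.combine(config.start_date, dt.time(12, 0)), tz=config.tz
    )
    index = pd.date_range(t0, periods=n_epochs, freq="min")

    states = np.full((n_ind, n_epochs), STATE_ACTIVE_WAKE, dtype=np.int8)

    onset = np.rint(
        rng.normal(config.night_sleep_start_mean_min, config.night_sleep_start_sd_min, (n_ind, n_nights))
    ).astype(int)
    offset = np.rint(
        rng.normal(config.night_sleep_end_mean_min, config.night_sleep_end_sd_min, (n_ind, n_nights))
    ).astype(int)
    onset = np.clip(onset, 1, EPOCHS_PER_DAY - 2)
    offset = np.clip(offset, onset + 60, EPOCHS_PER_DAY - 1)
    base = np.arange(n_nights) * EPOCHS_PER_DAY
    onset_idx = onset + base
    offset_idx = offset + base

    # tree preferences: softmax of standard-normal logits scaled by concentration
    logits = rng.standard_normal((n_ind, config.n_trees))
    conc = config.tree_preference_concentration
    if np.isinf(conc):
        prefs = np.zeros_like(logits)
        prefs[np.arange(n_ind), logits.argmax(axis=1)] = 1.0
    else:
        z = conc * logits
        z -= z.max(axis=1, keepdims=True)
        prefs = np.exp(z)
        prefs /= prefs.sum(axis=1, keepdims=True)
    cum = prefs.cumsum(axis=1)
    u = rng.random((n_ind, n_nights))
    trees = (u[:, :, None] > cum[:, None, :]).sum(axis=2)

    geom_p = 1.0 / config.wake_bout_mean_min

    def sample_duration() -> int:
        return int(rng.geometric(geom_p))

    # spontaneous wake bouts inside each sleep window
    wake_onsets: list[set[int]] = [set() for _ in range(n_ind)]
    for i in range(n_ind):
        for n in range(n_nights):
            o, f = onset_idx[i, n], offset_idx[i, n]
            states[i, o:f] = STATE_SLEEP
    for i in range(n_ind):
        for n in range(n_nights):
            o, f = onset_idx[i, n], offset_idx[i, n]
            hours = (f - o) / 60.0
            for _ in range(rng.poisson(config.wake_bout_rate_per_h * hours)):
                start = int(rng.integers(o, f))
                dur = sample_duration()
                kind = (
                    STATE_REST_WAKE
                    if rng.random() < config.resting_wake_prob
                    else STATE_ACTIVE_WAKE
                )
                states[i, start : min(start + dur, f)] = kind
    # recover actual wake-transition epochs after overlaps
    for i in range(n_ind):
        s = states[i]
        awake = s != STATE_SLEEP
        trans = np.nonzero(awake[1:] & ~awake[:-1])[0] + 1
        wake_onsets[i] = set(int(t) for t in trans)

    coupling_events: list[dict] = []
    if config.coupling_prob > 0 and n_ind > 1:
        for n in range(n_nights):
            for tree in np.unique(trees[:, n]):
                members = np.nonzero(trees[:, n] == tree)[0]
                if len(members) < 2:
                    continue
                lo = int(onset_idx[members, n].min())
                hi = int(offset_idx[members, n].max())
                pending = sorted(
                    t
                    for i in members
                    for t in wake_onsets[i]
                    if lo <= t < hi
                )
                heapq.heapify(pending)
                seen: set[int] = set()
                while pending:
                    t_on = heapq.heappop(pending)
                    if t_on in seen:
                        continue
                    seen.add(t_on)
                    t = t_on + 1
                    if t >= hi:
                        continue
                    for j in members:
                        if states[j, t] != STATE_SLEEP or states[j, t - 1] != STATE_SLEEP:
                            continue
                        if t >= offset_idx[j, n] or t <= onset_idx[j, n]:
                            continue
                        if rng.random() < config.coupling_prob:
                            dur = sample_duration()
                            end = min(t + dur, int(offset_idx[j, n]))
                            kind = (
                                STATE_REST_WAKE
                                if rng.random() < config.resting_wake_prob
                                else STATE_ACTIVE_WAKE
                            )
                            states[j, t:end] = kind
                            coupling_events.append(
                                {"night": n, "epoch": t, "individual": individuals[j], "tree": int(tree)}
                            )
                            if t not in seen:
                                heapq.heappush(pending, t)
    return GroundTruth(
        config=config,
        individuals=individuals,
        index=index,
        states=states,
        onset_idx=onset_idx,
        offset_idx=offset_idx,
        trees=trees,
        preferences=prefs,
        coupling_events=coupling_events,
    )


def state_emission_params(config: SimConfig) -> dict[int, tuple[float, float]]:
    return {
        STATE_SLEEP: (config.sleep_logvedba_mean, config.sleep_logvedba_sd),
        STATE_REST_WAKE: (config.restingwake_logvedba_mean, config.restingwake_logvedba_sd),
        STATE_ACTIVE_WAKE: (config.day_logvedba_mean, config.day_logvedba_sd),
    }


def render_minute_logvedba(truth: GroundTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Per-minute log-VeDBA frame straight from the emission model.

    Equivalent in distribution to rendering raw bursts and running the ingest
    pipeline; used for large simulation studies where raw-signal rendering
    adds nothing.
    """
    config = config or truth.config
    rng = _rng(config, 2)
    params = state_emission_params(config)
    n_ind, n_epochs = truth.states.shape
    out = np.empty((n_epochs, n_ind))
    noise = rng.standard_normal((n_ind, n_epochs))
    for code, (mu, sd) in params.items():
        mask = truth.states == code
        out.T[mask] = mu + sd * noise[mask]
    return pd.DataFrame(out, index=truth.index, columns=truth.individuals)


def _unit_waveform(n_samples: int, rate_hz: float) -> np.ndarray:
    """Fixed zero-static-free dynamic waveform used to hit a target VeDBA."""
    t = np.arange(n_samples) / rate_hz
    w = np.zeros((n_samples, 3))
    w[:, 0] = np.sin(2 * np.pi * 2.0 * t)
    w[:, 1] = np.cos(2 * np.pi * 2.3 * t)
    return w


def _waveform_gain(n_samples: int, rate_hz: float, smoothing_window_s: float) -> float:
    g = np.tile([0.0, 0.0, GRAVITY], (n_samples, 1))
    _, m = accel.compute_vedba(g + _unit_waveform(n_samples, rate_hz), rate_hz, smoothing_window_s)
    return m


def render_accel_bursts(
    truth: GroundTruth,
    config: SimConfig | None = None,
    individuals: list[str] | None = None,
    epoch_slice: slice = slice(None),
    rate_hz: float = 10.0,
    burst_duration_s: float = 2.5,
    smoothing_window_s: float = 0.7,
) -> pd.DataFrame:
    """Per-minute triaxial bursts whose mean VeDBA matches the emission draw.

    Each burst is gravity plus a fixed dynamic waveform scaled so that the
    ingest pipeline's burst-mean VeDBA equals the target exactly (the VeDBA of
    a scaled dynamic signal scales linearly). Deterministic for a fixed seed.
    """
    config = config or truth.config
    rng = _rng(config, 3)
    params = state_emission_params(config)
    n_samp = int(round(rate_hz * burst_duration_s))
    w = _unit_waveform(n_samp, rate_hz)
    gain = _waveform_gain(n_samp, rate_hz, smoothing_window_s)
    sel = truth.individuals if individuals is None else individuals
    epoch_idx = np.arange(len(truth.index))[epoch_slice]
    frames = []
    for ind in sel:
        i = truth.individuals.index(ind)
        mus = np.array([params[s][0] for s in truth.states[i, epoch_slice]])
        sds = np.array([params[s][1] for s in truth.states[i, epoch_slice]])
        logv = mus + sds * rng.standard_normal(len(mus))
        target = np.maximum(np.exp(logv) - accel.LOG_EPS, 0.0)
        scale = target / gain
        n_e = len(epoch_idx)
        sample_block = (
            np.tile([0.0, 0.0, GRAVITY], (n_e * n_samp, 1))
            + np.repeat(scale, n_samp)[:, None] * np.tile(w, (n_e, 1))
        )
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ind,
                    "timestamp": np.repeat(truth.index[epoch_idx], n_samp),
                    "sample_index": np.tile(np.arange(n_samp), n_e),
                    "acc_x": sample_block[:, 0],
                    "acc_y": sample_block[:, 1],
                    "acc_z": sample_block[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def render_daytime_stream(
    truth: GroundTruth,
    config: SimConfig | None = None,
    individuals: list[str] | None = None,
    date: dt.date | None = None,
    start: dt.time = dt.time(6, 0),
    end: dt.time = dt.time(18, 0),
    rate_hz: float = 12.0,
) -> pd.DataFrame:
    """Continuous daytime stream (default 12 Hz) for one calendar date."""
    config = config or truth.config
    rng = _rng(config, 4)
    params = state_emission_params(config)
    date = date or config.start_date
    sel = truth.individuals if individuals is None else individuals
    n_per_min = int(round(rate_hz * 60))
    w = _unit_waveform(n_per_min, rate_hz)
    gain = _waveform_gain(n_per_min, rate_hz, 0.7)
    t_start = pd.Timestamp(dt.datetime.combine(date, start), tz=config.tz)
    t_end = pd.Timestamp(dt.datetime.combine(date, end), tz=config.tz)
    minutes = pd.date_range(t_start, t_end, freq="min", inclusive="left")
    frames = []
    for ind in sel:
        i = truth.individuals.index(ind)
        pos = truth.index.get_indexer(minutes)
        states = np.where(pos >= 0, truth.states[i, np.maximum(pos, 0)], STATE_ACTIVE_WAKE)
        mus = np.array([params[s][0] for s in states])
        sds = np.array([params[s][1] for s in states])
        logv = mus + sds * rng.standard_normal(len(mus))
        scale = np.maximum(np.exp(logv) - accel.LOG_EPS, 0.0) / gain
        block = (
            np.tile([0.0, 0.0, GRAVITY], (len(minutes) * n_per_min, 1))
            + np.repeat(scale, n_per_min)[:, None] * np.tile(w, (len(minutes), 1))
        )
        ts = np.repeat(minutes, n_per_min) + np.tile(
            pd.to_timedelta(np.arange(n_per_min) / rate_hz, unit="s"), len(minutes)
        )
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ind,
                    "timestamp": ts,
                    "acc_x": block[:, 0],
                    "acc_y": block[:, 1],
                    "acc_z": block[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def render_gps_fixes(
    truth: GroundTruth,
    tree_map: TreeMap,
    config: SimConfig | None = None,
    n_morning_fixes: int = 12,
    include_day_track: bool = True,
) -> pd.DataFrame:
    """GPS fixes: morning/evening clusters at the true sleep tree plus a
    daytime loop of the configured nominal length around the site centre."""
    config = config or truth.config
    rng = _rng(config, 5)
    jitter = config.gps_jitter_m
    centroids = {}
    for tid in tree_map.tree_ids:
        c = tree_map.projected(tid).centroid
        centroids[tid] = (c.x, c.y)
    rows = []
    tz = config.tz
    nights = truth.night_dates()
    for i, ind in enumerate(truth.individuals):
        for n, night in enumerate(nights):
            cx, cy = centroids[int(truth.trees[i, n])]
            # morning cluster, next calendar day, before 06:15
            m0 = pd.Timestamp(
                dt.datetime.combine(night + dt.timedelta(days=1), dt.time(5, 50)), tz=tz
            )
            for k in range(n_morning_fixes):
                x = cx + rng.normal(0, jitter)
                y = cy + rng.normal(0, jitter)
                lon, lat = from_local_xy(x, y, tree_map.site_center)
                rows.append((ind, m0 + pd.Timedelta(seconds=30 * k), float(lon), float(lat)))
            # evening cluster at the tree keeps the day's last fix after 17:00
            e0 = pd.Timestamp(dt.datetime.combine(night, dt.time(17, 30)), tz=tz)
            for k in range(6):
                x = cx + rng.normal(0, jitter)
                y = cy + rng.normal(0, jitter)
                lon, lat = from_local_xy(x, y, tree_map.site_center)
                rows.append((ind, e0 + pd.Timedelta(seconds=60 * k), float(lon), float(lat)))
            if include_day_track and config.day_track_length_m > 0:
                L = config.day_track_length_m
                interval = config.day_track_fix_interval_s
                # start before 07:30 and run to 17:00 so the day passes the
                # travel-distance coverage rule
                t_day0 = pd.Timestamp(dt.datetime.combine(night, dt.time(7, 0)), tz=tz)
                n_fix = int((10 * 3600) // interval)
                radius = L / (2 * np.pi)
                theta = np.linspace(0, 2 * np.pi, n_fix)
                # circle through tonight's tree: leave the sleep site, loop,
                # and return, so the nominal length is the full day's path
                xs = cx + radius * (1 - np.cos(theta)) + rng.normal(0, jitter, n_fix)
                ys = cy + radius * np.sin(theta) + rng.normal(0, jitter, n_fix)
                lons, lats = from_local_xy(xs, ys, tree_map.site_center)
                for k in range(n_fix):
                    rows.append(
                        (
                            ind,
                            t_day0 + pd.Timedelta(seconds=interval * k),
                            float(lons[k]),
                            float(lats[k]),
                        )
                    )
    df = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lon", "lat"])
    return df.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


def inject_missingness(
    records: pd.DataFrame,
    missing_burst_prob: float,
    consecutive_runs: list[tuple[str, pd.Timestamp, int]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop whole bursts i.i.d. and/or insert specified consecutive gaps.

    ``records`` is the long burst frame; all rows of a dropped (individual,
    epoch) disappear. Returns (thinned records, provenance of dropped epochs).
    """
    if not 0.0 <= missing_burst_prob <= 1.0:
        raise ValueError("missing_burst_prob must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    epochs = records[["individual_id", "timestamp"]].drop_duplicates().reset_index(drop=True)
    drop = rng.random(len(epochs)) < missing_burst_prob
    dropped = epochs.loc[drop].copy()
    dropped["reason"] = "iid"
    extra = []
    for ind, start, length in consecutive_runs or []:
        run = pd.DataFrame(
            {
                "individual_id": ind,
                "timestamp": pd.date_range(start, periods=length, freq="min"),
                "reason": "run",
            }
        )
        extra.append(run)
    if extra:
        dropped = pd.concat([dropped] + extra, ignore_index=True).drop_duplicates(
            ["individual_id", "timestamp"]
        )
    key = records.merge(
        dropped[["individual_id", "timestamp"]].assign(_drop=True),
        on=["individual_id", "timestamp"],
        how="left",
    )
    out = records.loc[key["_drop"].isna().to_numpy()].reset_index(drop=True)
    return out, dropped.reset_index(drop=True)


def inject_missingness_minutes(
    frame: pd.DataFrame,
    missing_burst_prob: float,
    seed: int = 0,
    consecutive_runs: list[tuple[str, pd.Timestamp, int]] | None = None,
) -> pd.DataFrame:
    """Minute-frame analogue of :func:`inject_missingness` (sets NaN)."""
    if not 0.0 <= missing_burst_prob <= 1.0:
        raise ValueError("missing_burst_prob must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    out = frame.copy()
    mask = rng.random(out.shape) < missing_burst_prob
    out = out.mask(mask)
    for ind, start, length in consecutive_runs or []:
        rows = pd.date_range(start, periods=length, freq="min")
        out.loc[out.index.isin(rows), ind] = np.nan
    return out
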