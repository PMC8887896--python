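"""Group-level nocturnal wakefulness and synchronization, with null models.

All statistics run on an epoch matrix restricted to 21:00-05:00 local (480
one-minute epochs per night, well inside every individual's sleep period):

- ``prop_any_awake``: fraction of epochs (pooled over nights) in which at
  least one non-missing group member is awake.
- ``mean_prop_synchronized``: per epoch, the fraction of dyads of non-missing
  individuals that are in the same state (sleep or wake), averaged over epochs
  (a modal-state-fraction variant is available but degenerate; see
  :func:`group_wake_statistics`).

Two resampling nulls destroy cross-individual alignment while preserving
structure: the time-shift null circularly rotates each individual-night state
vector (conserving that night's wake total and autocorrelation), and the
night-permutation null reassigns each individual's nights to other night slots
(controlling for a shared stereotyped schedule). P-values are the proportion
of null values as or more extreme than the empirical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import MISSING, SLEEP, WAKE

NIGHT_WINDOW_START = "21:00"
NIGHT_WINDOW_EPOCHS = 480


def build_epoch_matrix(
    label_frame: pd.DataFrame, nights: list, window_start_hour: int = 21
) -> np.ndarray:
    """(n_nights, n_individuals, 480) state matrix from a minute label frame.

    ``label_frame``: rows = minute epochs (tz-aware index), columns =
    individuals, values in {SLEEP, WAKE, MISSING}. Night n covers
    [night 21:00, night+1 05:00).
    """
    tz = label_frame.index.tz
    mats = []
    for night in nights:
        start = pd.Timestamp(night, tz=tz) + pd.Timedelta(hours=window_start_hour)
        idx = pd.date_range(start, periods=NIGHT_WINDOW_EPOCHS, freq="min")
        sub = label_frame.reindex(idx).to_numpy(dtype=float)
        sub = np.where(np.isnan(sub), MISSING, sub)
        mats.append(sub.T.astype(np.int8))
    return np.stack(mats)


def group_wake_statistics(matrix: np.ndarray, statistic: str = "pairwise") -> tuple[float, float]:
    """(prop_any_awake, mean_prop_synchronized) over all nights and epochs.

    Per-epoch synchronization is, by default, the fraction of concordant
    dyads among non-missing individuals ("pairwise"); ``statistic="modal"``
    gives the modal-state fraction instead. The pairwise definition is the
    package default because the modal fraction is degenerate under the
    time-shift null: when no epoch has a wake majority, its mean reduces to
    one minus the (conserved) wake fraction, so resampling cannot move it.

    Epochs with no non-missing individual are excluded from both statistics;
    epochs with a single non-missing individual are excluded from the
    pairwise synchronization (agreement among fewer than two is undefined).
    """
    wake = matrix == WAKE
    sleep = matrix == SLEEP
    n_wake = wake.sum(axis=1).astype(float)  # (nights, epochs)
    n_sleep = sleep.sum(axis=1).astype(float)
    n_obs = n_wake + n_sleep
    valid = n_obs > 0
    if not valid.any():
        raise ValueError("no epoch has a non-missing individual")
    any_awake = (n_wake[valid] > 0).mean()
    if statistic == "pairwise":
        ok = n_obs > 1
        if not ok.any():
            raise ValueError("pairwise synchronization needs >= 2 observed individuals")
        nw, ns, n = n_wake[ok], n_sleep[ok], n_obs[ok]
        sync = ((nw * (nw - 1) + ns * (ns - 1)) / (n * (n - 1))).mean()
    elif statistic == "modal":
        sync = (np.maximum(n_wake[valid], n_sleep[valid]) / n_obs[valid]).mean()
    else:
        raise ValueError(f"unknown synchronization statistic {statistic!r}")
    return float(any_awake), float(sync)


@dataclass
class NullDistributionReport:
    statistic: str
    empirical: float
    nulls: np.ndarray
    p_value: float
    direction: str
    method: str
    seed: int

    @property
    def p_display(self) -> str:
        n = len(self.nulls)
        return f"< {1.0 / n:g}" if self.p_value == 0 else f"{self.p_value:g}"


def permutation_pvalue(empirical: float, nulls: np.ndarray, direction: str) -> float:
    """Proportion of null values as or more extreme than the empirical value."""
    nulls = np.asarray(nulls, dtype=float)
    if len(nulls) == 0:
        raise ValueError("null distribution is empty")
    if direction == "le":
        count = int((nulls <= empirical).sum())
    elif direction == "ge":
        count = int((nulls >= empirical).sum())
    else:
        raise ValueError(f"unknown direction {direction!r} (use 'le' or 'ge')")
    return count / len(nulls)


def _shifted(matrix: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Circularly shift each (night, individual) row of the epoch axis."""
    n_nights, n_ind, n_ep = matrix.shape
    col = (np.arange(n_ep)[None, None, :] - shifts[:, :, None]) % n_ep
    return np.take_along_axis(matrix, col, axis=2)


def time_shift_null(
    matrix: np.ndarray, n_iter: int = 1000, seed: int = 0, statistic: str = "pairwise"
) -> dict[str, NullDistributionReport]:
    """Time-shift null for both group statistics.

    Each individual-night vector is rotated by an offset uniform on {1..479}
    (0 excluded); missing epochs travel with the vector, so each night's wake
    total is conserved exactly.
    """
    rng = np.random.default_rng(seed)
    n_nights, n_ind, n_ep = matrix.shape
    emp_any, emp_sync = group_wake_statistics(matrix, statistic)
    nulls = np.empty((n_iter, 2))
    for it in range(n_iter):
        shifts = rng.integers(1, n_ep, size=(n_nights, n_ind))
        nulls[it] = group_wake_statistics(_shifted(matrix, shifts), statistic)
    return {
        "prop_any_awake": NullDistributionReport(
            "prop_any_awake",
            emp_any,
            nulls[:, 0],
            permutation_pvalue(emp_any, nulls[:, 0], "le"),
            "le",
            "time_shift",
            seed,
        ),
        "mean_prop_synchronized": NullDistributionReport(
            "mean_prop_synchronized",
            emp_sync,
            nulls[:, 1],
            permutation_pvalue(emp_sync, nulls[:, 1], "ge"),
            "ge",
            "time_shift",
            seed,
        ),
    }


def night_permutation_null(
    matrix: np.ndarray, n_iter: int = 1000, seed: int = 0, statistic: str = "pairwise"
) -> dict[str, NullDistributionReport]:
    """Night-permutation null: per individual, night vectors swap night slots.

    Clock alignment within the night is preserved; an individual's multiset of
    night vectors is conserved exactly.
    """
    n_nights, n_ind, _ = matrix.shape
    if n_nights < 2:
        raise ValueError("night permutation requires at least 2 nights")
    rng = np.random.default_rng(seed)
    emp_any, emp_sync = group_wake_statistics(matrix, statistic)
    nulls = np.empty((n_iter, 2))
    for it in range(n_iter):
        perm = np.empty_like(matrix)
        for i in range(n_ind):
            perm[:, i, :] = matrix[rng.permutation(n_nights), i, :]
        nulls[it] = group_wake_statistics(perm, statistic)
    return {
        "prop_any_awake": NullDistributionReport(
            "prop_any_awake",
            emp_any,
            nulls[:, 0],
            permutation_pvalue(emp_any, nulls[:, 0], "le"),
            "le",
            "night_permutation",
            seed,
        ),
        "mean_prop_synchronized": NullDistributionReport(
            "mean_prop_synchronized",
            emp_sync,
            nulls[:, 1],
            permutation_pvalue(emp_sync, nulls[:, 1], "ge"),
            "ge",
            "night_permutation",
            seed,
        ),
    }


def dyad_sync_scores(
    matrix: np.ndarray,
    individuals: list[str],
    nights: list,
    assignments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per dyad-night synchronization: agreements / co-observed minutes.

    Adds a ``same_tree`` flag from the assignment table when given; dyads with
    an excluded assignment get a missing flag. Dyad-nights with zero
    co-observed minutes are omitted.
    """
    tree_of = {}
    if assignments is not None:
        for _, r in assignments.iterrows():
            tree_of[(r["individual_id"], r["night_id"])] = (
                int(r["tree_id"]) if pd.notna(r["tree_id"]) else None
            )
    rows = []
    n_nights, n_ind, _ = matrix.shape
    for n, night in enumerate(nights):
        for a in range(n_ind):
            for b in range(a + 1, n_ind):
                va, vb = matrix[n, a], matrix[n, b]
                co = (va != MISSING) & (vb != MISSING)
                n_co = int(co.sum())
                if n_co == 0:
                    continue
                score = float((va[co] == vb[co]).mean())
                same_tree: bool | None = None
                if assignments is not None:
                    ta = tree_of.get((individuals[a], night))
                    tb = tree_of.get((individuals[b], night))
                    same_tree = (ta == tb) if ta is not None and tb is not None else None
                rows.append(
                    {
                        "id_a": individuals[a],
                        "id_b": individuals[b],
                        "night_id": night,
                        "sync_score": score,
                        "minutes_observed": n_co,
                        "same_tree": same_tree,
                    }
                )
    return pd.DataFrame(rows)
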