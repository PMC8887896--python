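"""Arousal-response (wake-contagion) design table and a logistic stand-in fit.

The response analysis asks whether a sleeping animal is more likely to wake at
epoch t when a same-tree group-mate was awake at t-1, and how the previous
night's sleep modulates that response. Eligible rows are epochs between 21:00
and 05:00, within the first study nights, in which the focal individual was
asleep for the three preceding epochs; the outcome is whether the focal is
awake at t. Covariates are individual-mean-centred previous-night total sleep
time and fragmentation, and their interactions with the group-mate predictor.

The table is written for mixed-model backends (the natural model is a
Bernoulli GLMM with individual and night intercepts); the built-in stand-in
is an ordinary logistic regression with cluster-robust (by individual)
errors, providing the sign/significance surface on the same fixed effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import MISSING, SLEEP, WAKE


def relative_covariates(night_metrics: pd.DataFrame) -> pd.DataFrame:
    """Individual-mean-centred night covariates.

    Adds rel_tst and rel_frag (value minus the individual's mean over its
    valid nights) to a frame with columns individual_id, night_id,
    total_sleep_time, sleep_fragmentation. Individuals with no valid nights
    keep NaN.
    """
    df = night_metrics.copy()
    for col, rel in [("total_sleep_time", "rel_tst"), ("sleep_fragmentation", "rel_frag")]:
        df[rel] = df[col] - df.groupby("individual_id")[col].transform("mean")
    return df


def relative_tree_occupancy(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per individual-night: individuals in its tree / all assigned that night."""
    df = assignments.dropna(subset=["tree_id"]).copy()
    per_night = df.groupby("night_id")["individual_id"].transform("size")
    per_tree = df.groupby(["night_id", "tree_id"])["individual_id"].transform("size")
    df["relative_occupancy"] = per_tree / per_night
    return df[["individual_id", "night_id", "relative_occupancy"]]


def build_arousal_table(
    matrix: np.ndarray,
    individuals: list[str],
    nights: list,
    assignments: pd.DataFrame,
    night_metrics: pd.DataFrame | None = None,
    first_n_nights: int = 14,
    min_sleep_run: int = 3,
) -> pd.DataFrame:
    """Epoch-level design table for the arousal-response model.

    ``matrix`` is the (nights, individuals, 480) 21:00-05:00 state matrix.
    A row exists for focal f at epoch t when: the night is within the first
    ``first_n_nights``; f was asleep at t-1, t-2 and t-3 (all within the
    window); f has a tree assignment; and at least one same-tree group-mate
    has a non-missing state at t-1. ``groupmate_awake_prev`` is 1 when any
    such group-mate was awake at t-1.
    """
    tree_of = {
        (r["individual_id"], r["night_id"]): int(r["tree_id"])
        for _, r in assignments.iterrows()
        if pd.notna(r["tree_id"])
    }
    rel = None
    if night_metrics is not None:
        rel = relative_covariates(night_metrics).set_index(["individual_id", "night_id"])

    rows = []
    n_nights = min(len(nights), first_n_nights)
    for n in range(n_nights):
        night = nights[n]
        prev_night = nights[n - 1] if n > 0 else None
        trees_tonight = {
            ind: tree_of.get((ind, night)) for ind in individuals
        }
        for fi, focal in enumerate(individuals):
            tree = trees_tonight[focal]
            if tree is None:
                continue
            mates = [
                j
                for j, ind in enumerate(individuals)
                if ind != focal and trees_tonight[ind] == tree
            ]
            if not mates:
                continue
            v = matrix[n, fi]
            mate_states = matrix[n, mates]  # (n_mates, 480)
            rel_tst = rel_frag = np.nan
            if rel is not None and prev_night is not None:
                key = (focal, prev_night)
                if key in rel.index:
                    rel_tst = rel.loc[key, "rel_tst"]
                    rel_frag = rel.loc[key, "rel_frag"]
            for t in range(min_sleep_run, matrix.shape[2]):
                if not np.all(v[t - min_sleep_run : t] == SLEEP):
                    continue
                if v[t] == MISSING:
                    continue
                prev = mate_states[:, t - 1]
                observed = prev != MISSING
                if not observed.any():
                    continue
                rows.append(
                    {
                        "focal_id": focal,
                        "night_id": night,
                        "epoch": t,
                        "awake": int(v[t] == WAKE),
                        "groupmate_awake_prev": int((prev[observed] == WAKE).any()),
                        "rel_tst_prev": rel_tst,
                        "rel_frag_prev": rel_frag,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "focal_id",
            "night_id",
            "epoch",
            "awake",
            "groupmate_awake_prev",
            "rel_tst_prev",
            "rel_frag_prev",
        ],
    )


def fit_response_standin(
    table: pd.DataFrame, include_interactions: bool = True
) -> pd.DataFrame:
    """Ordinary logistic fit of the arousal table (cluster-robust by focal).

    Returns a coefficient frame (coef, se, z, p). Covariate columns that are
    entirely missing are dropped; rows with missing values in the remaining
    covariates are dropped. Raises on a single-class outcome.
    """
    if table.empty:
        raise ValueError("arousal table is empty")
    cols = ["groupmate_awake_prev"]
    for c in ("rel_tst_prev", "rel_frag_prev"):
        if table[c].notna().any():
            cols.append(c)
    df = table.dropna(subset=cols).copy()
    if df["awake"].nunique() < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    X = df[cols].astype(float).copy()
    if include_interactions:
        for c in cols[1:]:
            X[f"groupmate_awake_prev:{c}"] = X["groupmate_awake_prev"] * X[c]
    X = sm.add_constant(X, has_constant="add")
    model = sm.Logit(df["awake"].to_numpy(), X)
    res = model.fit(disp=0, cov_type="cluster", cov_kwds={"groups": df["focal_id"].to_numpy()})
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
    )
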