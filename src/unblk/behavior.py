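"""Behavioral analyses: probe-test time in well and training latencies.

The probe test presents the three novel cues without reward; time spent in
the reward well indexes the learned reward expectation, and is analyzed by
a two-way ANOVA with odor (3 cues) and trial (1-10) as factors, trials
pooled across rats and rounds as replicates (the conventional df for this
design), plus planned comparisons: upshift vs blocked within the first
four-trial block and downshift vs blocked across all trials, as paired
t-tests on per-rat-round means.  Training latencies (odor port exit to
well entry) are analyzed with trial (1-30) and day (1, 2) as factors.

A per-rat-round aggregation mode is provided for the ANOVAs because trial-
level pooling inflates the error df.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .session_io import Session

logger = logging.getLogger("unblk")


def behavior_table(sessions: Sequence[Session]) -> pd.DataFrame:
    """Long-format behavioral measures, one row per completed trial.

    Columns: rat, round, day, trial_type, trial_index (within type, 1-based),
    rewarded, latency_s, time_in_well_s.
    """
    rows = []
    for session in sessions:
        meta = session.metadata
        rat = meta.get("rat_id", "rat")
        rnd = meta.get("round", 1)
        day = meta.get("day", session.units[0].day if session.units else 1)
        counter: dict[tuple[str, bool], int] = {}
        for trial in session.trials:
            if not trial.completed:
                continue
            rewarded = trial.t_reward is not None
            key = (trial.trial_type, rewarded)
            counter[key] = counter.get(key, 0) + 1
            rows.append({
                "rat": rat,
                "round": rnd,
                "day": day,
                "trial_type": trial.trial_type,
                "trial_index": counter[key],
                "rewarded": rewarded,
                "latency_s": trial.latency_s,
                "time_in_well_s": trial.time_in_well_s,
            })
    return pd.DataFrame(rows)


def _two_way_anova(df: pd.DataFrame, response: str, f1: str, f2: str) -> dict:
    """Two-way ANOVA with interaction via OLS; returns per-factor F, df, p."""
    cells = df.groupby([f1, f2], observed=True)[response].count()
    full = df[f1].nunique() * df[f2].nunique()
    if len(cells) < full or (cells < 1).any():
        have = set(cells.index)
        missing = [
            (a, b)
            for a in df[f1].unique() for b in df[f2].unique()
            if (a, b) not in have
        ]
        raise ValueError(f"empty design cells: {missing}")
    # the interaction term needs within-cell replicates; with one
    # observation per cell fall back to the additive model
    with_interaction = (cells >= 2).all()
    if with_interaction:
        model = smf.ols(f"{response} ~ C({f1}) * C({f2})", data=df).fit()
    else:
        logger.info("two-way ANOVA on %s: no within-cell replicates, "
                    "interaction dropped", response)
        model = smf.ols(f"{response} ~ C({f1}) + C({f2})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    resid_df = float(table.loc["Residual", "df"])
    keys = [(f"C({f1})", f1), (f"C({f2})", f2)]
    if with_interaction:
        keys.append((f"C({f1}):C({f2})", f"{f1}_x_{f2}"))
    for key, label in keys:
        F = float(table.loc[key, "F"])
        p = float(table.loc[key, "PR(>F)"])
        if table.loc[key, "sum_sq"] < 1e-12:  # zero effect (e.g. constant data)
            F, p = 0.0, 1.0
        out[label] = {
            "F": F,
            "df": (float(table.loc[key, "df"]), resid_df),
            "p": p,
        }
    if not with_interaction:
        out[f"{f1}_x_{f2}"] = None
    return out


def probe_anova(
    table: pd.DataFrame,
    max_trial: int = 10,
    aggregate: bool = False,
) -> dict:
    """Two-way ANOVA on probe-test time in well: odor x trial (1..max_trial).

    Uses the unrewarded novel-cue extinction trials.  ``aggregate=True``
    averages within rat-round before fitting (conservative df).
    """
    df = table[
        (table["day"] == "probe")
        & (~table["rewarded"])
        & (table["trial_index"] <= max_trial)
    ].dropna(subset=["time_in_well_s"]).copy()
    if df.empty:
        raise ValueError("no probe extinction trials in table")
    if aggregate:
        df = (
            df.groupby(["trial_type", "trial_index"], observed=True)
            ["time_in_well_s"].mean().reset_index()
        )
        model = smf.ols("time_in_well_s ~ C(trial_type) + C(trial_index)",
                        data=df).fit()
        table_ = sm.stats.anova_lm(model, typ=2)
        resid_df = float(table_.loc["Residual", "df"])
        return {
            lab: {
                "F": float(table_.loc[f"C({col})", "F"]),
                "df": (float(table_.loc[f"C({col})", "df"]), resid_df),
                "p": float(table_.loc[f"C({col})", "PR(>F)"]),
            }
            for col, lab in (("trial_type", "odor"), ("trial_index", "trial"))
        }
    out = _two_way_anova(df, "time_in_well_s", "trial_type", "trial_index")
    return {"odor": out["trial_type"], "trial": out["trial_index"],
            "odor_x_trial": out["trial_type_x_trial_index"]}


def planned_block_comparisons(
    table: pd.DataFrame,
    block: int = 4,
    max_trial: int = 10,
    upshift: str = "upshift",
    blocked: str = "blocked",
    downshift: str = "downshift",
) -> dict:
    """Planned probe-test contrasts on per-rat-round mean time in well.

    upshift vs blocked within the first ``block`` trials; downshift vs
    blocked across all trials.  Paired t-tests across rat-rounds; a contrast
    with fewer than two rat-rounds is flagged unanalyzable (NaN p).
    """
    df = table[(table["day"] == "probe") & (~table["rewarded"])].dropna(
        subset=["time_in_well_s"]
    )
    def _contrast(a: str, b: str, upto: int) -> dict:
        sub = df[df["trial_index"] <= upto]
        means = (
            sub[sub["trial_type"].isin([a, b])]
            .groupby(["rat", "round", "trial_type"], observed=True)
            ["time_in_well_s"].mean().unstack("trial_type")
        ).dropna()
        n = len(means)
        if n < 2:
            logger.warning("planned contrast %s vs %s unanalyzable: only %d "
                           "rat-round(s)", a, b, n)
            return {"t": np.nan, "p": np.nan, "n": n,
                    "mean_diff": np.nan, "analyzable": False}
        t, p = stats.ttest_rel(means[a], means[b])
        return {"t": float(t), "p": float(p), "n": n,
                "mean_diff": float((means[a] - means[b]).mean()),
                "analyzable": True}
    return {
        "upshift_vs_blocked_first_block": _contrast(upshift, blocked, block),
        "downshift_vs_blocked_all_trials": _contrast(downshift, blocked, max_trial),
    }


def latency_anova(
    table: pd.DataFrame,
    max_trial: int = 30,
    novel_only: bool = True,
) -> dict:
    """ANOVA on learning-day latencies with trial (1..max_trial) and day
    factors (trials pooled across rats/rounds and cue types)."""
    df = table[table["day"].isin([1, 2])].dropna(subset=["latency_s"]).copy()
    if novel_only:
        df = df[df["trial_type"] != "initial"]
    df = df[df["trial_index"] <= max_trial]
    if df.empty:
        raise ValueError("no learning-day trials in table")
    out = _two_way_anova(df, "latency_s", "trial_index", "day")
    return {"trial": out["trial_index"], "day": out["day"],
            "trial_x_day": out["trial_index_x_day"]}
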