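"""Trial-resolved sliding-window firing maps and their significance maps.

For a chosen trial type, firing is measured in 150 ms windows stepped by
50 ms away from novel-odor onset, separately for each of the first N trials
(trialwise maps are exempt from the min-trial rule).  Each cell of the map
is the across-unit mean of baseline-normalized rates (window rate minus the
same trial's ITI rate), or — in ``mode="initial"`` — of rates normalized to
the initially trained cue (the unit's same-window mean over initial-odor
trials).  Significance is a per-cell one-tailed one-sample t-test across
units of the normalized rates against zero; the alpha is a parameter
because different maps are conventionally thresholded at p<0.001 or
p<0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .session_io import COMPOUND_LEAD_S, Session, Trial, UnitRecording
from .rates import ITI_EPOCH, analyzable_trials, epoch_rate, sliding_windows, \
    sliding_window_starts

logger = logging.getLogger("unblk")


def novel_anchor(trial: Trial) -> float | None:
    """Time-lock point for novel-cue analyses: novel-odor onset on compound
    trials, the equivalent offset after odor onset otherwise."""
    if trial.t_novel_odor_on is not None:
        return trial.t_novel_odor_on
    if trial.t_odor_on is not None:
        return trial.t_odor_on + COMPOUND_LEAD_S
    return None


@dataclass
class TrialWindowMap:
    """Trial x window map of across-unit mean normalized firing (Hz).

    ``per_unit`` (unit x trial x window) is retained so the significance
    map can be computed across units for each cell.
    """

    values: np.ndarray            # (n_trials, n_windows)
    per_unit: np.ndarray          # (n_units, n_trials, n_windows)
    unit_ids: list[str]
    trial_type: str
    window_s: float
    step_s: float
    window_starts: np.ndarray     # offsets from novel-odor onset
    mode: str                     # "iti" | "initial"


def _unit_trial_windows(
    unit: UnitRecording,
    trials: Sequence[Trial],
    window_s: float,
    step_s: float,
    span_s: float,
) -> np.ndarray:
    out = np.full((len(trials), len(sliding_window_starts(span_s, window_s, step_s))),
                  np.nan)
    for j, trial in enumerate(trials):
        anchor = novel_anchor(trial)
        if anchor is None:
            continue
        out[j] = sliding_windows(unit.spikes, anchor, window_s, step_s, span_s)
    return out


def trialwise_heatmap(
    session_units: Sequence[tuple[UnitRecording, Session]],
    trial_type: str,
    n_trials: int = 10,
    window_s: float = 0.150,
    step_s: float = 0.050,
    span_s: float = 1.0,
    mode: str = "iti",
) -> TrialWindowMap:
    """Across-unit mean normalized firing for the first ``n_trials`` trials
    of ``trial_type``, in sliding windows from novel-odor onset.

    ``session_units`` pairs each unit with the session it was recorded in,
    so pseudo-populations pooled over sessions are supported.  Units lacking
    ``n_trials`` completed trials of the type are excluded (logged).
    """
    if mode not in ("iti", "initial"):
        raise ValueError("mode must be 'iti' or 'initial'")
    window_starts = sliding_window_starts(span_s, window_s, step_s)
    per_unit, kept_ids = [], []
    for unit, session in session_units:
        trials = analyzable_trials(session, trial_type=trial_type, min_trial=1)
        if len(trials) < n_trials:
            logger.info("heatmap: unit %s excluded (%d < %d %s trials)",
                        unit.unit_id, len(trials), n_trials, trial_type)
            continue
        trials = trials[:n_trials]
        rates = _unit_trial_windows(unit, trials, window_s, step_s, span_s)
        if mode == "iti":
            baseline = np.array([
                epoch_rate(unit.spikes, t, ITI_EPOCH) for t in trials
            ], dtype=float)[:, None]
        else:  # normalize to the initially trained cue: same-window mean
            init = analyzable_trials(session, trial_type="initial", min_trial=1)
            if not init:
                logger.info("heatmap: unit %s excluded (no initial trials "
                            "for mode='initial')", unit.unit_id)
                continue
            init_rates = _unit_trial_windows(unit, init, window_s, step_s, span_s)
            baseline = np.nanmean(init_rates, axis=0)[None, :]
        per_unit.append(rates - baseline)
        kept_ids.append(unit.unit_id)
    if not per_unit:
        raise ValueError(f"no unit has {n_trials} {trial_type!r} trials")
    stack = np.stack(per_unit)
    return TrialWindowMap(
        values=stack.mean(axis=0),
        per_unit=stack,
        unit_ids=kept_ids,
        trial_type=trial_type,
        window_s=window_s,
        step_s=step_s,
        window_starts=window_starts,
        mode=mode,
    )


def significance_map(
    trial_map: TrialWindowMap, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """One-tailed (greater) one-sample t-test across units per map cell.

    Returns (significant, p_values), both shaped like ``trial_map.values``.
    Degenerate zero-variance cells are reported significant when their mean
    is positive (with a warning), not significant otherwise.
    """
    x = trial_map.per_unit
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_1samp(x, 0.0, axis=0, alternative="greater",
                                nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    mean = np.nanmean(x, axis=0)
    degenerate = np.isnan(p) & ~np.isnan(mean) & (np.nanstd(x, axis=0) == 0)
    if degenerate.any():
        logger.warning("significance_map: %d degenerate zero-variance cells; "
                       "treated significant where mean > 0",
                       int(degenerate.sum()))
        p = np.where(degenerate, np.where(mean > 0, 0.0, 1.0), p)
    significant = p < alpha
    return significant, p
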