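"""Peri-event firing-rate statistics.

Epoch definitions are data, not code: every operation takes an
:class:`EpochDefinition` naming an anchor event and a half-open offset
window, so the control-task variant reuses the same machinery with
different definitions.  Conventions used throughout:

* all intervals and bins are half-open ``[start, end)`` — a spike exactly on
  a boundary belongs to the later bin;
* the ITI baseline is the 2 s preceding house-light onset;
* the default novel-odor epoch is 300–1300 ms after initial odor onset
  (an alternative anchored 1 s after novel-odor onset, i.e. 200–1200 ms, is
  provided);
* normalized firing is epoch rate minus same-trial ITI rate, in spikes/s;
* incomplete trials and trials before ``min_trial`` (default the 8th) are
  excluded from odor-period analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session_io import Session, Trial, UnitRecording

logger = logging.getLogger("unblk")

DEFAULT_MIN_TRIAL = 8  # odor-period analyses start with the 8th trial


@dataclass(frozen=True)
class EpochDefinition:
    """A named half-open window relative to a trial event."""

    name: str
    anchor_event: str
    start_offset_s: float
    end_offset_s: float

    def __post_init__(self):
        if self.end_offset_s <= self.start_offset_s:
            raise ValueError("epoch end must be after start")

    @property
    def duration_s(self) -> float:
        return self.end_offset_s - self.start_offset_s

    def window(self, trial: Trial) -> Optional[tuple[float, float]]:
        anchor = getattr(trial, self.anchor_event, None)
        if anchor is None:
            return None
        return (anchor + self.start_offset_s, anchor + self.end_offset_s)


ITI_EPOCH = EpochDefinition("iti", "t_light_on", -2.0, 0.0)
NOVEL_ODOR_EPOCH = EpochDefinition("novel_odor", "t_odor_on", 0.3, 1.3)
#: Alternative convention: the 1 s following novel-odor onset (novel odor
#: starts 200 ms after initial odor onset on compound trials).
NOVEL_ODOR_EPOCH_ALT = EpochDefinition("novel_odor_alt", "t_odor_on", 0.2, 1.2)


def count_in_window(spikes: np.ndarray, start: float, end: float) -> int:
    """Spike count in the half-open window [start, end)."""
    spikes = np.asarray(spikes)
    return int(np.searchsorted(spikes, end, "left")
               - np.searchsorted(spikes, start, "left"))


def epoch_rate(spikes: np.ndarray, trial: Trial,
               epoch: EpochDefinition) -> Optional[float]:
    """Firing rate (Hz) in ``epoch`` on ``trial``.

    Returns None (and logs the reason) when the anchor event is absent, so
    callers skip the trial rather than inventing a value.
    """
    win = epoch.window(trial)
    if win is None:
        logger.debug(
            "trial %d skipped for epoch %s: anchor %s absent",
            trial.trial_index, epoch.name, epoch.anchor_event,
        )
        return None
    return count_in_window(spikes, *win) / epoch.duration_s


def normalized_firing(epoch_rate_hz: float, iti_rate_hz: float) -> float:
    """Baseline-normalized firing: epoch rate minus ITI rate (may be < 0)."""
    return epoch_rate_hz - iti_rate_hz


def analyzable_trials(
    session: Session,
    trial_type: Optional[str] = None,
    min_trial: int = 1,
    completed_only: bool = True,
) -> list[Trial]:
    """Trials usable for firing-rate analyses.

    ``min_trial`` is 1-based on the session-wide trial order; passing 8
    applies the default odor-period rule of dropping the first 7 trials.
    """
    out = []
    for i, t in enumerate(session.trials):
        if completed_only and not t.completed:
            continue
        if i + 1 < min_trial:
            continue
        if trial_type is not None and t.trial_type != trial_type:
            continue
        out.append(t)
    return out


def epoch_rates_for_trials(
    spikes: np.ndarray, trials: Sequence[Trial], epoch: EpochDefinition
) -> np.ndarray:
    """Vectorized per-trial epoch rates; trials lacking the anchor yield NaN."""
    spikes = np.asarray(spikes)
    rates = np.full(len(trials), np.nan)
    for i, trial in enumerate(trials):
        win = epoch.window(trial)
        if win is not None:
            rates[i] = count_in_window(spikes, *win) / epoch.duration_s
    return rates


def session_rates(
    session: Session,
    epoch: EpochDefinition = NOVEL_ODOR_EPOCH,
    iti_epoch: EpochDefinition = ITI_EPOCH,
    min_trial: int = 1,
) -> pd.DataFrame:
    """Long-format per-unit, per-trial epoch statistics.

    Columns: unit_id, trial_index, trial_type, iti_rate, epoch_rate,
    normalized.  Trials missing either anchor are omitted.
    """
    trials = analyzable_trials(session, min_trial=min_trial)
    rows = []
    for unit in session.units:
        iti = epoch_rates_for_trials(unit.spikes, trials, iti_epoch)
        per = epoch_rates_for_trials(unit.spikes, trials, epoch)
        for trial, r_iti, r_ep in zip(trials, iti, per):
            if np.isnan(r_iti) or np.isnan(r_ep):
                continue
            rows.append(
                (unit.unit_id, trial.trial_index, trial.trial_type,
                 r_iti, r_ep, normalized_firing(r_ep, r_iti))
            )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "trial_index", "trial_type",
                 "iti_rate", "epoch_rate", "normalized"],
    )


@dataclass
class RateMatrix:
    """Binned per-trial firing rates: axes (unit, trial, bin), values in Hz."""

    values: np.ndarray
    unit_ids: list[str]
    trial_indices: list[int]
    bin_width_s: float
    alignment_event: str
    window_s: tuple[float, float]

    @property
    def bin_starts(self) -> np.ndarray:
        n = self.values.shape[2]
        return self.window_s[0] + self.bin_width_s * np.arange(n)

    def trial_mean(self) -> np.ndarray:
        """Mean over trials -> (unit, bin)."""
        return self.values.mean(axis=1)


def bin_spikes(
    spikes: np.ndarray, anchor: float, window: tuple[float, float],
    bin_width_s: float,
) -> np.ndarray:
    """Per-bin rates (Hz) in half-open bins covering ``window`` around
    ``anchor``.  Bin count is floor(span / bin_width); a spike exactly on a
    bin edge falls in the later bin."""
    start, end = window
    n_bins = int(np.floor((end - start) / bin_width_s + 1e-9))
    rel = np.asarray(spikes) - (anchor + start)
    idx = np.floor(rel / bin_width_s).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return counts / bin_width_s


def psth(
    units: Sequence[UnitRecording],
    trials: Sequence[Trial],
    alignment_event: str = "t_odor_on",
    window: tuple[float, float] = (-0.5, 1.5),
    bin_width_s: float = 0.05,
) -> RateMatrix:
    """Peri-event time histogram in 50 ms bins (per trial; averaging across
    trials is a separate reduction via :meth:`RateMatrix.trial_mean`)."""
    usable = [t for t in trials if getattr(t, alignment_event, None) is not None]
    skipped = len(trials) - len(usable)
    if skipped:
        logger.debug("psth: %d trials lack %s, skipped", skipped, alignment_event)
    n_bins = int(np.floor((window[1] - window[0]) / bin_width_s + 1e-9))
    values = np.zeros((len(units), len(usable), n_bins))
    for i, unit in enumerate(units):
        for j, trial in enumerate(usable):
            anchor = getattr(trial, alignment_event)
            values[i, j] = bin_spikes(unit.spikes, anchor, window, bin_width_s)
    return RateMatrix(
        values=values,
        unit_ids=[u.unit_id for u in units],
        trial_indices=[t.trial_index for t in usable],
        bin_width_s=bin_width_s,
        alignment_event=alignment_event,
        window_s=window,
    )


def sliding_window_starts(span_s: float, window_s: float, step_s: float) -> np.ndarray:
    """Start offsets of overlapping windows covering [0, span): count is
    floor((span - window) / step) + 1."""
    if span_s < window_s:
        raise ValueError("span must be >= window")
    n = int(np.floor((span_s - window_s) / step_s + 1e-9)) + 1
    return step_s * np.arange(n)


def sliding_windows(
    spikes: np.ndarray,
    anchor: float,
    window_s: float = 0.150,
    step_s: float = 0.050,
    span_s: float = 1.0,
) -> np.ndarray:
    """Rates (Hz) in 150 ms windows stepped by 50 ms away from ``anchor``."""
    starts = anchor + sliding_window_starts(span_s, window_s, step_s)
    spikes = np.asarray(spikes)
    lo = np.searchsorted(spikes, starts, "left")
    hi = np.searchsorted(spikes, starts + window_s, "left")
    return (hi - lo) / window_s


def smooth_bins(series: np.ndarray, k: int) -> np.ndarray:
    """Trailing moving average of width ``k``; output length n - k + 1.

    Used with k=4 for 50 ms rate bins, k=3 for 100 ms decoding bins and for
    trial-resolved accuracy curves.  No edge padding: shortening the series
    avoids inventing edge values.
    """
    series = np.asarray(series, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if series.size < k:
        raise ValueError(f"series of length {series.size} too short for k={k}")
    return np.convolve(series, np.full(k, 1.0 / k), mode="valid")
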