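"""Functional taxonomy of single units.

Units with baseline firing under 10 Hz are screened for phasic excitatory
responses to each of the four odor cues by comparing trialwise ITI rates
against trialwise odor-epoch rates (Welch t-test, one-tailed for an
increase, alpha = 0.01; a two-sided or trial-paired variant is available by
configuration).  Value coding is an excitatory response to at least one
odor together with significantly more epoch firing on upshift than blocked
trials and significantly less on downshift than blocked trials.  The
category assignment then follows a fixed decision order; a goodness-of-fit
chi-squared tests whether the three tuned subpopulations are uniformly
sized; and a trialwise correlation relates odor-epoch firing to behavioral
latency.

No multiple-comparison correction is applied: the screens run at the
per-test alpha, as in the analysis this package implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .session_io import Session, UnitRecording
from .rates import (
    DEFAULT_MIN_TRIAL,
    EpochDefinition,
    ITI_EPOCH,
    NOVEL_ODOR_EPOCH,
    analyzable_trials,
    epoch_rates_for_trials,
)

logger = logging.getLogger("unblk")

CATEGORY_ORDER = (
    "nonresponsive",
    "sensory_excluded",
    "value",
    "initial_only",
    "upshift_only",
    "downshift_only",
    "blocked_only",
    "predictive",
    "salience",
    "other_mixed",
)

#: The three tuned (single-novel-cue) categories.
TUNED_CATEGORIES = ("upshift_only", "downshift_only", "blocked_only")


@dataclass
class OdorTest:
    """One odor's excitatory-response screen result."""

    t_statistic: float
    p_value: float
    significant: bool
    direction: str  # "up" | "down"
    n_trials: int


@dataclass
class OdorResponse:
    """Per-odor screen outcomes for one unit."""

    unit_id: str
    baseline_mean_rate: float
    eligible: bool
    tests: dict[str, OdorTest] = field(default_factory=dict)
    unanalyzable: bool = False
    reason: str = ""

    def significant_odors(self) -> set[str]:
        return {o for o, t in self.tests.items() if t.significant}


@dataclass
class TaxonomyResult:
    unit_id: str
    category: str
    provenance: str


def _directional_test(
    sample: np.ndarray,
    reference: np.ndarray,
    direction: str,
    sided: str,
    paired: bool,
) -> tuple[float, float]:
    """t-test that ``sample`` differs from ``reference`` in ``direction``.

    Returns (t, p) where p already encodes the chosen sidedness; with
    ``sided="two"`` the caller must additionally check the direction.
    """
    alternative = {"one": direction, "two": "two-sided"}[sided]
    if paired:
        res = stats.ttest_rel(sample, reference, alternative=alternative)
    else:
        res = stats.ttest_ind(sample, reference, equal_var=False,
                              alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def screen_responsive(
    unit: UnitRecording,
    session: Session,
    alpha: float = 0.01,
    max_baseline_hz: float = 10.0,
    min_trial: int = DEFAULT_MIN_TRIAL,
    epoch: EpochDefinition = NOVEL_ODOR_EPOCH,
    iti_epoch: EpochDefinition = ITI_EPOCH,
    sided: str = "one",
    paired: bool = False,
) -> OdorResponse:
    """Screen one unit for excitatory phasic responses to each odor cue.

    For each trial type, trialwise odor-epoch rates are compared with the
    same trials' ITI rates (Welch two-sample by default; ``paired=True``
    pairs them by trial).  An odor is *significant* iff p < alpha and the
    direction is an increase.  Units whose mean ITI rate is at or above
    ``max_baseline_hz`` are flagged ineligible; units with fewer than two
    analyzable trials for some odor are flagged unanalyzable.
    """
    trials = analyzable_trials(session, min_trial=min_trial)
    iti_all = epoch_rates_for_trials(unit.spikes, trials, iti_epoch)
    ok = ~np.isnan(iti_all)
    baseline = float(np.mean(iti_all[ok])) if ok.any() else float("nan")
    resp = OdorResponse(
        unit_id=unit.unit_id,
        baseline_mean_rate=baseline,
        eligible=bool(baseline < max_baseline_hz),
    )
    if not resp.eligible:
        logger.debug("unit %s ineligible: baseline %.2f Hz >= %.1f Hz",
                     unit.unit_id, baseline, max_baseline_hz)
        return resp
    for odor in session.trial_types:
        sub = [t for t in trials if t.trial_type == odor]
        iti = epoch_rates_for_trials(unit.spikes, sub, iti_epoch)
        per = epoch_rates_for_trials(unit.spikes, sub, epoch)
        keep = ~(np.isnan(iti) | np.isnan(per))
        iti, per = iti[keep], per[keep]
        if len(per) < 2:
            resp.unanalyzable = True
            resp.reason = f"<2 analyzable {odor} trials"
            logger.debug("unit %s unanalyzable: %s", unit.unit_id, resp.reason)
            continue
        t, p = _directional_test(per, iti, "greater", sided, paired)
        direction = "up" if per.mean() >= iti.mean() else "down"
        significant = bool(p < alpha and direction == "up")
        resp.tests[odor] = OdorTest(t, p, significant, direction, int(len(per)))
    return resp


def is_value_coding(
    unit: UnitRecording,
    session: Session,
    response: Optional[OdorResponse] = None,
    alpha: float = 0.01,
    min_trial: int = DEFAULT_MIN_TRIAL,
    epoch: EpochDefinition = NOVEL_ODOR_EPOCH,
    sided: str = "one",
    **screen_kwargs,
) -> bool:
    """True iff the unit meets the operational value-coding definition:
    an excitatory response to at least one odor, significantly more
    odor-epoch activity on upshift than blocked trials, and significantly
    less on downshift than blocked trials (between-trial-type t-tests)."""
    if response is None:
        response = screen_responsive(
            unit, session, alpha=alpha, min_trial=min_trial, epoch=epoch,
            sided=sided, **screen_kwargs,
        )
    if not response.eligible or response.unanalyzable:
        return False
    if not response.significant_odors():
        return False
    if session.task_variant != "blocking":
        up, mid, down = "large", "medium", "small"
    else:
        up, mid, down = "upshift", "blocked", "downshift"
    def _rates(trial_type):
        sub = analyzable_trials(session, trial_type=trial_type, min_trial=min_trial)
        r = epoch_rates_for_trials(unit.spikes, sub, epoch)
        return r[~np.isnan(r)]
    r_up, r_mid, r_down = _rates(up), _rates(mid), _rates(down)
    if min(len(r_up), len(r_mid), len(r_down)) < 2:
        return False
    _, p_up = _directional_test(r_up, r_mid, "greater", sided, paired=False)
    _, p_down = _directional_test(r_down, r_mid, "less", sided, paired=False)
    if sided == "two":
        return bool(
            p_up < alpha and r_up.mean() > r_mid.mean()
            and p_down < alpha and r_down.mean() < r_mid.mean()
        )
    return bool(p_up < alpha and p_down < alpha)


def classify_unit(
    response: OdorResponse,
    value_flag: bool,
    novel_types: tuple[str, ...] = ("blocked", "upshift", "downshift"),
) -> TaxonomyResult:
    """Assign a functional category from the screen flags.

    Decision order: (1) no significant odor -> nonresponsive; (2) all four
    significant and not value-coding -> sensory_excluded; (3) value-coding
    -> value; (4) only the initial odor -> initial_only; (5) exactly one
    novel odor (initial not) -> that cue's tuned category; (6) upshift and
    downshift but not blocked -> predictive; (7) all three novel cues,
    initial not -> salience; (8) anything else -> other_mixed.
    """
    uid = response.unit_id
    if not response.eligible:
        return TaxonomyResult(uid, "nonresponsive",
                              "ineligible: baseline >= 10 Hz")
    if response.unanalyzable:
        return TaxonomyResult(uid, "nonresponsive",
                              f"unanalyzable: {response.reason}")
    sig = response.significant_odors()
    all_odors = set(response.tests)
    novel_sig = sig & set(novel_types)
    if not sig:
        return TaxonomyResult(uid, "nonresponsive", "no odor significant")
    if sig == all_odors and len(all_odors) == 4 and not value_flag:
        return TaxonomyResult(uid, "sensory_excluded",
                              "all four odors significant, not value-coding")
    if value_flag:
        return TaxonomyResult(uid, "value",
                              "upshift > blocked and downshift < blocked")
    if sig == {"initial"}:
        return TaxonomyResult(uid, "initial_only", "only initial significant")
    if "initial" not in sig and len(novel_sig) == 1:
        cue = next(iter(novel_sig))
        return TaxonomyResult(uid, f"{cue}_only", f"only {cue} significant")
    if "initial" not in sig and novel_sig == {"upshift", "downshift"}:
        return TaxonomyResult(uid, "predictive",
                              "upshift and downshift significant, blocked not")
    if "initial" not in sig and novel_sig == set(novel_types):
        return TaxonomyResult(uid, "salience",
                              "all three novel cues significant, initial not")
    return TaxonomyResult(uid, "other_mixed", f"significant: {sorted(sig)}")


def classify_session(
    session: Session,
    alpha: float = 0.01,
    max_baseline_hz: float = 10.0,
    min_trial: int = DEFAULT_MIN_TRIAL,
    epoch: EpochDefinition = NOVEL_ODOR_EPOCH,
    sided: str = "one",
    paired: bool = False,
) -> pd.DataFrame:
    """Screen and classify every unit in a session.

    Returns one row per unit: unit_id, category, value_flag, baseline rate,
    eligibility, and per-odor p-values.  Deterministic and independent of
    unit enumeration order.
    """
    rows = []
    for unit in session.units:
        resp = screen_responsive(
            unit, session, alpha=alpha, max_baseline_hz=max_baseline_hz,
            min_trial=min_trial, epoch=epoch, sided=sided, paired=paired,
        )
        vflag = is_value_coding(
            unit, session, response=resp, alpha=alpha, min_trial=min_trial,
            epoch=epoch, sided=sided,
        )
        result = classify_unit(resp, vflag, novel_types=session.novel_types)
        row = {
            "unit_id": unit.unit_id,
            "category": result.category,
            "value_flag": vflag,
            "baseline_rate": resp.baseline_mean_rate,
            "eligible": resp.eligible,
            "provenance": result.provenance,
        }
        for odor in session.trial_types:
            test = resp.tests.get(odor)
            row[f"p_{odor}"] = test.p_value if test else np.nan
            row[f"sig_{odor}"] = bool(test.significant) if test else False
        rows.append(row)
    base_cols = ["unit_id", "category", "value_flag", "baseline_rate",
                 "eligible", "provenance"]
    cols = base_cols + [f"{p}_{o}" for o in session.trial_types
                        for p in ("p", "sig")]
    return pd.DataFrame(rows, columns=cols if not rows else None)


def category_uniformity_test(counts) -> tuple[float, float]:
    """Goodness-of-fit chi-squared of tuned-cell counts against a uniform
    expectation (df = k - 1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2 or np.any(counts < 0):
        raise ValueError("counts must be a 1-D array of nonnegative numbers")
    res = stats.chisquare(counts)
    return float(res.statistic), float(res.pvalue)


def latency_firing_correlation(
    unit: UnitRecording,
    session: Session,
    trial_range: tuple[int, int] = (5, 30),
    epoch: EpochDefinition = NOVEL_ODOR_EPOCH,
) -> pd.DataFrame:
    """Pearson correlation between trialwise odor-epoch firing and latency.

    Computed per trial type over within-type trials ``trial_range`` (both
    ends inclusive, 1-based).  Trial types with fewer than 3 usable trials
    are flagged unanalyzable (NaN r).
    """
    lo, hi = trial_range
    rows = []
    for trial_type in session.novel_types:
        sub = analyzable_trials(session, trial_type=trial_type, min_trial=1)
        sub = sub[lo - 1:hi]  # within-type trial numbers lo..hi, 1-based
        rates = epoch_rates_for_trials(unit.spikes, sub, epoch)
        lats = np.array([t.latency_s if t.latency_s is not None else np.nan
                         for t in sub])
        keep = ~(np.isnan(rates) | np.isnan(lats))
        n = int(keep.sum())
        if n < 3:
            rows.append((unit.unit_id, trial_type, np.nan, np.nan, n, False))
            logger.debug("unit %s %s: only %d usable trials for latency "
                         "correlation", unit.unit_id, trial_type, n)
            continue
        if np.std(rates[keep]) == 0 or np.std(lats[keep]) == 0:
            rows.append((unit.unit_id, trial_type, np.nan, np.nan, n, False))
            continue
        r, p = stats.pearsonr(rates[keep], lats[keep])
        rows.append((unit.unit_id, trial_type, float(r), float(p), n, True))
    return pd.DataFrame(
        rows, columns=["unit_id", "trial_type", "r", "p", "n", "analyzable"]
    )


def confusion_matrix(
    taxonomy: pd.DataFrame, ground_truth_categories: dict[str, str]
) -> pd.DataFrame:
    """Cross-tabulate assigned vs ground-truth categories (synthetic data).

    Ground-truth generator categories map onto taxonomy labels directly
    except ``sensory`` -> ``sensory_excluded``.
    """
    remap = {"sensory": "sensory_excluded"}
    truth = taxonomy["unit_id"].map(
        lambda u: remap.get(ground_truth_categories[u], ground_truth_categories[u])
    )
    return pd.crosstab(truth, taxonomy["category"].values,
                       rownames=["truth"], colnames=["assigned"])
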