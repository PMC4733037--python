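"""Synthetic unblocking-study generator with ground-truth unit labels.

Emulates the statistical structure the analysis pipeline assumes: sessions
of four interleaved trial types (a reminder of the pre-trained cue plus
three novel cues signaling an upshifted, downshifted, or unchanged reward),
units of each functional coding profile firing as inhomogeneous Poisson
processes, cue responses that develop with training according to a logistic
learning curve, and behavioral read-outs (latency to the reward well,
time in the well on probe extinction trials) with cue-dependent means.

The generator's defaults are the study conditions: 30 trials per novel odor
per learning day, tuned responses of ~2 spikes/s above baseline at
asymptote, baseline rates lognormal with median 3 Hz (mostly under 10 Hz),
a learning curve that is <10% of asymptote on the first trial of day 1 and
near asymptote from early on day 2, and probe-day time-in-well ordered
upshift > blocked > downshift in the first four-trial block.

Spike generation is by thinning a piecewise-constant rate function; the
contract is the rate function (baseline plus per-trial cue modulation), not
the sampling algorithm.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

from .session_io import (
    NOVEL_TYPES,
    TRIAL_TYPES,
    Session,
    Trial,
    UnitRecording,
    validate_session,
)

#: Functional categories a unit can belong to.
CATEGORIES = (
    "nonresponsive",
    "sensory",
    "value",
    "upshift_only",
    "downshift_only",
    "blocked_only",
    "predictive",
    "salience",
    "initial_only",
)

#: Which trial types each category responds to, and with what multiple of the
#: profile's modulation.  Value cells step monotonically with predicted
#: reward (downshift +0, blocked +1, upshift +2 modulation units); salience
#: cells respond to all three novel cues; predictive cells to the two cues
#: signaling a change; sensory cells to all four odors.
CATEGORY_PREFERENCES: dict[str, dict[str, float]] = {
    "nonresponsive": {},
    "sensory": {"initial": 1.0, "blocked": 1.0, "upshift": 1.0, "downshift": 1.0},
    "value": {"blocked": 1.0, "upshift": 2.0},
    "upshift_only": {"upshift": 1.0},
    "downshift_only": {"downshift": 1.0},
    "blocked_only": {"blocked": 1.0},
    "predictive": {"upshift": 1.0, "downshift": 1.0},
    "salience": {"blocked": 1.0, "upshift": 1.0, "downshift": 1.0},
    "initial_only": {"initial": 1.0},
}

#: Categories whose cue response develops with training.  Sensory and
#: initial-odor cells respond from trial 1 (the initial cue is pre-trained;
#: sensory responses are non-associative).
RAMPED_CATEGORIES = frozenset(
    {"value", "upshift_only", "downshift_only", "blocked_only", "predictive", "salience"}
)

#: Categories driven by the novel odor (response locked to novel-odor onset
#: on compound trials) as opposed to the first odor in the stream.
NOVEL_DRIVEN = frozenset(
    {"value", "upshift_only", "downshift_only", "blocked_only", "predictive", "salience"}
)

_CONTROL_MAP = {"blocked": "medium", "upshift": "large", "downshift": "small"}

_REWARD_FOR_TYPE = {
    "initial": "medium", "blocked": "medium", "upshift": "large", "downshift": "small",
    "medium": "medium", "large": "large", "small": "small",
}

_DAY_CODE = {1: 1, 2: 2, "probe": 3}


@dataclass
class UnitProfile:
    """Ground-truth coding profile of one synthetic unit."""

    category: str
    baseline_rate: float
    modulation: float = 2.0
    learning_midpoint_trial: float = 82.0
    learning_slope: float = 0.10
    peak_jitter_s: float = 0.0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.modulation < 0:
            raise ValueError("modulation must be >= 0")


@dataclass
class GroundTruth:
    """Map unit_id -> :class:`UnitProfile` for every generated unit."""

    profiles: dict[str, UnitProfile] = field(default_factory=dict)

    def category(self, unit_id: str) -> str:
        return self.profiles[unit_id].category

    def update(self, other: "GroundTruth") -> None:
        self.profiles.update(other.profiles)


def _default_unit_counts() -> dict[str, int]:
    # Composition mirrors the reported single-study proportions: tuned
    # subpopulations 19/16/16, salience 10, predictive 16, value 5, plus
    # sensory, initial-only and nonresponsive backgrounds.
    return {
        "nonresponsive": 40,
        "sensory": 12,
        "initial_only": 12,
        "value": 5,
        "upshift_only": 19,
        "downshift_only": 16,
        "blocked_only": 16,
        "predictive": 16,
        "salience": 10,
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study.

    Counts and rates default to the study conditions (see module docstring).
    ``seed`` makes every session bit-exactly reproducible.
    """

    n_units_per_category: dict[str, int] = field(default_factory=_default_unit_counts)
    n_trials_per_novel_odor: int = 30
    n_reminder_trials: int = 30
    n_probe_reminder_trials_per_type: int = 10
    n_probe_trials_per_odor: int = 10
    iti_range_s: tuple[float, float] = (4.0, 8.0)
    baseline_median_hz: float = 3.0
    baseline_sigma: float = 0.3
    modulation_hz: float = 2.0
    learning_midpoint_trial: float = 82.0
    learning_slope: float = 0.10
    response_onset_s: float = 0.1
    response_duration_s: float = 1.2
    peak_jitter_sd_s: float = 0.0
    p_incomplete: float = 0.02
    # behavior: latency = lognormal(base) + novelty term decaying over the
    # first novel-cue trials, largest on day 1
    latency_median_s: float = 0.35
    latency_sigma: float = 0.25
    novelty_latency_s: dict = field(
        default_factory=lambda: {1: 0.9, 2: 0.35, "probe": 0.2}
    )
    novelty_decay_trials: float = 3.0
    # probe-day time in well: first-block means per novel cue, decaying with
    # extinction toward a common floor
    time_in_well_mean_s: dict = field(
        default_factory=lambda: {"upshift": 2.6, "blocked": 1.6, "downshift": 0.9}
    )
    time_in_well_floor_s: float = 0.4
    time_in_well_decay: float = 0.12
    time_in_well_sd_s: float = 0.45
    rewarded_time_in_well_s: dict = field(
        default_factory=lambda: {"small": 1.0, "medium": 1.6, "large": 2.2}
    )
    task_variant: str = "blocking"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.task_variant not in TRIAL_TYPES:
            raise ValueError(f"unknown task_variant {self.task_variant!r}")
        for cat, n in self.n_units_per_category.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if n < 0:
                raise ValueError(f"negative unit count for {cat!r}")
        if not 20 <= self.n_trials_per_novel_odor <= 40:
            raise ValueError("n_trials_per_novel_odor must be in [20, 40]")
        if not 1 <= self.n_probe_trials_per_odor <= 10:
            raise ValueError("n_probe_trials_per_odor must be in [1, 10]")
        if self.n_reminder_trials < 0 or self.n_probe_reminder_trials_per_type < 0:
            raise ValueError("trial counts must be nonnegative")
        needs_initial = any(
            self.n_units_per_category.get(c, 0) > 0
            for c in ("initial_only", "sensory")
        )
        if needs_initial and self.n_reminder_trials == 0:
            raise ValueError(
                "initial-odor-responsive profiles require n_reminder_trials > 0"
            )
        if not 0 <= self.p_incomplete < 1:
            raise ValueError("p_incomplete must be in [0, 1)")
        lo, hi = self.iti_range_s
        if lo < 2.5 or hi < lo:
            raise ValueError("iti_range_s must satisfy 2.5 <= lo <= hi")

    def hash(self) -> str:
        payload = json.dumps(_str_keys(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _str_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _str_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_str_keys(v) for v in obj]
    return obj


def learning_factor(
    cumulative_trial: Union[float, np.ndarray],
    midpoint: float,
    slope: float,
) -> Union[float, np.ndarray]:
    """Logistic learning curve: fraction of asymptotic modulation after
    ``cumulative_trial`` novel-cue trials of experience."""
    x = np.asarray(cumulative_trial, dtype=float)
    out = 1.0 / (1.0 + np.exp(-slope * (x - midpoint)))
    return float(out) if out.ndim == 0 else out


def _q(t: float) -> float:
    """Quantize a timestamp to the 0.1 ms schema resolution."""
    return round(t, 4)


def _trial_type_sequence(config: GeneratorConfig, day, rng) -> list[tuple[str, bool, bool]]:
    """Return (trial_type, compound, rewarded) tuples in session order."""
    novel = NOVEL_TYPES[config.task_variant]
    compound_task = config.task_variant == "blocking"
    seq: list[tuple[str, bool, bool]] = []
    if day in (1, 2):
        seq += [("initial", False, True)] * config.n_reminder_trials
        for t in novel:
            seq += [(t, compound_task, True)] * config.n_trials_per_novel_odor
        seq = [seq[i] for i in rng.permutation(len(seq))]
    else:  # probe: reminders of each type, then unrewarded novel-alone trials
        rem: list[tuple[str, bool, bool]] = []
        rem += [("initial", False, True)] * config.n_probe_reminder_trials_per_type
        for t in novel:
            rem += [(t, compound_task, True)] * config.n_probe_reminder_trials_per_type
        rem = [rem[i] for i in rng.permutation(len(rem))]
        ext: list[tuple[str, bool, bool]] = []
        for t in novel:
            ext += [(t, False, False)] * config.n_probe_trials_per_odor
        ext += [("initial", False, True)] * config.n_probe_trials_per_odor
        ext = [ext[i] for i in rng.permutation(len(ext))]
        seq = rem + ext
    return seq


def _day_novel_offset(config: GeneratorConfig, day) -> int:
    """Novel-cue trials experienced before this day starts."""
    per_day = 3 * config.n_trials_per_novel_odor
    return {1: 0, 2: per_day, "probe": 2 * per_day}[day]


def _build_trials(config: GeneratorConfig, day, rng):
    """Lay out the behavioral event stream; returns (trials, novel_counts).

    ``novel_counts[i]`` is the cumulative number of completed novel-cue
    trials (across days) up to and including trial i — the argument of the
    learning curve for that trial.
    """
    novel_types = set(NOVEL_TYPES[config.task_variant])
    seq = _trial_type_sequence(config, day, rng)
    trials: list[Trial] = []
    novel_counts: list[int] = []
    c = _day_novel_offset(config, day)
    within_type: dict[str, int] = {}
    cursor = 0.0
    index = 0
    for trial_type, compound, rewarded in seq:
        # aborted attempt (restart) before some trials
        if rng.random() < config.p_incomplete:
            light = _q(cursor + rng.uniform(*config.iti_range_s))
            if rng.random() < 0.5:  # never entered the odor port
                trials.append(Trial(index, trial_type, light, completed=False))
                cursor = light
            else:  # exited the odor port early
                port = _q(light + rng.uniform(0.2, 0.8))
                odor_on = _q(port + rng.uniform(0.05, 0.15))
                odor_off = _q(odor_on + rng.uniform(0.2, 0.8))
                trials.append(
                    Trial(index, trial_type, light, port, odor_on,
                          None, odor_off, completed=False)
                )
                cursor = odor_off
            novel_counts.append(c)
            index += 1
        # within-type trial number, counted separately for rewarded and
        # extinction presentations (probe reminders do not advance the
        # extinction index)
        key = (trial_type, rewarded)
        k = within_type.get(key, 0) + 1
        within_type[key] = k
        if trial_type in novel_types:
            c += 1
        light = _q(cursor + rng.uniform(*config.iti_range_s))
        port = _q(light + rng.uniform(0.2, 0.8))
        odor_on = _q(port + rng.uniform(0.05, 0.15))
        novel_on = _q(odor_on + 0.2) if compound else None
        odor_off = _q(odor_on + 1.0)
        # latency: lognormal base plus a novelty term on the first trials
        # with each novel odor, most pronounced on day 1
        lat = float(np.exp(rng.normal(math.log(config.latency_median_s),
                                      config.latency_sigma)))
        if trial_type in novel_types:
            amp = config.novelty_latency_s[day]
            lat += amp * math.exp(-(k - 1) / config.novelty_decay_trials)
        lat = min(lat, 2.8)
        well_entry = _q(odor_off + lat)
        if rewarded:
            size = _REWARD_FOR_TYPE[trial_type]
            reward = _q(well_entry + 0.15)
            tiw = config.rewarded_time_in_well_s[size] + rng.normal(0.0, 0.3)
            tiw = max(tiw, 0.3)
            well_exit = _q(well_entry + tiw)
        else:  # probe extinction trial: time in well indexes reward expectation
            size = "none"
            reward = None
            mean = config.time_in_well_mean_s[trial_type]
            floor = config.time_in_well_floor_s
            expect = floor + (mean - floor) * math.exp(
                -config.time_in_well_decay * (k - 1)
            )
            tiw = max(expect + rng.normal(0.0, config.time_in_well_sd_s), 0.05)
            well_exit = _q(well_entry + tiw)
        trials.append(
            Trial(index, trial_type, light, port, odor_on, novel_on, odor_off,
                  well_entry, reward, well_exit, reward_size=size, completed=True)
        )
        novel_counts.append(c)
        cursor = well_exit
        index += 1
    return trials, novel_counts


def _unit_spikes(profile, onset_s, duration_s, trials, novel_counts, session_end, rng):
    """Sample one unit's spike train by thinning a piecewise-constant rate."""
    prefs = CATEGORY_PREFERENCES[profile.category]
    starts, ends, amps = [], [], []
    ramped = profile.category in RAMPED_CATEGORIES
    for trial, c in zip(trials, novel_counts):
        if not trial.completed or trial.t_odor_on is None:
            continue
        mult = prefs.get(trial.trial_type, 0.0)
        if mult <= 0:
            continue
        f = (
            learning_factor(c, profile.learning_midpoint_trial, profile.learning_slope)
            if ramped else 1.0
        )
        amp = profile.modulation * mult * f
        if amp <= 0:
            continue
        if profile.category in NOVEL_DRIVEN and trial.is_compound:
            anchor = trial.t_novel_odor_on
        else:
            anchor = trial.t_odor_on
        start = anchor + onset_s
        starts.append(start)
        ends.append(start + duration_s)
        amps.append(amp)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    amps = np.asarray(amps)
    rmax = profile.baseline_rate + (amps.max() if amps.size else 0.0)
    n = rng.poisson(rmax * session_end)
    t = np.sort(rng.uniform(0.0, session_end, n))
    if amps.size:
        idx = np.searchsorted(starts, t, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        inside = (idx >= 0) & (t < ends[idx_c])
        rate = profile.baseline_rate + np.where(inside, amps[idx_c], 0.0)
    else:
        rate = np.full(t.shape, profile.baseline_rate)
    keep = rng.uniform(0.0, 1.0, n) < rate / rmax
    spikes = np.unique(np.round(t[keep], 4))
    return spikes


def _make_profiles(config: GeneratorConfig, rng) -> list[UnitProfile]:
    profiles = []
    for cat in CATEGORIES:
        for _ in range(config.n_units_per_category.get(cat, 0)):
            baseline = float(
                np.exp(rng.normal(math.log(config.baseline_median_hz),
                                  config.baseline_sigma))
            )
            jitter = (
                float(np.clip(rng.normal(0.0, config.peak_jitter_sd_s), -0.2, 0.2))
                if config.peak_jitter_sd_s > 0 else 0.0
            )
            profiles.append(
                UnitProfile(
                    category=cat,
                    baseline_rate=baseline,
                    modulation=config.modulation_hz,
                    learning_midpoint_trial=config.learning_midpoint_trial,
                    learning_slope=config.learning_slope,
                    peak_jitter_s=jitter,
                )
            )
    return profiles


def generate_session(
    config: GeneratorConfig,
    day: Union[int, str],
    round_index: int = 1,
    rat_id: Optional[str] = None,
) -> tuple[Session, GroundTruth]:
    """Generate one session for ``day`` in {1, 2, "probe"}.

    Trial types are interleaved in randomized order; each unit fires as an
    inhomogeneous Poisson process whose rate is its baseline plus, during
    the cue response window of its preferred trial types, the profile's
    modulation scaled by a logistic learning factor of cumulative novel-cue
    trial count (day 2 continues day 1's count).  Deterministic given
    ``config.seed``, ``round_index`` and ``day``.
    """
    config.validate()
    if day not in _DAY_CODE:
        raise ValueError(f"day must be one of {tuple(_DAY_CODE)}, got {day!r}")
    ss = np.random.SeedSequence([config.seed, round_index, _DAY_CODE[day]])
    rng_trials, rng_units = [np.random.default_rng(s) for s in ss.spawn(2)]
    trials, novel_counts = _build_trials(config, day, rng_trials)
    session_end = (trials[-1].end_time() + 2.0) if trials else 0.0

    rat = rat_id or f"rat{round_index:02d}"
    session_id = f"r{round_index:02d}_day{_DAY_CODE[day]}"
    profiles = _make_profiles(config, rng_units)
    units, truth = [], GroundTruth()
    for i, profile in enumerate(profiles):
        uid = f"r{round_index:02d}d{_DAY_CODE[day]}u{i:03d}"
        spikes = _unit_spikes(
            profile,
            config.response_onset_s + profile.peak_jitter_s,
            config.response_duration_s,
            trials, novel_counts, session_end, rng_units,
        )
        units.append(UnitRecording(uid, rat, session_id, day, spikes))
        truth.profiles[uid] = profile
    session = Session(
        trials=trials,
        units=units,
        task_variant=config.task_variant,
        metadata={
            "day": day,
            "round": round_index,
            "rat_id": rat,
            "seed": config.seed,
            "config_hash": config.hash(),
            "session_end_s": session_end,
            "synthetic": True,
            "ground_truth": {u.unit_id: truth.profiles[u.unit_id].category
                             for u in units},
        },
    )
    validate_session(session)
    return session, truth


@dataclass
class StudyRound:
    """One round of unblocking: two learning days plus the probe test."""

    day1: Session
    day2: Session
    probe: Session
    ground_truth: GroundTruth

    @property
    def sessions(self) -> tuple[Session, Session, Session]:
        return (self.day1, self.day2, self.probe)


def generate_study(config: GeneratorConfig, n_rounds: int = 1) -> list[StudyRound]:
    """Generate ``n_rounds`` independent (day1, day2, probe) session triples.

    Each round gets its own rat and its own units (the electrode is advanced
    between rounds, so units are new); unit ids are unique across the study.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rounds = []
    for r in range(1, n_rounds + 1):
        sessions = {}
        truth = GroundTruth()
        for day in (1, 2, "probe"):
            sess, gt = generate_session(config, day, round_index=r)
            sessions[day] = sess
            truth.update(gt)
        rounds.append(StudyRound(sessions[1], sessions[2], sessions["probe"], truth))
    return rounds
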