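"""Session data schema and file I/O.

A *session* is one behavioral recording: an ordered list of trials (event
timestamps on the session clock, in seconds) plus the spike timestamps of
every simultaneously recorded unit.  The same container is produced by the
synthetic generator and consumed by every analysis stage, so validation is
strict: malformed inputs are rejected with a JSON-pointer-style location,
never silently coerced.

Files are plain text: ``session.json`` holds trials, unit identifiers and
metadata; ``spikes.csv`` holds one ``unit_id,timestamp_s`` row per spike.
Timestamps are written with full float repr, so round-trips are bit-exact.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger("unblk")

#: Temporal resolution of the artifact: 0.1 ms.  Spikes closer together than
#: this are considered duplicates.
TIME_RESOLUTION_S = 1e-4

#: Trial types per task variant.  In the blocking task the three novel odors
#: are named by the reward manipulation they signal; in the control task the
#: cues are presented alone (no pre-trained compound) and are named by reward
#: size.
TRIAL_TYPES = {
    "blocking": ("initial", "blocked", "upshift", "downshift"),
    "control": ("initial", "medium", "large", "small"),
}

#: Novel (newly introduced) cue types, i.e. everything but the pre-trained cue.
NOVEL_TYPES = {
    "blocking": ("blocked", "upshift", "downshift"),
    "control": ("medium", "large", "small"),
}

REWARD_SIZES = ("none", "small", "medium", "large")
DAYS = (1, 2, "probe")

#: Timestamp fields in the order events occur within a trial.
EVENT_ORDER = (
    "t_light_on",
    "t_port_entry",
    "t_odor_on",
    "t_novel_odor_on",
    "t_odor_off",
    "t_well_entry",
    "t_reward",
    "t_well_exit",
)

ODOR_HOLD_S = 1.0        # completed cue trials: odor port hold duration
COMPOUND_LEAD_S = 0.2    # initial-odor lead on compound trials
ITI_WINDOW_S = 2.0       # pre-light baseline window length


class SessionValidationError(ValueError):
    """Raised when a session (or a session file) violates the schema.

    ``location`` is a JSON-pointer-style path such as
    ``/trials/3/t_well_entry`` naming the offending field.
    """

    def __init__(self, message: str, location: str = ""):
        self.location = location
        super().__init__(f"{location}: {message}" if location else message)


@dataclass
class Trial:
    """One behavioral trial.

    Timestamps are seconds on the session clock; ``None`` marks an event that
    did not occur (e.g. no reward on probe extinction trials, no novel odor
    on initial-odor trials).  ``completed`` is False for restarted/aborted
    trials, which are retained in files but excluded from firing-rate
    analyses.
    """

    trial_index: int
    trial_type: str
    t_light_on: float
    t_port_entry: Optional[float] = None
    t_odor_on: Optional[float] = None
    t_novel_odor_on: Optional[float] = None
    t_odor_off: Optional[float] = None
    t_well_entry: Optional[float] = None
    t_reward: Optional[float] = None
    t_well_exit: Optional[float] = None
    reward_size: str = "none"
    completed: bool = True

    def timestamps(self) -> list[tuple[str, float]]:
        """Present (name, time) pairs in event order."""
        out = []
        for name in EVENT_ORDER:
            v = getattr(self, name)
            if v is not None:
                out.append((name, v))
        return out

    @property
    def is_compound(self) -> bool:
        return self.t_novel_odor_on is not None

    @property
    def latency_s(self) -> Optional[float]:
        """Latency from odor port exit (odor off) to reward-well entry."""
        if self.t_well_entry is None or self.t_odor_off is None:
            return None
        return self.t_well_entry - self.t_odor_off

    @property
    def time_in_well_s(self) -> Optional[float]:
        """Cumulative time in the reward well (entry to exit)."""
        if self.t_well_exit is None or self.t_well_entry is None:
            return None
        return self.t_well_exit - self.t_well_entry

    def end_time(self) -> float:
        return self.timestamps()[-1][1]


@dataclass(eq=False)
class UnitRecording:
    """Spike timestamps of one isolated unit, session clock, seconds."""

    unit_id: str
    rat_id: str
    session_id: str
    day: Union[int, str]
    spikes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes, dtype=float)

    def __eq__(self, other):
        if not isinstance(other, UnitRecording):
            return NotImplemented
        return (
            (self.unit_id, self.rat_id, self.session_id, self.day)
            == (other.unit_id, other.rat_id, other.session_id, other.day)
            and np.array_equal(self.spikes, other.spikes)
        )


@dataclass(eq=False)
class Session:
    trials: list[Trial]
    units: list[UnitRecording]
    task_variant: str = "blocking"
    metadata: dict = field(default_factory=dict)

    @property
    def trial_types(self) -> tuple[str, ...]:
        return TRIAL_TYPES[self.task_variant]

    @property
    def novel_types(self) -> tuple[str, ...]:
        return NOVEL_TYPES[self.task_variant]

    def end_time(self) -> float:
        if "session_end_s" in self.metadata:
            return float(self.metadata["session_end_s"])
        return max((t.end_time() for t in self.trials), default=0.0)

    def unit(self, unit_id: str) -> UnitRecording:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def __eq__(self, other):
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.task_variant == other.task_variant
            and self.metadata == other.metadata
            and self.trials == other.trials
            and self.units == other.units
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _validate_trial(trial: Trial, variant: str, loc: str) -> None:
    if variant not in TRIAL_TYPES:
        raise SessionValidationError(f"unknown task variant {variant!r}", "/task_variant")
    if trial.trial_type not in TRIAL_TYPES[variant]:
        raise SessionValidationError(
            f"invalid trial_type {trial.trial_type!r} for variant {variant!r}",
            f"{loc}/trial_type",
        )
    if trial.reward_size not in REWARD_SIZES:
        raise SessionValidationError(
            f"invalid reward_size {trial.reward_size!r}", f"{loc}/reward_size"
        )
    ts = trial.timestamps()
    for name, v in ts:
        if not math.isfinite(v):
            raise SessionValidationError("non-finite timestamp", f"{loc}/{name}")
    for (n1, v1), (n2, v2) in zip(ts, ts[1:]):
        if v2 <= v1:
            raise SessionValidationError(
                f"{n2} ({v2}) must be after {n1} ({v1})", f"{loc}/{n2}"
            )
    if trial.completed and trial.t_odor_on is not None:
        if trial.t_odor_off is None:
            raise SessionValidationError(
                "completed cue trial lacks t_odor_off", f"{loc}/t_odor_off"
            )
        dur = trial.t_odor_off - trial.t_odor_on
        if abs(dur - ODOR_HOLD_S) > 1e-6:
            raise SessionValidationError(
                f"odor duration {dur:.4f} s != {ODOR_HOLD_S} s on completed trial",
                f"{loc}/t_odor_off",
            )
    if trial.t_novel_odor_on is not None:
        if trial.t_odor_on is None:
            raise SessionValidationError(
                "novel odor onset without initial odor onset", f"{loc}/t_novel_odor_on"
            )
        lead = trial.t_novel_odor_on - trial.t_odor_on
        if abs(lead - COMPOUND_LEAD_S) > 1e-6:
            raise SessionValidationError(
                f"initial-odor lead {lead:.4f} s != {COMPOUND_LEAD_S} s",
                f"{loc}/t_novel_odor_on",
            )


def validate_session(session: Session) -> None:
    """Check every schema invariant; raise :class:`SessionValidationError`.

    Checks per-trial event ordering and durations, non-overlap of successive
    trial windows (including the 2 s pre-light baseline window), and per-unit
    spike-train sanity (sorted, nonnegative, no duplicates at 0.1 ms, inside
    the session).
    """
    for i, trial in enumerate(session.trials):
        _validate_trial(trial, session.task_variant, f"/trials/{i}")
    # trial windows (pre-light ITI .. last event) must not overlap
    order = sorted(range(len(session.trials)), key=lambda i: session.trials[i].t_light_on)
    for a, b in zip(order, order[1:]):
        prev, nxt = session.trials[a], session.trials[b]
        if prev.end_time() > nxt.t_light_on - ITI_WINDOW_S + 1e-9:
            raise SessionValidationError(
                f"trial window overlaps the next trial's baseline window "
                f"(ends {prev.end_time():.4f}, next light {nxt.t_light_on:.4f})",
                f"/trials/{a}",
            )
    end = session.end_time()
    seen_ids = set()
    for j, unit in enumerate(session.units):
        loc = f"/units/{j}"
        if unit.unit_id in seen_ids:
            raise SessionValidationError(
                f"duplicate unit_id {unit.unit_id!r}", f"{loc}/unit_id"
            )
        seen_ids.add(unit.unit_id)
        if unit.day not in DAYS:
            raise SessionValidationError(f"invalid day {unit.day!r}", f"{loc}/day")
        s = unit.spikes
        if s.size:
            if not np.all(np.isfinite(s)):
                raise SessionValidationError("non-finite spike time", f"{loc}/spikes")
            if s[0] < 0:
                raise SessionValidationError("negative spike time", f"{loc}/spikes")
            d = np.diff(s)
            if np.any(d < 0):
                raise SessionValidationError("spikes not sorted", f"{loc}/spikes")
            if np.any(d < 0.5 * TIME_RESOLUTION_S):
                raise SessionValidationError(
                    "duplicate spikes at 0.1 ms resolution", f"{loc}/spikes"
                )
            if s[-1] > end + 1e-9:
                raise SessionValidationError(
                    f"spike at {s[-1]:.4f} beyond session end {end:.4f}",
                    f"{loc}/spikes",
                )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _trial_to_json(trial: Trial) -> dict:
    d = asdict(trial)
    return {k: v for k, v in d.items() if v is not None}


_REQUIRED_TRIAL_KEYS = ("trial_index", "trial_type", "t_light_on")


def _trial_from_json(obj: dict, loc: str) -> Trial:
    if not isinstance(obj, dict):
        raise SessionValidationError("trial must be an object", loc)
    for key in _REQUIRED_TRIAL_KEYS:
        if key not in obj:
            raise SessionValidationError(f"missing required field {key!r}", f"{loc}/{key}")
    known = {f for f in Trial.__dataclass_fields__}
    extra = set(obj) - known
    if extra:
        raise SessionValidationError(f"unknown fields {sorted(extra)}", loc)
    return Trial(**obj)


def write_session(session: Session, path: Union[str, Path]) -> Path:
    """Write a validated session to ``path`` (a directory).

    Produces ``session.json`` and ``spikes.csv``; timestamps are written with
    full float precision so ``read_session(write_session(s)) == s``.
    """
    validate_session(session)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    doc = {
        "task_variant": session.task_variant,
        "metadata": session.metadata,
        "trials": [_trial_to_json(t) for t in session.trials],
        "units": [
            {"unit_id": u.unit_id, "rat_id": u.rat_id,
             "session_id": u.session_id, "day": u.day}
            for u in session.units
        ],
    }
    with open(path / "session.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    with open(path / "spikes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "timestamp_s"])
        for u in session.units:
            for t in u.spikes:
                w.writerow([u.unit_id, repr(float(t))])
    logger.info("wrote session with %d trials, %d units to %s",
                len(session.trials), len(session.units), path)
    return path


def read_session(path: Union[str, Path]) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    try:
        with open(path / "session.json") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise SessionValidationError(f"invalid JSON: {e}", "/") from e
    if not isinstance(doc, dict):
        raise SessionValidationError("top-level document must be an object", "/")
    for key in ("task_variant", "trials", "units"):
        if key not in doc:
            raise SessionValidationError(f"missing key {key!r}", f"/{key}")
    trials = [
        _trial_from_json(t, f"/trials/{i}") for i, t in enumerate(doc["trials"])
    ]
    units = []
    for j, u in enumerate(doc["units"]):
        for key in ("unit_id", "rat_id", "session_id", "day"):
            if key not in u:
                raise SessionValidationError(f"missing key {key!r}", f"/units/{j}/{key}")
        units.append(UnitRecording(u["unit_id"], u["rat_id"], u["session_id"], u["day"]))
    by_id = {u.unit_id: [] for u in units}
    spikes_file = path / "spikes.csv"
    if spikes_file.exists():
        with open(spikes_file, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header != ["unit_id", "timestamp_s"]:
                raise SessionValidationError(
                    f"bad spikes.csv header {header}", "/spikes/header"
                )
            for k, row in enumerate(reader):
                if len(row) != 2:
                    raise SessionValidationError(f"bad row {row}", f"/spikes/{k}")
                uid, ts = row
                if uid not in by_id:
                    raise SessionValidationError(
                        f"spike for unknown unit {uid!r}", f"/spikes/{k}/unit_id"
                    )
                try:
                    by_id[uid].append(float(ts))
                except ValueError:
                    raise SessionValidationError(
                        f"bad timestamp {ts!r}", f"/spikes/{k}/timestamp_s"
                    ) from None
    for u in units:
        u.spikes = np.asarray(by_id[u.unit_id], dtype=float)
    session = Session(
        trials=trials,
        units=units,
        task_variant=doc["task_variant"],
        metadata=doc.get("metadata", {}),
    )
    validate_session(session)
    return session


def read_study(root: Union[str, Path]) -> list[Session]:
    """Read every session directory under ``root`` (sorted by name)."""
    root = Path(root)
    dirs = sorted(p.parent for p in root.glob("*/session.json"))
    if (root / "session.json").exists():
        dirs = [root] + dirs
    return [read_session(d) for d in dirs]
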