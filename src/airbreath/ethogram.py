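"""Behavioural event streams: tallies, synchrony, trigger attribution.

A trial is 15 min of video-coded behaviour for one group (or one isolated
fish) at one aquatic oxygen level.  The ethogram has four codes: breath
(surfacing air gulp), attack (bite/lunge), push (displacement) and avoid
(active retreat).  This module computes:

* per-fish / per-group tallies;
* the coefficient of dispersion (CD) — the variance/mean ratio of event
  counts over fixed 30-s bins, > 1 indicating temporal clumping
  (synchronous surfacing), < 1 uniformity;
* proximity attribution — the fraction of breaths occurring within a
  short window (default 5 s) after a reference event: a breath by another
  fish, the focal fish's own attack, being attacked, its own avoid, or
  any agonistic interaction involving it;
* the dominant (most aggressive) individual per group and group breath
  totals excluding it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedStatisticError

__all__ = [
    "BEHAVIOURS",
    "PROXIMITY_CATEGORIES",
    "BehaviourEvent",
    "Trial",
    "SynchronyResult",
    "ProximityResult",
    "tally",
    "coefficient_of_dispersion",
    "proximity_fraction",
    "dominant_individual",
    "group_breaths_excluding",
    "read_event_log",
    "read_activity_table",
    "trials_to_event_frame",
]

logger = logging.getLogger(__name__)

BEHAVIOURS = frozenset({"breath", "attack", "push", "avoid"})

PROXIMITY_CATEGORIES = (
    "breath_by_other",
    "own_attack",
    "being_attacked",
    "own_avoid",
    "any_interaction",
)

#: Agonistic behaviour codes (everything except breathing).
AGONISTIC = frozenset({"attack", "push", "avoid"})


@dataclass(frozen=True)
class BehaviourEvent:
    """One video-coded event: who did what, when, optionally to whom."""

    time: float
    fish_id: str
    behaviour: str
    target_id: str | None = None

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise SchemaError(f"unknown behaviour code {self.behaviour!r}")
        if self.target_id is not None and self.target_id == self.fish_id:
            raise SchemaError("event target must differ from actor")


@dataclass
class Trial:
    """All events for one group (or solitary fish) at one oxygen level."""

    group_id: str
    oxygen_level: str  # '100'..'20' (% air saturation) or 'recovery'
    roster: tuple[str, ...]
    events: list[BehaviourEvent] = field(default_factory=list)
    duration: float = 900.0
    activity: dict[str, float] = field(default_factory=dict)
    trial_id: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SchemaError("trial duration must be positive")
        roster = set(self.roster)
        for e in self.events:
            if not (0.0 <= e.time <= self.duration):
                raise SchemaError(f"event time {e.time} outside [0, {self.duration}]")
            if e.fish_id not in roster:
                raise SchemaError(f"event actor {e.fish_id!r} not in roster")
        self.events = sorted(self.events, key=lambda e: (e.time, e.fish_id))

    def of(self, behaviour: str) -> list[BehaviourEvent]:
        return [e for e in self.events if e.behaviour == behaviour]


@dataclass
class SynchronyResult:
    cd: float
    bin_width: float
    n_bins: int
    counts: np.ndarray
    variance_convention: str = "sample (n-1)"


@dataclass
class ProximityResult:
    category: str
    window: float
    fraction: float
    n_breaths: int


def tally(trial: Trial, behaviour: str, by_fish: bool = True):
    """Exact event counts per fish (dict, zero-filled over the roster) or
    for the whole group (int)."""
    if behaviour not in BEHAVIOURS:
        raise SchemaError(f"unknown behaviour code {behaviour!r}")
    counts = {f: 0 for f in trial.roster}
    for e in trial.events:
        if e.behaviour == behaviour:
            counts[e.fish_id] += 1
    return counts if by_fish else sum(counts.values())


def coefficient_of_dispersion(
    event_times: Sequence[float],
    duration: float = 900.0,
    bin_width: float = 30.0,
) -> SynchronyResult:
    """Variance/mean ratio of event counts across fixed time bins.

    Bins are anchored at time 0; a trailing partial bin (duration not a
    multiple of bin_width) is dropped with a warning, along with any
    events in it.  Sample variance (n−1 denominator) is used.  An empty
    stream has no defined CD.
    """
    if bin_width <= 0 or duration <= 0:
        raise ValueError("duration and bin_width must be positive")
    n_bins = int(duration // bin_width)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if duration % bin_width != 0:
        warnings.warn(
            f"duration {duration} not a multiple of bin_width {bin_width}; "
            "trailing partial bin dropped",
            stacklevel=2,
        )
    t = np.asarray(event_times, dtype=float)
    t = t[t < n_bins * bin_width]
    if t.size == 0:
        raise UndefinedStatisticError("CD undefined for an empty event stream")
    counts, _ = np.histogram(t, bins=n_bins, range=(0.0, n_bins * bin_width))
    mean = counts.mean()
    cd = float(counts.var(ddof=1) / mean)
    return SynchronyResult(cd=cd, bin_width=bin_width, n_bins=n_bins, counts=counts)


def _qualifies(event: BehaviourEvent, focal: str, category: str) -> bool:
    """Is ``event`` a valid reference event for a breath by ``focal``?"""
    b, actor, target = event.behaviour, event.fish_id, event.target_id
    if category == "breath_by_other":
        return b == "breath" and actor != focal
    if category == "own_attack":
        return b == "attack" and actor == focal
    if category == "being_attacked":
        return b == "attack" and target == focal
    if category == "own_avoid":
        return b == "avoid" and actor == focal
    if category == "any_interaction":
        # avoids involve only the avoider (targets of avoids are not coded)
        return b in AGONISTIC and (actor == focal or target == focal)
    raise ValueError(f"unknown proximity category {category!r}")


def proximity_fraction(
    trial: Trial,
    category: str,
    window: float = 5.0,
    scope: Iterable[str] | None = None,
) -> ProximityResult:
    """Fraction of breaths preceded, within (0, window] s, by a reference
    event of the given category.

    A breath at time t qualifies iff at least one reference event exists
    at time s with ``0 < t − s <= window``: the interval is half-open, so
    a simultaneous event (lag 0) does not count.  Each breath counts at
    most once per category regardless of how many reference events
    precede it.  ``scope`` restricts the breath set to those fish
    (default: whole roster).
    """
    if category not in PROXIMITY_CATEGORIES:
        raise ValueError(f"unknown proximity category {category!r}")
    if window <= 0:
        raise ValueError("window must be positive")
    scope_set = set(trial.roster) if scope is None else set(scope)
    breaths = [e for e in trial.of("breath") if e.fish_id in scope_set]
    if not breaths:
        raise UndefinedStatisticError("no breaths in scope: fraction undefined")
    n_qual = 0
    for b in breaths:
        for e in trial.events:
            if e.time >= b.time:
                break
            if b.time - e.time <= window and _qualifies(e, b.fish_id, category):
                n_qual += 1
                break
    return ProximityResult(
        category=category,
        window=window,
        fraction=n_qual / len(breaths),
        n_breaths=len(breaths),
    )


def dominant_individual(trials: Sequence[Trial]) -> str:
    """The most aggressive fish in a group: most attacks summed across
    that group's trials.

    Ties break on attacks + pushes, then lexicographic fish id; the
    tie-break path is logged.  A group with no attacks at all has no
    dominant.
    """
    if not trials:
        raise ValueError("no trials supplied")
    roster = trials[0].roster
    attacks = {f: 0 for f in roster}
    pushes = {f: 0 for f in roster}
    for tr in trials:
        for f, n in tally(tr, "attack").items():
            attacks[f] += n
        for f, n in tally(tr, "push").items():
            pushes[f] += n
    if sum(attacks.values()) == 0:
        raise UndefinedStatisticError("no attacks in group: no dominant individual")
    top = max(attacks.values())
    leaders = sorted(f for f, n in attacks.items() if n == top)
    if len(leaders) == 1:
        return leaders[0]
    logger.info("dominance tie on attacks among %s; breaking on attacks+pushes", leaders)
    combined = {f: attacks[f] + pushes[f] for f in leaders}
    top2 = max(combined.values())
    leaders2 = sorted(f for f, n in combined.items() if n == top2)
    if len(leaders2) > 1:
        logger.info("dominance tie persists among %s; lexicographic id", leaders2)
    return leaders2[0]


def group_breaths_excluding(
    trials: Sequence[Trial], excluded: str
) -> list[int]:
    """Per-trial breath totals over all roster fish except ``excluded``."""
    if not trials:
        raise ValueError("no trials supplied")
    if excluded not in trials[0].roster:
        raise SchemaError(f"{excluded!r} not in group roster")
    out = []
    for tr in trials:
        counts = tally(tr, "breath")
        out.append(sum(n for f, n in counts.items() if f != excluded))
    return out


# ---------------------------------------------------------------------------
# IO


def read_activity_table(path) -> pd.DataFrame:
    """Activity (total distance moved) table: trial_id, fish_id, distance."""
    df = pd.read_csv(path, dtype={"trial_id": str, "fish_id": str})
    missing = {"trial_id", "fish_id", "distance"} - set(df.columns)
    if missing:
        raise SchemaError(f"activity table missing columns: {sorted(missing)}")
    return df


def read_event_log(
    events_path,
    activity_path=None,
    duration: float = 900.0,
) -> list[Trial]:
    """Read a delimited behavioural event log into trials.

    Expected event columns: trial_id, group_id, oxygen_level, time_s,
    fish_id, behaviour, target_id (blank for untargeted events).  The
    roster of a trial is the union of fish seen in that group's events
    and (if given) the activity table, so silent fish are only recovered
    when an activity table lists them.
    """
    df = pd.read_csv(
        events_path,
        dtype={"trial_id": str, "group_id": str, "oxygen_level": str, "fish_id": str},
    )
    required = {"trial_id", "group_id", "oxygen_level", "time_s", "fish_id", "behaviour"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"event log missing columns: {sorted(missing)}")
    if "target_id" not in df.columns:
        df["target_id"] = np.nan

    activity = None
    if activity_path is not None:
        activity = read_activity_table(activity_path)

    group_roster: dict[str, set] = {}
    for gid, sub in df.groupby("group_id"):
        group_roster[gid] = set(sub["fish_id"])
    if activity is not None:
        id_map = df.drop_duplicates("trial_id").set_index("trial_id")["group_id"]
        for _, row in activity.iterrows():
            gid = id_map.get(row["trial_id"])
            if gid is not None:
                group_roster[gid].add(row["fish_id"])

    trials = []
    for tid, sub in df.groupby("trial_id", sort=True):
        gid = sub["group_id"].iloc[0]
        events = [
            BehaviourEvent(
                time=float(r.time_s),
                fish_id=str(r.fish_id),
                behaviour=str(r.behaviour),
                target_id=None if pd.isna(r.target_id) else str(r.target_id),
            )
            for r in sub.itertuples()
        ]
        act = {}
        if activity is not None:
            act = {
                str(r.fish_id): float(r.distance)
                for r in activity[activity["trial_id"] == tid].itertuples()
            }
        trials.append(
            Trial(
                group_id=str(gid),
                oxygen_level=str(sub["oxygen_level"].iloc[0]),
                roster=tuple(sorted(group_roster[gid])),
                events=events,
                duration=duration,
                activity=act,
                trial_id=str(tid),
            )
        )
    return trials


def trials_to_event_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Serialise trials back to the tidy event-log format."""
    rows = []
    for tr in trials:
        tid = tr.trial_id or f"{tr.group_id}_{tr.oxygen_level}"
        for e in tr.events:
            rows.append(
                {
                    "trial_id": tid,
                    "group_id": tr.group_id,
                    "oxygen_level": tr.oxygen_level,
                    "time_s": e.time,
                    "fish_id": e.fish_id,
                    "behaviour": e.behaviour,
                    "target_id": e.target_id if e.target_id is not None else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "group_id", "oxygen_level", "time_s",
            "fish_id", "behaviour", "target_id",
        ],
    )
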