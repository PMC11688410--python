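"""Protocol calendar: phases, corner assignment, water windows, dropouts.

The default 34-day schedule walks a cohort through adaptation shaping
(free access -> door -> nose poke -> restricted water), a place
preference / reversal block, four reaction-time task blocks of rising
difficulty, and a place-avoidance / extinction block.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import DAY_SECONDS, EventDataset, slice_by_day


class Phase(str, Enum):
    FREE_ADAPT = "FREE_ADAPT"
    DOOR_ADAPT = "DOOR_ADAPT"
    NP_ADAPT = "NP_ADAPT"
    WD_ADAPT = "WD_ADAPT"
    PP = "PP"
    REVERSAL = "REVERSAL"
    RT1 = "RT1"
    RT2 = "RT2"
    RT3 = "RT3"
    RT4 = "RT4"
    AVOIDANCE = "AVOIDANCE"
    HOME_CAGE_DELAY = "HOME_CAGE_DELAY"
    EXTINCTION = "EXTINCTION"


RT_PHASES = (Phase.RT1, Phase.RT2, Phase.RT3, Phase.RT4)


class DoorPolicy(str, Enum):
    ALWAYS_OPEN = "always_open"
    OPEN_ON_VISIT = "open_on_visit"
    OPEN_ON_POKE = "open_on_poke"
    ASSIGNED_ONLY = "assigned_only"
    RT_CONTINGENCY = "rt_contingency"
    ALL_CLOSED = "all_closed"


@dataclass(frozen=True)
class WaterWindow:
    """Daily interval during which the doors can deliver water.

    ``kind`` is one of ``unrestricted`` (no gating), ``restricted``
    (clock interval ``[start_clock, end_clock)``), or ``none`` (water
    never available).
    """

    kind: str
    start_clock: float | None = None
    end_clock: float | None = None

    @classmethod
    def unrestricted(cls) -> "WaterWindow":
        return cls("unrestricted")

    @classmethod
    def empty(cls) -> "WaterWindow":
        return cls("none")

    @classmethod
    def restricted(cls, start_clock: float, end_clock: float) -> "WaterWindow":
        return cls("restricted", float(start_clock), float(end_clock))

    @property
    def duration_hours(self) -> float:
        if self.kind == "unrestricted":
            return 24.0
        if self.kind == "none":
            return 0.0
        return (self.end_clock - self.start_clock) % 24.0

    def contains(self, t: float, t0: float, t0_clock: float = 6.0) -> bool:
        """Is protocol time ``t`` inside the window?

        ``t0_clock`` is the wall-clock hour at protocol start (lights-on).
        """
        if self.kind == "unrestricted":
            return True
        if self.kind == "none":
            return False
        clock = (t0_clock + (t - t0) / 3600.0) % 24.0
        lo, hi = self.start_clock % 24.0, self.end_clock % 24.0
        if lo <= hi:
            return lo <= clock < hi
        return clock >= lo or clock < hi


@dataclass(frozen=True)
class PhaseSpec:
    name: Phase
    day_first: int
    day_last: int
    doors: DoorPolicy
    water: WaterWindow
    precue_set: tuple[float, ...] | None = None
    cue_duration: float | None = None
    air_puff: bool = False

    def __post_init__(self) -> None:
        is_rt = self.name in RT_PHASES
        if is_rt and (not self.precue_set or self.cue_duration is None):
            raise ValueError(f"{self.name}: RT phase requires precue_set and cue_duration")
        if not is_rt and (self.precue_set is not None or self.cue_duration is not None):
            raise ValueError(f"{self.name}: precue/cue only valid for RT phases")
        if self.day_first > self.day_last:
            raise ValueError(f"{self.name}: empty day range")

    @property
    def days(self) -> range:
        return range(self.day_first, self.day_last + 1)


@dataclass(frozen=True)
class Protocol:
    phases: tuple[PhaseSpec, ...]
    t0: float = 0.0
    t0_clock: float = 6.0

    def __post_init__(self) -> None:
        expected = self.phases[0].day_first
        for ph in self.phases:
            if ph.day_first != expected:
                raise ValueError(f"phase calendar gap/overlap at day {ph.day_first} ({ph.name})")
            expected = ph.day_last + 1

    @property
    def n_days(self) -> int:
        return self.phases[-1].day_last - self.phases[0].day_first + 1

    @property
    def day_range(self) -> range:
        return range(self.phases[0].day_first, self.phases[-1].day_last + 1)

    def phase_for_day(self, day: int) -> PhaseSpec:
        for ph in self.phases:
            if ph.day_first <= day <= ph.day_last:
                return ph
        raise KeyError(f"day {day} outside the protocol calendar")


# ----------------------------------------------------------------------

DEFAULT_WATER_START = 18.0
DEFAULT_WATER_END = 21.0

#: corner layout: 1,2 front; 3,4 back; diagonals oppose
OPPOSITE_CORNER = {1: 4, 2: 3, 3: 2, 4: 1}


def build_default_protocol(
    t0: float = 0.0,
    water_start: float = DEFAULT_WATER_START,
    water_end: float = DEFAULT_WATER_END,
    t0_clock: float = 6.0,
) -> Protocol:
    """The default 34-day calendar.

    FREE 1-4, DOOR 5-6, NP 7-8, WD 9, PP 10-12, REVERSAL 13-15,
    RT1 16-18 ({2}s pre-cue, 7 s cue), RT2 19-21 ({2,4,8}, 7 s),
    RT3 22-24 ({2,4,8}, 3 s), RT4 25-28 ({2,4,8}, 1 s),
    AVOIDANCE 29, HOME_CAGE_DELAY 30, EXTINCTION 31-34.
    Water is unrestricted through NP adaptation, restricted to a 3-h
    dark-phase window from WD onward, and absent on the avoidance day.
    """
    unrestricted = WaterWindow.unrestricted()
    restricted = WaterWindow.restricted(water_start, water_end)
    phases = (
        PhaseSpec(Phase.FREE_ADAPT, 1, 4, DoorPolicy.ALWAYS_OPEN, unrestricted),
        PhaseSpec(Phase.DOOR_ADAPT, 5, 6, DoorPolicy.OPEN_ON_VISIT, unrestricted),
        PhaseSpec(Phase.NP_ADAPT, 7, 8, DoorPolicy.OPEN_ON_POKE, unrestricted),
        PhaseSpec(Phase.WD_ADAPT, 9, 9, DoorPolicy.OPEN_ON_POKE, restricted),
        PhaseSpec(Phase.PP, 10, 12, DoorPolicy.ASSIGNED_ONLY, restricted),
        PhaseSpec(Phase.REVERSAL, 13, 15, DoorPolicy.ASSIGNED_ONLY, restricted),
        PhaseSpec(Phase.RT1, 16, 18, DoorPolicy.RT_CONTINGENCY, restricted, (2.0,), 7.0),
        PhaseSpec(Phase.RT2, 19, 21, DoorPolicy.RT_CONTINGENCY, restricted, (2.0, 4.0, 8.0), 7.0),
        PhaseSpec(Phase.RT3, 22, 24, DoorPolicy.RT_CONTINGENCY, restricted, (2.0, 4.0, 8.0), 3.0),
        PhaseSpec(Phase.RT4, 25, 28, DoorPolicy.RT_CONTINGENCY, restricted, (2.0, 4.0, 8.0), 1.0),
        PhaseSpec(Phase.AVOIDANCE, 29, 29, DoorPolicy.ALL_CLOSED, WaterWindow.empty(), air_puff=True),
        PhaseSpec(Phase.HOME_CAGE_DELAY, 30, 30, DoorPolicy.ALL_CLOSED, WaterWindow.empty()),
        PhaseSpec(Phase.EXTINCTION, 31, 34, DoorPolicy.OPEN_ON_POKE, restricted),
    )
    return Protocol(phases=phases, t0=t0, t0_clock=t0_clock)


def load_protocol_config(path: str | Path) -> dict:
    """Read a YAML (or ``key: value``) override file for the protocol."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("protocol config must be a mapping")
    return cfg


def protocol_from_config(cfg: dict, t0: float = 0.0) -> Protocol:
    allowed = {"water_start", "water_end", "t0_clock"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown protocol config key(s): {sorted(unknown)}")
    return build_default_protocol(t0=t0, **{k: float(v) for k, v in cfg.items()})


def water_access_window(phase: PhaseSpec | Phase, protocol: Protocol | None = None) -> WaterWindow:
    """Water window for a phase (PhaseSpec, or Phase name looked up in a protocol)."""
    if isinstance(phase, PhaseSpec):
        return phase.water
    proto = protocol or build_default_protocol()
    for ph in proto.phases:
        if ph.name == phase:
            return ph.water
    raise KeyError(f"phase {phase} not in protocol")


def reversal_corner(corner: int, opposite: dict[int, int] | None = None) -> int:
    """Diagonally opposite corner (1<->4, 2<->3 under the default layout)."""
    mapping = opposite or OPPOSITE_CORNER
    if corner not in mapping:
        raise ValueError(f"invalid corner {corner!r}")
    return mapping[corner]


# ----------------------------------------------------------------------
# Corner assignment
# ----------------------------------------------------------------------

@dataclass
class CornerAssignment:
    """Assigned (place-preference) corner per animal; reversal is its opposite."""

    pp_corner: dict[str, int]
    opposite: dict[int, int] = field(default_factory=lambda: dict(OPPOSITE_CORNER))

    def reversal(self, animal_id: str) -> int:
        return self.opposite[self.pp_corner[animal_id]]

    def corner_for_phase(self, animal_id: str, phase: Phase) -> int | None:
        """The contingency-relevant corner for a phase, or None.

        PP uses the assigned corner; reversal, the RT tasks and avoidance
        all use the reversed corner; other phases have no assigned corner.
        """
        if phase == Phase.PP:
            return self.pp_corner[animal_id]
        if phase in (Phase.REVERSAL, *RT_PHASES, Phase.AVOIDANCE):
            return self.reversal(animal_id)
        return None


def _balanced_pick(pref: list[int], counts: Counter, n: int) -> int | None:
    """First corner in preference order whose count can grow while
    keeping the max-min spread of the final distribution <= 1."""
    base, extra = divmod(n, 4)
    over = sum(1 for c in (1, 2, 3, 4) if counts[c] > base)
    for c in pref:
        if counts[c] < base or (counts[c] == base and extra > 0 and over < extra):
            return c
    return None


def assign_corners(
    adaptation_visit_counts: pd.DataFrame,
    roster: pd.DataFrame,
    opposite: dict[int, int] | None = None,
) -> CornerAssignment:
    """Assign each animal its least-visited adaptation corner, balanced.

    Parameters
    ----------
    adaptation_visit_counts
        Indexed by animal_id with columns 1..4 (visit counts per corner).
    roster
        Roster frame with ``animal_id`` and ``genotype`` columns.

    Animals are processed in a deterministic order alternating genotypes;
    each receives the least-visited corner (ties -> lowest corner number)
    that keeps both total and per-genotype corner counts within a spread
    of one.
    """
    if roster.empty:
        raise ValueError("empty roster")
    for c in (1, 2, 3, 4):
        if c not in adaptation_visit_counts.columns:
            raise ValueError(f"visit counts missing corner {c}")
    missing = set(roster["animal_id"]) - set(adaptation_visit_counts.index)
    if missing:
        raise ValueError(f"visit counts missing animal(s): {sorted(missing)}")

    # interleave genotypes so balance constraints bind evenly
    by_geno = {
        g: sorted(roster.loc[roster["genotype"] == g, "animal_id"])
        for g in sorted(roster["genotype"].unique())
    }
    order: list[tuple[str, str]] = []
    queues = {g: list(ids) for g, ids in by_geno.items()}
    while any(queues.values()):
        for g in sorted(queues):
            if queues[g]:
                order.append((queues[g].pop(0), g))

    n_total = len(order)
    n_geno = {g: len(ids) for g, ids in by_geno.items()}
    total_counts: Counter = Counter()
    geno_counts: dict[str, Counter] = {g: Counter() for g in by_geno}
    assigned: dict[str, int] = {}
    for animal_id, g in order:
        row = adaptation_visit_counts.loc[animal_id]
        pref = sorted((1, 2, 3, 4), key=lambda c: (row[c], c))
        pick = None
        for c in pref:
            # corner must be open under the total-balance rule AND the
            # genotype-balance rule; genotype rule is relaxed if impossible
            if _balanced_pick([c], total_counts, n_total) is None:
                continue
            if _balanced_pick([c], geno_counts[g], n_geno[g]) is None:
                continue
            pick = c
            break
        if pick is None:
            pick = _balanced_pick(pref, total_counts, n_total)
        if pick is None:  # pragma: no cover - capacity always suffices
            raise RuntimeError("no corner with remaining capacity")
        assigned[animal_id] = pick
        total_counts[pick] += 1
        geno_counts[g][pick] += 1
    return CornerAssignment(pp_corner=assigned, opposite=dict(opposite or OPPOSITE_CORNER))


# ----------------------------------------------------------------------
# Dropout rule
# ----------------------------------------------------------------------

def detect_dropouts(
    dataset: EventDataset,
    protocol: Protocol,
) -> list[tuple[str, int, str]]:
    """Flag animals with 48-h (two full consecutive days) without licks.

    The first lick-free 48-h window triggers a ``rescue`` (animal removed
    to a water cage and re-introduced); a second, after the rescue,
    triggers ``remove``. Days on which the schedule itself provides no
    water (the avoidance day and the home-cage delay day) cannot count
    toward a window.
    """
    n_days = min(protocol.n_days, dataset.n_days)  # only recorded days can count
    if n_days == 0:
        return []
    lickable = {
        d: protocol.phase_for_day(d).water.kind != "none"
        for d in protocol.day_range
    }
    slices = slice_by_day(dataset, n_days=n_days)
    licks_per_day: dict[str, dict[int, int]] = {
        a: {} for a in dataset.animals["animal_id"]
    }
    visit_owner = dataset.visits.set_index("visit_id")["animal_id"]
    for sl in slices:
        if sl.licks.empty:
            totals = pd.Series(dtype=np.int64)
        else:
            totals = sl.licks.groupby(visit_owner.reindex(sl.licks["visit_id"]).to_numpy())["n_licks"].sum()
        for a in licks_per_day:
            licks_per_day[a][sl.day_index] = int(totals.get(a, 0))

    # evaluation starts at an animal's first recorded visit day: days before
    # introduction into the cage are not evidence of failure to drink
    first_day = (
        dataset.visits.groupby("animal_id")["t_start"]
        .min()
        .map(lambda t: int((t - dataset.t0) // DAY_SECONDS) + 1)
        if len(dataset.visits)
        else pd.Series(dtype=np.int64)
    )

    events: list[tuple[str, int, str]] = []
    for a in sorted(licks_per_day):
        if a not in first_day.index:
            continue
        dry = 0
        rescued = False
        for d in sorted(licks_per_day[a]):
            if d < first_day[a]:
                continue
            if not lickable.get(d, True):
                continue  # schedule provides no water: window neither grows nor resets
            if licks_per_day[a][d] > 0:
                dry = 0
                continue
            dry += 1
            if dry >= 2:
                if not rescued:
                    events.append((a, d, "rescue"))
                    rescued = True
                    dry = 0  # watered outside the cage
                else:
                    events.append((a, d, "remove"))
                    break
    return events


def apply_dropouts(roster: pd.DataFrame, events: list[tuple[str, int, str]]) -> pd.DataFrame:
    """Mark removed animals on a roster copy (removal_day = trigger day)."""
    roster = roster.copy()
    for animal_id, day, action in events:
        if action == "remove":
            roster.loc[roster["animal_id"] == animal_id, ["status", "removal_day"]] = ["removed", float(day)]
    return roster
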