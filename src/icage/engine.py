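"""Corner-contingency state machine and trial adjudication.

Given raw event streams and a protocol phase, this module decides door
openings and air puffs and classifies every reaction-time trial as
premature, correct, or abandoned. The same code path is used by the
simulator (to generate ground truth) and by re-analysis of recorded
event exports, so that replaying a simulated dataset reproduces the
simulator's own trial log exactly.

Trial timing conventions: the first nose poke of a visit to the assigned
corner initiates a trial at ``t_init``; a pre-cue delay ``D`` (drawn per
trial from the phase's pre-cue set) precedes cue onset; the cue lasts
``C`` seconds. A poke in the open interval ``(t_init, t_init+D)`` is
premature; a poke in ``[t_init+D, t_init+D+C)`` is correct (the LED is
on from exactly ``t_init+D``); no poke before ``t_init+D+C`` abandons
the trial, and later pokes are ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventDataset, visit_day_index
from .schedule import CornerAssignment, DoorPolicy, Phase, PhaseSpec, Protocol


class Outcome(str, Enum):
    PREMATURE = "PREMATURE"
    CORRECT = "CORRECT"
    ABANDONED = "ABANDONED"


@dataclass(frozen=True)
class TrialRecord:
    """One initiated reaction-time trial."""

    animal_id: str
    visit_id: int
    day_index: int
    t_init: float
    precue: float
    cue: float
    outcome: Outcome
    t_response: float | None
    reward: bool

    def __post_init__(self) -> None:
        if self.outcome == Outcome.CORRECT:
            assert self.t_response is not None
            assert self.t_init + self.precue <= self.t_response < self.t_init + self.precue + self.cue
        elif self.outcome == Outcome.PREMATURE:
            assert self.t_response is not None and not self.reward
            assert self.t_init < self.t_response < self.t_init + self.precue
        else:
            assert self.t_response is None and not self.reward


TRIAL_COLUMNS = [
    "animal_id", "day", "visit_id", "precue", "cue",
    "outcome", "t_init", "t_response", "reward",
]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [
        (t.animal_id, t.day_index, t.visit_id, t.precue, t.cue,
         t.outcome.value, t.t_init, np.nan if t.t_response is None else t.t_response, t.reward)
        for t in trials
    ]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    if df.empty:
        df = df.astype({
            "animal_id": object, "day": np.int64, "visit_id": np.int64,
            "precue": float, "cue": float, "outcome": object,
            "t_init": float, "t_response": float, "reward": bool,
        })
    return df


# ----------------------------------------------------------------------
# Pre-cue draws
# ----------------------------------------------------------------------

def draw_precue(rng: np.random.Generator, precue_set: Sequence[float]) -> float:
    """Draw one pre-cue delay i.i.d. uniform over the phase's set."""
    if len(precue_set) == 0:
        raise ValueError("empty precue_set")
    return float(precue_set[int(rng.integers(len(precue_set)))])


class PrecueStream:
    """Counter-based pre-cue draw stream shared by simulator and engine.

    The draw for trial ``i`` of an animal depends only on
    ``(seed, animal_id, i)``, so the engine re-derives the simulator's
    draws without consuming or synchronising any sequential RNG state.
    Uniformity comes from hashing with BLAKE2b.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)

    def draw(self, animal_id: str, trial_index: int, precue_set: Sequence[float]) -> float:
        if len(precue_set) == 0:
            raise ValueError("empty precue_set")
        msg = f"{self.seed}|{animal_id}|{trial_index}".encode()
        h = hashlib.blake2b(msg, digest_size=8).digest()
        u = int.from_bytes(h, "little")
        return float(precue_set[u % len(precue_set)])


# ----------------------------------------------------------------------
# Trial classification
# ----------------------------------------------------------------------

def classify_trial(
    poke_offsets_after_init: Sequence[float],
    precue: float,
    cue: float,
) -> tuple[Outcome, float | None]:
    """Classify a trial from post-initiation poke offsets (seconds).

    The first poke before ``precue + cue`` decides the outcome; pokes at
    or after cue offset are ignored (the trial has already lapsed).
    """
    if precue <= 0 or cue <= 0:
        raise ValueError("precue and cue must be positive")
    prev = 0.0
    for off in poke_offsets_after_init:
        if off <= 0:
            raise ValueError(f"non-positive poke offset {off}")
        if off < prev:
            raise ValueError("poke offsets must be ascending")
        prev = off
    if poke_offsets_after_init:
        first = float(poke_offsets_after_init[0])
        if first < precue:
            return Outcome.PREMATURE, first
        if first < precue + cue:
            return Outcome.CORRECT, first
    return Outcome.ABANDONED, None


# ----------------------------------------------------------------------
# Visit adjudication
# ----------------------------------------------------------------------

@dataclass
class VisitOutcome:
    door_opened: bool
    door_t: float | None
    trial: TrialRecord | None
    puff: bool


def adjudicate_visit(
    visit: pd.Series,
    poke_times: Sequence[float],
    phase: PhaseSpec,
    assigned_corner: int | None,
    precue_stream: PrecueStream | None,
    trial_index: int,
    protocol: Protocol,
) -> VisitOutcome:
    """Apply the phase's corner contingency to one visit.

    ``poke_times`` are absolute times, ascending, all within the visit.
    ``trial_index`` is the per-animal count of previously initiated
    trials (feeds the counter-based pre-cue stream).
    """
    corner = int(visit["corner"])
    day = int(visit_day_index(float(visit["t_start"]), protocol.t0))
    window = phase.water
    in_window = lambda t: window.contains(t, protocol.t0, protocol.t0_clock)  # noqa: E731

    if phase.doors == DoorPolicy.ALWAYS_OPEN:
        return VisitOutcome(True, float(visit["t_start"]), None, False)
    if phase.doors == DoorPolicy.OPEN_ON_VISIT:
        return VisitOutcome(True, float(visit["t_start"]), None, False)
    if phase.doors == DoorPolicy.OPEN_ON_POKE:
        if poke_times and in_window(poke_times[0]):
            return VisitOutcome(True, float(poke_times[0]), None, False)
        return VisitOutcome(False, None, None, False)
    if phase.doors == DoorPolicy.ASSIGNED_ONLY:
        if assigned_corner is None:
            raise ValueError(f"phase {phase.name} requires a corner assignment")
        if poke_times and corner == assigned_corner and in_window(poke_times[0]):
            return VisitOutcome(True, float(poke_times[0]), None, False)
        return VisitOutcome(False, None, None, False)
    if phase.doors == DoorPolicy.RT_CONTINGENCY:
        if assigned_corner is None:
            raise ValueError(f"phase {phase.name} requires a corner assignment")
        if corner != assigned_corner or not poke_times:
            return VisitOutcome(False, None, None, False)
        if precue_stream is None:
            raise ValueError("RT phase requires a precue stream")
        t_init = float(poke_times[0])
        D = precue_stream.draw(str(visit["animal_id"]), trial_index, phase.precue_set)
        offsets = [t - t_init for t in poke_times[1:]]
        outcome, off = classify_trial(offsets, D, phase.cue_duration)
        t_resp = None if off is None else t_init + off
        reward = outcome == Outcome.CORRECT and in_window(t_resp)
        trial = TrialRecord(
            animal_id=str(visit["animal_id"]),
            visit_id=int(visit["visit_id"]),
            day_index=day,
            t_init=t_init,
            precue=D,
            cue=float(phase.cue_duration),
            outcome=outcome,
            t_response=t_resp,
            reward=reward,
        )
        return VisitOutcome(reward, t_resp if reward else None, trial, False)
    if phase.doors == DoorPolicy.ALL_CLOSED:
        puff = bool(
            phase.air_puff
            and poke_times
            and assigned_corner is not None
            and corner == assigned_corner
        )
        return VisitOutcome(False, None, None, puff)
    raise ValueError(f"no door policy for phase {phase.name}")  # pragma: no cover


# ----------------------------------------------------------------------
# Batch driver
# ----------------------------------------------------------------------

def run_session(
    dataset: EventDataset,
    protocol: Protocol,
    assignment: CornerAssignment,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjudicate every visit of a dataset.

    Returns ``(trial_table, annotated_visits)``. Visits are processed in
    entry-time order; per-animal trial counters feed the counter-based
    pre-cue stream, so a dataset produced by the simulator under the same
    seed yields an identical trial table.
    """
    stream = PrecueStream(seed)
    visits = dataset.visits.sort_values(["t_start", "visit_id"], kind="stable")
    pokes_by_visit: dict[int, list[float]] = {}
    if len(dataset.pokes):
        for vid, grp in dataset.pokes.sort_values("t").groupby("visit_id"):
            pokes_by_visit[int(vid)] = grp["t"].tolist()

    trial_counters: dict[str, int] = {}
    trials: list[TrialRecord] = []
    annot = {
        "day": [], "phase": [], "n_pokes": [],
        "door_opened": [], "puff": [], "trial_initiated": [],
    }
    for _, visit in visits.iterrows():
        day = int(visit_day_index(float(visit["t_start"]), protocol.t0))
        phase = protocol.phase_for_day(day)
        animal_id = str(visit["animal_id"])
        pk = pokes_by_visit.get(int(visit["visit_id"]), [])
        corner = assignment.corner_for_phase(animal_id, phase.name) if assignment.pp_corner else None
        idx = trial_counters.get(animal_id, 0)
        out = adjudicate_visit(visit, pk, phase, corner, stream, idx, protocol)
        if out.trial is not None:
            trial_counters[animal_id] = idx + 1
            trials.append(out.trial)
        annot["day"].append(day)
        annot["phase"].append(phase.name.value)
        annot["n_pokes"].append(len(pk))
        annot["door_opened"].append(out.door_opened)
        annot["puff"].append(out.puff)
        annot["trial_initiated"].append(out.trial is not None)

    annotated = visits.reset_index(drop=True).assign(**annot)
    return trials_to_frame(trials), annotated
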