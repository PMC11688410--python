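"""Synthetic cohort generator.

Produces event datasets with the statistical structure the analysis
assumes: circadian (dark/light) Poisson visit arrival, genotype-specific
water-seeking motivation, a constant premature-poke hazard ``h`` during
the pre-cue delay, and an exponential cue-response latency with rate
``r`` after LED onset. Under this model the per-trial outcome
probabilities are available in closed form, which gives the analytic
oracle used throughout the test suite:

    p_premature = 1 - exp(-h*D)
    p_correct   = exp(-h*D) * (1 - exp(-r*C))
    p_abandoned = exp(-h*D) * exp(-r*C)

The simulator replays the same corner contingencies as the task engine
and draws pre-cue delays from the same counter-based stream, so running
its event output back through :func:`icage.engine.run_session` with the
same seed reproduces the ground-truth trial table exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import Outcome, PrecueStream, TrialRecord, trials_to_frame
from .events import DAY_SECONDS, EventDataset
from .schedule import (
    CornerAssignment,
    DoorPolicy,
    Phase,
    Protocol,
    assign_corners,
    build_default_protocol,
)

CORNERS = (1, 2, 3, 4)


@dataclass(frozen=True)
class GenotypeParams:
    """Generative parameters of one genotype.

    visit_rate_dark / visit_rate_light
        Poisson visit intensities, visits per hour.
    p_poke
        Probability that a visit includes an approach to the nose port
        (at least one poke in poke-gated phases; drinking attempt in the
        free/door phases).
    lick_burst_mean
        Mean licks per rewarded visit (burst size is 1 + Poisson(mean-1)).
    premature_hazard
        Constant hazard ``h`` (1/s) of poking during the pre-cue delay.
    cue_response_rate
        Rate ``r`` (1/s) of the exponential response latency after LED onset.
    p_visit_assigned
        Probability that a visit targets the contingency corner (phases
        with an assigned corner); the rest spread uniformly elsewhere.
    """

    visit_rate_dark: float = 2.0
    visit_rate_light: float = 0.4
    p_poke: float = 0.85
    lick_burst_mean: float = 15.0
    premature_hazard: float = 0.05
    cue_response_rate: float = 1.2
    p_visit_assigned: float = 0.6

    def __post_init__(self) -> None:
        for name in ("visit_rate_dark", "visit_rate_light", "premature_hazard",
                     "cue_response_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_poke", "p_visit_assigned"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lick_burst_mean < 1:
            raise ValueError("lick_burst_mean must be >= 1")


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort run."""

    n_per_genotype: dict[str, int]
    params: dict[str, GenotypeParams]
    protocol: Protocol
    seed: int
    visit_duration_median: float = 10.0
    visit_duration_sigma: float = 0.6
    name: str = "custom"

    def __post_init__(self) -> None:
        for g, n in self.n_per_genotype.items():
            if n < 1:
                raise ValueError(f"n_per_genotype[{g}] must be >= 1")
            if g not in self.params:
                raise ValueError(f"missing params for genotype {g}")


def expected_outcome_fractions(h: float, r: float, D: float, C: float) -> tuple[float, float, float]:
    """Closed-form (p_premature, p_correct, p_abandoned) for one (D, C) cell."""
    if h < 0 or r < 0:
        raise ValueError("rates must be non-negative")
    if D <= 0 or C <= 0:
        raise ValueError("D and C must be positive")
    p_prem = 1.0 - math.exp(-h * D)
    p_corr = math.exp(-h * D) * (1.0 - math.exp(-r * C))
    p_aband = math.exp(-h * D) * math.exp(-r * C)
    return p_prem, p_corr, p_aband


def simulate_trial_outcomes(
    h: float, r: float, D: float, C: float, n: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Monte-Carlo draw of ``n`` trial outcomes from the generative model.

    Returns ``(n_premature, n_correct, n_abandoned)``. Same per-trial
    mechanism as :func:`simulate_cohort` (premature time Exp(h) against
    the delay, then response latency Exp(r) against the cue), vectorised
    for oracle checks at large n.
    """
    if h < 0 or r < 0 or D <= 0 or C <= 0:
        raise ValueError("invalid parameters")
    t_prem = rng.exponential(1.0 / h, n) if h > 0 else np.full(n, np.inf)
    t_resp = rng.exponential(1.0 / r, n) if r > 0 else np.full(n, np.inf)
    prem = t_prem < D
    corr = ~prem & (t_resp < C)
    n_prem = int(prem.sum())
    n_corr = int(corr.sum())
    return n_prem, n_corr, n - n_prem - n_corr


# ----------------------------------------------------------------------
# Scenarios
# ----------------------------------------------------------------------

def scenario_paper_like(seed: int) -> SimConfig:
    """Cohort of 14 NonTg vs 10 TG with the qualitative group signature:
    TG visit more (higher water seeking) but are more impulsive (higher
    premature hazard) and less attentive (lower cue-response rate), so
    NonTg collect more rewards/licks and a higher %Correct on the harder
    reaction-time tasks."""
    return SimConfig(
        n_per_genotype={"NonTg": 14, "TG": 10},
        params={
            "NonTg": GenotypeParams(
                visit_rate_dark=2.0, visit_rate_light=0.4, p_poke=0.85,
                lick_burst_mean=15.0, premature_hazard=0.05,
                cue_response_rate=1.2, p_visit_assigned=0.6,
            ),
            "TG": GenotypeParams(
                visit_rate_dark=2.6, visit_rate_light=0.6, p_poke=0.85,
                lick_burst_mean=15.0, premature_hazard=0.15,
                cue_response_rate=0.5, p_visit_assigned=0.6,
            ),
        },
        protocol=build_default_protocol(),
        seed=seed,
        name="paper_like",
    )


def scenario_null(seed: int, n_per_genotype: int = 8) -> SimConfig:
    """Both genotypes share identical parameters (type-I error studies)."""
    shared = GenotypeParams()
    return SimConfig(
        n_per_genotype={"NonTg": n_per_genotype, "TG": n_per_genotype},
        params={"NonTg": shared, "TG": shared},
        protocol=build_default_protocol(),
        seed=seed,
        name="null",
    )


SCENARIOS = {"paper_like": scenario_paper_like, "null": scenario_null}


# ----------------------------------------------------------------------
# Cohort simulation
# ----------------------------------------------------------------------

@dataclass
class SimResult:
    dataset: EventDataset
    trials: pd.DataFrame
    assignment: CornerAssignment
    config: SimConfig


def _roster(config: SimConfig) -> pd.DataFrame:
    rows = []
    for g in sorted(config.n_per_genotype):
        for i in range(config.n_per_genotype[g]):
            rows.append((f"{g}{i + 1:02d}", g, "C1", "active", np.nan))
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "cage_id", "status", "removal_day"])


def _exp_or_inf(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


class _Collector:
    """Accumulates event rows during simulation."""

    def __init__(self) -> None:
        self.visits: list[tuple] = []   # (animal_id, corner, t_start, t_end)
        self.pokes: list[tuple] = []    # (visit_key, side, t)
        self.licks: list[tuple] = []    # (visit_key, t, n_licks)


def _simulate_animal_day(
    animal_id: str,
    day: int,
    par: GenotypeParams,
    protocol: Protocol,
    assignment: CornerAssignment | None,
    stream: PrecueStream,
    trial_counter: dict[str, int],
    prev_end: dict[str, float],
    rng: np.random.Generator,
    col: _Collector,
    trials: list[TrialRecord],
    dur_median: float = 10.0,
    dur_sigma: float = 0.6,
) -> None:
    phase = protocol.phase_for_day(day)
    if phase.name == Phase.HOME_CAGE_DELAY:
        return
    day_lo = protocol.t0 + (day - 1) * DAY_SECONDS
    # light phase occupies the first 12 h of the protocol day (t0 at lights-on)
    half = DAY_SECONDS / 2.0
    n_light = rng.poisson(par.visit_rate_light * 12.0)
    n_dark = rng.poisson(par.visit_rate_dark * 12.0)
    starts = np.sort(np.concatenate([
        day_lo + rng.uniform(0.0, half, n_light),
        day_lo + half + rng.uniform(0.0, half, n_dark),
    ]))
    n = len(starts)
    if n == 0:
        return
    durations = rng.lognormal(math.log(dur_median), dur_sigma, n)
    corner_u = rng.random(n)
    corner_alt = rng.integers(0, 3, n)
    engaged = rng.random(n) < par.p_poke
    latencies = 0.3 + rng.exponential(1.0, n)

    assigned = assignment.corner_for_phase(animal_id, phase.name) if assignment else None
    window = phase.water
    in_window = lambda t: window.contains(t, protocol.t0, protocol.t0_clock)  # noqa: E731

    for i in range(n):
        t_start = max(float(starts[i]), prev_end[animal_id] + 0.5)
        if t_start >= day_lo + DAY_SECONDS:
            continue  # pushed out of its day by the non-overlap rule: drop
        t_end = t_start + float(durations[i])
        if assigned is not None:
            if corner_u[i] < par.p_visit_assigned:
                corner = assigned
            else:
                others = [c for c in CORNERS if c != assigned]
                corner = others[int(corner_alt[i])]
        else:
            corner = CORNERS[int(corner_u[i] * 4.0)]

        vkey = len(col.visits)
        pokes: list[float] = []
        door_t: float | None = None

        if phase.doors in (DoorPolicy.ALWAYS_OPEN, DoorPolicy.OPEN_ON_VISIT):
            if engaged[i]:
                door_t = t_start
        elif phase.doors == DoorPolicy.OPEN_ON_POKE:
            if engaged[i]:
                t_poke = t_start + float(latencies[i])
                pokes.append(t_poke)
                if in_window(t_poke):
                    door_t = t_poke
        elif phase.doors == DoorPolicy.ASSIGNED_ONLY:
            if engaged[i]:
                t_poke = t_start + float(latencies[i])
                pokes.append(t_poke)
                if corner == assigned and in_window(t_poke):
                    door_t = t_poke
        elif phase.doors == DoorPolicy.RT_CONTINGENCY:
            if engaged[i]:
                t_init = t_start + float(latencies[i])
                pokes.append(t_init)
                if corner == assigned:
                    idx = trial_counter.get(animal_id, 0)
                    trial_counter[animal_id] = idx + 1
                    D = stream.draw(animal_id, idx, phase.precue_set)
                    C = float(phase.cue_duration)
                    t_prem = _exp_or_inf(rng, par.premature_hazard)
                    t_resp_lat = _exp_or_inf(rng, par.cue_response_rate)
                    if t_prem < D:
                        outcome, t_resp = Outcome.PREMATURE, t_init + t_prem
                        pokes.append(t_resp)
                    elif t_resp_lat < C:
                        outcome, t_resp = Outcome.CORRECT, t_init + D + t_resp_lat
                        pokes.append(t_resp)
                    else:
                        outcome, t_resp = Outcome.ABANDONED, None
                    reward = outcome == Outcome.CORRECT and in_window(t_resp)
                    if reward:
                        door_t = t_resp
                    trials.append(TrialRecord(
                        animal_id=animal_id, visit_id=vkey, day_index=day,
                        t_init=t_init, precue=D, cue=C, outcome=outcome,
                        t_response=t_resp, reward=reward,
                    ))
        elif phase.doors == DoorPolicy.ALL_CLOSED:
            if engaged[i]:
                pokes.append(t_start + float(latencies[i]))
            # puff (avoidance) is implied by corner == assigned; no water ever
        else:  # pragma: no cover
            raise ValueError(f"no simulation policy for {phase.name}")

        if door_t is not None:
            n_licks = 1 + int(rng.poisson(par.lick_burst_mean - 1.0))
            t_lick = door_t + 0.3
            col.licks.append((vkey, t_lick, n_licks))
            t_end = max(t_end, t_lick + 0.5)
        if pokes:
            t_end = max(t_end, pokes[-1] + 0.5)
            for t_poke in pokes:
                side = "left" if rng.random() < 0.5 else "right"
                col.pokes.append((vkey, side, t_poke))
        col.visits.append((animal_id, corner, t_start, t_end))
        prev_end[animal_id] = t_end


def simulate_cohort(config: SimConfig, days: Sequence[int] | None = None) -> SimResult:
    """Simulate a cohort and return events plus the ground-truth trial table.

    ``days`` restricts simulation to a subset of protocol days (default:
    the whole calendar). The place-preference corner assignment is
    derived from the simulated adaptation visits when adaptation days are
    included, exactly as the real pipeline derives it; otherwise it falls
    back to the balanced tie-break assignment on zero counts.
    """
    rng = np.random.default_rng(config.seed)
    stream = PrecueStream(config.seed)
    protocol = config.protocol
    roster = _roster(config)
    animal_ids = roster["animal_id"].tolist()
    geno_of = dict(zip(roster["animal_id"], roster["genotype"]))

    all_days = sorted(days) if days is not None else list(protocol.day_range)
    for d in all_days:
        protocol.phase_for_day(d)  # raises on out-of-calendar days
    adapt_days = [d for d in all_days if protocol.phase_for_day(d).name in
                  (Phase.FREE_ADAPT, Phase.DOOR_ADAPT, Phase.NP_ADAPT, Phase.WD_ADAPT)]
    later_days = [d for d in all_days if d not in adapt_days]

    col = _Collector()
    trials: list[TrialRecord] = []
    trial_counter: dict[str, int] = {}
    prev_end = {a: -math.inf for a in animal_ids}

    def run_days(day_list: list[int], assignment: CornerAssignment | None) -> None:
        for animal_id in animal_ids:
            par = config.params[geno_of[animal_id]]
            for day in day_list:
                _simulate_animal_day(
                    animal_id, day, par, protocol, assignment, stream,
                    trial_counter, prev_end, rng, col, trials,
                    dur_median=config.visit_duration_median,
                    dur_sigma=config.visit_duration_sigma,
                )

    run_days(adapt_days, None)

    counts = pd.DataFrame(0, index=animal_ids, columns=list(CORNERS))
    for animal_id, corner, _, _ in col.visits:
        counts.loc[animal_id, corner] += 1
    assignment = assign_corners(counts, roster)

    run_days(later_days, assignment)

    visits = pd.DataFrame(col.visits, columns=["animal_id", "corner", "t_start", "t_end"])
    order = np.lexsort((np.arange(len(visits)), visits["t_start"].to_numpy())) if len(visits) else np.array([], dtype=int)
    id_map = {int(old): new + 1 for new, old in enumerate(order)}
    visits = visits.iloc[order].reset_index(drop=True)
    visits.insert(0, "visit_id", np.arange(1, len(visits) + 1, dtype=np.int64))

    pokes = pd.DataFrame(col.pokes, columns=["visit_id", "side", "t"])
    licks = pd.DataFrame(col.licks, columns=["visit_id", "t", "n_licks"])
    if len(pokes):
        pokes["visit_id"] = pokes["visit_id"].map(id_map).astype(np.int64)
    if len(licks):
        licks["visit_id"] = licks["visit_id"].map(id_map).astype(np.int64)

    dataset = EventDataset(
        animals=roster, visits=visits, pokes=pokes, licks=licks,
        t0=protocol.t0, lights_on=6.0, lights_off=18.0,
    ).validate()

    trial_df = trials_to_frame(trials)
    if len(trial_df):
        trial_df["visit_id"] = trial_df["visit_id"].map(id_map).astype(np.int64)
        trial_df = trial_df.sort_values("visit_id", kind="stable").reset_index(drop=True)
    return SimResult(dataset=dataset, trials=trial_df, assignment=assignment, config=config)
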